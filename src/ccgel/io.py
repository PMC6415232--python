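"""Tabular output: CSV and JSON record serialisation with stable formatting.

Floats are written at 12 significant digits in both formats, so the CSV and
JSON serialisations of the same run carry identical values and re-running a
deterministic sweep reproduces byte-identical files.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import pandas as pd

__all__ = ["format_value", "read_table", "write_table"]

_SIG_DIGITS = 12


def format_value(v):
    """Canonical serialised form: floats at 12 significant digits."""
    if isinstance(v, bool) or v is None:
        return v
    if isinstance(v, float):
        if math.isnan(v):
            return None
        return float(f"{v:.{_SIG_DIGITS}g}")
    return v


def _normalise_rows(rows) -> list[dict]:
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict(orient="records")
    out = []
    for r in rows:
        if hasattr(r, "to_record"):
            r = r.to_record()
        out.append({k: format_value(v) for k, v in r.items()})
    return out


def write_table(rows, path, fmt: str | None = None, *, columns=None) -> Path:
    """Write homogeneous records as CSV (RFC-4180 style, with header) or JSON.

    ``fmt`` defaults to the file suffix.  An empty row list still produces a
    header-only CSV when ``columns`` is given (or an empty JSON array).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    if fmt not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    records = _normalise_rows(rows)
    if columns is None:
        columns = list(records[0]) if records else []
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="raise")
            writer.writeheader()
            for rec in records:
                writer.writerow(rec)
    return path


def read_table(path, fmt: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    if fmt == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path)
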