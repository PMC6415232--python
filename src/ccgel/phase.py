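"""Parameter sweeps: branch maps over Bjerrum length, the bistable overlap
range, the funnel over spring constant, and collapse curves.

The bistable (transition) range of lB is bounded by the two Bjerrum lengths at
which a branch's equilibrium crosses the condensation threshold beq = z·lB:
the counterion-condensation branch first becomes valid at the lower edge, and
the Debye–Hückel branch loses validity at the upper edge.  Edges are located
by a coarse sweep for the sign change of beq − z·lB followed by Brent root
bracketing, which is robust to narrow ranges at large spring constants.

All sweeps are deterministic: re-running reproduces tables bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import ChainParams, SolventConditions, validity_window
from .equilibrium import DEFAULT_BRACKET, solve_branch, solve_collapse

__all__ = [
    "OverlapRange",
    "PhaseRow",
    "collapse_curve",
    "find_overlap_range",
    "funnel_map",
    "phase_table",
    "sweep_bjerrum",
]

COARSE_STEP = 0.05  # nm; coarse lB sweep resolution before bisection
EDGE_TOL = 1e-4  # nm; default tolerance on overlap edges


def _solvent_from_salt(salt, lB: float) -> SolventConditions:
    if isinstance(salt, SolventConditions):
        return salt.at_bjerrum(lB)
    return SolventConditions(bjerrum_length_nm=lB, salt_species=tuple(salt))


@dataclass(frozen=True)
class PhaseRow:
    """One lB cell of the phase map: both branch equilibria and bistability."""

    lB: float  # nm
    a: float  # nm^-2 (bare spring constant)
    t: float  # nm^-2
    salt: str
    dh_beq: float | None
    cc_beq: float | None
    dh_g: float | None
    cc_g: float | None
    bistable: bool

    def to_record(self) -> dict:
        return {
            "lB": self.lB, "a": self.a, "t": self.t, "salt": self.salt,
            "dh_beq": self.dh_beq, "cc_beq": self.cc_beq,
            "dh_g": self.dh_g, "cc_g": self.cc_g, "bistable": self.bistable,
        }


@dataclass(frozen=True)
class OverlapRange:
    """Bjerrum-length interval over which both branches hold valid minima."""

    lB_low: float | None  # nm; CC root crosses beq = z*lB here
    lB_high: float | None  # nm; DH root crosses beq = z*lB here
    a: float
    salt: str
    found: bool = True

    @property
    def width(self) -> float:
        return (self.lB_high - self.lB_low) if self.found else 0.0

    def to_record(self) -> dict:
        return {
            "a": self.a, "salt": self.salt, "found": self.found,
            "lB_low": self.lB_low, "lB_high": self.lB_high,
            "width": self.width if self.found else None,
        }


def sweep_bjerrum(
    chain: ChainParams,
    salt,
    lB_grid,
    *,
    bracket=DEFAULT_BRACKET,
) -> list[PhaseRow]:
    """Solve both branches at every lB of the grid (κ recomputed per lB).

    ``salt`` is either a list of (molar, valence) species or a
    :class:`~ccgel.core.SolventConditions` whose salt is reused.  Branch
    equilibria that are invalid on their side of z·lB are reported absent
    (None) in the row; ``bistable`` is set when both are present.
    """
    lB_grid = np.asarray(lB_grid, dtype=float)
    if np.any(lB_grid <= 0) or np.any(np.diff(lB_grid) <= 0):
        raise ValueError("lB_grid must be positive and strictly increasing")
    rows = []
    for lB in lB_grid:
        solvent = _solvent_from_salt(salt, float(lB))
        dh = solve_branch("dh", chain, solvent, bracket=bracket)
        cc = solve_branch("cc", chain, solvent, bracket=bracket)
        rows.append(
            PhaseRow(
                lB=float(lB), a=chain.a0, t=chain.t,
                salt=solvent.describe_salt(),
                dh_beq=dh.beq if dh.valid else None,
                cc_beq=cc.beq if cc.valid else None,
                dh_g=dh.g_at_beq if dh.valid else None,
                cc_g=cc.g_at_beq if cc.valid else None,
                bistable=bool(dh.valid and cc.valid),
            )
        )
    return rows


def sweep_spring(
    a_grid,
    salt,
    lB: float,
    *,
    z: int = 1,
    branch: str = "cc",
    bracket=DEFAULT_BRACKET,
) -> pd.DataFrame:
    """Equilibrium spacing vs spring constant at fixed Bjerrum length.

    Stiffer springs are stretched less by the bead-bead repulsion, so beq
    decreases monotonically with a on either branch; swelling is larger at
    lower salt (weaker screening).
    """
    solvent = _solvent_from_salt(salt, float(lB))
    records = []
    for a in np.asarray(a_grid, dtype=float):
        chain = ChainParams(z=z, a0=float(a), t=0.0)
        res = solve_branch(branch, chain, solvent, bracket=bracket)
        records.append(
            {
                "a": float(a), "lB": float(lB), "branch": res.branch,
                "salt": solvent.describe_salt(),
                "beq": res.beq, "g": res.g_at_beq, "valid": res.valid,
            }
        )
    return pd.DataFrame.from_records(records)


def phase_table(rows) -> pd.DataFrame:
    """Tidy DataFrame from PhaseRow / OverlapRange / record lists."""
    return pd.DataFrame([r.to_record() if hasattr(r, "to_record") else r for r in rows])


def _branch_excess(branch, chain, salt, lB, bracket):
    """Signed distance beq − z·lB of a branch root, or None if no root."""
    solvent = _solvent_from_salt(salt, lB)
    res = solve_branch(branch, chain, solvent, bracket=bracket)
    if res.beq is None:
        return None
    return res.beq - chain.z * lB


def find_overlap_range(
    chain: ChainParams,
    salt,
    lB_bracket: tuple[float, float] = (0.2, 5.0),
    tol: float = EDGE_TOL,
    *,
    bracket=DEFAULT_BRACKET,
) -> OverlapRange:
    """Locate the bistable lB interval by root-finding on beq(lB) − z·lB.

    A coarse sweep (step ≤ 0.05 nm) finds where each branch's root crosses
    the threshold line; each crossing is then refined to ``tol`` with Brent's
    method.  If no bistability exists anywhere in ``lB_bracket`` an explicit
    not-found result is returned rather than raising.
    """
    lo, hi = lB_bracket
    if not (0 < lo < hi):
        raise ValueError(f"invalid lB bracket {lB_bracket}")
    n = max(int(np.ceil((hi - lo) / COARSE_STEP)) + 1, 8)
    grid = np.linspace(lo, hi, n)
    salt_desc = _solvent_from_salt(salt, grid[0]).describe_salt()

    def edge(branch):
        f = lambda lB: _branch_excess(branch, chain, salt, lB, bracket)
        prev_lB, prev_v = None, None
        for lB in grid:
            v = f(lB)
            if v is not None and prev_v is not None and prev_v * v <= 0:
                if v == 0:
                    return float(lB)
                return float(brentq(f, prev_lB, lB, xtol=tol))
            if v is not None:
                prev_lB, prev_v = lB, v
        return None

    # CC root crosses from above (beq > z*lB at small lB) to below at the
    # lower edge; DH root crosses from above to below at the upper edge.
    lB_low = edge("cc")
    lB_high = edge("dh")
    if lB_low is None or lB_high is None or lB_low >= lB_high:
        return OverlapRange(
            lB_low=None, lB_high=None, a=chain.a0, salt=salt_desc, found=False
        )
    return OverlapRange(
        lB_low=lB_low, lB_high=lB_high, a=chain.a0, salt=salt_desc, found=True
    )


def funnel_map(
    a_grid,
    salt,
    lB_bracket: tuple[float, float] = (0.05, 5.0),
    *,
    z: int = 1,
    tol: float = EDGE_TOL,
) -> list[OverlapRange]:
    """Overlap range per spring constant: the funnel of the transition region.

    As the springs stiffen the bistable interval narrows and slides toward
    the origin along the beq = lB diagonal, tapering to a point for very
    strong springs.
    """
    out = []
    for a in a_grid:
        chain = ChainParams(z=z, a0=float(a), t=0.0)
        out.append(find_overlap_range(chain, salt, lB_bracket, tol))
    return out


def collapse_curve(
    a0: float,
    t_values,
    salt,
    lB_grid,
    *,
    z: int = 1,
    method: str = "composite",
) -> pd.DataFrame:
    """Collapse curves beq(lB) for each stiffening strength t.

    One row per (t, lB): equilibrium spacing with the condensed-counterion
    spring stiffening a = a0 + (1/8e) t (lB/b), the effective spring constant
    at the solution, and whether lB/beq lies inside the condensed-layer
    validity window.  t = 0 shows only the mild passive contraction; large t
    drives sharp contraction from the condensation threshold onward.
    """
    lB_grid = np.asarray(lB_grid, dtype=float)
    lo_w, hi_w = validity_window()
    records = []
    for t in t_values:
        chain = ChainParams(z=z, a0=a0, t=float(t))
        for lB in lB_grid:
            solvent = _solvent_from_salt(salt, float(lB))
            res = solve_collapse(
                chain, solvent, method=method, warn_window=False
            )
            ratio = (lB / res.beq) if res.beq else np.nan
            records.append(
                {
                    "t": float(t), "lB": float(lB), "beq": res.beq,
                    "a_effective": res.a_effective, "lB_over_b": ratio,
                    "in_window": bool(lo_w < ratio < hi_w),
                    "valid": res.valid, "message": res.message,
                }
            )
    return pd.DataFrame.from_records(records)
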