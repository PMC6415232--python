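"""Equilibrium solvers: branch roots, profiles, bistability, collapse."""

import numpy as np
import pytest

from ccgel import (
    ChainParams,
    ModelDomainError,
    SolventConditions,
    free_energy_profile,
    g_cc,
    g_dh,
    is_bistable,
    salt_1_1,
    solve_branch,
    solve_collapse,
)
from ccgel.equilibrium import BeadSpringGel

from conftest import SALT_001, SALT_0001, grid_argmin


def _solvent(lB, salt=SALT_001):
    return SolventConditions(bjerrum_length_nm=lB, salt_species=salt)


class TestSolveBranch:
    def test_stretched_branch_in_transition_range(self, chain, solvent_lb2):
        res = solve_branch("dh", chain, solvent_lb2)
        assert res.valid and res.branch == "DH"
        assert res.beq == pytest.approx(2.5, abs=0.1)
        assert res.beq > solvent_lb2.lB

    def test_contracted_branch_in_transition_range(self, chain, solvent_lb2):
        res = solve_branch("cc", chain, solvent_lb2)
        assert res.valid and res.branch == "CC"
        assert res.beq == pytest.approx(1.7, abs=0.1)
        assert res.beq < solvent_lb2.lB

    def test_contracted_branch_terminates_at_threshold(self, chain):
        # at the lower edge of the printed overlap range the CC root sits on
        # the beq = lB line
        res = solve_branch("cc", chain, _solvent(1.60))
        assert res.beq == pytest.approx(1.60, abs=0.02)

    @pytest.mark.parametrize(
        "branch, a, lB",
        [
            ("dh", 0.1, 2.0), ("cc", 0.1, 2.0), ("dh", 1.0, 0.8),
            ("cc", 1.0, 1.5), ("dh", 5.0, 0.6), ("cc", 0.1, 10.0),
            ("cc", 0.5, 1.7),
        ],
    )
    def test_root_agrees_with_dense_grid_oracle(self, branch, a, lB):
        chain = ChainParams(z=1, a0=a)
        solvent = _solvent(lB)
        res = solve_branch(branch, chain, solvent)
        kappa = solvent.kappa()
        if branch == "dh":
            f = lambda b: g_dh(b, a, lB, kappa)
        else:
            f = lambda b: g_cc(b, a, 1, lB, kappa)
        assert res.beq == pytest.approx(grid_argmin(f), abs=1e-6)
        # beq is a strict local minimum
        assert f(res.beq) < min(f(res.beq - 1e-4), f(res.beq + 1e-4))

    def test_stiffer_springs_stretch_less(self):
        # both branches, at lB values where each is the physical one
        for branch, lB in (("dh", 2.0), ("cc", 1.7)):
            beqs = [
                solve_branch(branch, ChainParams(z=1, a0=a), _solvent(lB)).beq
                for a in (0.05, 0.1, 0.5, 1.0, 2.0)
            ]
            assert np.all(np.diff(beqs) < 0)

    def test_lower_salt_swells_more(self):
        for branch, lB in (("cc", 1.7), ("dh", 2.0)):
            chain = ChainParams(z=1, a0=0.5 if branch == "cc" else 0.1)
            low = solve_branch(branch, chain, _solvent(lB, SALT_0001)).beq
            high = solve_branch(branch, chain, _solvent(lB, SALT_001)).beq
            assert low > high

    def test_wrong_side_root_flagged_not_raised(self, chain):
        # far below the transition range the CC stationary point falls above
        # z*lB, where condensation cannot occur
        res = solve_branch("cc", chain, _solvent(1.0))
        assert res.beq is not None and not res.valid
        assert "wrong side" in res.message

    def test_stiffening_chain_rejected(self, solvent_lb2):
        with pytest.raises(ModelDomainError):
            solve_branch("cc", ChainParams(z=1, a0=0.1, t=4.0), solvent_lb2)

    def test_unknown_branch_rejected(self, chain, solvent_lb2):
        with pytest.raises(ValueError):
            solve_branch("xx", chain, solvent_lb2)


class TestFreeEnergyProfile:
    def test_double_well_inside_transition_range(self, chain, solvent_lb2):
        prof = free_energy_profile(chain, solvent_lb2, np.linspace(0.5, 6.0, 1101))
        assert len(prof.minima) == 2
        (b1, _), (b2, _) = prof.minima
        assert b1 < prof.junction < b2
        assert prof.maximum is not None
        assert prof.maximum[0] == prof.junction == 2.0

    def test_minima_match_branch_roots(self, chain, solvent_lb2):
        grid = np.linspace(0.5, 6.0, 2201)
        prof = free_energy_profile(chain, solvent_lb2, grid)
        cc = solve_branch("cc", chain, solvent_lb2).beq
        dh = solve_branch("dh", chain, solvent_lb2).beq
        spacing = grid[1] - grid[0]
        assert prof.minima[0][0] == pytest.approx(cc, abs=spacing)
        assert prof.minima[1][0] == pytest.approx(dh, abs=spacing)

    def test_single_minimum_below_transition_range(self, chain):
        prof = free_energy_profile(chain, _solvent(1.0), np.linspace(0.3, 6.0, 1101))
        assert len(prof.minima) == 1
        assert prof.minima[0][0] > prof.junction  # DH side
        assert prof.maximum is None

    def test_samples_equal_direct_branch_calls(self, chain, solvent_lb2):
        prof = free_energy_profile(chain, solvent_lb2, np.linspace(0.5, 6.0, 101))
        kappa = solvent_lb2.kappa()
        for b, g, label in zip(prof.b[::17], prof.g[::17], prof.branch[::17]):
            if label == "CC":
                assert g == g_cc(b, 0.1, 1, 2.0, kappa)
            else:
                assert g == g_dh(b, 0.1, 2.0, kappa)

    def test_grid_must_span_junction(self, chain, solvent_lb2):
        with pytest.raises(ModelDomainError):
            free_energy_profile(chain, solvent_lb2, np.linspace(2.5, 6.0, 50))


class TestBistability:
    @pytest.mark.parametrize(
        "lB, expected", [(2.0, True), (1.0, False), (3.0, False)]
    )
    def test_transition_range_membership(self, chain, lB, expected):
        bistable, dh, cc = is_bistable(chain, _solvent(lB))
        assert bistable is expected
        if bistable:
            assert dh.beq > lB > cc.beq


class TestSolveCollapse:
    def test_no_stiffening_reproduces_plain_branch(self, solvent_lb2):
        chain = ChainParams(z=1, a0=0.1, t=0.0)
        plain = solve_branch("cc", ChainParams(z=1, a0=0.1), solvent_lb2)
        for method in ("composite", "iterative"):
            res = solve_collapse(chain, solvent_lb2, method=method)
            assert res.beq == pytest.approx(plain.beq, abs=1e-9)

    def test_composite_root_agrees_with_dense_grid_oracle(self):
        chain = ChainParams(z=1, a0=0.1, t=50.0)
        solvent = _solvent(5.0)
        res = solve_collapse(chain, solvent, warn_window=False)
        kappa = solvent.kappa()
        f = lambda b: g_cc(b, 0.1, 1, 5.0, kappa) + 50.0 * 5.0 * b / (16 * np.e)
        assert res.beq == pytest.approx(grid_argmin(f), abs=1e-6)

    def test_contraction_monotone_in_stiffening(self):
        solvent = _solvent(5.0)
        beqs = [
            solve_collapse(
                ChainParams(z=1, a0=0.1, t=t), solvent, warn_window=False
            ).beq
            for t in (0.0, 4.0, 50.0)
        ]
        assert beqs[0] > beqs[1] > beqs[2]

    def test_effective_constant_reported_at_solution(self):
        chain = ChainParams(z=1, a0=0.1, t=4.0)
        res = solve_collapse(chain, _solvent(5.0), warn_window=False)
        expected = 0.1 + 4.0 * (5.0 / res.beq) / (8 * np.e)
        assert res.a_effective == pytest.approx(expected, rel=1e-12)

    def test_bracket_bound_hit_is_reported(self, solvent_lb2):
        chain = ChainParams(z=1, a0=0.1, t=50.0)
        res = solve_collapse(chain, solvent_lb2, bracket=(1.5, 3.0))
        assert not res.valid
        assert "collapsed to bound" in res.message

    def test_iterative_converges_to_frozen_spring_fixed_point(self):
        # at the fixed point, beq minimises g_cc with the effective constant
        chain = ChainParams(z=1, a0=0.1, t=4.0)
        solvent = _solvent(5.0)
        res = solve_collapse(chain, solvent, method="iterative", warn_window=False)
        frozen = solve_branch(
            "cc", ChainParams(z=1, a0=res.a_effective), solvent
        )
        assert res.beq == pytest.approx(frozen.beq, abs=1e-6)


class TestBeadSpringGel:
    def test_facade_matches_module_functions(self, chain, solvent_lb2):
        gel = BeadSpringGel(chain, solvent_lb2)
        assert gel.solve_branch("dh").beq == solve_branch("dh", chain, solvent_lb2).beq
        bistable, _, _ = gel.is_bistable()
        assert bistable

    def test_solve_picks_lower_free_energy_state(self, chain, solvent_lb2):
        gel = BeadSpringGel(chain, solvent_lb2)
        res = gel.solve()
        _, dh, cc = gel.is_bistable()
        assert res.g_at_beq == min(dh.g_at_beq, cc.g_at_beq)

    def test_summary_mentions_branch_and_spacing(self, chain, solvent_lb2):
        text = BeadSpringGel(chain, solvent_lb2).solve().summary()
        assert "beq" in text and "branch" in text
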