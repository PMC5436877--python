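import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamellosc.bifurcation import (BifurcationKind, LVRegime, RegimeMapMethod,
                                   accessible_lv_region, ecm_regime_map,
                                   lv_regime, sweep_1d, sweep_ecm_LE1)
from lamellosc.dynamics import simulate, simulate_system
from lamellosc.models import ecm_competition_system, gtpase_toggle_system
from lamellosc.params import ModelTag, ModelVariant, ParameterSet

pos = st.floats(min_value=0.05, max_value=5.0, allow_nan=False)


class TestLVRegime:
    def test_k09_path_is_bistable_throughout(self):
        """With L_E1 + L_E2 = 0.9 < l_c both exclusion states stay stable."""
        for L1 in np.linspace(0.05, 0.85, 17):
            r = lv_regime(1.0, 1.0, L1, 0.9 - L1, 1.0, 1.0)
            assert r is LVRegime.I_BISTABLE

    def test_coexistence_when_contraction_dominates(self):
        assert lv_regime(1.0, 1.0, 2.0, 2.0, 1.0) is LVRegime.IV_COEXIST
        # cross-check by simulation: both lamellipods persist
        sys = ecm_competition_system(1.0, 1.0, 2.0, 2.0, 1.0)
        traj = simulate_system(sys, [0.9, 0.1], t_end=200.0, n_out=100)
        assert min(traj.states[-1]) > 0.05

    def test_transcritical_boundary(self):
        assert lv_regime(1.0, 1.0, 1.0, 0.5, 1.0) is LVRegime.BOUNDARY

    def test_exclusion_regimes(self):
        # lamellipod with the weaker contraction wins
        assert lv_regime(1.0, 1.0, 0.5, 2.0, 1.0) is LVRegime.II_LAM1_WINS
        assert lv_regime(1.0, 1.0, 2.0, 0.5, 1.0) is LVRegime.III_LAM2_WINS

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lv_regime(0.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            lv_regime(1.0, 1.0, 1.0, 1.0, -0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(A1=pos, A2=pos, L1=pos, L2=pos, lc=pos, eps=pos)
    def test_exhaustive_and_consistent_with_invasion_eigenvalues(
            self, A1, A2, L1, L2, lc, eps):
        """Every positive coefficient combination gets a label consistent
        with the numerically computed boundary eigenvalues."""
        r = lv_regime(A1, A2, L1, L2, lc, eps)
        assert r in LVRegime
        if r is LVRegime.BOUNDARY:
            return
        sys = ecm_competition_system(A1, A2, L1, L2, lc, eps)
        inv2 = np.linalg.eigvals(sys.jac(np.array([eps * A1 / L1, 0.0])))
        inv1 = np.linalg.eigvals(sys.jac(np.array([0.0, eps * A2 / L2]))).real
        can2 = np.max(inv2.real) > 0
        can1 = np.max(inv1) > 0
        expected = {(False, False): LVRegime.I_BISTABLE,
                    (True, True): LVRegime.IV_COEXIST,
                    (True, False): LVRegime.II_LAM1_WINS,
                    (False, True): LVRegime.III_LAM2_WINS}[(can1, can2)]
        assert r is expected


class TestAccessibleRegion:
    def test_direct_substitution(self, model1b):
        params, _ = model1b
        p = params.with_(k_rho=0.0, gamma_rho=1.0, rho_T=2.0)
        assert accessible_lv_region(p)["max_LE_sum"] == pytest.approx(2.0)
        p = params.with_(k_rho=0.1, gamma_rho=1.5, rho_T=2.0)
        assert accessible_lv_region(p)["max_LE_sum"] == pytest.approx(3.2)

    def test_bound_holds_along_trajectories(self, model1b):
        """Simulated contraction strengths never exceed the conservation
        bound on L_E(rho_1) + L_E(rho_2)."""
        params, variant = model1b
        bound = accessible_lv_region(params)["max_LE_sum"]
        traj = simulate(params, variant, t_end=300.0, n_out=600)
        L1 = params.k_rho + params.gamma_rho * traj.component("rho1")
        L2 = params.k_rho + params.gamma_rho * traj.component("rho2")
        assert np.max(L1 + L2) <= bound + 1e-9


class TestSweeps:
    def test_constrained_competition_sweep_transcriticals(self):
        """K = 1.5 path: the bistable segment is flanked by transcritical
        points at L_E1 = 0.5 and L_E1 = l_c = 1."""
        res = sweep_ecm_LE1(K=1.5)
        tc = sorted(p.parameter_value for p in res.points
                    if p.kind is BifurcationKind.TRANSCRITICAL)
        assert len(tc) == 2
        assert tc[0] == pytest.approx(0.5, abs=1e-3)
        assert tc[1] == pytest.approx(1.0, abs=1e-3)

    def test_toggle_fold_pair_bounds_bistable_interval(self):
        def make(b):
            return gtpase_toggle_system(2.0, b, 3, 1.0)

        res = sweep_1d(make, "b_rho", 0.5, 5.0, n_steps=91, hi_box=6.0)
        folds = sorted(p.parameter_value for p in res.points
                       if p.kind is BifurcationKind.FOLD)
        assert len(folds) == 2
        lo, hi = folds
        assert 1.0 < lo < hi < 5.0
        # inside the interval: 2 stable states; outside: 1
        from lamellosc.equilibria import find_system_equilibria

        def n_stable(b):
            eqs = find_system_equilibria(make(b), n_starts=24, seed=0, hi=6.0)
            return sum(e.is_stable for e in eqs)

        assert n_stable(0.5 * (lo + hi)) == 2
        assert n_stable(lo - 0.3) == 1
        assert n_stable(hi + 0.3) == 1

    def test_sweep_precondition(self):
        def make(b):
            return gtpase_toggle_system(2.0, b, 3, 1.0)

        with pytest.raises(ValueError):
            sweep_1d(make, "b_rho", 2.0, 1.0)
        with pytest.raises(ValueError):
            sweep_1d(make, "b_rho", 1.0, 2.0, n_steps=10)


class TestRegimeMaps:
    def test_analytic_map_has_four_quadrant_regimes(self):
        grid = np.array([0.5, 1.5])
        rm = ecm_regime_map(grid, grid, l_c=1.0)
        assert rm.labels[0, 0] == LVRegime.I_BISTABLE.value
        assert rm.labels[1, 1] == LVRegime.IV_COEXIST.value
        assert rm.labels[0, 1] == LVRegime.III_LAM2_WINS.value  # L1 high, L2 low
        assert rm.labels[1, 0] == LVRegime.II_LAM1_WINS.value

    def test_numeric_map_agrees_with_analytic_off_boundary(self):
        grid = np.linspace(0.2, 3.8, 11)  # avoids the ratio = 1 boundaries
        analytic = ecm_regime_map(grid, grid, method=RegimeMapMethod.ANALYTIC_LV)
        numeric = ecm_regime_map(grid, grid,
                                 method=RegimeMapMethod.EQUILIBRIUM_COUNT)
        agree = (analytic.labels == numeric.labels).mean()
        assert agree >= 0.99

    def test_dataframe_shape(self):
        grid = np.linspace(0.5, 2.0, 4)
        rm = ecm_regime_map(grid, grid)
        df = rm.to_dataframe()
        assert len(df) == 16
        assert set(df.columns) == {"L_E1/A_E1", "L_E2/A_E2", "label"}
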