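import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamellosc.dynamics import Trajectory, mirror_trajectory, simulate
from lamellosc.phenotype import (PhenotypeLabel, Thresholds, classify_point,
                                 classify_trajectory, polarity_index)
from lamellosc.params import ModelTag, ModelVariant, ParameterSet

LABELS6 = ("R1", "rho1", "E1", "R2", "rho2", "E2")


def synthetic_oscillation(period: float, offset_frac: float, n_periods: int = 20,
                          n_out: int = 4000, amp: float = 0.5, base: float = 1.0):
    """Exact sinusoidal E1/E2 pair with known period and phase offset."""
    t = np.linspace(0.0, period * n_periods, n_out)
    E1 = base + amp * np.sin(2 * np.pi * t / period)
    E2 = base + amp * np.sin(2 * np.pi * (t / period - offset_frac))
    states = np.column_stack([0 * t + 0.5, 0 * t + 0.5, E1,
                              0 * t + 0.5, 0 * t + 0.5, E2])
    return Trajectory(t, states, LABELS6)


class TestMetrics:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(period=st.floats(5.0, 80.0), offset=st.floats(0.4, 0.6))
    def test_sinusoid_metrics_within_one_percent(self, period, offset):
        traj = synthetic_oscillation(period, offset)
        res = classify_trajectory(traj)
        assert res.label is PhenotypeLabel.OSC_ANTIPHASE
        assert res.metrics.period == pytest.approx(period, rel=0.01)
        assert res.metrics.phase_offset_fraction == pytest.approx(offset, abs=0.01)

    def test_in_phase_oscillation_is_osc_other(self):
        traj = synthetic_oscillation(20.0, 0.05)
        res = classify_trajectory(traj)
        assert res.label is PhenotypeLabel.OSC_OTHER

    def test_antiphase_amplitudes(self):
        traj = synthetic_oscillation(20.0, 0.5, amp=0.3)
        res = classify_trajectory(traj)
        assert res.metrics.amplitude_1 == pytest.approx(0.6, rel=0.02)
        assert res.metrics.n_periods_observed >= 5


class TestSteadyStates:
    def test_constant_symmetric_is_apolar(self):
        t = np.linspace(0, 100, 200)
        states = np.tile([0.5, 0.5, 0.8, 0.5, 0.5, 0.8], (200, 1))
        res = classify_trajectory(Trajectory(t, states, LABELS6))
        assert res.label is PhenotypeLabel.APOLAR_COEXIST
        assert res.polarity_index == 0.0

    def test_constant_asymmetric_is_polarized(self):
        t = np.linspace(0, 100, 200)
        states = np.tile([1.2, 0.1, 1.5, 0.1, 1.0, 0.2], (200, 1))
        res = classify_trajectory(Trajectory(t, states, LABELS6))
        assert res.label is PhenotypeLabel.POLARIZED_1
        res2 = classify_trajectory(
            mirror_trajectory(Trajectory(t, states, LABELS6)))
        assert res2.label is PhenotypeLabel.POLARIZED_2

    def test_too_short_trajectory_rejected(self):
        t = np.linspace(0, 1, 10)
        states = np.tile([0.5] * 6, (10, 1))
        with pytest.raises(ValueError):
            classify_trajectory(Trajectory(t, states, LABELS6))


class TestModelTrajectories:
    def test_antiphase_has_negative_zero_lag_correlation(self, hybrid):
        params, variant = hybrid
        traj = simulate(params, variant, t_end=6000.0, n_out=3000)
        res = classify_trajectory(traj)
        assert res.label is PhenotypeLabel.OSC_ANTIPHASE
        half = len(traj) // 2
        E1 = traj.component("E1")[half:]
        E2 = traj.component("E2")[half:]
        E1 = E1 - np.polyval(np.polyfit(traj.times[half:], E1, 1), traj.times[half:])
        E2 = E2 - np.polyval(np.polyfit(traj.times[half:], E2, 1), traj.times[half:])
        assert np.corrcoef(E1, E2)[0, 1] < 0

    def test_mirror_consistency_on_model_output(self, hybrid):
        params, variant = hybrid
        traj = simulate(params, variant, t_end=4000.0, n_out=2000)
        a = classify_trajectory(traj)
        b = classify_trajectory(mirror_trajectory(traj))
        swap = {PhenotypeLabel.POLARIZED_1: PhenotypeLabel.POLARIZED_2,
                PhenotypeLabel.POLARIZED_2: PhenotypeLabel.POLARIZED_1}
        assert b.label is swap.get(a.label, a.label)


class TestClassifyPoint:
    def test_competition_regime_i_is_bistable_polar(self):
        """Frozen competition in the bistable regime: initial bias decides
        the winner, so paired runs polarize oppositely."""
        p = ParameterSet(n=1, delta=1.0, b_R=1.0, k_E=1.0, gamma_E=0.0,
                         k_R=1.0, gamma_R=0.0, k_rho=0.8, gamma_rho=0.0,
                         eps=1.0, l_c=1.0)
        res = classify_point(p, ModelVariant(ModelTag.M1A), t_end=400.0,
                             n_out=400)
        assert res.label is PhenotypeLabel.BISTABLE_POLAR

    def test_competition_regime_iv_is_apolar(self):
        p = ParameterSet(n=1, delta=1.0, b_R=1.0, k_E=1.0, gamma_E=0.0,
                         k_R=1.0, gamma_R=0.0, k_rho=2.0, gamma_rho=0.0,
                         eps=1.0, l_c=1.0)
        res = classify_point(p, ModelVariant(ModelTag.M1A), t_end=400.0,
                             n_out=400)
        assert res.label is PhenotypeLabel.APOLAR_COEXIST

    def test_oscillatory_point_agrees_from_both_starts(self, hybrid):
        params, variant = hybrid
        res = classify_point(params, variant, t_end=6000.0, n_out=3000)
        assert res.label is PhenotypeLabel.OSC_ANTIPHASE
        assert res.diagnostics["labels"] == ["OSC_ANTIPHASE", "OSC_ANTIPHASE"]
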