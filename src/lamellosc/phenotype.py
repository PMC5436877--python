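"""Dynamical phenotype classification of model trajectories.

A trajectory is mapped onto the cell states observed experimentally:
persistent polarization (one lamellipod wins), apolar coexistence (both
lamellipods persist, identified with the "random" phenotype), and sustained
antiphase oscillation (the lamellipods alternate half a period apart).
Classification of a parameter point runs paired simulations from a slightly
E1-biased initial condition and its mirror image, which also detects
bistable polarity (opposite winners from mirrored starts).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .dynamics import Trajectory, default_initial_state, simulate
from .models import build_system, mirror_state
from .params import ModelVariant, ParameterSet

__all__ = [
    "PhenotypeLabel", "OscillationMetrics", "Thresholds",
    "PhenotypeResult", "classify_trajectory", "classify_point",
    "polarity_index", "is_oscillatory", "is_polarized",
]


class PhenotypeLabel(str, enum.Enum):
    APOLAR_COEXIST = "APOLAR_COEXIST"
    POLARIZED_1 = "POLARIZED_1"
    POLARIZED_2 = "POLARIZED_2"
    BISTABLE_POLAR = "BISTABLE_POLAR"
    OSC_ANTIPHASE = "OSC_ANTIPHASE"
    OSC_OTHER = "OSC_OTHER"
    UNCLASSIFIED = "UNCLASSIFIED"


def is_polarized(label: PhenotypeLabel) -> bool:
    return label in (PhenotypeLabel.POLARIZED_1, PhenotypeLabel.POLARIZED_2,
                     PhenotypeLabel.BISTABLE_POLAR)


def is_oscillatory(label: PhenotypeLabel) -> bool:
    return label in (PhenotypeLabel.OSC_ANTIPHASE, PhenotypeLabel.OSC_OTHER)


@dataclass
class OscillationMetrics:
    """Summary of a sustained oscillation in the lamellipod signals."""

    period: float
    amplitude_1: float
    amplitude_2: float
    phase_offset_fraction: float  # E2 peaks relative to E1 peaks, in periods
    n_periods_observed: int
    period_cv: float


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (the defaults are the package's own choices;
    no quantitative phenotype criteria are inherited from experiments)."""

    polarity_index: float = 0.2       # |E1-E2|/(E1+E2) above which a steady
                                      # state counts as polarized
    steady_rhs_norm: float = 1e-6     # terminal |rhs| below which the state
                                      # is treated as stationary
    peak_prominence_frac: float = 0.01  # peak prominence, fraction of mean
    min_periods: int = 5
    max_period_cv: float = 0.05
    min_amplitude_ratio: float = 0.9  # last/first cycle amplitude (non-decay)
    antiphase_window: tuple = (0.35, 0.65)
    transient_fraction: float = 0.5   # fraction of trajectory discarded


@dataclass
class PhenotypeResult:
    label: PhenotypeLabel
    polarity_index: float
    metrics: Optional[OscillationMetrics] = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"label": self.label.value, "polarity_index": self.polarity_index}
        if self.metrics is not None:
            out["metrics"] = vars(self.metrics).copy()
        out.update(self.diagnostics)
        return out


def polarity_index(E1: float, E2: float) -> float:
    tot = E1 + E2
    return abs(E1 - E2) / tot if tot > 0 else 0.0


def _cycle_amplitudes(signal: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Peak-to-trough amplitude of each full cycle (between adjacent peaks)."""
    amps = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = signal[a:b + 1]
        amps.append(seg.max() - seg.min())
    return np.asarray(amps)


def classify_trajectory(traj: Trajectory,
                        thresholds: Thresholds = Thresholds()) -> PhenotypeResult:
    """Classify a single trajectory.

    The first ``transient_fraction`` of the trajectory is discarded.  If the
    terminal right-hand side is numerically zero the state is stationary and
    labeled by its polarity index; otherwise sustained oscillations are
    detected from peaks of E1 and E2 and labeled antiphase when the two
    lamellipods peak close to half a period apart.
    """
    th = thresholds
    n = len(traj)
    start = int(n * th.transient_fraction)
    if n - start < 8:
        raise ValueError("trajectory too short for the transient window")
    t = traj.times[start:]
    E1 = traj.component("E1")[start:]
    E2 = traj.component("E2")[start:]
    final = traj.states[-1]

    pol = polarity_index(float(E1[-1]), float(E2[-1]))
    diagnostics: dict = {}

    if traj.params is not None and traj.variant is not None:
        f = build_system(traj.params, traj.variant).f
        rhs_norm = float(np.max(np.abs(f(final))))
    else:
        # fall back to a discrete time derivative estimate
        dt = t[-1] - t[-2]
        rhs_norm = float(np.max(np.abs(traj.states[-1] - traj.states[-2])) / dt)
    diagnostics["terminal_rhs_norm"] = rhs_norm

    if rhs_norm < th.steady_rhs_norm:
        if pol > th.polarity_index:
            label = (PhenotypeLabel.POLARIZED_1 if E1[-1] > E2[-1]
                     else PhenotypeLabel.POLARIZED_2)
        else:
            label = PhenotypeLabel.APOLAR_COEXIST
        return PhenotypeResult(label, pol, diagnostics=diagnostics)

    # oscillation detection on the analysis window
    prom1 = th.peak_prominence_frac * max(float(np.mean(E1)), 1e-12)
    prom2 = th.peak_prominence_frac * max(float(np.mean(E2)), 1e-12)
    pk1, _ = find_peaks(E1, prominence=prom1)
    pk2, _ = find_peaks(E2, prominence=prom2)
    diagnostics["n_peaks_E1"] = int(len(pk1))
    diagnostics["n_peaks_E2"] = int(len(pk2))
    # period statistics come from the channel with more detected peaks, so
    # that relabeling the lamellipods cannot change the verdict
    sig, pk = (E2, pk2) if len(pk2) > len(pk1) else (E1, pk1)

    if len(pk) >= 2:
        intervals = np.diff(t[pk])
        period = float(np.mean(intervals))
        cv = float(np.std(intervals) / period) if period > 0 else np.inf
        n_periods = len(intervals)
        amps = _cycle_amplitudes(sig, pk)
        amps1 = _cycle_amplitudes(E1, pk1) if len(pk1) >= 2 else np.array([0.0])
        amps2 = _cycle_amplitudes(E2, pk2) if len(pk2) >= 2 else np.array([0.0])
        amp_ratio = float(amps[-1] / amps[0]) if amps[0] > 0 else 0.0
        sustained = (n_periods >= th.min_periods and cv < th.max_period_cv
                     and amp_ratio > th.min_amplitude_ratio)
        diagnostics.update(period_cv=cv, amplitude_ratio=amp_ratio)
        if sustained:
            # phase of E2 peaks relative to the preceding E1 peak
            offsets = []
            for tp in t[pk2]:
                prev = t[pk1][t[pk1] <= tp]
                if len(prev):
                    offsets.append(((tp - prev[-1]) / period) % 1.0)
            offset = float(np.mean(offsets)) if offsets else 0.0
            metrics = OscillationMetrics(
                period=period,
                amplitude_1=float(amps1.max()),
                amplitude_2=float(amps2.max()),
                phase_offset_fraction=offset,
                n_periods_observed=n_periods,
                period_cv=cv,
            )
            lo, hi = th.antiphase_window
            label = (PhenotypeLabel.OSC_ANTIPHASE if lo <= offset <= hi
                     else PhenotypeLabel.OSC_OTHER)
            return PhenotypeResult(label, pol, metrics=metrics,
                                   diagnostics=diagnostics)

    return PhenotypeResult(PhenotypeLabel.UNCLASSIFIED, pol,
                           diagnostics=diagnostics)


def classify_point(params: ParameterSet, variant: ModelVariant, seed: int = 0,
                   t_end: float = 3000.0, n_out: int = 3000,
                   e_bias: float = 0.01, e_base: float = 0.5,
                   thresholds: Thresholds = Thresholds(),
                   rel_tol: float = 1e-8, abs_tol: float = 1e-10,
                   ) -> PhenotypeResult:
    """Classify a parameter point via paired (biased + mirrored) simulations.

    Opposite polarization from the two starts yields BISTABLE_POLAR;
    agreement yields the common label; any other disagreement is reported as
    UNCLASSIFIED with both labels in the diagnostics.
    """
    init = default_initial_state(params, variant, e_bias=e_bias,
                                 e_base=e_base, seed=seed)
    from .models import state_labels
    labels = state_labels(variant)
    init_m = mirror_state(init, labels)

    results = []
    for y0 in (init, init_m):
        traj = simulate(params, variant, init=y0, t_end=t_end, n_out=n_out,
                        rel_tol=rel_tol, abs_tol=abs_tol)
        results.append(classify_trajectory(traj, thresholds))
    a, b = results

    pair = {a.label, b.label}
    if pair == {PhenotypeLabel.POLARIZED_1, PhenotypeLabel.POLARIZED_2}:
        return PhenotypeResult(PhenotypeLabel.BISTABLE_POLAR,
                               0.5 * (a.polarity_index + b.polarity_index),
                               metrics=a.metrics,
                               diagnostics={"labels": [a.label.value, b.label.value]})
    if a.label == b.label:
        return PhenotypeResult(a.label,
                               0.5 * (a.polarity_index + b.polarity_index),
                               metrics=a.metrics or b.metrics,
                               diagnostics={"labels": [a.label.value, b.label.value]})
    return PhenotypeResult(PhenotypeLabel.UNCLASSIFIED,
                           0.5 * (a.polarity_index + b.polarity_index),
                           diagnostics={"labels": [a.label.value, b.label.value],
                                        "reason": "paired runs disagree"})
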