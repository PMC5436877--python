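"""Numerical integration of the lamellipod models.

Relaxation dynamics in these models feature sharp transitions between
slowly drifting plateaus, so a stiff-capable integrator (LSODA) with tight
tolerances is the default.  Output is sampled on a uniform grid decoupled
from the internal steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import System, build_system, mirror_state, state_labels
from .params import ModelVariant, ParameterSet, validate

__all__ = [
    "Trajectory", "IntegrationError", "simulate", "simulate_system",
    "default_initial_state", "conservation_error", "mirror_trajectory",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time t = {last_time:g})")
        self.last_time = last_time


@dataclass
class Trajectory:
    """Uniformly sampled solution of one model run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_out, dim)
    labels: tuple[str, ...]
    params: Optional[ParameterSet] = None
    variant: Optional[ModelVariant] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states must have matching length")

    def __len__(self) -> int:
        return len(self.times)

    def component(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(),
                   df.drop(columns="time").to_numpy(),
                   tuple(c for c in df.columns if c != "time"))


def default_initial_state(params: ParameterSet, variant: ModelVariant,
                          e_bias: float = 0.01, e_base: float = 0.5,
                          seed: Optional[int] = None) -> np.ndarray:
    """Near-symmetric initial condition with a small ECM asymmetry.

    Lamellipod 1 starts with contact level ``e_base * (1 + e_bias)`` and
    lamellipod 2 with ``e_base * (1 - e_bias)``; GTPase levels start equal
    (a quarter of the total each for conserved variants) so the eventual
    polarity direction is decided by the dynamics, not by a large bias.
    A seed adds a tiny reproducible jitter to break residual symmetry.
    """
    R = 0.25 * params.R_T if variant.conserved else 0.5
    rho = 0.25 * params.rho_T if variant.conserved else 0.5
    y = {"R1": R, "R2": R, "rho1": rho, "rho2": rho,
         "E1": e_base * (1.0 + e_bias), "E2": e_base * (1.0 - e_bias)}
    if variant.conserved:
        y["RI"] = params.R_T - 2 * R
        y["rhoI"] = params.rho_T - 2 * rho
    if variant.has_effectors:
        y.update({"w1": R, "w2": R, "c1": rho, "c2": rho})
    labels = state_labels(variant)
    out = np.array([y[lab] for lab in labels], dtype=float)
    if seed is not None:
        rng = np.random.default_rng(seed)
        jitter = 1.0 + 1e-4 * rng.standard_normal(out.size)
        out = out * jitter
    return out


def simulate_system(system: System, init: Sequence[float], t_end: float,
                    n_out: int = 1000, rel_tol: float = DEFAULT_RTOL,
                    abs_tol: float = DEFAULT_ATOL, t_start: float = 0.0,
                    method: str = "LSODA") -> Trajectory:
    """Integrate an arbitrary ``System`` on a uniform output grid.

    A transient undershoot below ``-abs_tol`` (the positive orthant is
    analytically invariant) triggers one retry at 100x tighter tolerance
    before failing.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if not (0 < rel_tol < 1 and 0 < abs_tol < 1):
        raise ValueError("tolerances must lie in (0, 1)")
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (system.dim,):
        raise ValueError(f"initial state must have shape ({system.dim},)")

    t_eval = np.linspace(t_start, t_end, n_out)

    def attempt(rtol: float, atol: float):
        return solve_ivp(lambda t, y: system.f(y), (t_start, t_end), y0,
                         method=method, t_eval=t_eval, rtol=rtol, atol=atol)

    sol = attempt(rel_tol, abs_tol)
    if sol.success and sol.y.min() < -abs_tol:
        sol = attempt(rel_tol * 1e-2, abs_tol * 1e-2)
        if sol.success and sol.y.min() < -abs_tol:
            raise IntegrationError("state left the positive orthant beyond tolerance",
                                   float(sol.t[-1]))
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t_start
        raise IntegrationError(f"integration failed: {sol.message}", last)

    states = sol.y.T.copy()
    # round tiny negative excursions (within tolerance) back to the orthant
    np.clip(states, 0.0, None, out=states)
    return Trajectory(sol.t.copy(), states, system.labels)


def simulate(params: ParameterSet, variant: ModelVariant,
             init: Optional[Sequence[float]] = None, t_end: float = 1000.0,
             n_out: int = 1000, rel_tol: float = DEFAULT_RTOL,
             abs_tol: float = DEFAULT_ATOL, method: str = "LSODA",
             seed: Optional[int] = None) -> Trajectory:
    """Integrate a model variant; ``init`` defaults to the near-symmetric state."""
    validate(params, variant).raise_if_invalid()
    system = build_system(params, variant)
    if init is None:
        init = default_initial_state(params, variant, seed=seed)
    traj = simulate_system(system, init, t_end, n_out=n_out,
                           rel_tol=rel_tol, abs_tol=abs_tol, method=method)
    traj.params = params
    traj.variant = variant
    return traj


def conservation_error(traj: Trajectory) -> tuple[float, float]:
    """Max deviation of the Rac and Rho totals along a conserved trajectory."""
    if traj.params is None or traj.variant is None or not traj.variant.conserved:
        raise ValueError("conservation_error requires a conserved-variant trajectory")
    rac = traj.component("R1") + traj.component("R2") + traj.component("RI")
    rho = traj.component("rho1") + traj.component("rho2") + traj.component("rhoI")
    return (float(np.abs(rac - traj.params.R_T).max()),
            float(np.abs(rho - traj.params.rho_T).max()))


def mirror_trajectory(traj: Trajectory) -> Trajectory:
    """Trajectory with lamellipods 1 and 2 relabeled."""
    return Trajectory(traj.times.copy(),
                      mirror_state(traj.states, traj.labels),
                      traj.labels, traj.params, traj.variant)
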