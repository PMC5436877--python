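"""Bifurcation analysis: branch sweeps, regime maps, and the closed-form
Lotka-Volterra regime classification of the isolated competition submodel.

The isolated ECM (lamellipod-competition) submodel

    dE_k/dt = eps * A_Ek * E_k - E_k * (L_Ek * E_k + l_c * E_j)

is classic two-species competition.  Its exclusion equilibria sit at
E_k* = eps * A_Ek / L_Ek, and lamellipod j can invade the k-wins state iff
its boundary growth rate eps*A_Ej - l_c*E_k* is positive.  The four regimes
(bistable polarity, exclusion either way, coexistence) follow from the two
invasion eigenvalues; the regime boundaries are transcritical bifurcations.

One-parameter sweeps use natural-parameter continuation: equilibria at each
step seed the root search at the next, branches are matched by nearest
neighbor, and sign changes of the leading eigenvalue real part are refined
by bisection and labeled Hopf (complex pair) or transcritical (real
eigenvalue on a persisting branch); branch terminations are refined to fold
points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .equilibria import (Equilibrium, Stability, classify_stability,
                         fd_jacobian, find_system_equilibria, _newton_polish)
from .models import System, ecm_competition_system, reduced_system
from .params import ModelVariant, ParameterSet

__all__ = [
    "LVRegime", "BifurcationKind", "BifurcationPoint", "Branch", "SweepResult",
    "RegimeMap", "RegimeMapMethod", "lv_regime", "accessible_lv_region",
    "sweep_1d", "sweep_parameter", "sweep_ecm_LE1", "ecm_regime_map",
    "regime_map_2d",
]


class LVRegime(str, enum.Enum):
    I_BISTABLE = "I_BISTABLE"
    II_LAM1_WINS = "II_LAM1_WINS"
    III_LAM2_WINS = "III_LAM2_WINS"
    IV_COEXIST = "IV_COEXIST"
    BOUNDARY = "BOUNDARY"


def lv_regime(A_E1: float, A_E2: float, L_E1: float, L_E2: float,
              l_c: float, eps: float = 1.0,
              boundary_tol: float = 1e-12) -> LVRegime:
    """Closed-form regime of the isolated competition submodel.

    Computed from the invasion eigenvalues of the two exclusion equilibria:
    lamellipod j invades the k-wins state iff eps*A_Ej - l_c*(eps*A_Ek/L_Ek)
    is positive.  Neither invades -> bistable polarity; both -> coexistence;
    exactly one -> competitive exclusion by that lamellipod.
    """
    if min(A_E1, A_E2, L_E1, L_E2) <= 0:
        raise ValueError("A_E and L_E must be positive")
    if l_c < 0:
        raise ValueError("l_c must be non-negative")
    inv2 = eps * A_E2 - l_c * (eps * A_E1 / L_E1)  # 2 invading the 1-wins state
    inv1 = eps * A_E1 - l_c * (eps * A_E2 / L_E2)  # 1 invading the 2-wins state
    if abs(inv1) <= boundary_tol or abs(inv2) <= boundary_tol:
        return LVRegime.BOUNDARY
    if inv1 > 0 and inv2 > 0:
        return LVRegime.IV_COEXIST
    if inv1 < 0 and inv2 < 0:
        return LVRegime.I_BISTABLE
    return LVRegime.II_LAM1_WINS if inv2 < 0 else LVRegime.III_LAM2_WINS


def accessible_lv_region(params: ParameterSet) -> dict:
    """Conservation bound on total contraction for the linear-feedback model.

    With L_E(rho) = k_rho + gamma_rho * rho linear and rho_1 + rho_2 <= rho_T,
    the sum L_E(rho_1) + L_E(rho_2) can never exceed
    2*k_rho + gamma_rho*rho_T, which carves the coexistence corner out of the
    competition parameter plane when the bound is below 2*l_c.
    """
    if params.rho_T is None:
        raise ValueError("accessible_lv_region requires a conserved parameter set")
    bound = 2.0 * params.k_rho + params.gamma_rho * params.rho_T
    return {"max_LE_sum": bound, "excludes_coexistence": bound < 2.0 * params.l_c}


# --- one-parameter sweeps --------------------------------------------------

class BifurcationKind(str, enum.Enum):
    HOPF = "HOPF"
    FOLD = "FOLD"
    TRANSCRITICAL = "TRANSCRITICAL"


@dataclass
class BifurcationPoint:
    kind: BifurcationKind
    parameter_name: str
    parameter_value: float
    state: np.ndarray
    leading_eigenvalues: np.ndarray

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "parameter_name": self.parameter_name,
                "parameter_value": float(self.parameter_value),
                "state": [float(x) for x in self.state],
                "leading_eigenvalues": [[float(e.real), float(e.imag)]
                                        for e in np.atleast_1d(self.leading_eigenvalues)]}


@dataclass
class Branch:
    """One continuation branch: aligned parameter values and equilibria."""
    values: list = field(default_factory=list)
    equilibria: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SweepResult:
    parameter_name: str
    branches: list
    points: list  # BifurcationPoint

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for bid, br in enumerate(self.branches):
            for v, eq in zip(br.values, br.equilibria):
                lead = eq.leading_eigenvalue
                row = {"parameter": v, "branch": bid,
                       "stability": eq.stability.value,
                       "lead_re": lead.real, "lead_im": lead.imag}
                for lab, x in zip(eq.labels, eq.state):
                    row[lab] = x
                rows.append(row)
        return pd.DataFrame(rows)


def _leading_re(eq: Equilibrium) -> float:
    return float(np.max(eq.eigenvalues.real))


def _match(prev_states: np.ndarray, new_states: np.ndarray,
           zero_tol: float = 1e-5) -> list:
    """Greedy nearest-neighbor matching (indices into new for each prev).

    Roots on different boundary faces (differing zero-component patterns)
    are penalized so that, near a transcritical crossing, a boundary branch
    keeps its boundary root instead of capturing a nearby interior one.
    """
    out = [-1] * len(prev_states)
    if len(new_states) == 0:
        return out
    d = np.linalg.norm(prev_states[:, None, :] - new_states[None, :, :], axis=-1)
    prev_zero = prev_states < zero_tol
    new_zero = new_states < zero_tol
    pattern_mismatch = (prev_zero[:, None, :] != new_zero[None, :, :]).any(axis=-1)
    d = d + 1e3 * pattern_mismatch * (d < 0.1)  # only near-collisions need it
    used = set()
    for _ in range(min(len(prev_states), len(new_states))):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if not np.isfinite(d[i, j]):
            break
        out[i] = j
        used.add(j)
        d[i, :] = np.inf
        d[:, j] = np.inf
    return out


def _continue_root(make_system: Callable[[float], System], value: float,
                   guess: np.ndarray, residual_tol: float = 1e-9
                   ) -> Optional[Equilibrium]:
    """Polish a single equilibrium at the given parameter value from a guess."""
    system = make_system(value)
    root = _newton_polish(system, np.atleast_2d(guess))[0]
    if not np.isfinite(root).all():
        return None
    res = float(np.max(np.abs(system.f(root))))
    if res > residual_tol or root.min() < -1e-8:
        return None
    root = np.clip(root, 0.0, None)
    J = system.jac(root) if system.jac is not None else fd_jacobian(system.f, root)
    ev = np.linalg.eigvals(J)
    return Equilibrium(root, ev, classify_stability(ev), res, system.labels)


def sweep_1d(make_system: Callable[[float], System], parameter_name: str,
             lo: float, hi: float, n_steps: int = 101, n_starts: int = 24,
             seed: int = 0, dedup_tol: float = 1e-5, hi_box: float = 2.0,
             bisect_tol: float = 1e-6, match_tol: float = 0.25) -> SweepResult:
    """Natural-parameter continuation over [lo, hi] with bifurcation detection.

    At each step the previous step's equilibria seed the root search along
    with fresh multistarts.  Eigenvalue sign changes along a persisting
    branch are bisected to ``bisect_tol`` in the parameter and labeled HOPF
    (complex leading pair) or TRANSCRITICAL (real); branch ends are bisected
    on root existence and labeled FOLD.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if n_steps < 50:
        raise ValueError("n_steps must be >= 50")
    values = np.linspace(lo, hi, n_steps)
    branches: list[Branch] = []
    active: list[Branch] = []
    points: list[BifurcationPoint] = []

    for step, v in enumerate(values):
        system = make_system(v)
        extra = (np.array([b.equilibria[-1].state for b in active])
                 if active else None)
        eqs = find_system_equilibria(system, n_starts=n_starts,
                                     seed=seed + step, dedup_tol=dedup_tol,
                                     hi=hi_box, extra_starts=extra)
        if not active:
            for eq in eqs:
                br = Branch([v], [eq])
                branches.append(br)
                active.append(br)
            continue

        prev_states = np.array([b.equilibria[-1].state for b in active])
        new_states = np.array([e.state for e in eqs]) if eqs else np.empty((0, system.dim))
        assign = _match(prev_states, new_states)
        taken = set(a for a in assign if a >= 0)
        still_active = []
        for bi, br in enumerate(active):
            j = assign[bi]
            dist = (np.max(np.abs(prev_states[bi] - new_states[j]))
                    if j >= 0 else np.inf)
            scale = max(1.0, np.max(np.abs(prev_states[bi])))
            if j >= 0 and dist < match_tol * scale:
                prev_eq = br.equilibria[-1]
                new_eq = eqs[j]
                re_a, re_b = _leading_re(prev_eq), _leading_re(new_eq)
                za, zb = abs(re_a) <= 1e-9, abs(re_b) <= 1e-9
                if re_a * re_b < 0 and not (za or zb):
                    pt = _refine_eig_crossing(make_system, parameter_name,
                                              br.values[-1], v, prev_eq,
                                              bisect_tol)
                    if pt is not None:
                        points.append(pt)
                elif za != zb:
                    # the crossing sits exactly on a grid point
                    eq0, v0 = (prev_eq, br.values[-1]) if za else (new_eq, v)
                    ev = eq0.eigenvalues
                    lead = ev[np.argsort(-ev.real)][:2]
                    kind = (BifurcationKind.HOPF if abs(lead[0].imag) > 1e-6
                            else BifurcationKind.TRANSCRITICAL)
                    points.append(BifurcationPoint(kind, parameter_name, v0,
                                                   eq0.state, lead))
                br.values.append(v)
                br.equilibria.append(new_eq)
                still_active.append(br)
            else:
                pt = _refine_fold(make_system, parameter_name, br.values[-1],
                                  v, br.equilibria[-1], bisect_tol)
                if pt is not None:
                    points.append(pt)
        for j, eq in enumerate(eqs):
            if j not in taken:
                br = Branch([v], [eq])
                branches.append(br)
                still_active.append(br)
                if step > 0:
                    # a branch born mid-sweep disappears toward lower values:
                    # refine its turning point as a fold
                    pt = _refine_fold(make_system, parameter_name, v,
                                      values[step - 1], eq, bisect_tol)
                    if pt is not None:
                        points.append(pt)
        active = still_active

    # merge duplicates; a fold coinciding with a transcritical is the same
    # crossing seen from a terminating branch, keep the transcritical label
    uniq: list[BifurcationPoint] = []
    order = {BifurcationKind.HOPF: 0, BifurcationKind.TRANSCRITICAL: 1,
             BifurcationKind.FOLD: 2}
    for pt in sorted(points, key=lambda p: order[p.kind]):
        if not any(abs(p.parameter_value - pt.parameter_value) < 50 * bisect_tol
                   and np.max(np.abs(p.state - pt.state)) < 0.05
                   for p in uniq):
            uniq.append(pt)
    uniq.sort(key=lambda p: p.parameter_value)
    return SweepResult(parameter_name, branches, uniq)


def _refine_eig_crossing(make_system, name: str, v_lo: float, v_hi: float,
                         eq_lo: Equilibrium, tol: float) -> Optional[BifurcationPoint]:
    """Bisect the parameter at which the branch's leading real part crosses 0."""
    state = eq_lo.state
    f_lo = _leading_re(eq_lo)
    a, b = v_lo, v_hi
    eq_mid = eq_lo
    while b - a > tol:
        m = 0.5 * (a + b)
        eq = _continue_root(make_system, m, state)
        if eq is None:
            b = m
            continue
        state = eq.state
        eq_mid = eq
        if _leading_re(eq) * np.sign(f_lo) > 0:
            a = m
        else:
            b = m
    ev = eq_mid.eigenvalues
    lead = ev[np.argsort(-ev.real)][:2]
    kind = (BifurcationKind.HOPF if abs(lead[0].imag) > 1e-6
            else BifurcationKind.TRANSCRITICAL)
    return BifurcationPoint(kind, name, 0.5 * (a + b), eq_mid.state, lead)


def _refine_fold(make_system, name: str, v_exist: float, v_absent: float,
                 eq_exist: Equilibrium, tol: float) -> Optional[BifurcationPoint]:
    """Bisect the parameter at which a branch ceases to exist (fold).

    ``v_exist`` carries the branch, ``v_absent`` does not; either ordering
    of the two values is accepted.
    """
    state = eq_exist.state
    eq_last = eq_exist
    direction = np.sign(v_absent - v_exist)
    span = abs(v_absent - v_exist)
    while abs(v_absent - v_exist) > tol:
        m = 0.5 * (v_exist + v_absent)
        eq = _continue_root(make_system, m, state)
        # the continued root must stay near the branch, not jump elsewhere
        if eq is not None and np.max(np.abs(eq.state - state)) < 0.5 * max(1.0, np.max(np.abs(state))):
            v_exist = m
            state = eq.state
            eq_last = eq
        else:
            v_absent = m
    v_star = 0.5 * (v_exist + v_absent)
    # distinguish a true fold (the branch is annihilated) from a transcritical
    # crossing, where the locally colliding branches persist beyond the point:
    # the latter is reported by the surviving branch's eigenvalue crossing,
    # so no point is emitted here
    probe = v_star + direction * max(100 * tol, 0.02 * span)
    eq_probe = _continue_root(make_system, probe, state)
    persists = (eq_probe is not None and
                np.max(np.abs(eq_probe.state - state)) < 0.2 * max(1.0, np.max(np.abs(state))))
    if persists:
        return None
    ev = eq_last.eigenvalues
    lead = ev[np.argsort(-ev.real)][:1]
    return BifurcationPoint(BifurcationKind.FOLD, name, v_star,
                            eq_last.state, lead)


def sweep_parameter(params: ParameterSet, variant: ModelVariant, name: str,
                    lo: float, hi: float, n_steps: int = 101, **kw) -> SweepResult:
    """Sweep a ParameterSet field for a full model variant (reduced coords)."""

    def make(v: float) -> System:
        return reduced_system(params.with_(**{name: v}), variant)

    hi_box = max(2.0, params.R_T or 0.0, params.rho_T or 0.0)
    return sweep_1d(make, name, lo, hi, n_steps, hi_box=hi_box, **kw)


def sweep_ecm_LE1(K: float, A_E1: float = 1.0, A_E2: float = 1.0,
                  l_c: float = 1.0, eps: float = 1.0, lo: float = 0.1,
                  hi: Optional[float] = None, n_steps: int = 141,
                  **kw) -> SweepResult:
    """Constrained competition sweep: L_E1 varies with L_E1 + L_E2 = K fixed."""
    if hi is None:
        hi = K - 0.1
    if not (0 < lo < hi < K):
        raise ValueError("sweep range must satisfy 0 < lo < hi < K")

    def make(L_E1: float) -> System:
        return ecm_competition_system(A_E1, A_E2, L_E1, K - L_E1, l_c, eps)

    hi_box = max(2.0, 2.0 * eps * max(A_E1, A_E2) / lo)
    return sweep_1d(make, "L_E1", lo, hi, n_steps, hi_box=hi_box, **kw)


# --- two-parameter regime maps --------------------------------------------

class RegimeMapMethod(str, enum.Enum):
    ANALYTIC_LV = "ANALYTIC_LV"
    EQUILIBRIUM_COUNT = "EQUILIBRIUM_COUNT"
    SIMULATION_CLASSIFIER = "SIMULATION_CLASSIFIER"


@dataclass
class RegimeMap:
    x_param: str
    y_param: str
    x_values: np.ndarray
    y_values: np.ndarray
    labels: np.ndarray  # dtype=object, shape (len(y), len(x))
    method: RegimeMapMethod

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (len(self.y_values), len(self.x_values)):
            raise ValueError("label matrix shape must match the grids")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{self.x_param: x, self.y_param: y,
                 "label": self.labels[iy, ix]}
                for iy, y in enumerate(self.y_values)
                for ix, x in enumerate(self.x_values)]
        return pd.DataFrame(rows)


def _lv_label_from_equilibria(eqs: Sequence[Equilibrium],
                              tol: float = 1e-6) -> str:
    stable = [e for e in eqs if e.is_stable]
    excl1 = [e for e in stable if e.state[0] > tol and e.state[1] <= tol]
    excl2 = [e for e in stable if e.state[1] > tol and e.state[0] <= tol]
    coex = [e for e in stable if e.state[0] > tol and e.state[1] > tol]
    if coex:
        return LVRegime.IV_COEXIST.value
    if excl1 and excl2:
        return LVRegime.I_BISTABLE.value
    if excl1:
        return LVRegime.II_LAM1_WINS.value
    if excl2:
        return LVRegime.III_LAM2_WINS.value
    return LVRegime.BOUNDARY.value


def ecm_regime_map(x_ratios: np.ndarray, y_ratios: np.ndarray,
                   l_c: float = 1.0, A_E1: float = 1.0, A_E2: float = 1.0,
                   eps: float = 1.0,
                   method: RegimeMapMethod = RegimeMapMethod.ANALYTIC_LV,
                   n_starts: int = 12, seed: int = 0) -> RegimeMap:
    """Regime map of the isolated competition submodel.

    Axes are the contraction/protrusion ratios L_E1/A_E1 (x) and
    L_E2/A_E2 (y), as in the four-regime competition diagram; the analytic
    regime boundaries are the transcritical lines where each ratio equals
    l_c / A_E of the opposite lamellipod.
    """
    x_ratios = np.asarray(x_ratios, dtype=float)
    y_ratios = np.asarray(y_ratios, dtype=float)
    labels = np.empty((len(y_ratios), len(x_ratios)), dtype=object)
    for iy, ry in enumerate(y_ratios):
        for ix, rx in enumerate(x_ratios):
            L1, L2 = rx * A_E1, ry * A_E2
            if method is RegimeMapMethod.ANALYTIC_LV:
                labels[iy, ix] = lv_regime(A_E1, A_E2, L1, L2, l_c, eps).value
            elif method is RegimeMapMethod.EQUILIBRIUM_COUNT:
                sys = ecm_competition_system(A_E1, A_E2, L1, L2, l_c, eps)
                box = 2.0 * eps * max(A_E1 / L1, A_E2 / L2)
                eqs = find_system_equilibria(sys, n_starts=n_starts, seed=seed,
                                             hi=box)
                labels[iy, ix] = _lv_label_from_equilibria(eqs)
            else:
                raise ValueError("ecm_regime_map supports ANALYTIC_LV or "
                                 "EQUILIBRIUM_COUNT")
    return RegimeMap("L_E1/A_E1", "L_E2/A_E2", x_ratios, y_ratios, labels, method)


def regime_map_2d(params: ParameterSet, variant: ModelVariant, x_param: str,
                  y_param: str, x_values: np.ndarray, y_values: np.ndarray,
                  method: RegimeMapMethod = RegimeMapMethod.SIMULATION_CLASSIFIER,
                  seed: int = 0, t_end: float = 6000.0, n_out: int = 3000,
                  ) -> RegimeMap:
    """Phenotype map of a full model variant over a 2-parameter grid.

    Each grid point is classified by paired simulations (a slightly biased
    initial condition and its mirror image), which distinguishes bistable
    polarity from single-sided polarization.
    """
    if method is not RegimeMapMethod.SIMULATION_CLASSIFIER:
        raise ValueError("full-model regime maps use SIMULATION_CLASSIFIER; "
                         "use ecm_regime_map for the isolated submodel")
    from .phenotype import classify_point
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    labels = np.empty((len(y_values), len(x_values)), dtype=object)
    for iy, y in enumerate(y_values):
        for ix, x in enumerate(x_values):
            p = params.with_(**{x_param: x, y_param: y})
            res = classify_point(p, variant, seed=seed, t_end=t_end, n_out=n_out)
            labels[iy, ix] = res.label.value
    return RegimeMap(x_param, y_param, x_values, y_values, labels, method)
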