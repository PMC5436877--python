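"""Right-hand sides of the two-lamellipod models and their isolated submodels.

For each lamellipod k (with j the other one) the generic dimensionless form is

    dR_k/dt   = b_R / (1 + rho_k^n) * R_I  -  delta * R_k
    drho_k/dt = b_rho(E_k) / (1 + R_k^n) * rho_I  -  rho_k
    dE_k/dt   = eps * (B_E + A_E * E_k)  -  E_k * (L_E * E_k + l_c * E_j)

with the ECM input to Rho activation b_rho(E), the protrusion terms B_E/A_E
and the contraction term L_E taking linear (M1 family) or Hill (M2/M3)
forms.  Conserved variants carry the inactive pools R_I, rho_I as explicit
dynamic variables so that the totals are a testable first integral; for
equilibrium work a reduced form with the pools eliminated algebraically is
also provided.

All state functions are vectorized over leading array dimensions: a state
array of shape (..., dim) yields a derivative of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .params import ModelTag, ModelVariant, ParameterSet, validate

__all__ = [
    "System", "state_labels", "state_dim", "rho_activation_input", "rhs",
    "build_system", "reduced_system", "expand_reduced_state",
    "ecm_competition_system", "gtpase_toggle_system",
    "conserved_toggle_system", "mirror_state",
]


@dataclass(frozen=True)
class System:
    """A first-order ODE system dy/dt = f(y) with named components.

    ``f`` must accept arrays of shape (..., dim).  ``jac``, if provided,
    returns the (..., dim, dim) Jacobian; otherwise finite differences are
    used downstream.
    """

    f: Callable[[np.ndarray], np.ndarray]
    dim: int
    labels: tuple[str, ...]
    name: str = ""
    jac: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __call__(self, y: np.ndarray) -> np.ndarray:
        return self.f(np.asarray(y, dtype=float))


# --- state layout ----------------------------------------------------------

_BASE = ("R1", "rho1", "E1", "R2", "rho2", "E2")
_POOLS = ("RI", "rhoI")
_EFFECTORS = ("w1", "c1", "w2", "c2")


def state_labels(variant: ModelVariant, reduced: bool = False) -> tuple[str, ...]:
    """Component names of the state vector, in integration order."""
    labels = list(_BASE)
    if variant.conserved and not reduced:
        labels += _POOLS
    if variant.has_effectors:
        labels += _EFFECTORS
    return tuple(labels)


def state_dim(variant: ModelVariant, reduced: bool = False) -> int:
    return len(state_labels(variant, reduced))


def mirror_state(y: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Relabel lamellipods 1 <-> 2 (exchange symmetry of the model)."""
    y = np.asarray(y, dtype=float)
    idx = []
    labels = list(labels)
    for lab in labels:
        if lab.endswith("1"):
            idx.append(labels.index(lab[:-1] + "2"))
        elif lab.endswith("2"):
            idx.append(labels.index(lab[:-1] + "1"))
        else:
            idx.append(labels.index(lab))
    return y[..., idx]


# --- kinetic pieces --------------------------------------------------------

def _hill3(x: np.ndarray, x0: float) -> np.ndarray:
    x3 = x * x * x
    return x3 / (x0 ** 3 + x3)


def rho_activation_input(params: ParameterSet, variant: ModelVariant, Ek):
    """ECM input to Rho activation, b_rho(E_k).

    Linear ``k_E + gamma_E * E`` for the M1 family; saturating Hill form
    ``k_E + gamma_E * E^3 / (E0^3 + E^3)`` for M2/M3.
    """
    Ek = np.asarray(Ek, dtype=float)
    if np.any(Ek < 0):
        raise ValueError("ECM level must be non-negative")
    if variant.hill_kinetics:
        return params.k_E + params.gamma_E * _hill3(Ek, params.E0)
    return params.k_E + params.gamma_E * Ek


# --- full model right-hand side -------------------------------------------

def rhs(params: ParameterSet, variant: ModelVariant, y: np.ndarray,
        check: bool = False) -> np.ndarray:
    """Time derivative of the full state for any variant.

    With ``check=True`` the parameter set is validated against the variant
    and negative state components are rejected.
    """
    if check:
        validate(params, variant).raise_if_invalid()
        if np.any(np.asarray(y) < 0):
            raise ValueError("state components must be non-negative")
    sys = build_system(params, variant)
    return sys.f(np.asarray(y, dtype=float))


def _make_rhs(params: ParameterSet, variant: ModelVariant,
              reduced: bool) -> Callable[[np.ndarray], np.ndarray]:
    p = params
    n = p.n
    conserved = variant.conserved
    hill = variant.hill_kinetics
    effectors = variant.has_effectors
    ecm_to_rac = variant.ecm_to_rac
    pool_offset = 6

    def f(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        R1, rho1, E1, R2, rho2, E2 = (y[..., i] for i in range(6))
        if conserved:
            if reduced:
                RI = p.R_T - R1 - R2
                rhoI = p.rho_T - rho1 - rho2
            else:
                RI = y[..., pool_offset]
                rhoI = y[..., pool_offset + 1]
        else:
            RI = rhoI = 1.0
        if effectors:
            off = pool_offset if reduced else pool_offset + 2
            w1, c1, w2, c2 = (y[..., off + i] for i in range(4))
            srcR1, srcrho1, srcR2, srcrho2 = w1, c1, w2, c2
        else:
            srcR1, srcrho1, srcR2, srcrho2 = R1, rho1, R2, rho2

        bR1 = bR2 = p.b_R
        if ecm_to_rac:
            bR1 = p.b_R * (1.0 + p.gamma_ER * _hill3(E1, p.E0))
            bR2 = p.b_R * (1.0 + p.gamma_ER * _hill3(E2, p.E0))

        if hill:
            brho1 = p.k_E + p.gamma_E * _hill3(E1, p.E0)
            brho2 = p.k_E + p.gamma_E * _hill3(E2, p.E0)
            BE1 = p.k_R + p.gamma_R * _hill3(R1, p.R0)
            BE2 = p.k_R + p.gamma_R * _hill3(R2, p.R0)
            AE1 = AE2 = 0.0
            LE1 = p.k_rho + p.gamma_rho * _hill3(rho1, p.rho0)
            LE2 = p.k_rho + p.gamma_rho * _hill3(rho2, p.rho0)
        else:
            brho1 = p.k_E + p.gamma_E * E1
            brho2 = p.k_E + p.gamma_E * E2
            BE1 = BE2 = 0.0
            AE1 = p.k_R + p.gamma_R * srcR1
            AE2 = p.k_R + p.gamma_R * srcR2
            LE1 = p.k_rho + p.gamma_rho * srcrho1
            LE2 = p.k_rho + p.gamma_rho * srcrho2

        dR1 = bR1 / (1.0 + rho1 ** n) * RI - p.delta * R1
        dR2 = bR2 / (1.0 + rho2 ** n) * RI - p.delta * R2
        drho1 = brho1 / (1.0 + R1 ** n) * rhoI - rho1
        drho2 = brho2 / (1.0 + R2 ** n) * rhoI - rho2
        dE1 = p.eps * (BE1 + AE1 * E1) - E1 * (LE1 * E1 + p.l_c * E2)
        dE2 = p.eps * (BE2 + AE2 * E2) - E2 * (LE2 * E2 + p.l_c * E1)

        parts = [dR1, drho1, dE1, dR2, drho2, dE2]
        if conserved and not reduced:
            parts += [-(dR1 + dR2), -(drho1 + drho2)]
        if effectors:
            parts += [p.eps2 * (R1 - w1), p.eps2 * (rho1 - c1),
                      p.eps2 * (R2 - w2), p.eps2 * (rho2 - c2)]
        return np.stack([np.broadcast_to(np.asarray(q, dtype=float), y[..., 0].shape)
                         for q in parts], axis=-1)

    return f


def build_system(params: ParameterSet, variant: ModelVariant) -> System:
    """Full ODE system with explicit inactive pools (conserved variants)."""
    labels = state_labels(variant)
    return System(_make_rhs(params, variant, reduced=False), len(labels), labels,
                  name=f"{variant.tag.value}")


def reduced_system(params: ParameterSet, variant: ModelVariant) -> System:
    """System with conserved pools eliminated via R_I = R_T - R_1 - R_2.

    For non-conserved variants this is identical to ``build_system``.  The
    reduced form removes the structurally zero eigenvalues of the
    conservation laws, making equilibrium hyperbolicity well defined.
    """
    labels = state_labels(variant, reduced=True)
    return System(_make_rhs(params, variant, reduced=True), len(labels), labels,
                  name=f"{variant.tag.value}-reduced")


def expand_reduced_state(y: np.ndarray, params: ParameterSet,
                         variant: ModelVariant) -> np.ndarray:
    """Map a reduced state back to the full layout (reinsert the pools)."""
    y = np.asarray(y, dtype=float)
    if not variant.conserved:
        return y
    RI = params.R_T - y[..., 0] - y[..., 3]
    rhoI = params.rho_T - y[..., 1] - y[..., 4]
    pools = np.stack([RI, rhoI], axis=-1)
    return np.concatenate([y[..., :6], pools, y[..., 6:]], axis=-1)


# --- isolated submodels ----------------------------------------------------

def ecm_competition_system(A_E1: float, A_E2: float, L_E1: float, L_E2: float,
                           l_c: float, eps: float = 1.0) -> System:
    """Isolated lamellipod-competition (Lotka-Volterra) submodel.

    The ECM equations with frozen coefficients and no basal protrusion:

        dE_k/dt = eps * A_Ek * E_k - E_k * (L_Ek * E_k + l_c * E_j)

    i.e. classic two-species competition, whose exclusion equilibria sit at
    E_k* = eps * A_Ek / L_Ek.
    """
    if min(A_E1, A_E2, L_E1, L_E2) <= 0:
        raise ValueError("A_E and L_E coefficients must be positive")
    if l_c < 0 or eps <= 0:
        raise ValueError("l_c must be >= 0 and eps > 0")

    def f(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        E1, E2 = y[..., 0], y[..., 1]
        dE1 = eps * A_E1 * E1 - E1 * (L_E1 * E1 + l_c * E2)
        dE2 = eps * A_E2 * E2 - E2 * (L_E2 * E2 + l_c * E1)
        return np.stack([dE1, dE2], axis=-1)

    def jac(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        E1, E2 = y[..., 0], y[..., 1]
        J = np.empty(y.shape[:-1] + (2, 2))
        J[..., 0, 0] = eps * A_E1 - 2 * L_E1 * E1 - l_c * E2
        J[..., 0, 1] = -l_c * E1
        J[..., 1, 0] = -l_c * E2
        J[..., 1, 1] = eps * A_E2 - 2 * L_E2 * E2 - l_c * E1
        return J

    return System(f, 2, ("E1", "E2"), name="ecm-competition", jac=jac)


def gtpase_toggle_system(b_R: float, b_rho: float, n: int = 1,
                         delta: float = 1.0) -> System:
    """Single-compartment Rac-Rho mutual-inhibition submodel, abundant pools.

        dR/dt   = b_R / (1 + rho^n) - delta * R
        drho/dt = b_rho / (1 + R^n) - rho

    Monostable for n = 1 (Michaelis-Menten crosstalk); bistable for n > 1
    and suitable activation rates (the classic toggle switch).
    """

    def f(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        R, rho = y[..., 0], y[..., 1]
        dR = b_R / (1.0 + rho ** n) - delta * R
        drho = b_rho / (1.0 + R ** n) - rho
        return np.stack([dR, drho], axis=-1)

    def jac(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        R, rho = y[..., 0], y[..., 1]
        J = np.empty(y.shape[:-1] + (2, 2))
        J[..., 0, 0] = -delta
        J[..., 0, 1] = -b_R * n * rho ** (n - 1) / (1.0 + rho ** n) ** 2
        J[..., 1, 0] = -b_rho * n * R ** (n - 1) / (1.0 + R ** n) ** 2
        J[..., 1, 1] = -1.0
        return J

    return System(f, 2, ("R", "rho"), name="gtpase-toggle", jac=jac)


def conserved_toggle_system(b_R: float, b_rho1: float, b_rho2: float,
                            n: int, delta: float, R_T: float,
                            rho_T: float) -> System:
    """Two-lamellipod GTPase subsystem with conserved pools, ECM decoupled.

    Reduced coordinates (R1, rho1, R2, rho2) with the inactive pools
    eliminated; the Rho activation inputs b_rho(E_k) are frozen as the
    parameters b_rho1, b_rho2.
    """

    def f(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        R1, rho1, R2, rho2 = (y[..., i] for i in range(4))
        RI = R_T - R1 - R2
        rhoI = rho_T - rho1 - rho2
        dR1 = b_R / (1.0 + rho1 ** n) * RI - delta * R1
        dR2 = b_R / (1.0 + rho2 ** n) * RI - delta * R2
        drho1 = b_rho1 / (1.0 + R1 ** n) * rhoI - rho1
        drho2 = b_rho2 / (1.0 + R2 ** n) * rhoI - rho2
        return np.stack([dR1, drho1, dR2, drho2], axis=-1)

    return System(f, 4, ("R1", "rho1", "R2", "rho2"), name="conserved-toggle")
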