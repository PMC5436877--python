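"""Steady-state enumeration and linear stability classification.

Equilibria are located by batched damped Newton iteration from a seeded
Latin-hypercube multistart over the positive orthant, plus points on the
single-lamellipod boundary faces (E_k = 0) where the competition submodels
keep their exclusion states.  Conserved variants are analyzed in reduced
coordinates (inactive pools eliminated) so that the structurally zero
eigenvalues of the conservation laws do not obscure hyperbolicity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import qmc

from .models import System, expand_reduced_state, reduced_system
from .params import ModelVariant, ParameterSet, validate

__all__ = [
    "Stability", "Equilibrium", "classify_stability", "fd_jacobian",
    "jacobian", "find_equilibria", "find_system_equilibria",
]

RESIDUAL_TOL = 1e-9
EIG_TOL = 1e-8


class Stability(str, enum.Enum):
    STABLE_NODE = "STABLE_NODE"
    STABLE_FOCUS = "STABLE_FOCUS"
    SADDLE = "SADDLE"
    UNSTABLE_NODE = "UNSTABLE_NODE"
    UNSTABLE_FOCUS = "UNSTABLE_FOCUS"
    NONHYPERBOLIC = "NONHYPERBOLIC"

    @property
    def is_stable(self) -> bool:
        return self in (Stability.STABLE_NODE, Stability.STABLE_FOCUS)


@dataclass
class Equilibrium:
    """A steady state with its linearization spectrum."""

    state: np.ndarray
    eigenvalues: np.ndarray
    stability: Stability
    residual: float
    labels: tuple[str, ...] = ()

    @property
    def is_stable(self) -> bool:
        return self.stability.is_stable

    @property
    def leading_eigenvalue(self) -> complex:
        return complex(self.eigenvalues[np.argmax(self.eigenvalues.real)])

    def to_dict(self) -> dict:
        return {
            "state": {lab: float(v) for lab, v in zip(self.labels, self.state)}
            if self.labels else [float(v) for v in self.state],
            "eigenvalues": [[float(e.real), float(e.imag)] for e in self.eigenvalues],
            "stability": self.stability.value,
            "residual": float(self.residual),
        }


def classify_stability(eigenvalues: Sequence[complex],
                       tol: float = EIG_TOL) -> Stability:
    """Label a spectrum: stable/unstable node/focus, saddle, or nonhyperbolic.

    A FOCUS label requires that a genuinely complex pair governs the leading
    (largest) real part.
    """
    ev = np.asarray(eigenvalues, dtype=complex)
    if ev.size == 0:
        raise ValueError("empty spectrum")
    re = ev.real
    if np.any(np.abs(re) <= tol):
        return Stability.NONHYPERBOLIC
    lead = np.max(re)
    leading_complex = bool(np.any((np.abs(re - lead) < 10 * tol) & (np.abs(ev.imag) > tol)))
    if lead < -tol:
        return Stability.STABLE_FOCUS if leading_complex else Stability.STABLE_NODE
    if np.all(re > tol):
        return Stability.UNSTABLE_FOCUS if leading_complex else Stability.UNSTABLE_NODE
    # mixed signs: saddle, unless the unstable part is an oscillatory pair
    return Stability.UNSTABLE_FOCUS if leading_complex else Stability.SADDLE


def fd_jacobian(f, y: np.ndarray, rel_step: float = 1e-6,
                abs_floor: float = 1e-8) -> np.ndarray:
    """Central finite-difference Jacobian, batched over leading dimensions."""
    y = np.asarray(y, dtype=float)
    dim = y.shape[-1]
    J = np.empty(y.shape[:-1] + (dim, dim))
    for j in range(dim):
        h = np.maximum(rel_step * np.abs(y[..., j]), abs_floor)
        yp = y.copy()
        ym = y.copy()
        yp[..., j] += h
        ym[..., j] -= h
        J[..., :, j] = (f(yp) - f(ym)) / (2.0 * h)[..., None]
    return J


def jacobian(params: ParameterSet, variant: ModelVariant, state,
             reduced: bool = True) -> np.ndarray:
    """Jacobian of a model variant's rhs at a state (reduced coordinates by
    default, matching the equilibrium analysis)."""
    from .models import build_system
    sys = reduced_system(params, variant) if reduced else build_system(params, variant)
    return fd_jacobian(sys.f, np.asarray(state, dtype=float))


# --- multistart Newton -----------------------------------------------------

def _multistart_points(system: System, n_starts: int, seed: int,
                       hi: float) -> np.ndarray:
    """LHS sample of the positive orthant plus boundary-face and near-origin
    seeds (exclusion states live on the faces E_k = 0)."""
    sampler = qmc.LatinHypercube(d=system.dim, seed=seed)
    pts = sampler.random(n_starts) * hi
    extras = [np.full(system.dim, 1e-3)]
    e_idx = [i for i, lab in enumerate(system.labels) if lab in ("E1", "E2")]
    for i in e_idx:
        faced = pts[: max(2, n_starts // 8)].copy()
        faced[:, i] = 0.0
        extras.append(faced)
    if len(e_idx) == 2:
        both = pts[: max(2, n_starts // 8)].copy()
        both[:, e_idx] = 0.0
        extras.append(both)
    return np.vstack([pts] + [np.atleast_2d(e) for e in extras])


def _newton_polish(system: System, starts: np.ndarray, max_iter: int = 80,
                   tol: float = 1e-12) -> np.ndarray:
    """Damped Newton on a batch of starting points; returns final iterates."""
    y = np.array(starts, dtype=float)
    active = np.ones(len(y), dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        ya = y[active]
        fa = system.f(ya)
        done = np.max(np.abs(fa), axis=-1) < tol
        if done.all():
            idx = np.flatnonzero(active)
            active[idx[done]] = False
            continue
        J = system.jac(ya) if system.jac is not None else fd_jacobian(system.f, ya)
        # regularize near-singular Jacobians slightly
        J = J + 1e-14 * np.eye(system.dim)
        try:
            step = np.linalg.solve(J, fa[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("...ij,...j->...i", np.linalg.pinv(J), fa)
        bad = ~np.isfinite(step).all(axis=-1)
        step[bad] = 0.0
        # damp very large steps to keep iterates in a sane region
        norm = np.max(np.abs(step), axis=-1, keepdims=True)
        scale = np.minimum(1.0, 10.0 / np.maximum(norm, 1e-300))
        ya = ya - step * scale
        y[active] = ya
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    return y


def find_system_equilibria(system: System, n_starts: int = 64, seed: int = 0,
                           dedup_tol: float = 1e-5, hi: float = 2.0,
                           residual_tol: float = RESIDUAL_TOL,
                           extra_starts: Optional[np.ndarray] = None,
                           ) -> list[Equilibrium]:
    """Enumerate non-negative equilibria of an arbitrary system.

    Roots are polished to residual below ``residual_tol``, deduplicated at
    ``dedup_tol`` (infinity norm), restricted to the closed positive orthant
    and sorted by E1 (or the first coordinate) descending.
    """
    if n_starts < 8:
        raise ValueError("n_starts must be >= 8")
    starts = _multistart_points(system, n_starts, seed, hi)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([np.atleast_2d(np.asarray(extra_starts, dtype=float)), starts])
    roots = _newton_polish(system, starts)
    res = np.max(np.abs(system.f(roots)), axis=-1)
    ok = np.isfinite(roots).all(axis=-1) & (res < residual_tol)
    ok &= roots.min(axis=-1) > -1e-8
    roots = np.clip(roots[ok], 0.0, None)

    unique: list[np.ndarray] = []
    for r in roots:
        if not any(np.max(np.abs(r - u)) < dedup_tol for u in unique):
            unique.append(r)

    sort_idx = system.labels.index("E1") if "E1" in system.labels else 0
    unique.sort(key=lambda r: -r[sort_idx])

    out = []
    for r in unique:
        J = system.jac(r) if system.jac is not None else fd_jacobian(system.f, r)
        ev = np.linalg.eigvals(J)
        out.append(Equilibrium(state=r, eigenvalues=ev,
                               stability=classify_stability(ev),
                               residual=float(np.max(np.abs(system.f(r)))),
                               labels=system.labels))
    return out


def find_equilibria(params: ParameterSet, variant: ModelVariant,
                    n_starts: int = 64, seed: int = 0,
                    dedup_tol: float = 1e-5) -> list[Equilibrium]:
    """Equilibria of a model variant in reduced coordinates.

    For conserved variants the search domain per GTPase coordinate extends
    to the total pool size.
    """
    validate(params, variant).raise_if_invalid()
    system = reduced_system(params, variant)
    hi = max(2.0, params.R_T or 0.0, params.rho_T or 0.0)
    return find_system_equilibria(system, n_starts=n_starts, seed=seed,
                                  dedup_tol=dedup_tol, hi=hi)
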