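"""Model variants and parameter sets for the two-lamellipod Rac-Rho-ECM models.

Five model variants share a common skeleton: in each of two lamellipods a
mutually antagonistic Rac-Rho pair drives protrusion (Rac) and contraction
(Rho) of the lamellipod, whose size doubles as the level of cell-ECM contact
signaling E_k feeding back onto Rho activation.  The variants differ in

* kinetics: linear feedback terms (the lamellipod-competition family M1A,
  M1B, M1C) versus saturating Hill terms with cooperativity 3 (M2, M3);
* GTPase availability: abundant inactive pools (M1A, M2) versus a conserved
  total shared between lamellipods (M1B, M1C, M3);
* effector intermediates: M1C inserts first-order Rac/Rho effector trackers
  between the GTPases and the lamellipod feedback terms.

All quantities are dimensionless: time is scaled by the Rho inactivation
rate and GTPase levels by the IC50 of the crosstalk Hill functions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional


class ModelTag(str, enum.Enum):
    """Model designations for the five variants."""

    M1A = "M1A"  # lamellipod competition, abundant GTPase pools
    M1B = "M1B"  # lamellipod competition, conserved GTPase pools
    M1C = "M1C"  # as M1B plus effector intermediates w, c
    M2 = "M2"   # bistable GTPase toggle, abundant pools
    M3 = "M3"   # hybrid: bistable toggle with conserved pools


# Variants in which the total of each GTPase is a conserved quantity.
CONSERVED_TAGS = frozenset({ModelTag.M1B, ModelTag.M1C, ModelTag.M3})
# Variants using saturating Hill feedback/ECM terms (cooperativity 3).
HILL_TAGS = frozenset({ModelTag.M2, ModelTag.M3})


@dataclass(frozen=True)
class ModelVariant:
    """A model tag plus structural switches.

    ``ecm_to_rac`` enables the optional ECM -> Rac activation feedback and is
    admissible only for the hybrid model M3.
    """

    tag: ModelTag
    ecm_to_rac: bool = False

    def __post_init__(self) -> None:
        if self.ecm_to_rac and self.tag is not ModelTag.M3:
            raise ValueError("ecm_to_rac is an M3-only extension")

    @property
    def conserved(self) -> bool:
        return self.tag in CONSERVED_TAGS

    @property
    def hill_kinetics(self) -> bool:
        return self.tag in HILL_TAGS

    @property
    def has_effectors(self) -> bool:
        return self.tag is ModelTag.M1C

    @classmethod
    def parse(cls, spec: "str | dict | ModelVariant") -> "ModelVariant":
        if isinstance(spec, ModelVariant):
            return spec
        if isinstance(spec, str):
            return cls(ModelTag(spec.upper()))
        return cls(ModelTag(str(spec["tag"]).upper()), bool(spec.get("ecm_to_rac", False)))


_UNSET = None


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and feedback strengths of one model variant.

    Fields irrelevant to a given variant may be left ``None``; ``validate``
    reports which fields a variant actually uses.

    n          Hill coefficient of the Rac-Rho mutual inhibition (>= 1).
    delta      Rac inactivation rate relative to Rho's (> 0).
    b_R        basal Rac activation rate (>= 0).
    k_E        ECM-independent part of the Rho activation input (>= 0).
    gamma_E    ECM -> Rho feedback strength: linear slope for M1*, Hill
               magnitude for M2/M3 (>= 0).
    E0         IC50 of the ECM Hill term (M2/M3 only, > 0).
    k_R        basal protrusion rate (>= 0).
    gamma_R    Rac -> protrusion feedback strength (>= 0).
    R0         IC50 of the Rac protrusion Hill term (M2/M3, > 0).
    k_rho      basal contraction rate (>= 0).
    gamma_rho  Rho -> contraction feedback strength (>= 0).
    rho0       IC50 of the Rho contraction Hill term (M2/M3, > 0).
    eps        timescale ratio of ECM protrusion dynamics to GTPase dynamics.
    eps2       effector relaxation rate (M1C only, > 0).
    l_c        direct lamellipod-lamellipod competition strength (>= 0).
    R_T, rho_T total Rac / Rho (conserved variants only, > 0).
    gamma_ER   ECM -> Rac feedback magnitude (M3 with ecm_to_rac, >= 0).
    """

    n: int = 1
    delta: float = 1.0
    b_R: float = 1.0
    k_E: float = 0.0
    gamma_E: float = 0.0
    E0: Optional[float] = _UNSET
    k_R: float = 0.0
    gamma_R: float = 0.0
    R0: Optional[float] = _UNSET
    k_rho: float = 0.0
    gamma_rho: float = 0.0
    rho0: Optional[float] = _UNSET
    eps: float = 1.0
    eps2: Optional[float] = _UNSET
    l_c: float = 0.0
    R_T: Optional[float] = _UNSET
    rho_T: Optional[float] = _UNSET
    gamma_ER: Optional[float] = _UNSET

    def with_(self, **updates) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)

    def to_dict(self, drop_none: bool = True) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if drop_none and v is None:
                continue
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**d)


# --- field-relevance table -------------------------------------------------

_COMMON = ("n", "delta", "b_R", "k_E", "gamma_E", "k_R", "gamma_R",
           "k_rho", "gamma_rho", "eps", "l_c")
_HILL_IC50 = ("E0", "R0", "rho0")
_TOTALS = ("R_T", "rho_T")

# bound kind: "pos" strict > 0, "nonneg" >= 0, "int_ge1" integer >= 1
_BOUNDS = {
    "n": "int_ge1", "delta": "pos", "b_R": "nonneg", "k_E": "nonneg",
    "gamma_E": "nonneg", "E0": "pos", "k_R": "nonneg", "gamma_R": "nonneg",
    "R0": "pos", "k_rho": "nonneg", "gamma_rho": "nonneg", "rho0": "pos",
    "eps": "pos", "eps2": "pos", "l_c": "nonneg", "R_T": "pos",
    "rho_T": "pos", "gamma_ER": "nonneg",
}


def required_fields(variant: ModelVariant) -> tuple[str, ...]:
    req = list(_COMMON)
    if variant.hill_kinetics:
        req += list(_HILL_IC50)
    if variant.conserved:
        req += list(_TOTALS)
    if variant.has_effectors:
        req.append("eps2")
    if variant.ecm_to_rac:
        req.append("gamma_ER")
    return tuple(req)


@dataclass
class ValidationReport:
    """Outcome of checking a parameter set against a model variant."""

    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            raise ValueError("invalid parameter set: " + "; ".join(self.errors))


def validate(params: ParameterSet, variant: ModelVariant) -> ValidationReport:
    """Check bounds, required fields, and flag fields a variant ignores."""
    rep = ValidationReport()
    required = set(required_fields(variant))
    for f in fields(params):
        name = f.name
        value = getattr(params, name)
        if name in required:
            if value is None:
                rep.errors.append(f"{name} is required for {variant.tag.value} but missing")
                continue
        elif value is not None and name not in _COMMON:
            rep.warnings.append(f"{name} is ignored for {variant.tag.value}")
        if value is None:
            continue
        kind = _BOUNDS[name]
        if kind == "int_ge1":
            if value < 1 or int(value) != value:
                rep.errors.append(f"{name} must be an integer >= 1, got {value!r}")
        elif kind == "pos":
            if not (value > 0) or not math.isfinite(value):
                rep.errors.append(f"{name} must be > 0, got {value!r}")
        elif not (value >= 0) or not math.isfinite(value):
            rep.errors.append(f"{name} must be >= 0, got {value!r}")
    return rep
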