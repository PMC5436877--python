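"""Mapping experimental perturbations onto model parameters.

The experimentally observed shifts in the fractions of polarized,
oscillatory and random (apolar) melanoma cells are interpreted as parameter
changes:

* ROCK inhibition weakens Rho-driven contraction      -> gamma_rho down
* microtubule ablation releases Rho GEFs              -> gamma_rho up
* PI3K upregulation (invasive lines) boosts protrusion-> gamma_R up
* Rac inhibition                                      -> gamma_R down
* higher fibronectin density boosts ECM->Rho signaling-> gamma_E up
* mechanical / resource coupling changes              -> l_c scaled

Scenario checks sweep each mapped parameter over its fold range and verify
the direction in which the polarized/oscillatory boundary moves.
Population-level phenotype fractions are estimated by sampling multiplicative
lognormal heterogeneity on the feedback strengths and classifying each
synthetic cell.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelVariant, ParameterSet
from .phenotype import (PhenotypeLabel, Thresholds, classify_point,
                        is_oscillatory, is_polarized)

__all__ = [
    "PerturbationKind", "PerturbationSpec", "apply_perturbation",
    "ScenarioOutcome", "ScenarioReport", "scenario_checks",
    "PopulationSpec", "PhenotypeFractions", "phenotype_fractions",
]


class PerturbationKind(str, enum.Enum):
    ROCK_INHIBITION = "ROCK_INHIBITION"
    PI3K_UP = "PI3K_UP"
    FN_UP = "FN_UP"
    MT_ABLATION = "MT_ABLATION"
    RAC_INHIBITION = "RAC_INHIBITION"
    COUPLING_CHANGE = "COUPLING_CHANGE"


# target parameter and the fold direction that matches the biology
_PERTURBATION_TABLE = {
    PerturbationKind.ROCK_INHIBITION: ("gamma_rho", "down"),
    PerturbationKind.PI3K_UP: ("gamma_R", "up"),
    PerturbationKind.FN_UP: ("gamma_E", "up"),
    PerturbationKind.MT_ABLATION: ("gamma_rho", "up"),
    PerturbationKind.RAC_INHIBITION: ("gamma_R", "down"),
    PerturbationKind.COUPLING_CHANGE: ("l_c", "any"),
}


@dataclass(frozen=True)
class PerturbationSpec:
    kind: PerturbationKind
    fold_change: float

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")

    @property
    def parameter(self) -> str:
        return _PERTURBATION_TABLE[self.kind][0]


def apply_perturbation(params: ParameterSet, spec: PerturbationSpec) -> ParameterSet:
    """Scale the mapped parameter by the fold change; all else unchanged."""
    name, direction = _PERTURBATION_TABLE[spec.kind]
    value = getattr(params, name)
    if value is None:
        raise ValueError(f"parameter {name} is not set on this parameter set")
    if (direction == "down" and spec.fold_change > 1) or \
       (direction == "up" and spec.fold_change < 1):
        warnings.warn(f"{spec.kind.value} normally implies a fold "
                      f"{'<' if direction == 'down' else '>'} 1, got "
                      f"{spec.fold_change}", stacklevel=2)
    return params.with_(**{name: value * spec.fold_change})


# --- scenario checks -------------------------------------------------------

@dataclass
class ScenarioOutcome:
    scenario: str
    parameter: str
    fold_grid: np.ndarray
    values: np.ndarray
    labels: list
    boundary_value: Optional[float]
    passed: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "parameter": self.parameter,
                "folds": [float(f) for f in self.fold_grid],
                "values": [float(v) for v in self.values],
                "labels": list(self.labels),
                "boundary_value": (None if self.boundary_value is None
                                   else float(self.boundary_value)),
                "passed": bool(self.passed), "note": self.note}


@dataclass
class ScenarioReport:
    outcomes: dict

    @property
    def all_passed(self) -> bool:
        return all(o.passed for o in self.outcomes.values())

    def to_dict(self) -> dict:
        return {k: o.to_dict() for k, o in self.outcomes.items()}


# Each scenario: (parameter, fold range swept, expected side of the boundary
# where oscillation lies).  "high" means oscillation at high parameter values.
_SCENARIOS = {
    # ROCK inhibition: lowering gamma_rho turns oscillation into polarity
    "O1": ("gamma_rho", (0.25, 1.0), "high"),
    # PI3K upregulation: raising gamma_R promotes oscillation
    "O2": ("gamma_R", (0.4, 1.2), "high"),
    # fibronectin increase: raising gamma_E promotes oscillation
    "O3": ("gamma_E", (0.4, 1.6), "high"),
    # Rac inhibition: lowering gamma_R suppresses oscillation
    "P1": ("gamma_R", (0.3, 1.0), "high"),
    # microtubule ablation: raising gamma_rho promotes oscillation
    "P2": ("gamma_rho", (0.5, 1.3), "high"),
}


def _boundary_check(folds: np.ndarray, labels: Sequence[PhenotypeLabel],
                    osc_side: str) -> tuple[Optional[int], bool, str]:
    """Verify a single polarized/oscillatory boundary with the right
    orientation; intermediate apolar/unclassified points are tolerated."""
    osc = [is_oscillatory(l) for l in labels]
    pol = [is_polarized(l) for l in labels]
    if not any(osc):
        return None, False, "no oscillatory point on the sweep"
    if not any(pol):
        return None, False, "no polarized point on the sweep"
    first_osc = osc.index(True)
    last_osc = len(osc) - 1 - osc[::-1].index(True)
    first_pol = pol.index(True)
    last_pol = len(pol) - 1 - pol[::-1].index(True)
    if osc_side == "high":
        ok = last_pol < first_osc
    else:
        ok = last_osc < first_pol
    return (first_osc if osc_side == "high" else first_pol), ok, ""


def scenario_checks(params: ParameterSet, variant: ModelVariant,
                    scenarios: Sequence[str] = ("O1", "O2", "O3", "P1", "P2"),
                    n_grid: int = 7, seed: int = 0, t_end: float = 6000.0,
                    n_out: int = 3000,
                    thresholds: Thresholds = Thresholds()) -> ScenarioReport:
    """Run the experiment-direction checks on a calibrated bundle.

    For each scenario the mapped parameter is swept over its fold range
    around the bundle's base value; the check passes when polarized labels
    occupy the low side and oscillatory labels the high side of a single
    boundary (all scenarios here promote oscillation at high values of the
    mapped parameter).
    """
    outcomes = {}
    for sc in scenarios:
        name, (f_lo, f_hi), osc_side = _SCENARIOS[sc]
        base = getattr(params, name)
        folds = np.linspace(f_lo, f_hi, n_grid)
        values = folds * base
        labels = []
        for v in values:
            res = classify_point(params.with_(**{name: v}), variant, seed=seed,
                                 t_end=t_end, n_out=n_out, thresholds=thresholds)
            labels.append(res.label)
        b_idx, ok, note = _boundary_check(folds, labels, osc_side)
        boundary = None
        if b_idx is not None and b_idx > 0:
            boundary = 0.5 * (values[b_idx - 1] + values[b_idx])
        elif b_idx == 0:
            boundary = values[0]
        outcomes[sc] = ScenarioOutcome(sc, name, folds, values,
                                       [l.value for l in labels], boundary,
                                       ok, note)
    return ScenarioReport(outcomes)


# --- population heterogeneity ----------------------------------------------

DEFAULT_HETEROGENEOUS = ("gamma_R", "gamma_rho", "gamma_E")


@dataclass
class PopulationSpec:
    """A heterogeneous population around a base parameter set.

    Each sampled cell multiplies the selected parameters by independent
    lognormal factors exp(sigma * N(0,1)) — multiplicative noise with median
    1 — mimicking cell-to-cell variability in feedback strengths.
    """

    params: ParameterSet
    variant: ModelVariant
    sigmas: dict = field(default_factory=lambda: {k: 0.3 for k in DEFAULT_HETEROGENEOUS})
    n_cells: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(s < 0 for s in self.sigmas.values()):
            raise ValueError("sigmas must be non-negative")


@dataclass
class PhenotypeFractions:
    fractions: dict
    n_cells: int
    seed: int
    cells: Optional[pd.DataFrame] = None

    def __getitem__(self, label) -> float:
        key = label.value if isinstance(label, PhenotypeLabel) else str(label)
        return self.fractions.get(key, 0.0)

    @property
    def oscillatory(self) -> float:
        return sum(v for k, v in self.fractions.items()
                   if is_oscillatory(PhenotypeLabel(k)))

    @property
    def polarized(self) -> float:
        return sum(v for k, v in self.fractions.items()
                   if is_polarized(PhenotypeLabel(k)))

    def to_dict(self) -> dict:
        return {"fractions": dict(self.fractions), "n_cells": self.n_cells,
                "seed": self.seed, "oscillatory": self.oscillatory,
                "polarized": self.polarized}


def phenotype_fractions(popspec: PopulationSpec, t_end: float = 6000.0,
                        n_out: int = 3000,
                        thresholds: Thresholds = Thresholds()) -> PhenotypeFractions:
    """Classify a seeded synthetic population and aggregate label fractions.

    Classification failures are counted as UNCLASSIFIED, never dropped.
    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(popspec.seed)
    rows = []
    counts: dict = {}
    for i in range(popspec.n_cells):
        updates = {}
        for name, sigma in popspec.sigmas.items():
            base = getattr(popspec.params, name)
            if base is None:
                raise ValueError(f"heterogeneous parameter {name} is unset")
            updates[name] = base * float(np.exp(sigma * rng.standard_normal()))
        p = popspec.params.with_(**updates)
        try:
            res = classify_point(p, popspec.variant, seed=popspec.seed,
                                 t_end=t_end, n_out=n_out, thresholds=thresholds)
            label = res.label
        except Exception as err:  # robustness: a failed cell is still counted
            label = PhenotypeLabel.UNCLASSIFIED
            warnings.warn(f"cell {i} classification failed: {err}", stacklevel=2)
        counts[label.value] = counts.get(label.value, 0) + 1
        rows.append({**updates, "label": label.value})
    fractions = {k: v / popspec.n_cells for k, v in counts.items()}
    return PhenotypeFractions(fractions, popspec.n_cells, popspec.seed,
                              cells=pd.DataFrame(rows))
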