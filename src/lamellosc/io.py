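"""Configuration loading, shipped parameter bundles, and task execution.

Configs and reports are JSON; tabular numerics (trajectories, branches,
regime maps, populations) are CSV.  A run writes its artifacts plus a
run-log recording parameters, package version, seed and wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .params import ModelVariant, ParameterSet, validate

logger = logging.getLogger("lamellosc")

TASKS = ("simulate", "equilibria", "sweep", "regime-map", "population",
         "scenarios")

BUNDLE_NAMES = ("fig3_lv", "model1b_osc", "model2", "fig5_hybrid")


class ConfigError(ValueError):
    """Raised for invalid run configurations; carries all schema problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


def _bundle_text(name: str) -> str:
    ref = resources.files("lamellosc") / "bundles" / f"{name}.json"
    return ref.read_text()


def load_bundle(name: str) -> dict:
    """Load a shipped parameter bundle by name (raw dict form)."""
    if name not in BUNDLE_NAMES:
        raise KeyError(f"unknown bundle {name!r}; available: {BUNDLE_NAMES}")
    raw = _bundle_text(name)
    data = json.loads(raw)
    data["_hash"] = hashlib.sha256(raw.encode()).hexdigest()[:16]
    return data


def bundle_model(name: str, overrides: Optional[dict] = None
                 ) -> tuple[ParameterSet, ModelVariant, dict]:
    """Resolve a bundle into a validated (ParameterSet, ModelVariant) pair."""
    data = load_bundle(name)
    if "variant" not in data:
        raise ValueError(f"bundle {name!r} describes an isolated submodel, "
                         "not a full model variant")
    variant = ModelVariant.parse(data["variant"])
    pdict = dict(data["parameters"])
    if overrides:
        pdict.update(overrides)
    params = ParameterSet.from_dict(pdict)
    rep = validate(params, variant)
    rep.raise_if_invalid()
    return params, variant, data


@dataclass
class RunConfig:
    """A fully resolved analysis task."""

    task: str
    variant: Optional[ModelVariant] = None
    params: Optional[ParameterSet] = None
    bundle: Optional[str] = None
    options: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: Path = Path(".")
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"task": self.task, "seed": self.seed,
               "options": dict(self.options)}
        if self.bundle:
            out["bundle"] = self.bundle
        if self.variant is not None:
            out["variant"] = {"tag": self.variant.tag.value,
                              "ecm_to_rac": self.variant.ecm_to_rac}
        if self.params is not None:
            out["parameters"] = self.params.to_dict()
        return out


def load_config(path, overrides: Optional[dict] = None,
                seed: Optional[int] = None, out_dir=None) -> RunConfig:
    """Load and validate a JSON run configuration.

    Schema problems are collected and reported exhaustively.  A missing
    seed defaults to 0 (logged).  Either a bundle name or an inline
    parameter set (with a variant) must resolve to a valid model, except
    for tasks on the isolated competition submodel.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    return parse_config(raw, overrides=overrides, seed=seed, out_dir=out_dir)


def parse_config(raw: dict, overrides: Optional[dict] = None,
                 seed: Optional[int] = None, out_dir=None) -> RunConfig:
    problems = []
    task = raw.get("task")
    if task not in TASKS:
        problems.append(f"task must be one of {TASKS}, got {task!r}")
    cfg_seed = raw.get("seed")
    if cfg_seed is None:
        cfg_seed = 0
        logger.info("no seed in config; defaulting to 0")
    if seed is not None:
        cfg_seed = seed
    options = dict(raw.get("options", {}))
    provenance = {}

    params = variant = None
    bundle = raw.get("bundle")
    submodel_task = bool(options.get("submodel") == "ecm_competition" or
                         bundle == "fig3_lv")
    if bundle is not None and not submodel_task:
        try:
            params, variant, data = bundle_model(bundle, overrides)
            provenance = {"bundle": bundle, "bundle_hash": data["_hash"]}
        except (KeyError, ValueError) as err:
            problems.append(str(err))
    elif bundle == "fig3_lv":
        data = load_bundle(bundle)
        options.setdefault("coefficients", data["coefficients"])
        options.setdefault("K_paths", data["K_paths"])
        provenance = {"bundle": bundle, "bundle_hash": data["_hash"]}
    elif "parameters" in raw:
        try:
            variant = ModelVariant.parse(raw.get("variant", "M3"))
            pdict = dict(raw["parameters"])
            if overrides:
                pdict.update(overrides)
            params = ParameterSet.from_dict(pdict)
            rep = validate(params, variant)
            problems.extend(rep.errors)
            for w in rep.warnings:
                logger.warning("%s", w)
        except (KeyError, ValueError) as err:
            problems.append(str(err))
    elif not submodel_task:
        problems.append("config needs a 'bundle' or inline 'parameters'")

    if task == "population" and params is not None and variant is not None:
        if options.get("check_conservation") and not variant.conserved:
            problems.append("conservation check requested for a "
                            "non-conserved variant")
    if problems:
        raise ConfigError(problems)
    return RunConfig(task=task, variant=variant, params=params, bundle=bundle,
                     options=options, seed=int(cfg_seed),
                     out_dir=Path(out_dir) if out_dir else Path(raw.get("out_dir", ".")),
                     provenance=provenance)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def run(cfg: RunConfig) -> dict:
    """Execute a run configuration and write its artifacts.

    Returns a manifest of written files; idempotent for fixed inputs.
    """
    from . import dynamics, equilibria, bifurcation, phenotype, experiments

    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = cfg.options
    written = {}

    if cfg.task == "simulate":
        traj = dynamics.simulate(cfg.params, cfg.variant,
                                 t_end=float(opts.get("t_end", 2000.0)),
                                 n_out=int(opts.get("n_out", 2000)),
                                 seed=cfg.seed)
        traj.to_csv(out / "trajectory.csv")
        res = phenotype.classify_trajectory(traj)
        _write_json(res.to_dict(), out / "classification.json")
        written = {"trajectory": "trajectory.csv",
                   "classification": "classification.json"}

    elif cfg.task == "equilibria":
        eqs = equilibria.find_equilibria(cfg.params, cfg.variant,
                                         n_starts=int(opts.get("n_starts", 64)),
                                         seed=cfg.seed)
        _write_json([e.to_dict() for e in eqs], out / "equilibria.json")
        written = {"equilibria": "equilibria.json"}

    elif cfg.task == "sweep":
        if opts.get("submodel") == "ecm_competition":
            co = opts.get("coefficients", {})
            res = bifurcation.sweep_ecm_LE1(
                K=float(opts["K"]), A_E1=co.get("A_E1", 1.0),
                A_E2=co.get("A_E2", 1.0), l_c=co.get("l_c", 1.0),
                eps=co.get("eps", 1.0))
        else:
            res = bifurcation.sweep_parameter(
                cfg.params, cfg.variant, opts["parameter"],
                float(opts["lo"]), float(opts["hi"]),
                n_steps=int(opts.get("n_steps", 101)), seed=cfg.seed)
        res.to_dataframe().to_csv(out / "branches.csv", index=False)
        _write_json([p.to_dict() for p in res.points],
                    out / "bifurcation_points.json")
        written = {"branches": "branches.csv",
                   "points": "bifurcation_points.json"}

    elif cfg.task == "regime-map":
        method = bifurcation.RegimeMapMethod(opts.get("method", "ANALYTIC_LV"))
        if method in (bifurcation.RegimeMapMethod.ANALYTIC_LV,
                      bifurcation.RegimeMapMethod.EQUILIBRIUM_COUNT):
            co = opts.get("coefficients", {})
            grid = np.linspace(float(opts.get("lo", 0.1)),
                               float(opts.get("hi", 4.0)),
                               int(opts.get("n", 41)))
            rm = bifurcation.ecm_regime_map(grid, grid,
                                            l_c=co.get("l_c", 1.0),
                                            A_E1=co.get("A_E1", 1.0),
                                            A_E2=co.get("A_E2", 1.0),
                                            eps=co.get("eps", 1.0),
                                            method=method, seed=cfg.seed)
        else:
            rm = bifurcation.regime_map_2d(
                cfg.params, cfg.variant, opts["x_param"], opts["y_param"],
                np.asarray(opts["x_values"], dtype=float),
                np.asarray(opts["y_values"], dtype=float),
                method=method, seed=cfg.seed)
        rm.to_dataframe().to_csv(out / "regime_map.csv", index=False)
        written = {"regime_map": "regime_map.csv"}

    elif cfg.task == "population":
        spec = experiments.PopulationSpec(
            cfg.params, cfg.variant,
            sigmas=opts.get("sigmas", {k: 0.3 for k in
                                       experiments.DEFAULT_HETEROGENEOUS}),
            n_cells=int(opts.get("n_cells", 100)), seed=cfg.seed)
        frac = experiments.phenotype_fractions(
            spec, t_end=float(opts.get("t_end", 6000.0)),
            n_out=int(opts.get("n_out", 3000)))
        frac.cells.to_csv(out / "population.csv", index=False)
        _write_json(frac.to_dict(), out / "fractions.json")
        written = {"population": "population.csv", "fractions": "fractions.json"}

    elif cfg.task == "scenarios":
        rep = experiments.scenario_checks(
            cfg.params, cfg.variant,
            scenarios=tuple(opts.get("scenarios", ("O1", "O2", "O3", "P1", "P2"))),
            n_grid=int(opts.get("n_grid", 7)), seed=cfg.seed,
            t_end=float(opts.get("t_end", 6000.0)),
            n_out=int(opts.get("n_out", 3000)))
        _write_json({"all_passed": rep.all_passed, **rep.to_dict()},
                    out / "scenarios.json")
        written = {"scenarios": "scenarios.json"}

    else:  # pragma: no cover - guarded by config validation
        raise ConfigError([f"unknown task {cfg.task!r}"])

    from . import __version__
    log = {"task": cfg.task, "seed": cfg.seed, "version": __version__,
           "wall_time_s": round(time.time() - t0, 3),
           "provenance": cfg.provenance,
           "parameters": cfg.params.to_dict() if cfg.params else None,
           "artifacts": written}
    _write_json(log, out / "run_log.json")
    return written
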