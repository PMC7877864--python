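"""Staged pipeline tying the workflow together, with artifact manifest.

Stages: ``generate`` (plausible cohort) -> ``select`` (trial-matched
population) -> ``calibrate`` (optional) -> ``simulate`` (two monotherapy
arms) -> ``classify`` (responder partition) -> ``combine`` (combination
arms). Each stage writes text artifacts; the manifest records every file's
sha256 together with the seed and a config snapshot so deterministic stages
reproduce identical hashes on rerun.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .calibrate import default_anti_il6_targets
from .config import RunConfig
from .dynamics import SolverSettings
from .model import CrohnsQSPModel
from .population import BaselineTargets, Cohort
from .synthetic import (baseline_targets_from_fixture, make_paper_defaults,
                        make_trial_fixture)
from .trial import TrialSpec

__all__ = ["run_pipeline", "PipelineDependencyError", "ALL_STAGES"]

ALL_STAGES = ("generate", "select", "calibrate", "simulate", "classify",
              "combine")
_REQUIRES = {
    "select": "generate",
    "calibrate": "select",
    "simulate": "select",
    "classify": "simulate",
    "combine": "select",
}


class PipelineDependencyError(RuntimeError):
    """A stage was requested without its prerequisite stage or artifact."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _model_from(config: RunConfig) -> CrohnsQSPModel:
    solver = SolverSettings(method=config.solver.method,
                            rtol=config.solver.rtol, atol=config.solver.atol)
    model = CrohnsQSPModel(solver=solver)
    if config.kd_nM:
        model = model.with_params(model.params, kd_overrides=dict(config.kd_nM))
    return model


def _baseline_targets(config: RunConfig) -> BaselineTargets:
    fixture = make_trial_fixture(
        seed=config.seed, n_per_arm=config.baseline.fixture_n,
        baseline_law={"CRP": (config.baseline.crp_median, config.baseline.crp_gsd),
                      "FCP": (config.baseline.fcp_median, config.baseline.fcp_gsd)},
        stat_kind=config.baseline.kind)
    return baseline_targets_from_fixture(fixture, config.baseline.tolerance)


def run_pipeline(config: RunConfig, stages=ALL_STAGES,
                 out_dir: str | Path | None = None) -> dict:
    """Run the requested stages and return the artifact manifest.

    Stage outputs are reused from ``out_dir`` when a prerequisite stage is
    not part of this run; a missing prerequisite raises
    :class:`PipelineDependencyError` naming the stage to run first.
    """
    stages = tuple(stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    defaults = make_paper_defaults()
    model = _model_from(config)
    manifest: dict = {"config": config.snapshot(), "seed": config.seed,
                      "stages": list(stages), "artifacts": {}}

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)), "sha256": _sha256(path),
            "seed": config.seed}

    ctx: dict = {}

    def need(artifact: str, loader, stage: str):
        if artifact in ctx:
            return ctx[artifact]
        loaded = loader()
        if loaded is None:
            raise PipelineDependencyError(
                f"stage {stage!r} requires the {_REQUIRES[stage]!r} stage "
                "to run first (or its artifacts in the output directory)")
        ctx[artifact] = loaded
        return loaded

    def load_cohort_file(name: str):
        csv = out / f"{name}.csv"
        meta = out / f"{name}.meta.json"
        if csv.exists():
            return Cohort.from_csv(csv, meta if meta.exists() else None)
        return None

    spec = TrialSpec(horizon_days=config.trial.horizon_days)

    if "generate" in stages:
        cohort = model.generate_population(config.cohort_size, seed=config.seed)
        ctx["cohort"] = cohort
        cohort.to_csv(out / "cohort.csv", out / "cohort.meta.json")
        record("cohort", out / "cohort.csv")

    if "select" in stages:
        cohort = need("cohort", lambda: load_cohort_file("cohort"), "select")
        targets = _baseline_targets(config)
        population = model.select_population(cohort, targets,
                                             config.population_size,
                                             seed=config.seed)
        ctx["population"] = population
        population.to_csv(out / "population.csv", out / "population.meta.json")
        (out / "baseline_targets.json").write_text(
            json.dumps(targets.as_dict(), indent=2))
        record("population", out / "population.csv")
        record("baseline_targets", out / "baseline_targets.json")

    if "calibrate" in stages and config.calibration.enabled:
        population = need("population", lambda: load_cohort_file("population"),
                          "calibrate")
        ids = population.ids
        stride = max(1, len(ids) // config.calibration.population_size)
        surrogate = population.subset(
            ids[::stride][: config.calibration.population_size])
        result = model.fit(default_anti_il6_targets(), surrogate,
                           config.calibration.params, seed=config.seed,
                           maxfev=config.calibration.maxfev,
                           n_starts=config.calibration.n_starts)
        ctx["model"] = result.model
        ctx["calibration"] = result
        (out / "calibration.json").write_text(
            json.dumps(result.as_dict(), indent=2))
        record("calibration", out / "calibration.json")

    fitted_model = ctx.get("model", model)

    if "simulate" in stages:
        population = need("population", lambda: load_cohort_file("population"),
                          "simulate")
        for key in ("regimen_a", "regimen_b"):
            regimen = defaults["regimens"][getattr(config.trial, key)]
            res = fitted_model.simulate_arm(population, [regimen])
            ctx[f"arm_{key[-1]}"] = res
            stem = f"arm_{res.name.replace('/', '_')}"
            res.to_long_frame().to_csv(out / f"{stem}.csv", index=False)
            res.summary("CRP").to_csv(out / f"{stem}_crp_summary.csv")
            record(stem, out / f"{stem}.csv")

    if "classify" in stages:
        if "arm_a" not in ctx or "arm_b" not in ctx:
            raise PipelineDependencyError(
                "stage 'classify' requires the 'simulate' stage to run first")
        criterion = defaults["criteria"][config.criterion]
        partition = fitted_model.classify_responders(ctx["arm_a"], ctx["arm_b"],
                                                     criterion)
        (out / "partition.json").write_text(
            json.dumps(partition.as_dict(), indent=2))
        record("partition", out / "partition.json")

    if "combine" in stages:
        population = need("population", lambda: load_cohort_file("population"),
                          "combine")
        reg_a = defaults["regimens"][config.trial.regimen_a]
        reg_b = defaults["regimens"][config.trial.regimen_b]
        res_a, res_b, res_ab = fitted_model.simulate_combination(
            population, reg_a, reg_b, spec=spec)
        summary = {
            "final_day": float(res_ab.times[-1]),
            "median_CRP": {r.name: float(r.series("CRP").iloc[:, -1].median())
                           for r in (res_a, res_b, res_ab)},
            "median_FCP": {r.name: float(r.series("FCP").iloc[:, -1].median())
                           for r in (res_a, res_b, res_ab)},
        }
        (out / "combination.json").write_text(json.dumps(summary, indent=2))
        res_ab.to_long_frame().to_csv(out / "arm_combination.csv", index=False)
        record("combination", out / "combination.json")
        record("arm_combination", out / "arm_combination.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
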