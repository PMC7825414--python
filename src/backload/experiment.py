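"""Configuration-driven experiment runner.

A YAML config describes the whole study: cohort, task battery, sensor
noise, feature provenance, target moment, estimator and sweep settings.
``run_experiment`` executes the staged pipeline

    generate -> features -> train -> sweep -> evaluate -> report

into a run directory.  Each stage writes its outputs plus a manifest entry
keyed by a content hash of the config fields it depends on; re-running with
an unchanged config reuses cached stages.  A master seed is split into
independent per-stage seeds, so stages are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import evaluate as ev
from .anthropometry import AnthroConfig, sample_cohort
from .battery import BatteryConfig, build_task_battery
from .estimator import GbdtConfig, loso_cv
from .features import CANONICAL_LOCATIONS, FeatureMatrix, assemble_dataset, subset_features
from .simulate import NoiseConfig, degrade_to_real, simulate_trial
from .sweep import enumerate_subsets, run_sweep
from .trialio import write_trial

logger = logging.getLogger(__name__)

STAGES = ("generate", "features", "train", "sweep", "evaluate", "report")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Block):
    n: int = 10
    height_mean: float = 1.8
    height_sd: float = 0.1
    mass_mean: float = 79.0
    mass_sd: float = 14.0


class BatteryBlock(_Block):
    box_masses: list[float] = [5.0, 10.0, 15.0, 23.0]
    shelf_pairs: list[list[str]] = [
        ["low", "mid"], ["mid", "low"], ["low", "high"], ["high", "low"], ["mid", "high"]]
    styles: list[str] = ["squat", "stoop", "lateral", "diagonal"]
    repetitions: int = 5


class NoiseBlock(_Block):
    insole_gain_sd: float = 0.15
    insole_additive_sd: float = 20.0
    insole_saturation: float | None = None
    cop_sd: float = 0.01
    imu_angle_bias_sd: float = 0.5
    imu_angle_white_sd: float = 0.3


class FeatureBlock(_Block):
    provenance: str = "idealized"  # idealized | real
    stride: int = 2  # time decimation when assembling training samples


class EstimatorBlock(_Block):
    n_trees: int = 100
    learning_rate: float = 0.1
    max_bins: int = 255
    max_leaves: int = 31
    min_samples_leaf: int = 20


class SweepBlock(_Block):
    subsets: str | list[list[str]] = "named"  # "all" | "named" | explicit list
    named: list[list[str]] = [
        ["trunk"], ["insole"], ["trunk", "insole"], list(CANONICAL_LOCATIONS)]
    stride: int = 4  # extra decimation on top of the feature stride


class ExperimentConfig(_Block):
    seed: int = 0
    rate: float = 100.0
    target: str = "extension"  # extension | lateral_bending
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    battery: BatteryBlock = Field(default_factory=BatteryBlock)
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    features: FeatureBlock = Field(default_factory=FeatureBlock)
    estimator: EstimatorBlock = Field(default_factory=EstimatorBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    save_trials: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def stage_seeds(master: int) -> dict[str, int]:
    """Independent per-stage seeds below 2**31, spawned from the master seed."""
    ss = np.random.SeedSequence(master)
    vals = ss.generate_state(len(STAGES)) % (2**31 - 1)
    return dict(zip(STAGES, (int(v) for v in vals)))


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        return bool(rec and rec["hash"] == digest and all(Path(p).exists() for p in rec["outputs"]))

    def record(self, stage: str, digest: str, outputs: list[Path], seed: int) -> None:
        self.data[stage] = {
            "hash": digest,
            "outputs": [str(p) for p in outputs],
            "seed": seed,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def _simulate_all(config: ExperimentConfig, cohort, tasks, seed: int):
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=(len(cohort), len(tasks)))
    trials = []
    for i, anthro in enumerate(cohort):
        for j, task in enumerate(tasks):
            trials.append(simulate_trial(anthro, task, rate=config.rate,
                                         seed=int(trial_seeds[i, j])))
    return trials


def _features_paths(outdir: Path) -> dict[str, Path]:
    return {
        "values": outdir / "features.npz",
        "channels": outdir / "channels.json",
        "index": outdir / "feature_index.parquet",
    }


def _save_features(outdir: Path, fm: FeatureMatrix, y: np.ndarray) -> list[Path]:
    p = _features_paths(outdir)
    np.savez_compressed(p["values"], values=fm.values, target=y)
    p["channels"].write_text(json.dumps(
        [{"name": c.name, "location": c.location, "kind": c.kind,
          "units": c.units, "requires": list(c.requires)} for c in fm.channels],
        indent=1))
    meta = fm.index.copy()
    meta.to_parquet(p["index"], index=False)
    return list(p.values())


def _load_features(outdir: Path, provenance: str) -> tuple[FeatureMatrix, np.ndarray]:
    from .features import ChannelInfo

    p = _features_paths(outdir)
    data = np.load(p["values"])
    channels = [ChannelInfo(c["name"], c["location"], c["kind"], c["units"],
                            tuple(c["requires"]))
                for c in json.loads(p["channels"].read_text())]
    index = pd.read_parquet(p["index"])
    return FeatureMatrix(data["values"], channels, index, provenance), data["target"]


def run_experiment(
    config: ExperimentConfig,
    outdir: str | Path,
    upto: str = "report",
) -> Path:
    """Execute the pipeline into ``outdir`` up to (and including) ``upto``."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    seeds = stage_seeds(config.seed)
    wanted = STAGES[: STAGES.index(upto) + 1]

    cohort = tasks = None
    fm = y = None
    cv_results = {}
    gbdt = GbdtConfig(seed=seeds["train"], **config.estimator.model_dump())

    def need(stage: str, digest: str, outputs: list[Path]) -> bool:
        if manifest.fresh(stage, digest, outputs):
            logger.info("stage %s cached, skipping", stage)
            return False
        return True

    # ---- generate -------------------------------------------------------
    gen_hash = _hash([config.cohort.model_dump(), config.battery.model_dump(), config.seed])
    cohort_csv = outdir / "cohort.csv"
    battery_csv = outdir / "battery.csv"
    anthro_cfg = AnthroConfig(
        height_mean=config.cohort.height_mean, height_sd=config.cohort.height_sd,
        mass_mean=config.cohort.mass_mean, mass_sd=config.cohort.mass_sd)
    battery_cfg = BatteryConfig(
        box_masses=tuple(config.battery.box_masses),
        shelf_pairs=tuple(tuple(p) for p in config.battery.shelf_pairs),
        styles=tuple(config.battery.styles),
        repetitions=config.battery.repetitions)
    cohort = sample_cohort(config.cohort.n, anthro_cfg, seed=seeds["generate"])
    tasks = build_task_battery(battery_cfg, seed=seeds["generate"] + 1)
    if "generate" in wanted and need("generate", gen_hash, [cohort_csv, battery_csv]):
        t0 = time.time()
        pd.DataFrame([{
            "participant_id": a.participant_id, "body_mass": a.body_mass,
            "body_height": a.body_height, "sex": a.sex} for a in cohort]
        ).to_csv(cohort_csv, index=False)
        pd.DataFrame([{
            "task_id": t.task_id, "box_mass": t.box_mass, "style": t.style,
            "origin": t.origin_shelf.name, "destination": t.destination_shelf.name,
            "duration": t.duration, "pick_time": t.pick_time, "place_time": t.place_time}
            for t in tasks]).to_csv(battery_csv, index=False)
        manifest.record("generate", gen_hash, [cohort_csv, battery_csv], seeds["generate"])
        logger.info("generate: %d participants x %d tasks (%.1fs)",
                    len(cohort), len(tasks), time.time() - t0)
    if upto == "generate":
        return outdir

    # ---- features -------------------------------------------------------
    feat_hash = _hash([gen_hash, config.features.model_dump(), config.noise.model_dump(),
                       config.target, config.rate])
    feat_files = list(_features_paths(outdir).values())
    if "features" in wanted and need("features", feat_hash, feat_files):
        t0 = time.time()
        trials = _simulate_all(config, cohort, tasks, seeds["features"])
        if config.save_trials:
            tdir = outdir / "trials"
            tdir.mkdir(exist_ok=True)
            for tr in trials:
                write_trial(tr, tdir / f"{tr.participant_id}_{tr.task_id}.parquet")
        if config.features.provenance == "real":
            noise = NoiseConfig(**config.noise.model_dump())
            rng = np.random.default_rng(seeds["features"] + 7)
            trials = [degrade_to_real(tr, noise, seed=int(rng.integers(2**31 - 1)))
                      for tr in trials]
        fm, y = assemble_dataset(trials, provenance=config.features.provenance,
                                 target=config.target, stride=config.features.stride)
        _save_features(outdir, fm, y)
        manifest.record("features", feat_hash, feat_files, seeds["features"])
        logger.info("features: %s samples x %s channels (%.1fs)",
                    fm.n_samples, len(fm.channels), time.time() - t0)
    if upto == "features":
        return outdir

    if fm is None:
        fm, y = _load_features(outdir, config.features.provenance)

    def named_subsets():
        if config.sweep.subsets == "all":
            return enumerate_subsets()
        if config.sweep.subsets == "named":
            return [tuple(s) for s in config.sweep.named]
        return [tuple(s) for s in config.sweep.subsets]

    # ---- train ----------------------------------------------------------
    train_hash = _hash([feat_hash, config.estimator.model_dump(), config.sweep.named])
    metrics_json = outdir / "cv_metrics.json"
    pred_parquet = outdir / "cv_predictions.parquet"
    if "train" in wanted and need("train", train_hash, [metrics_json, pred_parquet]):
        t0 = time.time()
        rows = {}
        preds = {}
        for subset in named_subsets():
            name = "+".join(subset)
            cv = loso_cv(subset_features(fm, subset), y, gbdt, keep_models=False)
            rep = ev.accuracy_report(cv, cohort)
            rows[name] = {
                "r2_mean": rep.r2_mean, "r2_per_participant": rep.r2_per_participant,
                "rmse_bwbh": rep.rmse_bwbh, "rmse_nm": rep.rmse_nm,
                "mape_pct": rep.mape_pct, "n_channels": len(subset_features(fm, subset).channels),
            }
            preds[name] = cv.y_pred
        pd.DataFrame({"y_true": y, **{f"pred_{k}": v for k, v in preds.items()}}
                     ).to_parquet(pred_parquet, index=False)
        metrics_json.write_text(json.dumps(
            {"config_hash": train_hash, "seed": config.seed, "subsets": rows}, indent=1))
        manifest.record("train", train_hash, [metrics_json, pred_parquet], seeds["train"])
        logger.info("train: %d subsets (%.1fs)", len(rows), time.time() - t0)
    if upto == "train":
        return outdir

    # ---- sweep ----------------------------------------------------------
    sweep_hash = _hash([train_hash, config.sweep.model_dump()])
    sweep_csv = outdir / "sweep.csv"
    sweep_md = outdir / "sweep.md"
    if "sweep" in wanted and need("sweep", sweep_hash, [sweep_csv, sweep_md]):
        t0 = time.time()
        subsets = enumerate_subsets() if config.sweep.subsets == "all" else named_subsets()
        table = run_sweep(fm, y, cohort, subsets=subsets, config=gbdt,
                          stride=config.sweep.stride)
        table.table.to_csv(sweep_csv, index=False)
        sweep_md.write_text(
            f"# Sensor-subset sweep (config {sweep_hash}, seed {config.seed})\n\n"
            + table.to_markdown() + "\n")
        manifest.record("sweep", sweep_hash, [sweep_csv, sweep_md], seeds["sweep"])
        logger.info("sweep: %d rows (%.1fs)", len(table.table), time.time() - t0)
    if upto == "sweep":
        return outdir

    # ---- evaluate -------------------------------------------------------
    eval_hash = _hash([train_hash, "evaluate-v1"])
    eval_json = outdir / "evaluation.json"
    importance_csv = outdir / "importance.csv"
    if "evaluate" in wanted and need("evaluate", eval_hash, [eval_json, importance_csv]):
        t0 = time.time()
        sub = subset_features(fm, ("trunk", "insole"))
        cv_ti = loso_cv(sub, y, gbdt, keep_models=True)
        imp = ev.cv_permutation_importance(cv_ti, sub, y, repeats=5, seed=seeds["evaluate"])
        imp.table.to_csv(importance_csv, index=False)
        cv_t = loso_cv(subset_features(fm, ("trunk",)), y, gbdt, keep_models=False)
        per_ti, mean_ti = ev.r2_by_participant(cv_ti)
        per_t, mean_t = ev.r2_by_participant(cv_t)
        p_val = ev.wilcoxon_paired(
            np.array([per_ti[p] for p in cv_ti.participants]),
            np.array([per_t[p] for p in cv_ti.participants]))
        eval_json.write_text(json.dumps({
            "config_hash": eval_hash, "seed": config.seed,
            "trunk_insole_r2": {"mean": mean_ti, "per_participant": per_ti},
            "trunk_r2": {"mean": mean_t, "per_participant": per_t},
            "wilcoxon_p_trunk_vs_trunk_insole": p_val,
            "top_channels": imp.top(5),
        }, indent=1))
        manifest.record("evaluate", eval_hash, [eval_json, importance_csv], seeds["evaluate"])
        logger.info("evaluate (%.1fs)", time.time() - t0)
    if upto == "evaluate":
        return outdir

    # ---- report ---------------------------------------------------------
    rep_hash = _hash([eval_hash, sweep_hash, "report-v1"])
    report_md = outdir / "report.md"
    if need("report", rep_hash, [report_md]):
        from .report import render_report

        render_report(outdir, config)
        manifest.record("report", rep_hash, [report_md], seeds["report"])
    return outdir
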