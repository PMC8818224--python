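"""End-to-end experiment orchestration.

simulate → record through both loggers → rail calibration → 14-channel
features → label alignment and cleaning → one random forest per device and
ethogram resolution (2 × 3 = 6 models by default) → evaluation and
two-logger comparison tables.

One master seed fans out deterministically to every stage (per-stage
offsets), so any stage can be re-run in isolation and the whole report is
byte-reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as caio
from .calibrate import CalibrationReference, calibrate
from .classify import (LABEL_COLUMN, PREDICTORS, ModelConfig, SplitSpec,
                       cross_validate, split_dataset, tune_depth)
from .devicesim import (IDEAL_RATE, AccelTrace, DeviceProfile, SessionPlan,
                        apply_device, builtin_profiles, compose_session,
                        default_behaviour_specs, plan_intervals,
                        rotation_about)
from .ethogram import (BehaviourHierarchy, align_labels, default_hierarchy,
                       drop_unassignable)
from .evaluate import (comparison_table, compare_devices,
                       mean_difference, overall_accuracy, per_class_accuracy)
from .features import derive_features

_SEED_MOD = 2**31

# narrative bout template: rests, stalking approaches, and chases; seconds
_SESSION_TEMPLATE: tuple[tuple[str, float], ...] = (
    ("lie", 8.0), ("sit", 4.0), ("head movement", 3.0),
    ("lying stalk", 6.0), ("standing stalk", 4.0), ("walking stalk", 4.0),
    ("walk", 6.0), ("trot", 4.0), ("canter", 4.0), ("gallop", 5.0),
    ("pounce", 1.2), ("other", 4.0),
    ("stand", 5.0), ("crouch", 4.0), ("head movement", 3.0),
    ("crouching stalk", 4.0), ("sitting stalk", 4.0),
    ("trotting stalk", 4.0),
    ("trot", 3.0), ("canter", 3.0), ("gallop", 4.0), ("other", 4.0),
    ("lie", 6.0), ("sit", 3.0), ("stand", 4.0),
    ("walking stalk", 3.0), ("trotting stalk", 3.0),
    ("walk", 4.0), ("gallop", 4.0), ("pounce", 1.0),
)


def stage_seed(master: int, offset: int) -> int:
    """Derive a per-stage seed from the master seed (kept below 2^31)."""
    return (master * 1009 + offset) % _SEED_MOD


def default_session_plan(size: str = "small", seed: int = 0,
                         mounting_angle: float = 20.0) -> SessionPlan:
    """Build an exercise-bout plan covering all 17 fine behaviours.

    ``small`` is one pass of the bout template (≈ 2 min of recording);
    ``full`` repeats it six times (≈ 12 min, i.e. a typical bout of several
    chases punctuated by rests). A mounting offset of ``mounting_angle``
    degrees about a seeded axis emulates a non-centred collar.
    """
    repeats = {"small": 1, "full": 6}.get(size)
    if repeats is None:
        raise ValueError("size must be 'small' or 'full'")
    rng = np.random.default_rng(stage_seed(seed, 11))
    axis = rng.normal(size=3)
    offset = rotation_about(axis, mounting_angle)
    return SessionPlan(segments=_SESSION_TEMPLATE * repeats,
                       rail_window=10.0, mounting_offset=offset,
                       noise_sd=0.05, seed=stage_seed(seed, 13))


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the six-model experiment."""

    plan: SessionPlan
    devices: tuple[DeviceProfile, ...]
    resolutions: tuple[str, ...] = ("fine", "medium", "coarse")
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.devices or not self.resolutions:
            raise ValueError("need at least one device and one resolution")


def default_config(size: str = "small", seed: int = 0,
                   output_dir: str | None = None,
                   n_trees: int = 500,
                   depth_grid: tuple[int | None, ...] = (5, 10, 20)
                   ) -> ExperimentConfig:
    return ExperimentConfig(
        plan=default_session_plan(size, seed),
        devices=builtin_profiles(),
        split=SplitSpec(seed=stage_seed(seed, 17)),
        model=ModelConfig(seed=stage_seed(seed, 19), n_trees=n_trees,
                          depth_grid=depth_grid),
        output_dir=output_dir,
        seed=seed)


def build_device_dataset(ideal: AccelTrace, intervals: pd.DataFrame,
                         device: DeviceProfile,
                         rail_window: float) -> tuple[pd.DataFrame, dict]:
    """Record, calibrate, featurise, and label one device's view.

    Returns the cleaned per-sample dataset (14 predictors + fine behaviour
    label) and a small provenance dict (rows removed, residual angle).
    """
    recorded = apply_device(ideal, device)
    ref = CalibrationReference(window=(0.5, rail_window - 0.5))
    corrected, corr = calibrate(recorded, ref)
    feats = derive_features(corrected)
    track = align_labels(intervals, corrected)
    feats[LABEL_COLUMN] = track.labels
    dataset, removed = drop_unassignable(feats)
    prov = {"device": device.name, "rows": len(dataset),
            "rows_removed_unassignable": removed,
            "calibration_residual_deg": corr.residual_angle}
    return dataset, prov


def _collapse_column(labels: pd.Series, level: str,
                     hierarchy: BehaviourHierarchy) -> pd.Series:
    if level == "fine":
        return labels
    mapping = hierarchy.map_for(level)
    return labels.map(mapping)


def run_experiment(config: ExperimentConfig,
                   hierarchy: BehaviourHierarchy | None = None) -> dict:
    """Run the full experiment; returns (and optionally writes) the report.

    The report nests per-device, per-resolution metrics (train / validation
    / test / 5-fold CV), confusion matrices, importance tables, and — when
    two devices are configured — per-behaviour comparison tables with the
    mean accuracy difference per resolution.
    """
    hierarchy = hierarchy or default_hierarchy()
    specs = default_behaviour_specs()
    ideal, _ = compose_session(config.plan, specs, rate=IDEAL_RATE)
    intervals = plan_intervals(config.plan)

    datasets: dict[str, pd.DataFrame] = {}
    report: dict = {"seed": config.seed, "devices": {}, "comparisons": {},
                    "provenance": []}
    for device in config.devices:
        ds, prov = build_device_dataset(ideal, intervals, device,
                                        config.plan.rail_window)
        datasets[device.name] = ds
        report["provenance"].append(prov)

    fits: dict[tuple[str, str], dict] = {}
    for di, device in enumerate(config.devices):
        dev_report: dict = {}
        base = datasets[device.name]
        for ri, level in enumerate(config.resolutions):
            ds = base.copy()
            ds[LABEL_COLUMN] = _collapse_column(ds[LABEL_COLUMN], level,
                                                hierarchy)
            split = replace(config.split,
                            seed=stage_seed(config.seed, 100 + di))
            mconf = replace(config.model,
                            seed=stage_seed(config.seed,
                                            200 + 10 * di + ri))
            train, valid, test = split_dataset(ds, split)
            fit = tune_depth(train, valid, mconf)
            fit.evaluate_test(test)
            _, cv_summary = cross_validate(train, mconf,
                                           max_depth=fit.chosen_depth)
            cm_valid = fit.confusion_valid
            entry = {
                "level": level,
                "chosen_depth": fit.chosen_depth,
                "n_trees": fit.n_trees_used,
                "metrics": {tag: vars(m) for tag, m in fit.metrics.items()},
                "cv": vars(cv_summary),
                "overall_accuracy_pct": overall_accuracy(cm_valid, set()),
                "overall_accuracy_other_disregarded_pct":
                    overall_accuracy(cm_valid, {"other"}),
                "per_class_accuracy_pct": per_class_accuracy(cm_valid),
                "confusion_valid": cm_valid.to_dict(),
                "importance": fit.importance.to_dict("records"),
            }
            dev_report[level] = entry
            fits[(device.name, level)] = {
                "fit": fit, "valid": valid, "entry": entry}
        report["devices"][device.name] = dev_report

    # structural check: collapsing the fine model's validation predictions
    # to coarse can only merge errors away, never create them
    if "fine" in config.resolutions and "coarse" in config.resolutions:
        coarse_map = hierarchy.map_for("coarse")
        for device in config.devices:
            f = fits[(device.name, "fine")]
            valid = f["valid"]
            pred = f["fit"].model.predict(
                valid[PREDICTORS].to_numpy(float))
            truth = valid[LABEL_COLUMN].to_numpy(object)
            fine_acc = float(np.mean(pred == truth))
            coll_acc = float(np.mean(
                np.array([coarse_map[p] for p in pred], object)
                == np.array([coarse_map[t] for t in truth], object)))
            assert coll_acc >= fine_acc - 1e-12
            report["devices"][device.name].setdefault(
                "collapse_check", {})["fine_accuracy"] = fine_acc
            report["devices"][device.name][
                "collapse_check"]["collapsed_coarse_accuracy"] = coll_acc

    if len(config.devices) == 2:
        dev_a, dev_b = (d.name for d in config.devices)
        for level in config.resolutions:
            cm_a = fits[(dev_a, level)]["fit"].confusion_valid
            cm_b = fits[(dev_b, level)]["fit"].confusion_valid
            rows = []
            for beh in hierarchy.vocabulary(level):
                if beh == "other":
                    continue
                if beh not in cm_a.index or beh not in cm_b.index:
                    continue
                n_a, n_b = int(cm_a.loc[beh].sum()), int(cm_b.loc[beh].sum())
                if n_a == 0 or n_b == 0:
                    continue
                rows.append(compare_devices(
                    beh, int(cm_a.loc[beh, beh]), n_a,
                    int(cm_b.loc[beh, beh]), n_b,
                    device_a=dev_a, device_b=dev_b))
            report["comparisons"][level] = {
                "table": comparison_table(rows).to_dict("records"),
                "mean_difference": mean_difference(rows),
            }

    if config.output_dir is not None:
        _write_report(report, fits, config)
    return report


def _write_report(report: dict, fits: dict, config: ExperimentConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=float))
    for (dev, level), f in fits.items():
        tag = f"{dev.lower()}_{level}"
        f["fit"].confusion_valid.to_csv(out / f"confusion_valid_{tag}.csv")
        if f["fit"].confusion_test is not None:
            f["fit"].confusion_test.to_csv(out / f"confusion_test_{tag}.csv")
        f["fit"].importance.to_csv(out / f"importance_{tag}.csv",
                                   index=False)
    for level, comp in report["comparisons"].items():
        pd.DataFrame(comp["table"]).to_csv(
            out / f"comparison_{level}.csv", index=False)


def make_fixture(output_dir, size: str = "small", seed: int = 0) -> dict:
    """Write a ready-to-run synthetic session to disk.

    Produces one trace CSV per built-in device profile, the fine label
    intervals, and the session plan (seed included), all derived from one
    ideal ground-truth recording.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    plan = default_session_plan(size, seed)
    specs = default_behaviour_specs()
    ideal, _ = compose_session(plan, specs, rate=IDEAL_RATE)
    intervals = plan_intervals(plan)
    paths = {"plan": out / "plan.yaml", "labels": out / "labels.csv"}
    caio.write_plan_yaml(plan, paths["plan"])
    caio.write_labels_csv(intervals, paths["labels"])
    for device in builtin_profiles():
        rec = apply_device(ideal, device)
        p = out / f"trace_{device.name.lower()}.csv"
        caio.write_trace_csv(rec, p)
        paths[device.name] = p
    return {k: str(v) for k, v in paths.items()}
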