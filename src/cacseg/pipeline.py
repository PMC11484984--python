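"""End-to-end pipeline: phantoms -> (optional AL) -> training -> scoring -> report.

A run is fully determined by its :class:`RunConfig` (one master seed; every
random stream is derived from it). Artifacts — phantom cases, the model
checkpoint, predicted masks, score reports, confusion matrices, the metric
report and a manifest with per-stage wall times — are written under a run
directory so a re-run with the same config reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .agatston import find_lesions, assign_segments_from_mask, score_report, RiskPolicy
from .active_learning import run_al_loop
from .evaluation import (binary_detection_metrics, confusion_from_matches,
                         linear_weighted_kappa, match_lesions, micro_metrics,
                         per_class_metrics, weighted_kappa, ConfusionMatrix)
from .multitask import MultiTaskConfig, MultiTaskModel, build_slice_dataset
from .phantom import PhantomConfig, generate_phantom, write_case, write_volume
from .segments import load_default_diagram
from .evaluation import RISK_LABELS

__all__ = ["RunConfig", "run_pipeline", "segment_recovery_experiment",
           "zero_cac_filter_experiment"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (seed + all stage parameters)."""

    seed: int = 0
    n_cases: int = 10
    zero_cac_fraction: float = 0.2
    train_fraction: float = 0.6
    val_fraction: float = 0.1
    region_fraction: float = 0.5
    epochs: int = 10
    use_active_learning: bool = False
    al_rounds: int = 3
    al_budget: int = 5
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: MultiTaskConfig = field(default_factory=MultiTaskConfig)
    risk_policy: RiskPolicy = field(default_factory=RiskPolicy)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("phantom", {}).items()})
        model = MultiTaskConfig(**raw.pop("model", {}))
        policy = RiskPolicy(**raw.pop("risk_policy", {}))
        return cls(phantom=phantom, model=model, risk_policy=policy, **raw)


def _generate_cases(cfg: RunConfig):
    rng = np.random.default_rng(cfg.seed)
    n_zero = int(round(cfg.zero_cac_fraction * cfg.n_cases))
    flags = np.zeros(cfg.n_cases, dtype=bool)
    flags[rng.choice(cfg.n_cases, size=n_zero, replace=False)] = True
    from dataclasses import replace as dc_replace
    cases = [
        generate_phantom(dc_replace(cfg.phantom, zero_cac=bool(z)),
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
        for z in flags
    ]
    n_train = int(round(cfg.train_fraction * cfg.n_cases))
    n_val = int(round(cfg.val_fraction * cfg.n_cases))
    return cases[:n_train], cases[n_train:n_train + n_val], cases[n_train + n_val:]


def _evaluate_split(cases, model, cfg: RunConfig):
    diagram = load_default_diagram()
    pairs, risk_counts = [], np.zeros((4, 4), dtype=np.int64)
    vol_stats = []
    for case in cases:
        pred_mask = model.predict_segment_mask(case.image)
        truth = find_lesions(case.cac_mask, case.image)
        assign_segments_from_mask(truth, case.cac_mask)
        m = match_lesions(truth, case.cac_mask, pred_mask)
        pairs.extend(m.pairs)
        vol_stats.append(binary_detection_metrics(case.cac_mask, pred_mask, truth))

        ref_total = score_report(truth, diagram, cfg.risk_policy).total
        pred_lesions = find_lesions(pred_mask, case.image)
        assign_segments_from_mask(pred_lesions, pred_mask)
        pred_total = (score_report(pred_lesions, diagram, cfg.risk_policy).total
                      if pred_lesions else 0.0)
        i = RISK_LABELS.index(cfg.risk_policy.category(ref_total))
        j = RISK_LABELS.index(cfg.risk_policy.category(pred_total))
        risk_counts[i, j] += 1

    cm = confusion_from_matches(pairs, diagram)
    risk_cm = ConfusionMatrix(risk_counts, RISK_LABELS)

    def _safe(fn, *args):
        # degenerate matrices (tiny runs, single occupied category) have no kappa
        try:
            return fn(*args)
        except ValueError:
            return None

    report = {
        "n_matched_lesions": cm.total,
        "micro": _safe(micro_metrics, cm),
        "segment_weighted_kappa": _safe(weighted_kappa, cm,
                                        diagram.disagreement_weights()),
        "risk_linear_weighted_kappa": _safe(linear_weighted_kappa, risk_cm),
        "voxel_f1_mean": float(np.mean([s["volume"]["f1"] for s in vol_stats])),
    }
    return cm, risk_cm, report


def segment_recovery_experiment(
    n_train: int = 20,
    n_test: int = 5,
    epochs: int = 20,
    seed: int = 0,
    phantom: PhantomConfig | None = None,
    model_config: MultiTaskConfig | None = None,
) -> tuple[MultiTaskModel, dict]:
    """Train the multi-task model on easy phantoms and measure recovery.

    Returns the trained model and a report with the lesion-level
    correct-segment assignment rate and the mean voxel-level binary F1 on
    held-out phantoms — the toy-scale analogue of a reader-study evaluation.
    """
    phantom = phantom or PhantomConfig()
    rng = np.random.default_rng(seed)
    train_cases = [generate_phantom(phantom, seed=int(rng.integers(0, 2 ** 31 - 1)))
                   for _ in range(n_train)]
    test_cases = [generate_phantom(phantom, seed=int(rng.integers(0, 2 ** 31 - 1)))
                  for _ in range(n_test)]
    samples = build_slice_dataset(train_cases, region_fraction=0.5, seed=seed)
    model = MultiTaskModel(model_config or MultiTaskConfig(seed=seed))
    model.fit(samples, epochs=epochs)

    n_correct = n_lesions = 0
    voxel_f1 = []
    for case in test_cases:
        pred = model.predict_segment_mask(case.image)
        truth = find_lesions(case.cac_mask, case.image)
        assign_segments_from_mask(truth, case.cac_mask)
        m = match_lesions(truth, case.cac_mask, pred)
        n_lesions += len(truth)
        n_correct += sum(1 for ref, hyp in m.pairs if ref == hyp)
        voxel_f1.append(
            binary_detection_metrics(case.cac_mask, pred)["volume"]["f1"])
    report = {
        "n_train": n_train,
        "n_test": n_test,
        "n_lesions": n_lesions,
        "lesion_segment_accuracy": n_correct / n_lesions if n_lesions else None,
        "voxel_f1_mean": float(np.mean(voxel_f1)),
    }
    return model, report


def zero_cac_filter_experiment(
    model: MultiTaskModel,
    n_cases: int = 10,
    extra_noise_sd: float = 15.0,
    seed: int = 0,
    phantom: PhantomConfig | None = None,
) -> dict:
    """False-positive lesion counts on noisy calcium-free phantoms.

    Predicts each noisy zero-CAC phantom with the zero-CAC filter disabled and
    enabled and counts false-positive lesions; the filter can only remove
    predicted calcium, so the filtered count must never exceed the unfiltered
    one.
    """
    from dataclasses import replace as dc_replace
    from .phantom import degrade_with_noise

    phantom = dc_replace(phantom or PhantomConfig(), zero_cac=True)
    rng = np.random.default_rng(seed)
    off = dc_replace(model.config, use_zero_cac_filter=False)
    unfiltered, filtered = [], []
    for _ in range(n_cases):
        case = generate_phantom(phantom, seed=int(rng.integers(0, 2 ** 31 - 1)))
        noisy = degrade_with_noise(case.image, extra_noise_sd,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)))

        def _n_fp(cfg):
            model.config = cfg
            pred = model.predict_segment_mask(noisy)
            return len(find_lesions(pred, noisy))

        original = model.config
        try:
            unfiltered.append(_n_fp(off))
            filtered.append(_n_fp(dc_replace(original, use_zero_cac_filter=True)))
        finally:
            model.config = original
    return {
        "n_cases": n_cases,
        "fp_unfiltered": unfiltered,
        "fp_filtered": filtered,
        "max_fp_increase": max(f - u for f, u in zip(filtered, unfiltered)),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns the metric report (also written to disk)."""
    out = Path(out_dir)
    if (out / "manifest.json").exists():
        raise FileExistsError(
            f"{out} already holds a completed run; use a fresh directory")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    t0 = time.time()

    train_cases, val_cases, test_cases = _generate_cases(config)
    for i, case in enumerate(train_cases + val_cases + test_cases):
        write_case(case, out / "cases" / f"case_{i:03d}")
    manifest["stages"]["generate"] = {"seconds": time.time() - t0,
                                      "n_train": len(train_cases),
                                      "n_val": len(val_cases),
                                      "n_test": len(test_cases)}

    t1 = time.time()
    samples = build_slice_dataset(train_cases, config.region_fraction,
                                  seed=config.seed)
    if config.use_active_learning:
        model, state = run_al_loop(samples, config.model,
                                   n_rounds=config.al_rounds,
                                   budget=config.al_budget, seed=config.seed)
        (out / "al_history.json").write_text(json.dumps(state.history, indent=2))
    else:
        model = MultiTaskModel(config.model)
        model.fit(samples, epochs=config.epochs,
                  log_path=out / "training_log.csv")
    model.save(out / "checkpoint.npz")
    manifest["stages"]["train"] = {"seconds": time.time() - t1,
                                   "n_slices": len(samples)}

    t2 = time.time()
    (out / "predictions").mkdir(parents=True, exist_ok=True)
    for i, case in enumerate(test_cases):
        mask = model.predict_segment_mask(case.image)
        write_volume(out / "predictions" / f"test_{i:03d}_mask.nii.gz",
                     mask.voxels, case.image.in_plane_spacing,
                     case.image.slice_thickness)
    cm, risk_cm, report = _evaluate_split(test_cases, model, config)
    cm.to_csv(out / "segment_confusion.csv")
    risk_cm.to_csv(out / "risk_confusion.csv")
    per_class_metrics(cm).to_csv(out / "per_class_metrics.csv")
    (out / "metric_report.json").write_text(json.dumps(report, indent=2))
    manifest["stages"]["evaluate"] = {"seconds": time.time() - t2}

    manifest["total_seconds"] = time.time() - t0
    manifest["config"] = json.loads(json.dumps(asdict(config), default=str))
    manifest["artifacts"] = sorted(str(p.relative_to(out))
                                   for p in out.rglob("*") if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
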