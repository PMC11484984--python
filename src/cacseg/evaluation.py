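"""Agreement and performance statistics for segment-level calcium scoring.

Covers lesion matching between a reference and a predicted mask, K x K
lesion-assignment confusion matrices, micro and per-class detection metrics,
Cohen's kappa with an arbitrary disagreement-weight matrix (adjoining-segment
disagreements weighted 0.5), ordinal linear-weighted kappa for the four CVD
risk categories, ICC(2,1) absolute agreement, binary detection metrics on the
voxel and lesion level, and seeded percentile-bootstrap confidence intervals.

Micro metrics are computed over correctly *detected* lesions only (a missed
lesion never enters the assignment confusion matrix), which is why micro
sensitivity and micro precision coincide with the correct-assignment fraction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .agatston import Lesion
from .phantom import LabelVolume
from .segments import SegmentDiagram, SEGMENT_LABELS, load_default_diagram

__all__ = [
    "ConfusionMatrix", "MetricSet", "match_lesions", "confusion_from_matches",
    "micro_metrics", "per_class_metrics", "weighted_kappa",
    "linear_weighted_kappa", "binary_detection_metrics",
    "icc_absolute_agreement", "bootstrap_ci",
    "load_reference_segment_confusion", "load_reference_risk_confusion",
]

RISK_LABELS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are the reference, columns the prediction."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.labels):
            raise ValueError("label list does not match matrix size")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "reference"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(df.to_numpy(), tuple(df.columns))


@dataclass
class MetricSet:
    """Per-class and micro-averaged metrics, optionally with 95% CIs."""

    per_class: pd.DataFrame | None = None
    micro: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def load_reference_segment_confusion() -> ConfusionMatrix:
    """13x13 segment-assignment confusion matrix of the published multicenter
    test set (1797 matched lesions), shipped as a package fixture."""
    ref = importlib.resources.files("cacseg.data") / "segment_confusion_test.csv"
    with importlib.resources.as_file(ref) as p:
        return ConfusionMatrix.from_csv(p)


def load_reference_risk_confusion() -> ConfusionMatrix:
    """4x4 CVD risk-category confusion matrix of the published multicenter
    test set (455 patients), shipped as a package fixture."""
    ref = importlib.resources.files("cacseg.data") / "risk_confusion_test.csv"
    with importlib.resources.as_file(ref) as p:
        return ConfusionMatrix.from_csv(p)


# ---------------------------------------------------------------------------
# lesion matching

@dataclass
class MatchResult:
    """Outcome of matching reference lesions against a predicted label volume."""

    pairs: list[tuple[str, str]]  # (reference label, predicted label)
    missed: list[int]  # lesion ids with no predicted overlap
    false_positive_components: int

    @property
    def n_detected(self) -> int:
        return len(self.pairs)


def match_lesions(
    truth_lesions: list[Lesion],
    truth_mask: LabelVolume,
    predicted: LabelVolume,
) -> MatchResult:
    """Match reference lesions to predicted segment labels.

    A reference lesion counts as detected iff at least one of its voxels
    overlaps predicted foreground; its predicted segment is the majority
    predicted label over the overlap (ties broken toward the lower canonical
    index). Predicted components with no reference overlap are false positives.
    """
    if truth_mask.shape != predicted.shape:
        raise ValueError("reference and prediction geometries differ")
    pred = predicted.voxels
    pairs, missed = [], []
    for les in truth_lesions:
        if les.segment is None:
            raise ValueError(f"reference lesion {les.lesion_id} unlabeled")
        vox = les.voxel_set
        plabels = pred[vox[:, 0], vox[:, 1], vox[:, 2]]
        plabels = plabels[plabels > 0]
        if plabels.size == 0:
            missed.append(les.lesion_id)
            continue
        counts = np.bincount(plabels, minlength=len(SEGMENT_LABELS) + 1)
        pred_label = SEGMENT_LABELS[int(counts[1:].argmax())]  # argmax: lowest index wins ties
        pairs.append((les.segment, pred_label))

    truth_fg = truth_mask.voxels > 0
    comp, n = ndimage.label(pred > 0, structure=np.ones((3, 3, 3)))
    fp = sum(1 for cid in range(1, n + 1)
             if not truth_fg[comp == cid].any())
    return MatchResult(pairs, missed, fp)


def confusion_from_matches(
    matches: MatchResult | list[tuple[str, str]],
    diagram: SegmentDiagram | None = None,
) -> ConfusionMatrix:
    """Aggregate matched (reference, predicted) label pairs into a matrix."""
    diagram = diagram or load_default_diagram()
    pairs = matches.pairs if isinstance(matches, MatchResult) else matches
    k = len(diagram.labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for ref, pred in pairs:
        counts[diagram.index(ref), diagram.index(pred)] += 1
    return ConfusionMatrix(counts, tuple(diagram.labels))


# ---------------------------------------------------------------------------
# confusion-matrix statistics

def micro_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Micro-averaged precision, sensitivity, specificity and F1.

    Over a single multi-class assignment matrix, micro precision and micro
    sensitivity both equal trace/total (each off-diagonal count is one FP and
    one FN); micro specificity pools the per-class TN/(TN+FP) counts.
    """
    c = cm.counts
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    tr = np.trace(c)
    row, col, diag = c.sum(axis=1), c.sum(axis=0), np.diag(c)
    tn = n - row - col + diag
    fp = col - diag
    sens = prec = tr / n
    spec = tn.sum() / (tn + fp).sum()
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    return {"precision": float(prec), "sensitivity": float(sens),
            "specificity": float(spec), "f1": float(f1)}


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest precision/sensitivity/specificity/F1 per class.

    Undefined ratios (0/0, e.g. a class that is never predicted) are reported
    as 0.0 with ``undefined=True``, mirroring the dash convention of reader
    studies.
    """
    c = cm.counts.astype(float)
    n = c.sum()
    row, col, diag = c.sum(axis=1), c.sum(axis=0), np.diag(c)
    tp, fp, fn = diag, col - diag, row - diag
    tn = n - row - col + diag

    def safe(num, den):
        den = np.asarray(den, dtype=float)
        out = np.zeros_like(den)
        ok = den > 0
        out[ok] = np.asarray(num, dtype=float)[ok] / den[ok]
        return out, ~ok

    prec, prec_undef = safe(tp, tp + fp)
    sens, sens_undef = safe(tp, tp + fn)
    spec, _ = safe(tn, tn + fp)
    f1_den = 2 * tp + fp + fn
    f1, f1_undef = safe(2 * tp, f1_den)
    return pd.DataFrame({
        "support": row.astype(int),
        "precision": prec, "sensitivity": sens,
        "specificity": spec, "f1": f1,
        "undefined": prec_undef | sens_undef | f1_undef,
    }, index=list(cm.labels))


def weighted_kappa(cm: ConfusionMatrix, W: np.ndarray) -> float:
    """Cohen's kappa with an arbitrary disagreement-weight matrix.

    kappa_w = 1 - sum(W * p_obs) / sum(W * p_exp), with p_exp the outer
    product of the marginal proportions. W must be symmetric with zero
    diagonal and entries in [0, 1]; all-ones off-diagonal W recovers the
    unweighted kappa.
    """
    W = np.asarray(W, dtype=float)
    c = cm.counts
    if W.shape != c.shape:
        raise ValueError("weight matrix shape does not match the confusion matrix")
    if np.diag(W).any() or not np.allclose(W, W.T) or W.min() < 0 or W.max() > 1:
        raise ValueError("W must be symmetric, zero-diagonal, entries in [0, 1]")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    p = c / cm.total
    e = np.outer(p.sum(axis=1), p.sum(axis=0))
    expected = (W * e).sum()
    if expected <= 0:
        raise ValueError("degenerate marginals: expected disagreement is zero")
    return float(1.0 - (W * p).sum() / expected)


def linear_weighted_kappa(cm: ConfusionMatrix) -> float:
    """Linear ordinal weighted kappa: W_ij = |i - j| / (K - 1)."""
    k = len(cm.labels)
    if k < 2:
        raise ValueError("need at least two ordered categories")
    W = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    return weighted_kappa(cm, W)


# ---------------------------------------------------------------------------
# binary detection and continuous agreement

def binary_detection_metrics(
    truth_mask: LabelVolume,
    predicted: LabelVolume,
    truth_lesions: list[Lesion] | None = None,
) -> dict[str, dict[str, float]]:
    """Precision/sensitivity/F1 for binary calcium detection.

    ``volume`` level counts voxels (foreground vs background); ``lesion``
    level counts detected / missed reference lesions and false-positive
    predicted components (requires ``truth_lesions``).
    """
    if truth_mask.shape != predicted.shape:
        raise ValueError("mask geometries differ")
    t = truth_mask.voxels > 0
    p = predicted.voxels > 0
    tp = float((t & p).sum())
    prec = tp / p.sum() if p.sum() else 0.0
    sens = tp / t.sum() if t.sum() else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    out = {"volume": {"precision": prec, "sensitivity": sens, "f1": f1}}
    if truth_lesions is not None:
        # binary detection does not need segment labels, only overlap
        n_det = sum(
            1 for les in truth_lesions
            if (predicted.voxels[les.voxel_set[:, 0], les.voxel_set[:, 1],
                                 les.voxel_set[:, 2]] > 0).any())
        n_miss = len(truth_lesions) - n_det
        comp, ncomp = ndimage.label(p, structure=np.ones((3, 3, 3)))
        n_fp = sum(1 for cid in range(1, ncomp + 1)
                   if not t[comp == cid].any())
        lprec = n_det / (n_det + n_fp) if n_det + n_fp else 0.0
        lsens = n_det / (n_det + n_miss) if n_det + n_miss else 0.0
        lf1 = 2 * lprec * lsens / (lprec + lsens) if lprec + lsens else 0.0
        out["lesion"] = {"precision": lprec, "sensitivity": lsens, "f1": lf1,
                         "detected": n_det, "missed": n_miss,
                         "false_positives": n_fp}
    return out


def icc_absolute_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    Closed form from the two-way ANOVA decomposition with n subjects and k=2
    raters. Returns NaN if both raters are constant (agreement undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    data = np.stack([x, y], axis=1)  # (n, k)
    n, k = data.shape
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        return float("nan")
    return float((msr - mse) / denom)


def bootstrap_ci(
    statistic,
    data,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for ``statistic(resampled_data)``.

    ``data`` is a sequence of exchangeable units (lesions for assignment
    metrics, patients for risk agreement); the statistic receives a resampled
    list of the same length.
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    data = list(data)
    if len(data) < 2:
        raise ValueError("need at least 2 units to resample")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    n = len(data)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        stats[b] = statistic([data[i] for i in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
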