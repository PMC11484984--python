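"""Agreement statistics: confusion metrics, weighted kappa, ICC, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

import cacseg
from cacseg import LabelVolume
from cacseg.agatston import find_lesions, assign_segments_from_mask
from cacseg.evaluation import (ConfusionMatrix, bootstrap_ci,
                               binary_detection_metrics, confusion_from_matches,
                               icc_absolute_agreement, linear_weighted_kappa,
                               match_lesions, micro_metrics, per_class_metrics,
                               weighted_kappa)
from cacseg.segments import SEGMENT_LABELS


def _expand(cm):
    """Label pairs from a counts matrix (for the sklearn oracle)."""
    yt, yp = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            yt += [i] * cm[i, j]
            yp += [j] * cm[i, j]
    return yt, yp


# ---------------------------------------------------------------------------
# published test-set matrices

def test_reference_segment_matrix_totals(segment_cm):
    assert segment_cm.total == 1797
    assert list(segment_cm.labels) == list(SEGMENT_LABELS)
    assert int(np.trace(segment_cm.counts)) == 1316


def test_micro_metrics_on_reference_matrix(segment_cm):
    m = micro_metrics(segment_cm)
    assert m["sensitivity"] == pytest.approx(1316 / 1797)
    assert round(m["sensitivity"], 3) == 0.732
    assert round(m["specificity"], 3) == 0.978
    assert m["precision"] == m["sensitivity"]  # single-label assignment task


def test_per_class_sensitivities_on_reference_matrix(segment_cm):
    pc = per_class_metrics(segment_cm)
    assert round(pc.loc["p-RCA", "sensitivity"], 2) == 0.94
    assert round(pc.loc["m-LAD", "sensitivity"], 2) == 0.53
    assert round(pc.loc["p-LCX", "sensitivity"], 2) == 0.80
    assert pc.loc["s-RCA", "sensitivity"] == 0.0
    assert pc.loc["s-RCA", "undefined"]  # never predicted: 0/0 precision
    # micro sensitivity is the support-weighted mean of class sensitivities
    m = micro_metrics(segment_cm)
    weighted = (pc["sensitivity"] * pc["support"]).sum() / pc["support"].sum()
    assert weighted == pytest.approx(m["sensitivity"])


def test_risk_matrix_marginals_and_kappa(risk_cm):
    assert list(risk_cm.counts.sum(axis=1)) == [194, 121, 66, 74]
    assert list(risk_cm.counts.sum(axis=0)) == [164, 145, 69, 77]
    assert risk_cm.total == 455
    assert round(linear_weighted_kappa(risk_cm), 3) == 0.909


def test_segment_kappa_under_adjacency_weights(segment_cm, diagram):
    kappa = weighted_kappa(segment_cm, diagram.disagreement_weights())
    assert 0.75 <= kappa <= 0.85


# ---------------------------------------------------------------------------
# kappa properties and oracle equivalence

def test_weighted_kappa_perfect_agreement():
    cm = ConfusionMatrix(np.diag([5, 3, 2]), ("a", "b", "c"))
    W = 1.0 - np.eye(3)
    assert weighted_kappa(cm, W) == pytest.approx(1.0)


def test_linear_kappa_antidiagonal_is_minus_one():
    cm = ConfusionMatrix(np.array([[0, 5], [5, 0]]), ("lo", "hi"))
    assert linear_weighted_kappa(cm) == pytest.approx(-1.0)


def test_all_ones_weights_reduce_to_unweighted_kappa_oracle():
    """kappa_w with W = 1 - I equals textbook unweighted Cohen's kappa."""
    rng = np.random.default_rng(12345)
    for _ in range(100):
        counts = rng.integers(0, 20, size=(4, 4))
        counts[0, 0] += 5  # ensure non-degenerate marginals
        cm = ConfusionMatrix(counts, ("a", "b", "c", "d"))
        W = 1.0 - np.eye(4)
        yt, yp = _expand(counts)
        assert weighted_kappa(cm, W) == pytest.approx(
            cohen_kappa_score(yt, yp), abs=1e-12)


def test_linear_kappa_matches_sklearn_on_reference_matrix(risk_cm):
    yt, yp = _expand(risk_cm.counts)
    assert linear_weighted_kappa(risk_cm) == pytest.approx(
        cohen_kappa_score(yt, yp, weights="linear"), abs=1e-12)


def test_weighted_kappa_rejects_bad_weight_matrices(segment_cm):
    with pytest.raises(ValueError):
        weighted_kappa(segment_cm, np.eye(13))  # nonzero diagonal
    with pytest.raises(ValueError):
        weighted_kappa(segment_cm, np.ones((4, 4)) - np.eye(4))  # wrong shape


# ---------------------------------------------------------------------------
# lesion matching

def test_match_lesions_rules(phantom_case):
    truth = find_lesions(phantom_case.cac_mask, phantom_case.image)
    assign_segments_from_mask(truth, phantom_case.cac_mask)

    perfect = match_lesions(truth, phantom_case.cac_mask, phantom_case.cac_mask)
    assert perfect.n_detected == len(truth)
    assert not perfect.missed and perfect.false_positive_components == 0
    assert all(r == p for r, p in perfect.pairs)

    empty = LabelVolume(np.zeros_like(phantom_case.cac_mask.voxels))
    nothing = match_lesions(truth, phantom_case.cac_mask, empty)
    assert nothing.n_detected == 0
    assert len(nothing.missed) == len(truth)


def test_match_lesions_majority_overlap_rule():
    truth_mask = np.zeros((1, 4, 10), dtype=np.int16)
    truth_mask[0, 1:3, 0:5] = 1  # one 10-voxel p-RCA lesion
    img = cacseg.CTVolume(np.where(truth_mask > 0, 300.0, 0.0))
    truth = find_lesions(LabelVolume(truth_mask), img)
    assign_segments_from_mask(truth, LabelVolume(truth_mask))

    pred = np.zeros_like(truth_mask)
    pred[0, 1:3, 0:3] = 2   # 6 voxels m-RCA
    pred[0, 1:3, 3:5] = 3   # 4 voxels d-RCA
    m = match_lesions(truth, LabelVolume(truth_mask), LabelVolume(pred))
    assert m.pairs == [("p-RCA", "m-RCA")]  # 60/40 majority

    pred[0, 1:3, 3:5] = 0
    pred[0, 1:3, 0:3] = 0
    pred[0, 1, 0:2] = 5     # tie 2 vs 2 -> lower canonical index wins
    pred[0, 1, 2:4] = 9
    m = match_lesions(truth, LabelVolume(truth_mask), LabelVolume(pred))
    assert m.pairs == [("p-RCA", SEGMENT_LABELS[4])]


def test_confusion_from_matches_counts(diagram):
    cm = confusion_from_matches([("p-RCA", "p-RCA")], diagram)
    assert cm.counts[0, 0] == 1 and cm.total == 1
    cm = confusion_from_matches([(l, l) for l in SEGMENT_LABELS], diagram)
    assert np.trace(cm.counts) == 13
    assert cm.counts.sum() - np.trace(cm.counts) == 0


def test_binary_detection_metrics_counting(phantom_case):
    truth = find_lesions(phantom_case.cac_mask, phantom_case.image)
    ident = binary_detection_metrics(phantom_case.cac_mask,
                                     phantom_case.cac_mask, truth)
    assert ident["volume"]["f1"] == pytest.approx(1.0)
    assert ident["lesion"]["f1"] == pytest.approx(1.0)

    # add one spurious component far from the truth
    pred = phantom_case.cac_mask.voxels.copy()
    pred[-1, 60:62, 30:32] = 1
    m = binary_detection_metrics(phantom_case.cac_mask, LabelVolume(pred), truth)
    n = len(truth)
    assert m["lesion"]["precision"] == pytest.approx(n / (n + 1))
    assert m["lesion"]["sensitivity"] == pytest.approx(1.0)


def test_voxel_f1_matches_contingency_oracle(phantom_case):
    rng = np.random.default_rng(0)
    pred = phantom_case.cac_mask.voxels.copy()
    drop = rng.random(pred.shape) < 0.3
    pred[drop] = 0
    m = binary_detection_metrics(phantom_case.cac_mask, LabelVolume(pred))
    t = phantom_case.cac_mask.voxels.ravel() > 0
    p = pred.ravel() > 0
    tp = np.sum(t & p); fp = np.sum(~t & p); fn = np.sum(t & ~p)
    f1 = 2 * tp / (2 * tp + fp + fn)
    assert m["volume"]["f1"] == pytest.approx(f1)


# ---------------------------------------------------------------------------
# ICC and bootstrap

def test_icc_identical_raters_is_one():
    x = np.array([1.0, 5.0, 9.0, 2.0, 4.0])
    assert icc_absolute_agreement(x, x) == pytest.approx(1.0)


def test_icc_penalizes_constant_shift():
    x = np.array([1.0, 5.0, 9.0, 2.0, 4.0])
    assert icc_absolute_agreement(x, x + 3.0) < 1.0


def test_icc_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    subj_effect = rng.normal(0, 2, 30)
    x = subj_effect + rng.normal(0, 1, 30)
    y = subj_effect + 0.5 + rng.normal(0, 1, 30)
    df = pd.DataFrame({
        "subject": np.tile(np.arange(30), 2),
        "rater": np.repeat(["a", "b"], 30),
        "score": np.concatenate([x, y]),
    })
    icc2 = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                    ratings="score")
    # two-way random, single measure, absolute agreement (label varies by version)
    sel = icc2.Type.isin(["ICC2", "ICC(A,1)"])
    expected = float(icc2.loc[sel, "ICC"].iloc[0])
    assert icc_absolute_agreement(x, y) == pytest.approx(expected, abs=1e-10)


def test_icc_recovers_known_variance_components():
    """With subject variance s2 and noise variance n2 (no rater effect),
    the population ICC(2,1) is s2 / (s2 + n2)."""
    rng = np.random.default_rng(11)
    s2, n2 = 4.0, 1.0
    subj = rng.normal(0, np.sqrt(s2), 4000)
    x = subj + rng.normal(0, np.sqrt(n2), 4000)
    y = subj + rng.normal(0, np.sqrt(n2), 4000)
    assert icc_absolute_agreement(x, y) == pytest.approx(s2 / (s2 + n2), abs=0.03)


def test_bootstrap_ci_basics():
    data = list(np.arange(50, dtype=float))
    lo, hi = bootstrap_ci(np.mean, data, B=200, seed=5)
    lo2, hi2 = bootstrap_ci(np.mean, data, B=200, seed=5)
    assert (lo, hi) == (lo2, hi2)  # seeded
    assert lo <= np.mean(data) <= hi
    clo, chi = bootstrap_ci(lambda d: 1.0, data, B=100, seed=1)
    assert clo == chi == 1.0  # constant statistic: zero width


def test_bootstrap_coverage_of_known_mean():
    rng = np.random.default_rng(21)
    hits = 0
    reps = 60
    for r in range(reps):
        sample = rng.normal(0.0, 1.0, 40)
        lo, hi = bootstrap_ci(np.mean, list(sample), B=200, seed=r)
        hits += lo <= 0.0 <= hi
    assert 0.80 <= hits / reps <= 1.0  # nominal 95%, small-sample slack


def test_confusion_matrix_csv_round_trip(tmp_path, segment_cm):
    path = tmp_path / "cm.csv"
    segment_cm.to_csv(path)
    back = ConfusionMatrix.from_csv(path)
    assert np.array_equal(back.counts, segment_cm.counts)
    assert back.labels == segment_cm.labels
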