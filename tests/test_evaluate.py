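"""Nested-CV machinery: aggregation, ROC/AUC, Youden, K selection, protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gaitprog as gp
from gaitprog.config import CvConfig, PipelineConfig
from gaitprog.evaluate import (_FoldCache, aggregate_subject, auc_mann_whitney,
                               confusion_metrics, importance_heatmap,
                               inner_select_k, k_distribution, roc_auc,
                               run_nested_cv, youden_threshold)


# ---------------------------------------------------------------------------
# aggregation


@pytest.mark.parametrize("probs,expected", [
    ([0.2, 0.9, 0.4], 0.4),
    ([0.2, 0.4], 0.3),
    ([0.7], 0.7),
])
def test_median_aggregation(probs, expected):
    assert aggregate_subject(probs) == pytest.approx(expected)


def test_aggregation_is_permutation_invariant(rng):
    probs = rng.random(9)
    assert aggregate_subject(probs) == aggregate_subject(probs[::-1])


def test_empty_aggregation_raises():
    with pytest.raises(ValueError):
        aggregate_subject([])


# ---------------------------------------------------------------------------
# AUC


def _auc_brute_force(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_auc_separated_is_one():
    assert auc_mann_whitney(np.array([0.9, 0.8, 0.2, 0.1]),
                            np.array([1, 1, 0, 0])) == 1.0


def test_auc_all_ties_is_half():
    assert auc_mann_whitney(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0])) == 0.5


def test_auc_matches_pairwise_enumeration(rng):
    scores = np.round(rng.random(8), 1)  # ties likely
    labels = np.array([1, 1, 1, 0, 0, 0, 1, 0])
    assert auc_mann_whitney(scores, labels) == pytest.approx(
        _auc_brute_force(scores, labels), abs=1e-12)


def test_roc_auc_delong_ci_brackets_auc(rng):
    scores = rng.random(30)
    labels = (rng.random(30) < 0.5).astype(int)
    labels[:3], labels[-3:] = 1, 0
    curve, auc, (lo, hi) = roc_auc(scores, labels)
    assert 0.0 <= lo <= auc <= hi <= 1.0


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        auc_mann_whitney(np.array([0.1, 0.2]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# Youden threshold


def test_youden_separated_groups_give_j_one():
    scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2])
    labels = np.array([1, 1, 1, 0, 0])
    t = youden_threshold(scores, labels)
    assert 0.3 < t < 0.7
    pred = scores >= t
    assert np.all(pred == labels.astype(bool))


def test_youden_matches_exhaustive_search():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.7])
    labels = np.array([0, 1, 0, 1, 0, 1])
    t = youden_threshold(scores, labels)

    def j_at(thr):
        pred = scores >= thr
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (labels == 0).sum()
        return sens + spec - 1

    best = max(j_at(thr) for thr in np.linspace(0, 1, 2001))
    assert j_at(t) == pytest.approx(best, abs=1e-12)


def test_youden_anti_separated_warns_but_returns(caplog):
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([1, 1, 0, 0])
    with caplog.at_level("WARNING"):
        t = youden_threshold(scores, labels)
    assert any("J" in r.message for r in caplog.records)


def test_youden_degenerate_raises():
    with pytest.raises(ValueError):
        youden_threshold(np.full(4, 0.5), np.array([0, 1, 0, 1]))


# ---------------------------------------------------------------------------
# confusion metrics and K distribution


def test_confusion_metrics_perfection_and_symmetry():
    perfect = confusion_metrics(5, 0, 0, 7)
    assert all(v == 1.0 for v in perfect.values())
    half = confusion_metrics(10, 10, 10, 10)
    assert all(v == pytest.approx(0.5) for k, v in half.items() if k != "f1")
    assert half["f1"] == pytest.approx(0.5)


def test_confusion_metrics_zero_denominator_is_nan():
    m = confusion_metrics(0, 0, 3, 7)
    assert np.isnan(m["sensitivity"])
    with pytest.raises(ValueError):
        confusion_metrics(0, 0, 0, 0)


def test_k_distribution_single_fold():
    d = k_distribution([9])
    assert d["median"] == 9 and d["mean"] == 9 and d["range"] == (9, 9)


def test_k_distribution_percentages_sum_to_100():
    d = k_distribution([5] * 4 + [7] * 2 + [13] * 14 + [15] * 15 + [25] * 11)
    assert abs(d["table"]["percentage"].sum() - 100.0) <= 0.3


# ---------------------------------------------------------------------------
# inner K selection on a constructed profile


class _FakeCache:
    """Scores engineered so the pooled inner AUC peaks uniquely at K = 15."""

    def __init__(self, labels):
        self.labels = labels

    def predictions(self, i, j, k):
        quality = 1.0 - abs(k - 15) / 20.0
        u = (j * 0.37) % 1.0           # deterministic pseudo-noise in [0, 1)
        score = self.labels[j] * quality + u
        return 0.0, score


def test_stage_two_refinement_finds_peak_at_15():
    labels = np.array([i % 2 for i in range(20)])
    cache = _FakeCache(labels)
    best, profile = inner_select_k(cache, 99, list(range(20)), labels, CvConfig())
    assert set(profile) >= {7, 13, 19, 25}
    assert 15 in profile           # reached via refinement around 13/19
    assert best == 15


def test_single_candidate_grid_is_returned():
    labels = np.array([i % 2 for i in range(10)])
    cfg = CvConfig(stage1=(13,), refine_offsets=())
    best, profile = inner_select_k(_FakeCache(labels), 99, list(range(10)), labels, cfg)
    assert best == 13 and set(profile) == {13}


def test_exact_tie_prefers_smaller_k():
    class Flat:
        def predictions(self, i, j, k):
            return 0.0, float(j % 2)  # AUC identical for every K
    labels = np.array([j % 2 for j in range(10)])
    best, profile = inner_select_k(Flat(), 99, list(range(10)), labels, CvConfig())
    assert best == min(profile)


# ---------------------------------------------------------------------------
# full protocol on the small planted cohort


@pytest.fixture(scope="module")
def small_cv(small_features):
    features, labels = small_features
    cfg = PipelineConfig()
    cfg.boost.n_learners = 30
    return run_nested_cv(features, labels, cfg, seed=11), features, labels, cfg


def test_fold_count_equals_subject_count(small_cv):
    res, features, labels, _ = small_cv
    assert len(res.folds) == features["subject_id"].nunique()
    held = [f.held_out_subject for f in res.folds]
    assert sorted(held) == sorted(labels)


def test_selected_k_within_grid_and_score_is_median(small_cv):
    res, *_ = small_cv
    for f in res.folds:
        assert 5 <= f.selected_k <= 25
        assert f.subject_score == pytest.approx(np.median(f.cycle_probs))
        assert 0.0 <= f.subject_score <= 1.0


def test_confusion_cells_sum_to_subjects(small_cv):
    res, features, *_ = small_cv
    assert sum(res.confusion.values()) == features["subject_id"].nunique()


def test_planted_cohort_reaches_high_auc(small_cv):
    res, *_ = small_cv
    assert res.auc >= 0.9


def test_importance_maps_are_5x6(small_cv):
    res, *_ = small_cv
    assert res.importance_mean.shape == (5, 6)
    assert res.importance_sd.shape == (5, 6)
    assert not res.importance_mean.isna().any().any()


def test_nested_cv_is_deterministic(small_features):
    features, labels = small_features
    cfg = PipelineConfig()
    cfg.boost.n_learners = 10
    cfg.cv.stage1 = (7, 13)
    cfg.cv.refine_offsets = ()
    r1 = run_nested_cv(features, labels, cfg, seed=3)
    r2 = run_nested_cv(features, labels, cfg, seed=3)
    np.testing.assert_array_equal(r1.scores, r2.scores)
    assert [f.selected_k for f in r1.folds] == [f.selected_k for f in r2.folds]
    assert r1.auc == r2.auc


def test_mutating_held_out_subject_changes_nothing_in_its_fold(small_features):
    features, labels = small_features
    cfg = PipelineConfig()
    cfg.boost.n_learners = 10
    names = gp.FEATURE_NAMES
    sids = sorted(features["subject_id"].unique())

    def fold_artifacts(feats, i):
        X = np.ascontiguousarray(feats[names].to_numpy(float))
        subj = feats["subject_id"].map({s: k for k, s in enumerate(sids)}).to_numpy()
        y = np.array([1 if labels[s] == "Good" else 0 for s in sids])
        cache = _FoldCache(X, y[subj], subj, names, cfg, seed=5)
        params, sel = cache.selection((i,))
        _, other = cache.predictions(i, (i + 1) % len(sids), 13)
        return params, sel, other

    for i in [0, 3, 5, 8, 12]:
        p1, s1, o1 = fold_artifacts(features, i)
        corrupted = features.copy()
        rows = corrupted["subject_id"] == sids[i]
        corrupted.loc[rows, names] = 1e6
        p2, s2, o2 = fold_artifacts(corrupted, i)
        np.testing.assert_array_equal(p1.mean, p2.mean)
        np.testing.assert_array_equal(p1.sd, p2.sd)
        assert s1.mrmr_order == s2.mrmr_order
        np.testing.assert_array_equal(s1.relieff_weights, s2.relieff_weights)
        assert o1 == o2


def test_importance_heatmap_recovers_planted_region(small_features):
    features, labels = small_features
    X = features[gp.FEATURE_NAMES].to_numpy(float)
    y = features["subject_id"].map(labels).eq("Good").astype(int).to_numpy()
    mean_map, sd_map, top = importance_heatmap(X, y, gp.FEATURE_NAMES)
    assert mean_map.shape == (5, 6) and sd_map.shape == (5, 6)
    # the planted mean-amplitude effect sits in (5-8 Hz, slice 1)
    assert mean_map.loc["5-8 Hz", "s1"] == mean_map.loc["5-8 Hz"].max()
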