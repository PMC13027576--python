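"""z-scoring, mRMR and ReliefF against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

import gaitprog as gp
from gaitprog.selection import (_discretize, mrmr_select, relieff_rank,
                                select_features, zscore_apply, zscore_fit)


# ---------------------------------------------------------------------------
# z-score


def test_two_point_standardization():
    params = zscore_fit(np.array([[0.0], [2.0]]))
    assert params.mean[0] == 1.0
    assert params.sd[0] == pytest.approx(math.sqrt(2.0))
    scaled = zscore_apply(params, np.array([[0.0], [2.0]]))
    np.testing.assert_allclose(scaled.ravel(), [-1 / math.sqrt(2), 1 / math.sqrt(2)])


def test_train_statistics_are_zero_mean_unit_sd(rng):
    X = rng.standard_normal((40, 6)) * 3 + 5
    params = zscore_fit(X)
    scaled = zscore_apply(params, X)
    np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_constant_feature_maps_to_zero():
    X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
    scaled = zscore_apply(zscore_fit(X), X)
    np.testing.assert_array_equal(scaled[:, 1], 0.0)


def test_held_out_row_uses_training_params(rng):
    X = rng.standard_normal((20, 3))
    params = zscore_fit(X)
    row = rng.standard_normal((1, 3))
    np.testing.assert_allclose(zscore_apply(params, row),
                               (row - X.mean(0)) / X.std(0, ddof=1))


def test_single_row_training_raises():
    with pytest.raises(ValueError):
        zscore_fit(np.ones((1, 3)))


# ---------------------------------------------------------------------------
# brute-force MI / mRMR oracle


def _mi_oracle(a, b):
    """Plug-in MI by explicit cell enumeration."""
    n = len(a)
    mi = 0.0
    for va in set(a):
        for vb in set(b):
            pab = sum(1 for x, y in zip(a, b) if x == va and y == vb) / n
            if pab == 0:
                continue
            pa = sum(1 for x in a if x == va) / n
            pb = sum(1 for y in b if y == vb) / n
            mi += pab * math.log(pab / (pa * pb))
    return mi


def _mrmr_oracle(codes, y, n_select):
    """Greedy MI-quotient selection by direct enumeration."""
    p = codes.shape[1]
    selected = []
    while len(selected) < n_select:
        best, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            rel = _mi_oracle(list(codes[:, j]), list(y))
            if not selected:
                score = rel
            else:
                red = np.mean([_mi_oracle(list(codes[:, j]), list(codes[:, s]))
                               for s in selected])
                score = rel / max(red, 1e-12)
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


def test_mrmr_picks_the_informative_feature_first(rng):
    n = 120
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 5))
    X[:, 3] = y + 0.01 * rng.standard_normal(n)  # near-perfect predictor
    names = [f"f{j}" for j in range(5)]
    assert mrmr_select(X, y, names, n_select=1) == ["f3"]


def test_mrmr_matches_brute_force_on_six_features(rng):
    n = 80
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 6))
    X[:, 1] += 1.2 * y
    X[:, 4] += 0.8 * y
    X[:, 5] = X[:, 1] + 0.05 * rng.standard_normal(n)
    names = [f"f{j}" for j in range(6)]
    got = mrmr_select(X, y, names, n_select=4)
    codes, _ = _discretize(X, None)
    expect = [names[j] for j in _mrmr_oracle(codes, y, 4)]
    assert got == expect


def test_mrmr_duplicate_feature_not_selected_second(rng):
    n = 300
    y = rng.integers(0, 2, n)
    base = y + 0.05 * rng.standard_normal(n)
    X = np.column_stack([base, base.copy(), rng.standard_normal(n) + 1.0 * y])
    got = mrmr_select(X, y, ["a_first", "b_dup", "c_weak"], n_select=2)
    assert got[0] == "a_first"      # tie between a/b broken by name
    assert got[1] == "c_weak"       # the duplicate is maximally redundant


def test_mrmr_exhaustion_returns_all_features(rng):
    X = rng.standard_normal((50, 4))
    y = rng.integers(0, 2, 50)
    got = mrmr_select(X, y, list("abcd"), n_select=4)
    assert sorted(got) == list("abcd")


def test_mrmr_invariant_to_row_and_column_permutations(rng):
    n = 60
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 5))
    X[:, 2] += y
    names = [f"f{j}" for j in range(5)]
    ref = set(mrmr_select(X, y, names, n_select=3))
    perm = rng.permutation(n)
    assert set(mrmr_select(X[perm], y[perm], names, n_select=3)) == ref
    cols = rng.permutation(5)
    assert set(mrmr_select(X[:, cols], y, [names[c] for c in cols], n_select=3)) == ref


def test_mrmr_single_class_raises():
    with pytest.raises(ValueError):
        mrmr_select(np.random.default_rng(0).random((10, 3)), np.zeros(10), list("abc"), 2)


# ---------------------------------------------------------------------------
# ReliefF


def _relieff_oracle(X, y, k):
    """Literal ReliefF: explicit neighbor enumeration per instance."""
    n, p = X.shape
    rng_f = X.max(0) - X.min(0)
    rng_f[rng_f == 0] = 1.0
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    w = np.zeros(p)
    for i in range(n):
        d = np.sqrt((((X - X[i]) / rng_f) ** 2).sum(1))
        d[i] = np.inf
        for c in classes:
            idx = [j for j in range(n) if y[j] == c and j != i]
            idx.sort(key=lambda j: d[j])
            kc = min(k, len(idx))
            for j in idx[:kc]:
                diff = np.abs(X[i] - X[j]) / rng_f
                if c == y[i]:
                    w -= diff / (n * kc)
                else:
                    w += priors[c] / (1 - priors[y[i]]) * diff / (n * kc)
    return w


def test_relieff_matches_hand_enumeration_on_four_points():
    X = np.array([[0.0, 0.0], [0.1, 1.0], [1.0, 0.1], [0.9, 1.1]])
    y = np.array([0, 0, 1, 1])
    got = relieff_rank(X, y, k_neighbors=1)
    np.testing.assert_allclose(got, _relieff_oracle(X, y, 1), atol=1e-12)


def test_relieff_matches_oracle_on_random_data(rng):
    X = rng.standard_normal((24, 4))
    y = rng.integers(0, 2, 24)
    y[:3] = 0
    y[-3:] = 1
    np.testing.assert_allclose(relieff_rank(X, y, 3), _relieff_oracle(X, y, 3),
                               atol=1e-12)


def test_relieff_constant_feature_weight_zero(rng):
    X = np.column_stack([rng.standard_normal(20), np.full(20, 7.0)])
    y = np.array([0, 1] * 10)
    w = relieff_rank(X, y, 3)
    assert w[1] == 0.0


def test_relieff_separating_feature_beats_noise():
    wins = 0
    for s in range(20):
        r = np.random.default_rng(s)
        y = np.array([0] * 20 + [1] * 20)
        X = np.column_stack([y + 0.05 * r.standard_normal(40),
                             r.standard_normal(40)])
        w = relieff_rank(X, y, 5)
        wins += w[0] > w[1]
    assert wins == 20


def test_relieff_weights_bounded(rng):
    X = rng.random((40, 6))
    y = rng.integers(0, 2, 40)
    y[:4] = 0
    y[-4:] = 1
    w = relieff_rank(X, y, 10)
    assert np.all(w >= -1.0) and np.all(w <= 1.0)


def test_relieff_single_class_raises():
    with pytest.raises(ValueError):
        relieff_rank(np.random.default_rng(0).random((10, 2)), np.ones(10), 3)


# ---------------------------------------------------------------------------
# leakage / determinism of the composed selection


def test_selection_ignores_held_out_rows(rng):
    X = rng.standard_normal((60, 8))
    y = rng.integers(0, 2, 60)
    y[:5] = 0
    y[-5:] = 1
    train = np.arange(40)
    names = [f"f{j}" for j in range(8)]

    def run(Xfull):
        params = zscore_fit(Xfull[train])
        res = select_features(zscore_apply(params, Xfull[train]), y[train], names,
                              n_mrmr=6, relieff_k=3)
        return params, res

    p1, r1 = run(X)
    mutated = X.copy()
    mutated[40:] = 999.0  # arbitrary corruption of held-out rows
    p2, r2 = run(mutated)
    np.testing.assert_array_equal(p1.mean, p2.mean)
    np.testing.assert_array_equal(p1.sd, p2.sd)
    assert r1.mrmr_order == r2.mrmr_order
    np.testing.assert_array_equal(r1.relieff_weights, r2.relieff_weights)
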