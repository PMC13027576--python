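"""Histogram-based depth-limited decision tree (numba-compiled).

The weak learner of the boosting ensemble: features are pre-discretized into
quantile bins (codes), and splits are searched over bin boundaries with the
weighted Gini criterion.  Compiled with numba because the nested
cross-validation protocol fits tens of thousands of small ensembles.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def build_tree(codes, y01, w, max_depth, min_leaf, n_bins):
    """Fit one tree on binned features.

    Parameters: ``codes`` (n, k) uint8 bin codes, ``y01`` (n,) int8 labels,
    ``w`` (n,) float64 sample weights.  Returns flat node arrays
    (feature, threshold-bin, left, right, leaf P(class 1)); ``feature == -1``
    marks a leaf.
    """
    n, k = codes.shape
    max_nodes = 2 ** (max_depth + 1) - 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.full(max_nodes, -1, np.int64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    val = np.zeros(max_nodes, np.float64)

    idx = np.arange(n)
    stack_node = np.zeros(max_nodes, np.int64)
    stack_depth = np.zeros(max_nodes, np.int64)
    stack_lo = np.zeros(max_nodes, np.int64)
    stack_hi = np.zeros(max_nodes, np.int64)
    n_nodes = 1
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    sp = 1
    h0 = np.zeros(n_bins, np.float64)
    h1 = np.zeros(n_bins, np.float64)
    c0h = np.zeros(n_bins, np.int64)
    c1h = np.zeros(n_bins, np.int64)
    while sp > 0:
        sp -= 1
        node = stack_node[sp]
        depth = stack_depth[sp]
        lo = stack_lo[sp]
        hi = stack_hi[sp]
        w0 = 0.0
        w1 = 0.0
        for t in range(lo, hi):
            i = idx[t]
            if y01[i] == 1:
                w1 += w[i]
            else:
                w0 += w[i]
        tot = w0 + w1
        val[node] = 0.5 if tot <= 0.0 else w1 / tot
        if depth >= max_depth or hi - lo < 2 * min_leaf or w0 == 0.0 or w1 == 0.0:
            continue
        best_gain = 1e-12
        best_f = -1
        best_b = -1
        parent_imp = w0 * w1 / tot
        for f in range(k):
            for b in range(n_bins):
                h0[b] = 0.0
                h1[b] = 0.0
                c0h[b] = 0
                c1h[b] = 0
            for t in range(lo, hi):
                i = idx[t]
                c = codes[i, f]
                if y01[i] == 1:
                    h1[c] += w[i]
                    c1h[c] += 1
                else:
                    h0[c] += w[i]
                    c0h[c] += 1
            a0 = 0.0
            a1 = 0.0
            cl = 0
            ntot = hi - lo
            for b in range(n_bins - 1):
                a0 += h0[b]
                a1 += h1[b]
                cl += c0h[b] + c1h[b]
                if cl < min_leaf or ntot - cl < min_leaf:
                    continue
                lw = a0 + a1
                rw = tot - lw
                if lw <= 0.0 or rw <= 0.0:
                    continue
                gain = parent_imp - (a0 * a1 / lw) - ((w0 - a0) * (w1 - a1) / rw)
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_b = b
        if best_f < 0:
            continue
        tmp = np.empty(hi - lo, np.int64)
        a = 0
        for t in range(lo, hi):
            i = idx[t]
            if codes[i, best_f] <= best_b:
                tmp[a] = i
                a += 1
        b_ = a
        for t in range(lo, hi):
            i = idx[t]
            if codes[i, best_f] > best_b:
                tmp[b_] = i
                b_ += 1
        for t in range(hi - lo):
            idx[lo + t] = tmp[t]
        feat[node] = best_f
        thr[node] = best_b
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        stack_node[sp] = lid
        stack_depth[sp] = depth + 1
        stack_lo[sp] = lo
        stack_hi[sp] = lo + a
        sp += 1
        stack_node[sp] = rid
        stack_depth[sp] = depth + 1
        stack_lo[sp] = lo + a
        stack_hi[sp] = hi
        sp += 1
    return feat, thr, left, right, val


@njit(cache=True)
def predict_tree(codes, feat, thr, left, right, val):
    """Leaf P(class 1) for every row of binned features."""
    n = codes.shape[0]
    out = np.empty(n, np.float64)
    for i in range(n):
        node = 0
        while feat[node] >= 0:
            if codes[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = val[node]
    return out


@njit(cache=True)
def mutual_information_codes(a, b, ka, kb):
    """Plug-in mutual information (nats) between two integer code vectors."""
    n = a.shape[0]
    joint = np.zeros((ka, kb), np.float64)
    pa = np.zeros(ka, np.float64)
    pb = np.zeros(kb, np.float64)
    inv = 1.0 / n
    for i in range(n):
        joint[a[i], b[i]] += inv
        pa[a[i]] += inv
        pb[b[i]] += inv
    mi = 0.0
    for x in range(ka):
        if pa[x] <= 0.0:
            continue
        for y in range(kb):
            j = joint[x, y]
            if j > 0.0:
                mi += j * np.log(j / (pa[x] * pb[y]))
    return mi


@njit(cache=True)
def boost_rounds(codes, y01, w0, maj_idx, n_keep, gumbel, n_learners, learning_rate,
                 max_depth, min_leaf, n_bins, max_retries, eps_min):
    """Run the full undersample-fit-reweight boosting loop in compiled code.

    ``gumbel`` holds one row of Gumbel noise per undersampling attempt (empty
    when undersampling is inactive).  Returns packed per-round tree arrays,
    the vote weights, the recorded subsample of every accepted round and the
    number of accepted rounds.
    """
    n, k = codes.shape
    n_maj = maj_idx.shape[0]
    undersampling = gumbel.shape[0] > 0 and n_keep < n_maj
    max_nodes = 2 ** (max_depth + 1) - 1
    feat_all = np.full((n_learners, max_nodes), -1, np.int64)
    thr_all = np.full((n_learners, max_nodes), -1, np.int64)
    left_all = np.full((n_learners, max_nodes), -1, np.int64)
    right_all = np.full((n_learners, max_nodes), -1, np.int64)
    val_all = np.zeros((n_learners, max_nodes), np.float64)
    alphas = np.zeros(n_learners, np.float64)
    n_min = n - n_maj
    sub_size = (n_min + n_keep) if undersampling else n
    subs = np.zeros((n_learners, sub_size), np.int64)

    in_maj = np.zeros(n, np.uint8)
    for i in range(n_maj):
        in_maj[maj_idx[i]] = 1

    w = w0.copy()
    y_sign = np.empty(n, np.float64)
    for i in range(n):
        y_sign[i] = 1.0 if y01[i] == 1 else -1.0

    rounds = 0
    attempt = 0
    retries = 0
    while rounds < n_learners:
        if undersampling:
            if attempt >= gumbel.shape[0]:
                break
            keys = np.empty(n_maj, np.float64)
            for i in range(n_maj):
                wi = w[maj_idx[i]]
                if wi < 1e-300:
                    wi = 1e-300
                keys[i] = np.log(wi) + gumbel[attempt, i]
            attempt += 1
            order = np.argsort(-keys)
            sub = np.empty(sub_size, np.int64)
            p = 0
            for i in range(n):
                if in_maj[i] == 0:
                    sub[p] = i
                    p += 1
            for i in range(n_keep):
                sub[p] = maj_idx[order[i]]
                p += 1
            sub = np.sort(sub)
        else:
            sub = np.arange(n)
        ws = np.empty(sub_size, np.float64)
        tot = 0.0
        for i in range(sub_size):
            tot += w[sub[i]]
        for i in range(sub_size):
            ws[i] = w[sub[i]] / tot
        codes_sub = np.empty((sub_size, k), np.uint8)
        y_sub = np.empty(sub_size, np.int8)
        for i in range(sub_size):
            for j in range(k):
                codes_sub[i, j] = codes[sub[i], j]
            y_sub[i] = y01[sub[i]]
        feat, thr, left, right, val = build_tree(codes_sub, y_sub, ws,
                                                 max_depth, min_leaf, n_bins)
        pred = predict_tree(codes, feat, thr, left, right, val)
        eps = 0.0
        for i in range(n):
            h = 1.0 if pred[i] > 0.5 else -1.0
            if h != y_sign[i]:
                eps += w[i]
        if eps >= 0.5:
            if undersampling and retries < max_retries:
                retries += 1
                continue
            break
        retries = 0
        if eps < eps_min:
            eps = eps_min
        alpha = learning_rate * 0.5 * np.log((1.0 - eps) / eps)
        feat_all[rounds] = feat
        thr_all[rounds] = thr
        left_all[rounds] = left
        right_all[rounds] = right
        val_all[rounds] = val
        alphas[rounds] = alpha
        subs[rounds, :] = sub
        tot = 0.0
        for i in range(n):
            h = 1.0 if pred[i] > 0.5 else -1.0
            w[i] = w[i] * np.exp(-alpha * y_sign[i] * h)
            tot += w[i]
        for i in range(n):
            w[i] /= tot
        rounds += 1
    return feat_all, thr_all, left_all, right_all, val_all, alphas, subs, rounds


def fit_bins(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin edges per feature; shape (p, n_bins - 1)."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    return np.quantile(X, qs, axis=0).T.copy()


def apply_bins(X: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Map values to uint8 bin codes with the training edges."""
    n, p = X.shape
    codes = np.empty((n, p), dtype=np.uint8)
    for j in range(p):
        codes[:, j] = np.searchsorted(edges[j], X[:, j], side="right")
    return codes
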