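"""Fold-internal feature selection: z-scoring, mRMR reduction, ReliefF ranking.

All three stages are fitted on training rows only; the nested cross-validation
driver guarantees that no held-out subject's cycles ever reach them.  Every
tie is broken by canonical (alphabetical) feature name so the selection is
deterministic under row and column permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

log = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# z-score scaling


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean/SD estimated on training data only."""

    mean: np.ndarray
    sd: np.ndarray


def zscore_fit(train: np.ndarray) -> ScalerParams:
    """Estimate standardization parameters; constant features get an SD floor."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    if np.any(sd <= _EPS):
        log.warning("%d constant feature(s) will scale to 0", int(np.sum(sd <= _EPS)))
    return ScalerParams(mean=mean, sd=np.where(sd <= _EPS, 1.0, sd))


def zscore_apply(params: ScalerParams, rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    return (rows - params.mean) / params.sd


# ---------------------------------------------------------------------------
# mutual information on discretized features


def _discretize(X: np.ndarray, n_bins: Optional[int]) -> Tuple[np.ndarray, int]:
    """Equal-frequency binning of each column; returns integer codes."""
    n, p = X.shape
    if n_bins is None:
        n_bins = min(10, max(2, int(np.sqrt(n))))
    # rank-based equal-frequency bins; ties share a bin by construction
    codes = np.empty((n, p), dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(p):
        edges = np.quantile(X[:, j], qs)
        codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return codes, n_bins


def _mi_from_codes(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    """Plug-in mutual information (nats) between two integer code vectors."""
    from ._tree import mutual_information_codes
    return float(mutual_information_codes(np.ascontiguousarray(a, dtype=np.int64),
                                          np.ascontiguousarray(b, dtype=np.int64),
                                          ka, kb))


@dataclass
class SelectionResult:
    """Ordered mRMR survivors and their ReliefF weights."""

    mrmr_order: List[str]
    relieff_weights: np.ndarray  # aligned with mrmr_order

    def top_k(self, k: int) -> List[str]:
        order = _stable_rank(np.asarray(self.relieff_weights), self.mrmr_order)
        return [self.mrmr_order[i] for i in order[:k]]


def _stable_rank(weights: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Indices by descending weight, ties broken by canonical name order."""
    name_rank = np.argsort(np.argsort(names))
    return np.lexsort((name_rank, -weights))


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    n_select: int = 30,
    variant: str = "quotient",
    n_bins: Optional[int] = None,
) -> List[str]:
    """Greedy minimum-redundancy maximum-relevance selection.

    The first feature maximizes the mutual information I(f; y); each next
    feature maximizes I(f; y) / mean_s I(f; s) over the already-selected set
    s (quotient form; the difference form I(f;y) - mean_s I(f;s) is
    available).  MI is a plug-in estimate on equal-frequency-binned values.
    Deterministic: all ties break by canonical feature name.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if len(names) != p:
        raise ValueError("names must match the number of columns")
    if n_select > p:
        raise ValueError(f"cannot select {n_select} of {p} features")
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("mRMR requires at least two classes")
    codes, kb = _discretize(X, n_bins)
    ky = classes.size

    relevance = np.array([_mi_from_codes(codes[:, j], y_codes, kb, ky) for j in range(p)])
    name_rank = np.argsort(np.argsort(names))

    selected: List[int] = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for _ in range(n_select):
        if not selected:
            score = relevance.copy()
        else:
            red = redundancy_sum / len(selected)
            if variant == "quotient":
                score = relevance / np.maximum(red, _EPS)
            else:
                score = relevance - red
        score = np.where(remaining, score, -np.inf)
        cand = np.flatnonzero(score == score.max())
        j = int(cand[np.argmin(name_rank[cand])])
        selected.append(j)
        remaining[j] = False
        upd = np.flatnonzero(remaining)
        for m in upd:
            redundancy_sum[m] += _mi_from_codes(codes[:, m], codes[:, j], kb, kb)
    return [names[j] for j in selected]


# ---------------------------------------------------------------------------
# ReliefF


def relieff_rank(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
) -> np.ndarray:
    """Standard ReliefF weights over all instances (no subsampling).

    For every instance the k nearest hits (same class) and, per other class,
    the k nearest misses are found by Euclidean distance; feature weights
    accumulate -diff/(m*k) over hits and prior-weighted +diff/(m*k) over
    misses, with diff = |xa - xb| / range(f).  With range-normalized diffs
    the weights lie in [-1, 1]; constant features get weight 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("ReliefF requires at least two classes")
    counts = np.bincount(y_codes)
    priors = counts / n

    rng_f = X.max(axis=0) - X.min(axis=0)
    safe_rng = np.where(rng_f <= _EPS, 1.0, rng_f)
    live = rng_f > _EPS

    Xn = X / safe_rng  # pre-divide so |xa-xb| is already range-normalized
    sq = np.einsum("ij,ij->i", Xn, Xn)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Xn @ Xn.T)
    np.fill_diagonal(d2, np.inf)

    w = np.zeros(p)
    m = n
    idx_of = [np.flatnonzero(y_codes == c) for c in range(classes.size)]
    for ci in range(classes.size):
        rows = idx_of[ci]
        if rows.size == 0:
            continue
        for c in range(classes.size):
            cols = idx_of[c]
            if ci == c:
                kc = min(k_neighbors, cols.size - 1)
                if kc < k_neighbors:
                    log.warning("class %r has %d members; k reduced to %d",
                                classes[c], cols.size, kc)
            else:
                kc = min(k_neighbors, cols.size)
            if kc <= 0:
                continue
            block = d2[np.ix_(rows, cols)]
            if kc < cols.size:
                nb = np.argpartition(block, kc - 1, axis=1)[:, :kc]
            else:
                nb = np.broadcast_to(np.arange(cols.size), (rows.size, cols.size)).copy()
            neigh = Xn[cols[nb]]                    # (n_rows, kc, p)
            diffs = np.abs(Xn[rows][:, None, :] - neigh).sum(axis=(0, 1))
            if ci == c:
                w -= diffs / (m * kc)
            else:
                w += (priors[c] / (1.0 - priors[ci])) * diffs / (m * kc)
    w[~live] = 0.0
    return w


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    n_mrmr: int = 30,
    relieff_k: int = 10,
    variant: str = "quotient",
    mi_bins: Optional[int] = None,
) -> SelectionResult:
    """mRMR reduction followed by ReliefF ranking of the survivors."""
    n_mrmr = min(n_mrmr, len(names))
    order = mrmr_select(X, y, names, n_select=n_mrmr, variant=variant, n_bins=mi_bins)
    cols = [list(names).index(nm) for nm in order]
    weights = relieff_rank(X[:, cols], y, k_neighbors=relieff_k)
    return SelectionResult(mrmr_order=order, relieff_weights=weights)
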