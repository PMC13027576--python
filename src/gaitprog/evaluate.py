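"""Nested leave-one-subject-out evaluation of the cycle-level classifier.

Protocol: every subject is held out once (outer loop).  On the remaining
subjects an inner leave-one-subject-out loop picks the number of top-ranked
features K that maximizes the pooled inner AUC — evaluated on a coarse grid
{7, 13, 19, 25} and then refined on the odd neighbors of the best value —
after which scaler -> mRMR -> ReliefF -> top-K -> RUSBoost are fitted on the
full outer-training cycles and the held-out subject's cycles are scored.
Cycle probabilities aggregate to one subject score (median), and all primary
metrics (ROC/AUC with CI, Youden operating point, confusion-matrix metrics)
are computed over the pooled subject-level scores.

Every preprocessing artifact is fitted strictly inside its training fold.
Because the inner fold of outer subject i with inner holdout j trains on the
subject set minus {i, j} — symmetric in (i, j) — fold artifacts are cached
per unordered pair and reused for the mirrored fold; the cache never sees
held-out data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .boost import fit_rusboost
from .config import CvConfig, PipelineConfig
from .features import parse_feature_name
from .selection import (ScalerParams, SelectionResult, select_features,
                        zscore_apply, zscore_fit)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary metrics


def aggregate_subject(cycle_probs: Sequence[float], method: str = "median") -> float:
    """Collapse one subject's cycle-level probabilities to a single score."""
    probs = np.asarray(cycle_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("cannot aggregate an empty probability list")
    if method == "median":
        return float(np.median(probs))
    if method == "mean":
        return float(np.mean(probs))
    if method == "max":
        return float(np.max(probs))
    raise ValueError(f"unknown aggregation {method!r}")


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as P(random positive outranks random negative), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_se(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong standard error of the Mann-Whitney AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # structural components: for each positive, fraction of negatives it beats
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    ci_method: str = "delong",
    n_bootstrap: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Tuple[Tuple[np.ndarray, np.ndarray, np.ndarray], float, Tuple[float, float]]:
    """ROC curve, AUC and a 95% confidence interval.

    Returns ``((fpr, tpr, thresholds), auc, (lo, hi))``.  The CI uses the
    DeLong analytic variance by default; a subject-level bootstrap is
    available.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = auc_mann_whitney(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    if ci_method == "delong":
        se = _delong_se(scores, labels)
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = scores.size
        vals = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            if labels[idx].min() == labels[idx].max():
                continue
            vals.append(auc_mann_whitney(scores[idx], labels[idx]))
        lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return (fpr, tpr, thr), auc, (float(max(0.0, lo)), float(min(1.0, hi)))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct observed
    scores; a subject is called positive when its score >= threshold.  Ties
    prefer higher specificity, then the lower threshold.  An anti-separated
    score set yields J <= 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("degenerate score set: all scores identical")
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden threshold requires both classes")
    best = None  # (J, specificity, -threshold)
    best_thr = None
    for t in (distinct[:-1] + distinct[1:]) / 2.0:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        key = (sens + spec - 1.0, spec, -t)
        if best is None or key > best:
            best, best_thr = key, float(t)
    if best[0] <= 0:
        log.warning("Youden J = %.3f <= 0: scores rank inversely to the labels", best[0])
    return best_thr


def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> Dict[str, float]:
    """Sensitivity, specificity, PPV, NPV, accuracy and F1 from confusion counts.

    Zero-denominator ratios are reported as NaN with a warning.
    """
    cells = dict(tp=tp, fn=fn, fp=fp, tn=tn)
    if any(v < 0 for v in cells.values()):
        raise ValueError("confusion counts must be non-negative")
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("confusion matrix is all zeros")

    def ratio(num, den, name):
        if den == 0:
            log.warning("%s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    acc = (tp + tn) / total
    f1 = (float("nan") if np.isnan(sens) or np.isnan(ppv) or (ppv + sens) == 0
          else 2 * ppv * sens / (ppv + sens))
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
            "accuracy": acc, "f1": f1}


def k_distribution(k_values: Sequence[int]) -> Dict:
    """Frequency table plus median/mean/range of the fold-level K values."""
    ks = np.asarray(list(k_values), dtype=int)
    if ks.size == 0:
        raise ValueError("no fold K values")
    uniq, counts = np.unique(ks, return_counts=True)
    table = pd.DataFrame({
        "K": uniq,
        "n_folds": counts,
        "percentage": np.round(100.0 * counts / ks.size, 1),
    })
    return {
        "table": table,
        "median": float(np.median(ks)),
        "mean": float(np.mean(ks)),
        "range": (int(ks.min()), int(ks.max())),
    }


# ---------------------------------------------------------------------------
# fold artifacts with pair-level caching


class _FoldCache:
    """Training-fold artifacts keyed by the excluded subject set.

    ``selection(excluded)`` fits scaler + mRMR + ReliefF on all cycles whose
    subject is not excluded; ``predictions(i, j, K)`` trains the pair-fold
    ensemble and returns the aggregated scores of both excluded subjects.
    """

    def __init__(self, X: np.ndarray, y01: np.ndarray, subj_idx: np.ndarray,
                 names: Sequence[str], cfg: PipelineConfig, seed: int):
        self.X = X
        self.y01 = y01
        self.subj = subj_idx
        self.names = list(names)
        self.cfg = cfg
        self.seed = seed
        self._sel: Dict[tuple, Tuple[ScalerParams, SelectionResult]] = {}
        self._pred: Dict[tuple, Tuple[float, float]] = {}
        self._ctx_key: tuple = ()
        self._ctx: Dict = {}

    def _train_mask(self, excluded: tuple) -> np.ndarray:
        return ~np.isin(self.subj, excluded)

    def _context(self, key: tuple) -> Dict:
        """Per-fold scaled/binned training matrix in ReliefF rank order.

        Consecutive K evaluations of the same fold reuse it (single slot);
        bin edges are per-feature, so the first-K columns of the ranked
        matrix are exactly what a fresh fit on those K features would bin.
        """
        if key == self._ctx_key:
            return self._ctx
        from ._tree import apply_bins, fit_bins
        params, sel = self.selection(key)
        ranked = sel.top_k(len(sel.mrmr_order))
        cols = np.array([self.names.index(nm) for nm in ranked])
        mask = self._train_mask(key)
        Xs = zscore_apply(params, self.X[mask])[:, cols]
        edges = fit_bins(Xs, self.cfg.boost.n_bins)
        codes = apply_bins(Xs, edges)
        self._ctx = {"params": params, "ranked": ranked, "cols": cols,
                     "mask": mask, "Xs": Xs, "edges": edges, "codes": codes}
        self._ctx_key = key
        return self._ctx

    def selection(self, excluded: tuple) -> Tuple[ScalerParams, SelectionResult]:
        key = tuple(sorted(excluded))
        if key not in self._sel:
            mask = self._train_mask(key)
            ytr = self.y01[mask]
            if ytr.min() == ytr.max():
                raise ValueError(f"training fold excluding {key} lost a class")
            params = zscore_fit(self.X[mask])
            Xs = zscore_apply(params, self.X[mask])
            sel = self.cfg.selection
            result = select_features(Xs, ytr, self.names, n_mrmr=sel.n_mrmr,
                                     relieff_k=sel.relieff_k, variant=sel.mrmr_variant,
                                     mi_bins=sel.mi_bins)
            self._sel[key] = (params, result)
        return self._sel[key]

    def _fit_model(self, excluded: tuple, k: int):
        ctx = self._context(excluded)
        seed = int(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(*excluded, k)).generate_state(1)[0])
        model = fit_rusboost(ctx["Xs"][:, :k], self.y01[ctx["mask"]], self.cfg.boost,
                             seed=seed, feature_names=ctx["ranked"][:k],
                             prebinned=(ctx["edges"][:k], ctx["codes"][:, :k]))
        return ctx, model

    def _fit_and_score(self, excluded: tuple, k: int) -> Dict[int, float]:
        ctx, model = self._fit_model(excluded, k)
        out = {}
        for s in excluded:
            rows = self.subj == s
            Xh = zscore_apply(ctx["params"], self.X[rows])[:, ctx["cols"][:k]]
            probs = model.predict_proba(Xh)[:, 1]
            out[s] = aggregate_subject(probs, self.cfg.cv.aggregate)
        return out

    def predictions(self, i: int, j: int, k: int) -> Tuple[float, float]:
        """Aggregated scores (score_i, score_j) of the pair-fold model."""
        a, b = (i, j) if i < j else (j, i)
        key = (a, b, k)
        if key not in self._pred:
            scores = self._fit_and_score((a, b), k)
            self._pred[key] = (scores[a], scores[b])
        sa, sb = self._pred[key]
        return (sa, sb) if (a, b) == (i, j) else (sb, sa)

    def outer_predict(self, i: int, k: int) -> Tuple[np.ndarray, List[str]]:
        """Cycle probabilities for held-out subject i from the outer model,
        plus the K feature names that model was trained on."""
        ctx, model = self._fit_model((i,), k)
        rows = self.subj == i
        Xh = zscore_apply(ctx["params"], self.X[rows])[:, ctx["cols"][:k]]
        return model.predict_proba(Xh)[:, 1], list(ctx["ranked"][:k])


# ---------------------------------------------------------------------------
# inner K selection


def inner_select_k(
    cache: _FoldCache,
    outer_subject: int,
    train_subjects: Sequence[int],
    subject_labels: np.ndarray,
    cfg: CvConfig,
) -> Tuple[int, Dict[int, float]]:
    """Two-stage search for the feature count K maximizing the pooled inner AUC.

    Stage 1 evaluates the coarse grid; stage 2 the not-yet-evaluated odd
    neighbors (best +/- 2, +/- 4) clipped to [k_min, k_max].  Ties select the
    smallest K.
    """
    profile: Dict[int, float] = {}

    def evaluate_stage(ks: Sequence[int]) -> None:
        # inner folds are visited once per stage, all candidate K in a row,
        # so the per-fold scaled/binned context is reused across K
        scores = {k: [] for k in ks}
        labs = {k: [] for k in ks}
        for j in train_subjects:
            for k in ks:
                try:
                    _, sj = cache.predictions(outer_subject, j, k)
                except ValueError as exc:
                    log.warning("inner fold (%d, %d) skipped: %s",
                                outer_subject, j, exc)
                    continue
                scores[k].append(sj)
                labs[k].append(subject_labels[j])
        for k in ks:
            profile[k] = auc_mann_whitney(np.array(scores[k]), np.array(labs[k]))

    stage1 = sorted(k for k in cfg.stage1 if cfg.k_min <= k <= cfg.k_max)
    evaluate_stage(stage1)
    best = min(k for k, v in profile.items() if v == max(profile.values()))
    stage2 = sorted({best + o for o in cfg.refine_offsets}
                    & set(range(cfg.k_min, cfg.k_max + 1)) - set(profile))
    if stage2:
        evaluate_stage(stage2)
    best = min(k for k, v in profile.items() if v == max(profile.values()))
    return best, profile


# ---------------------------------------------------------------------------
# full nested protocol


@dataclass
class FoldResult:
    """One outer fold: the held-out subject and everything chosen without it."""

    held_out_subject: str
    selected_k: int
    inner_auc_profile: Dict[int, float]
    cycle_probs: np.ndarray
    subject_score: float
    selected_features: List[str]


@dataclass
class NestedCvResult:
    """Pooled nested-CV output over all outer folds."""

    folds: List[FoldResult]
    subject_ids: List[str]
    scores: np.ndarray
    labels: np.ndarray              # 1 = Good
    roc: Tuple[np.ndarray, np.ndarray, np.ndarray]
    auc: float
    auc_ci: Tuple[float, float]
    ci_method: str
    youden: float
    confusion: Dict[str, int]       # tp/fn/fp/tn at the Youden threshold
    metrics: Dict[str, float]
    k_summary: Dict
    importance_mean: pd.DataFrame   # bands x slices, Mean features
    importance_sd: pd.DataFrame
    top_features: List[str]


def importance_heatmap(
    X: np.ndarray,
    y01: np.ndarray,
    names: Sequence[str],
    relieff_k: int = 10,
    top_n: int = 25,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Post-hoc global ReliefF importance arranged as band x slice matrices.

    Runs on the full labeled cohort (explicitly outside cross-validation;
    interpretive only).  Returns (Mean map, SD map, top-N feature names).
    """
    params = zscore_fit(X)
    from .selection import relieff_rank, _stable_rank
    weights = relieff_rank(zscore_apply(params, X), y01, k_neighbors=relieff_k)
    by_name = dict(zip(names, weights))
    bands, slices = [], []
    for nm in names:
        stat, lo, hi, s = parse_feature_name(nm)
        bands.append((lo, hi))
        slices.append(s)
    band_labels = sorted(set(bands))
    slice_labels = sorted(set(slices))
    maps = {}
    for stat in ("Mean", "SD"):
        mat = pd.DataFrame(index=[f"{lo:g}-{hi:g} Hz" for lo, hi in band_labels],
                           columns=[f"s{s}" for s in slice_labels], dtype=float)
        for nm in names:
            st, lo, hi, s = parse_feature_name(nm)
            if st == stat:
                mat.loc[f"{lo:g}-{hi:g} Hz", f"s{s}"] = by_name[nm]
        maps[stat] = mat
    order = _stable_rank(np.asarray(weights), list(names))
    top = [list(names)[i] for i in order[:top_n]]
    return maps["Mean"], maps["SD"], top


def run_nested_cv(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    cfg: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> NestedCvResult:
    """Run the full nested leave-one-subject-out protocol.

    ``features`` holds one row per gait cycle (key columns subject_id /
    trial_id / cycle_index plus the canonical feature columns); ``labels``
    maps every subject to "Good" or "Poor".
    """
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    names = [c for c in features.columns
             if c not in ("subject_id", "trial_id", "cycle_index")]

    sids = sorted(features["subject_id"].astype(str).unique())
    missing = [s for s in sids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for subjects {missing}")
    usable = [s for s in sids if (features["subject_id"].astype(str) == s).any()]
    y_subj = np.array([1 if labels[s] == "Good" else 0 for s in usable])
    if min(y_subj.sum(), len(usable) - y_subj.sum()) < 3:
        raise ValueError("nested CV needs at least 3 subjects per class")

    subj_to_idx = {s: i for i, s in enumerate(usable)}
    subj_idx = features["subject_id"].astype(str).map(subj_to_idx).to_numpy()
    X = np.ascontiguousarray(features[names].to_numpy(dtype=float))
    y01 = y_subj[subj_idx]

    from .config import dump_config
    log.info("nested LOSO CV: %d subjects (%d Good / %d Poor), %d cycles, seed=%d",
             len(usable), int(y_subj.sum()), int(len(usable) - y_subj.sum()),
             len(features), seed)
    log.debug("resolved configuration:\n%s", dump_config(cfg))
    cache = _FoldCache(X, y_subj[subj_idx], subj_idx, names, cfg, seed)
    folds: List[FoldResult] = []
    for i, sid in enumerate(usable):
        train_subjects = [j for j in range(len(usable)) if j != i]
        best_k, profile = inner_select_k(cache, i, train_subjects, y_subj, cfg.cv)
        probs, top_features = cache.outer_predict(i, best_k)
        folds.append(FoldResult(
            held_out_subject=sid, selected_k=best_k, inner_auc_profile=profile,
            cycle_probs=probs, selected_features=top_features,
            subject_score=aggregate_subject(probs, cfg.cv.aggregate)))
        log.info("outer fold %d/%d (%s): K=%d, score=%.3f",
                 i + 1, len(usable), sid, best_k, folds[-1].subject_score)

    scores = np.array([f.subject_score for f in folds])
    curve, auc, ci = roc_auc(scores, y_subj, ci_method=cfg.cv.ci_method,
                             n_bootstrap=cfg.cv.n_bootstrap, seed=seed)
    thr = youden_threshold(scores, y_subj)
    pred = scores >= thr
    tp = int(np.sum(pred & (y_subj == 1)))
    fn = int(np.sum(~pred & (y_subj == 1)))
    fp = int(np.sum(pred & (y_subj == 0)))
    tn = int(np.sum(~pred & (y_subj == 0)))
    metrics = confusion_metrics(tp, fn, fp, tn)
    ksum = k_distribution([f.selected_k for f in folds])
    imp_mean, imp_sd, top = importance_heatmap(X, y01, names,
                                               relieff_k=cfg.selection.relieff_k)
    return NestedCvResult(
        folds=folds, subject_ids=usable, scores=scores, labels=y_subj,
        roc=curve, auc=auc, auc_ci=ci, ci_method=cfg.cv.ci_method, youden=thr,
        confusion={"tp": tp, "fn": fn, "fp": fp, "tn": tn}, metrics=metrics,
        k_summary=ksum, importance_mean=imp_mean, importance_sd=imp_sd,
        top_features=top)
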