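"""Random-undersampling boosting (RUSBoost) for imbalanced gait-cycle labels.

Adaptive boosting in which each round's weak learner is fitted on a random
subsample where the majority class is undersampled (without replacement,
respecting the current boosting weights) to the target class ratio.  The
round's error is always computed on the *full* weighted training set —
undersampling affects learner fitting only — so the ensemble remains a valid
boosting of the original distribution.  On exactly balanced data the
undersampling step is a no-op and the ensemble coincides bitwise with plain
adaptive boosting under the same seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._tree import apply_bins, boost_rounds, fit_bins, predict_tree
from .config import BoostConfig

log = logging.getLogger(__name__)

_EPS_LOSS = 1e-6


@dataclass
class RusBoostModel:
    """A fitted ensemble: binned-threshold trees plus per-learner vote weights."""

    feature_names: Tuple[str, ...]
    bin_edges: np.ndarray
    trees: List[tuple] = field(default_factory=list)
    alphas: List[float] = field(default_factory=list)
    classes: Tuple[str, str] = ("Poor", "Good")   # index 0 / 1
    config: Optional[BoostConfig] = None
    seed: Optional[int] = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed vote margin sum(alpha_t * h_t(x)), h in {-1, +1}."""
        X = np.ascontiguousarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        codes = apply_bins(X, self.bin_edges)
        margin = np.zeros(X.shape[0])
        for tree, alpha in zip(self.trees, self.alphas):
            h = np.where(predict_tree(codes, *tree) > 0.5, 1.0, -1.0)
            margin += alpha * h
        return margin

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) class probabilities via softmax over the vote margins."""
        f = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-2.0 * f))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def to_json(self) -> str:
        """Self-describing serialization: config, seed, bins and all trees."""
        import json
        payload = {
            "feature_names": list(self.feature_names),
            "classes": list(self.classes),
            "seed": self.seed,
            "config": self.config.model_dump() if self.config else None,
            "bin_edges": self.bin_edges.tolist(),
            "alphas": self.alphas,
            "trees": [[arr.tolist() for arr in tree] for tree in self.trees],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "RusBoostModel":
        import json
        d = json.loads(text)
        model = cls(
            feature_names=tuple(d["feature_names"]),
            bin_edges=np.asarray(d["bin_edges"], dtype=float),
            classes=tuple(d["classes"]),
            seed=d["seed"],
            config=BoostConfig(**d["config"]) if d["config"] else None,
        )
        model.alphas = [float(a) for a in d["alphas"]]
        for tree in d["trees"]:
            feat, thr, left, right, val = tree
            model.trees.append((np.asarray(feat, np.int64), np.asarray(thr, np.int64),
                                np.asarray(left, np.int64), np.asarray(right, np.int64),
                                np.asarray(val, np.float64)))
        return model


def fit_rusboost(
    X: np.ndarray,
    y: np.ndarray,
    cfg: BoostConfig | None = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    undersample: bool = True,
    record_subsamples: Optional[list] = None,
    prebinned: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> RusBoostModel:
    """Fit the ensemble on cycle rows with already-selected (scaled) features.

    ``y`` holds 0/1 class indices (1 = Good).  ``record_subsamples``, when a
    list, receives each round's subsample index array (for auditing).
    ``prebinned`` optionally supplies (bin_edges, codes) for X, skipping the
    quantile-binning step; edges/codes must come from ``fit_bins``/
    ``apply_bins`` on the same columns.
    """
    cfg = cfg or BoostConfig()
    X = np.ascontiguousarray(X, dtype=float)
    y01 = np.ascontiguousarray(y, dtype=np.int8)
    n = X.shape[0]
    counts = np.bincount(y01, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present in the training data")
    minority = int(np.argmin(counts))
    if counts[minority] < cfg.min_leaf:
        raise ValueError(
            f"minority class has {counts[minority]} rows, below the tree minimum leaf "
            f"({cfg.min_leaf}); lower boost.min_leaf or provide more cycles")

    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{j}" for j in range(X.shape[1]))
    if prebinned is not None:
        edges, codes = prebinned
        codes = np.ascontiguousarray(codes)
    else:
        edges = fit_bins(X, cfg.n_bins)
        codes = apply_bins(X, edges)

    min_idx = np.flatnonzero(y01 == minority)
    maj_idx = np.flatnonzero(y01 != minority)
    n_keep = min(maj_idx.size, max(1, int(round(counts[minority] / cfg.target_ratio))))

    undersampling = undersample and n_keep < maj_idx.size
    if undersampling:
        # one row of Gumbel noise per undersampling attempt (rounds + retries)
        rng = np.random.default_rng(seed)
        gumbel = rng.gumbel(size=(cfg.n_learners + cfg.max_retries, maj_idx.size))
    else:
        gumbel = np.zeros((0, 0))

    # class-balanced initial weights: each class carries total weight 1/2,
    # so the round error is prevalence-neutral and a leave-one-subject-out
    # fold's slight class surplus cannot tilt every round's vote
    w0 = np.where(y01 == 1, 0.5 / counts[1], 0.5 / counts[0])
    feat, thr, left, right, val, alphas, subs, rounds = boost_rounds(
        codes, y01, w0, maj_idx.astype(np.int64), n_keep, gumbel,
        cfg.n_learners, cfg.learning_rate, cfg.max_depth, cfg.min_leaf,
        cfg.n_bins, cfg.max_retries, _EPS_LOSS)
    if rounds == 0:
        raise RuntimeError("no weak learner achieved weighted error below 0.5")
    if rounds < cfg.n_learners:
        log.warning("boosting stopped after %d/%d rounds (weighted error >= 0.5)",
                    rounds, cfg.n_learners)
    model = RusBoostModel(feature_names=names, bin_edges=edges, config=cfg, seed=seed)
    for t in range(rounds):
        model.trees.append((feat[t], thr[t], left[t], right[t], val[t]))
        model.alphas.append(float(alphas[t]))
        if record_subsamples is not None:
            record_subsamples.append(subs[t])
    return model
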