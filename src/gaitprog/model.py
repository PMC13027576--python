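"""Model/Results interface over the full prognostic pipeline.

`OutcomePrognosisModel` is constructed from a per-cycle feature table plus
subject outcome labels (or directly from a cohort of subjects, in which case
segmentation, featurization and MCID labeling run first); ``fit`` executes
the nested leave-one-subject-out evaluation and returns an
`OutcomePrognosisResults` carrying the subject-level discrimination
estimates, their uncertainty, the operating-point diagnostics and the
post-hoc importance maps, with a statsmodels-style ``summary()``.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .data import SubjectRecord
from .evaluate import NestedCvResult, run_nested_cv
from .features import extract_features
from .labeling import label_subjects
from .segment import segment_trial
from .stats import koos_total, sensitivity_logistic


class OutcomePrognosisModel:
    """Preoperative-gait prognostic model for knee-osteotomy outcomes."""

    def __init__(self, features: pd.DataFrame, labels: Mapping[str, str],
                 config: Optional[PipelineConfig] = None):
        self.features = features
        self.labels = dict(labels)
        self.config = config or PipelineConfig()
        self.baseline_totals: Optional[Mapping[str, float]] = None

    @classmethod
    def from_cohort(cls, subjects: Sequence[SubjectRecord],
                    config: Optional[PipelineConfig] = None) -> "OutcomePrognosisModel":
        """Segment every trial, extract the 60 wavelet features and label outcomes."""
        config = config or PipelineConfig()
        stances = []
        for rec in subjects:
            for trial in rec.trials:
                stances.extend(segment_trial(trial, subject_id=rec.subject_id, cfg=config))
        features = extract_features(stances, config.cwt)
        labels = label_subjects(subjects, config.label)
        model = cls(features, labels, config)
        model.baseline_totals = {s.subject_id: koos_total(s.koos_pre) for s in subjects}
        return model

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, labels: Mapping[str, str],
                       config: Optional[PipelineConfig] = None) -> "OutcomePrognosisModel":
        return cls(features, labels, config)

    def fit(self, seed: Optional[int] = None) -> "OutcomePrognosisResults":
        cv = run_nested_cv(self.features, self.labels, self.config, seed=seed)
        return OutcomePrognosisResults(self, cv)


class OutcomePrognosisResults:
    """Nested-CV results: discrimination, operating point, importance."""

    def __init__(self, model: OutcomePrognosisModel, cv: NestedCvResult):
        self.model = model
        self.cv = cv

    # -- headline quantities -------------------------------------------------
    @property
    def auc(self) -> float:
        return self.cv.auc

    @property
    def auc_ci(self):
        return self.cv.auc_ci

    @property
    def youden_threshold(self) -> float:
        return self.cv.youden

    @property
    def confusion(self):
        return self.cv.confusion

    @property
    def metrics(self):
        return self.cv.metrics

    @property
    def k_distribution(self):
        return self.cv.k_summary

    @property
    def subject_scores(self) -> pd.Series:
        return pd.Series(self.cv.scores, index=self.cv.subject_ids, name="score")

    @property
    def importance_mean(self) -> pd.DataFrame:
        return self.cv.importance_mean

    @property
    def importance_sd(self) -> pd.DataFrame:
        return self.cv.importance_sd

    def baseline_sensitivity(self):
        """Baseline-adjusted logistic sensitivity analysis of the scores."""
        if self.model.baseline_totals is None:
            raise ValueError("model was built without KOOS records; "
                             "supply baseline totals via stats.sensitivity_logistic")
        ids = self.cv.subject_ids
        return sensitivity_logistic(
            self.cv.scores, [self.model.baseline_totals[s] for s in ids],
            ["Good" if l else "Poor" for l in self.cv.labels])

    def summary(self) -> str:
        c = self.cv
        m = c.metrics
        ks = c.k_summary
        lines = [
            "          Gait-based outcome prognosis (nested LOSO CV)",
            "=" * 64,
            f"Subjects: {len(c.subject_ids)}   Good: {int(c.labels.sum())}   "
            f"Poor: {int((1 - c.labels).sum())}   Cycles: {len(self.model.features)}",
            f"AUC: {c.auc:.3f}   95% CI ({c.ci_method}): "
            f"[{c.auc_ci[0]:.3f}, {c.auc_ci[1]:.3f}]",
            f"Youden threshold: {c.youden:.3f}",
            f"Confusion (TP/FN/FP/TN): {c.confusion['tp']}/{c.confusion['fn']}/"
            f"{c.confusion['fp']}/{c.confusion['tn']}",
            f"Sensitivity: {m['sensitivity']:.2f}   Specificity: {m['specificity']:.2f}   "
            f"Accuracy: {m['accuracy']:.2f}",
            f"PPV: {m['ppv']:.2f}   NPV: {m['npv']:.2f}   F1: {m['f1']:.2f}",
            f"Selected K: median {ks['median']:g}, mean {ks['mean']:.1f}, "
            f"range {ks['range'][0]}-{ks['range'][1]}",
            "-" * 64,
            "Top features (global ReliefF): " + ", ".join(c.top_features[:5]),
            "=" * 64,
        ]
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------
    def plot_roc(self, ax=None):
        """ROC curve of the pooled subject-level scores."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        fpr, tpr, _ = self.cv.roc
        ax.plot(fpr, tpr, lw=2,
                label=f"AUC {self.auc:.2f} [{self.auc_ci[0]:.2f}, {self.auc_ci[1]:.2f}]")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    def plot_importance(self, axes=None):
        """Band x slice ReliefF importance heatmaps (Mean and SD features)."""
        import matplotlib.pyplot as plt
        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(10, 3.5))
        for ax, (title, mat) in zip(axes, [("Mean features", self.cv.importance_mean),
                                           ("SD features", self.cv.importance_sd)]):
            im = ax.imshow(mat.to_numpy(dtype=float), aspect="auto", cmap="viridis")
            ax.set_xticks(range(mat.shape[1]), mat.columns)
            ax.set_yticks(range(mat.shape[0]), mat.index)
            ax.set_title(title)
            ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return axes
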