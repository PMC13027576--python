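"""Baseline group comparisons and the baseline-adjusted sensitivity analysis.

The sensitivity analysis asks whether the gait-derived subject-level
prediction score carries prognostic information beyond the preoperative KOOS
level: a logistic regression of the outcome on (prediction score, baseline
KOOS total) with likelihood-ratio inference per covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import KOOS_SUBSCALES, StatsConfig
from .data import KoosRecord

log = logging.getLogger(__name__)


def compare_groups(a, b=None, kind: str = "continuous",
                   cfg: StatsConfig | None = None) -> Tuple[float, float]:
    """Two-sided group comparison: t-test (continuous) or chi-square (categorical).

    Continuous: pass two value arrays; pooled-variance by default, Welch by
    config.  Categorical: pass a contingency table (groups x categories);
    Pearson chi-square, continuity correction off by default.  Identical
    zero-variance groups return (0, 1).
    """
    cfg = cfg or StatsConfig()
    if kind == "continuous":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 observations per group")
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            return 0.0, 1.0
        res = sps.ttest_ind(a, b, equal_var=(cfg.t_test == "pooled"))
        return float(res.statistic), float(res.pvalue)
    if kind == "categorical":
        table = np.asarray(a, dtype=float)
        keep_r = table.sum(axis=1) > 0
        keep_c = table.sum(axis=0) > 0
        if not keep_r.all() or not keep_c.all():
            log.warning("dropping empty contingency rows/columns")
            table = table[keep_r][:, keep_c]
        res = sps.chi2_contingency(table, correction=cfg.chi2_continuity)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown kind {kind!r}")


def koos_total(koos: KoosRecord) -> float:
    """Baseline KOOS total: the mean of the five subscale scores."""
    return float(np.mean([koos.subscales[s] for s in KOOS_SUBSCALES]))


def account_exclusions(screened: int, exclusions: Mapping[str, int]) -> Dict:
    """Screening-to-analysis accounting: screened minus each exclusion count.

    Raises if any count is negative or the arithmetic goes below zero.
    """
    if screened < 0:
        raise ValueError("screened count must be non-negative")
    running = screened
    steps = []
    for reason, n in exclusions.items():
        if n < 0:
            raise ValueError(f"exclusion count for {reason!r} is negative")
        running -= n
        steps.append({"reason": reason, "excluded": int(n), "remaining": int(running)})
    if running < 0:
        raise ValueError("exclusions exceed the screened count")
    return {"screened": int(screened), "steps": steps, "analyzable": int(running)}


@dataclass
class SensitivityResult:
    """Logistic-regression sensitivity analysis with LRT inference."""

    params: pd.Series                 # coefficients incl. intercept
    odds_ratios: pd.Series            # exp(beta) per covariate
    or_ci: pd.DataFrame               # Wald 95% bounds per covariate
    lrt_stats: pd.Series              # 2*(ll_full - ll_reduced) per covariate
    lrt_pvalues: pd.Series
    ll_full: float
    ll_reduced: Dict[str, float]

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "coef": self.params.drop("const"),
            "OR": self.odds_ratios,
            "OR 2.5%": self.or_ci["lo"],
            "OR 97.5%": self.or_ci["hi"],
            "LRT": self.lrt_stats,
            "p(LRT)": self.lrt_pvalues,
        })
        return out


def sensitivity_logistic(
    scores: Sequence[float],
    baseline_totals: Sequence[float],
    labels: Sequence[str] | np.ndarray,
    min_subjects: int = 10,
) -> SensitivityResult:
    """Logistic fit of outcome on (prediction score, baseline KOOS total).

    Inference per covariate is by likelihood-ratio test against the model
    without it (chi-square, 1 df); odds ratios carry Wald 95% intervals.
    Perfect separation raises an explicit diagnostic rather than silently
    diverging; near-collinear designs emit a condition-number warning.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray([1 if l == "Good" else 0 for l in labels] if isinstance(labels[0], str)
                   else labels, dtype=float)
    X = pd.DataFrame({"score": np.asarray(scores, float),
                      "baseline_koos": np.asarray(baseline_totals, float)})
    if y.size < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects, got {y.size}")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    cond = np.linalg.cond(np.column_stack([np.ones(y.size), X.to_numpy()]))
    if cond > 1e8:
        log.warning("design matrix condition number %.2g: near-collinear covariates", cond)

    def fit(design: pd.DataFrame):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                return sm.Logit(y, sm.add_constant(design, has_constant="add")).fit(disp=0)
            except (PerfectSeparationWarning, Exception) as exc:
                if "separation" in str(exc).lower() or isinstance(exc, PerfectSeparationWarning):
                    raise ValueError(
                        "perfect separation: a covariate fully determines the outcome; "
                        "the MLE does not exist") from exc
                raise

    full = fit(X)
    lrt_stats, lrt_p, ll_red = {}, {}, {}
    for cov in X.columns:
        reduced = fit(X.drop(columns=[cov]))
        stat = max(0.0, 2.0 * (full.llf - reduced.llf))
        lrt_stats[cov] = stat
        lrt_p[cov] = float(sps.chi2.sf(stat, df=1))
        ll_red[cov] = float(reduced.llf)

    params = full.params
    covs = list(X.columns)
    ors = np.exp(params[covs])
    ci = full.conf_int().loc[covs]
    or_ci = pd.DataFrame({"lo": np.exp(ci[0]), "hi": np.exp(ci[1])}, index=covs)
    return SensitivityResult(
        params=params, odds_ratios=ors, or_ci=or_ci,
        lrt_stats=pd.Series(lrt_stats), lrt_pvalues=pd.Series(lrt_p),
        ll_full=float(full.llf), ll_reduced=ll_red)
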