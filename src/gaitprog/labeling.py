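"""Good/Poor outcome dichotomization from KOOS change scores.

A subject is a responder ("Good") when the pre-to-post improvement exceeds
the minimal clinically important difference (MCID) on at least three of the
five KOOS subscales; two or fewer responding subscales is "Poor".
"Exceeding" is read as a strict inequality by default; a config flag allows
>= because published MCID sources differ on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

from .config import KOOS_SUBSCALES, LabelConfig
from .data import KoosRecord


@dataclass(frozen=True)
class OutcomeLabel:
    label: str                      # "Good" | "Poor"
    flags: Mapping[str, bool]       # per-subscale MCID achievement
    n_achieved: int


def classify_outcome(pre: KoosRecord, post: KoosRecord,
                     cfg: LabelConfig | None = None) -> OutcomeLabel:
    """Apply the MCID responder rule to one subject's pre/post KOOS records."""
    cfg = cfg or LabelConfig()
    flags: Dict[str, bool] = {}
    for s in KOOS_SUBSCALES:
        delta = post.subscales[s] - pre.subscales[s]
        thr = cfg.mcid[s]
        flags[s] = (delta > thr) if cfg.strict_inequality else (delta >= thr)
    n = sum(flags.values())
    label = "Good" if n >= cfg.min_subscales_good else "Poor"
    return OutcomeLabel(label=label, flags=flags, n_achieved=n)


def label_subjects(subjects, cfg: LabelConfig | None = None) -> Dict[str, str]:
    """Label a cohort in place; returns {subject_id: label}."""
    out: Dict[str, str] = {}
    for rec in subjects:
        if rec.koos_pre is None or rec.koos_post is None:
            raise ValueError(f"subject {rec.subject_id}: incomplete KOOS records")
        res = classify_outcome(rec.koos_pre, rec.koos_post, cfg)
        rec.label = res.label
        out[rec.subject_id] = res.label
    return out
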