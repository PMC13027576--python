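"""Synthetic gait-cohort generator.

The generator does not attempt biomechanical realism; it reproduces the
*statistical and detectability* structure the analysis pipeline assumes, so
every downstream stage is testable without clinical data:

* lumbar anteroposterior acceleration carries exactly one dominant anterior
  peak per stride at the planted initial-contact (IC) instant, and the
  tibial pitch angular velocity one dominant anterior peak at toe-off (TO);
* the tibial acceleration is a smooth stride-periodic baseline (harmonics
  below the 5 Hz analysis floor, plus gravity on the vertical axis) with
  Gaussian-windowed sinusoid bursts planted in chosen stance sub-phases and
  frequency bands, plus white noise;
* KOOS scores are drawn so that the MCID responder rule reproduces the
  requested Good/Poor label by construction.

Burst amplitudes are drawn per cycle: for "mean-amplitude" effects a
bounded (uniform) law whose *mean* is the group level; for
"cycle-variability" effects a train of sub-bursts whose amplitudes deviate
antithetically from a common base by the group level, so the amplitude SD
within every cycle equals the group level and the within-region
variability signature is consistent cycle after cycle.

Seeding follows a splittable counter scheme: the child generator of subject
``i`` and stream ``s`` (0 = gait parameters, 1 = trial signals, 2 = KOOS) is
``default_rng(SeedSequence(master_seed, spawn_key=(i, s)))``, so adding or
removing one subject never shifts another subject's draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import KOOS_SUBSCALES, LabelConfig
from .data import ImuTrial, KoosRecord, SensorStream, SubjectRecord
from .labeling import classify_outcome

log = logging.getLogger(__name__)

GRAVITY = 9.81


class PlantedEffect(BaseModel):
    """One group-discriminative burst planted in a band x slice region."""

    model_config = ConfigDict(extra="forbid")

    band_hz: Tuple[float, float] = (5.0, 8.0)
    slice_index: int = Field(1, ge=1, le=6)
    channel: str = Field("mean-amplitude", pattern="^(mean-amplitude|cycle-variability)$")
    good_level: float = Field(..., ge=0.0)
    poor_level: float = Field(..., ge=0.0)
    base_level: float = Field(1.0, ge=0.0,
                              description="common amplitude mean for cycle-variability effects")
    jitter_sd: float = Field(0.1, ge=0.0,
                             description="common amplitude SD for mean-amplitude effects")
    n_sub_bursts: Optional[int] = Field(None, ge=1,
                                        description="sub-bursts per slice; default 1 for "
                                                    "mean-amplitude, 3 for cycle-variability")

    @model_validator(mode="after")
    def _band(self) -> "PlantedEffect":
        lo, hi = self.band_hz
        if not (5.0 <= lo < hi <= 20.0):
            raise ValueError(f"band {self.band_hz} must lie within the 5-20 Hz analysis range")
        return self

    def resolved_sub_bursts(self) -> int:
        if self.n_sub_bursts is not None:
            return self.n_sub_bursts
        return 1 if self.channel == "mean-amplitude" else 3

    def amplitude_params(self, group: str) -> Tuple[float, float]:
        """(mean, sd) of the per-cycle burst amplitude for a group."""
        level = self.good_level if group == "Good" else self.poor_level
        if self.channel == "mean-amplitude":
            return level, self.jitter_sd
        return self.base_level, level


def default_effects() -> List[PlantedEffect]:
    """Large planted effects in the regions the analysis is meant to recover.

    A 3x mean-amplitude difference in the 5-8 Hz band during loading
    response (slice 1), and a 16x within-cycle amplitude-variability
    difference in the same band during late stance (slice 5); both give
    feature-level standardized effects well beyond d = 1.5.
    """
    return [
        PlantedEffect(band_hz=(5.0, 8.0), slice_index=1, channel="mean-amplitude",
                      good_level=0.5, poor_level=1.5, jitter_sd=0.1),
        PlantedEffect(band_hz=(5.0, 8.0), slice_index=5, channel="cycle-variability",
                      good_level=0.05, poor_level=0.8, base_level=0.8),
    ]


class KoosParams(BaseModel):
    """Pre-operative score distributions per group and improvement draws."""

    model_config = ConfigDict(extra="forbid")

    pre_mean_good: Dict[str, float] = Field(default_factory=lambda: {
        "Pain": 48.0, "Symptoms": 53.0, "ADL": 40.0, "Sport/Rec": 40.0, "QOL": 27.0})
    pre_mean_poor: Dict[str, float] = Field(default_factory=lambda: {
        "Pain": 63.0, "Symptoms": 73.0, "ADL": 65.0, "Sport/Rec": 56.0, "QOL": 43.0})
    pre_sd: float = Field(15.0, gt=0.0)
    improve_margin: Tuple[float, float] = (2.0, 25.0)   # uniform excess over MCID
    nonimprove_range: Tuple[float, float] = (-15.0, -1.0)  # uniform offset below MCID
    max_attempts: int = Field(200, ge=1)


class CohortSpec(BaseModel):
    """Everything needed to generate one synthetic cohort deterministically."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    n_good: int = Field(37, ge=0)
    n_poor: int = Field(30, ge=0)
    cycles_per_subject: int = Field(18, ge=3, description="analyzable cycles after edge exclusion")
    trials_per_subject: int = Field(1, ge=1)
    fs: float = Field(100.0, gt=0.0)
    stride_mean_s: float = Field(1.1, gt=0.0)
    stride_sd_s: float = Field(0.08, ge=0.0)
    stance_mean_s: float = Field(0.65, gt=0.0)
    stance_sd_s: float = Field(0.05, ge=0.0)
    cycle_jitter_s: float = Field(0.02, ge=0.0, description="within-subject stride jitter")
    stance_jitter_s: float = Field(0.01, ge=0.0)
    noise_sd: float = Field(0.25, ge=0.0, description="tibial accelerometer noise, m/s^2")
    burst_window_frac: float = Field(0.5, gt=0.0, le=1.0,
                                     description="burst Gaussian-window SD as a fraction "
                                                 "of the slice duration")
    effects: List[PlantedEffect] = Field(default_factory=list)
    koos: KoosParams = Field(default_factory=KoosParams)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _feasible(self) -> "CohortSpec":
        if self.n_good + self.n_poor < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.stance_mean_s >= self.stride_mean_s:
            raise ValueError("stance duration must be shorter than the stride period")
        return self


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject gait timing drawn once from the cohort-level law."""

    subject_id: str
    group: str
    stride_mean_s: float
    stance_mean_s: float


def _rng(spec_seed: int, subject_index: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec_seed, spawn_key=(subject_index, stream, *extra)))


def _piecewise_phase(t: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Phase increasing by 2*pi between consecutive anchor times, extrapolated linearly."""
    k = np.arange(anchors.size, dtype=float)
    phase = np.interp(t, anchors, 2.0 * np.pi * k)
    # linear extrapolation beyond the anchor range
    if anchors.size >= 2:
        rate0 = 2.0 * np.pi / (anchors[1] - anchors[0])
        rate1 = 2.0 * np.pi / (anchors[-1] - anchors[-2])
        before = t < anchors[0]
        after = t > anchors[-1]
        phase[before] = (t[before] - anchors[0]) * rate0
        phase[after] = 2.0 * np.pi * k[-1] + (t[after] - anchors[-1]) * rate1
    return phase


def _gauss_peaks(t: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        lo = np.searchsorted(t, c - 5 * sigma)
        hi = np.searchsorted(t, c + 5 * sigma)
        out[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return out


def generate_trial(
    spec: CohortSpec,
    subject: SubjectParams,
    rng: np.random.Generator,
    trial_id: str = "trial0",
    n_strides: Optional[int] = None,
) -> Tuple[ImuTrial, Dict[str, np.ndarray]]:
    """One synthetic walking trial plus its ground-truth event annotations.

    ``n_strides`` defaults to ``cycles_per_subject + 4`` so that the
    first-2/last-2 edge exclusion retains exactly ``cycles_per_subject``
    analyzable cycles.  Fewer than 7 strides would leave under 3 analyzable
    cycles and is rejected.
    """
    n = n_strides if n_strides is not None else spec.cycles_per_subject + 4
    if n < 7:
        raise ValueError(f"at least 7 strides required, got {n}")
    fs = spec.fs
    strides = subject.stride_mean_s + spec.cycle_jitter_s * rng.standard_normal(n)
    stances = subject.stance_mean_s + spec.stance_jitter_s * rng.standard_normal(n)
    if np.any(stances >= strides) or np.any(stances <= 0):
        raise ValueError("infeasible timing: stance must be positive and shorter than stride")

    lead = 0.6
    ic_times = lead + np.concatenate(([0.0], np.cumsum(strides[:-1])))
    to_times = ic_times + stances
    total = to_times[-1] + lead
    n_samples = int(round(total * fs)) + 1
    t = np.arange(n_samples) / fs

    # snap ground-truth events to the sample grid so peaks sit on samples
    ic_idx = np.round(ic_times * fs).astype(int)
    to_idx = np.round(to_times * fs).astype(int)
    ic_times = ic_idx / fs
    to_times = to_idx / fs

    phi = _piecewise_phase(t, ic_times)     # stride phase anchored at IC
    psi = _piecewise_phase(t, to_times)     # stride phase anchored at TO
    noise = spec.noise_sd

    # taper the periodic baseline outside [first IC, last TO] so the lead-in
    # and lead-out carry no competing pseudo-event peaks
    env = np.ones(n_samples)
    before = t < ic_times[0]
    after = t > to_times[-1]
    env[before] = np.exp(-0.5 * ((t[before] - ic_times[0]) / 0.15) ** 2)
    env[after] = np.exp(-0.5 * ((t[after] - to_times[-1]) / 0.15) ** 2)

    g = GRAVITY
    # --- lumbar stream: IC peak carrier on the anteroposterior axis
    lum_acc = np.empty((n_samples, 3))
    lum_acc[:, 0] = env * 0.3 * np.sin(phi + 0.2) + 0.5 * noise * rng.standard_normal(n_samples)
    lum_acc[:, 1] = g + env * 0.8 * np.cos(2 * phi) + 0.5 * noise * rng.standard_normal(n_samples)
    lum_acc[:, 2] = (env * (0.5 * np.cos(phi) + 0.15 * np.cos(2 * phi + 0.4))
                     + 3.0 * _gauss_peaks(t, ic_times, 0.025)
                     + 0.5 * noise * rng.standard_normal(n_samples))
    lum_gyr = np.empty((n_samples, 3))
    for j, (amp, ph) in enumerate(((8.0, 0.3), (6.0, 1.1), (10.0, 2.0))):
        lum_gyr[:, j] = env * amp * np.cos(phi + ph) + 10.0 * noise * rng.standard_normal(n_samples)

    # --- tibial stream: TO peak carrier on the pitch gyroscope
    tib_gyr = np.empty((n_samples, 3))
    tib_gyr[:, 0] = (env * 30.0 * np.cos(psi) + 150.0 * _gauss_peaks(t, to_times, 0.02)
                     + 10.0 * noise * rng.standard_normal(n_samples))
    tib_gyr[:, 1] = env * 12.0 * np.cos(phi + 0.8) + 10.0 * noise * rng.standard_normal(n_samples)
    tib_gyr[:, 2] = env * 15.0 * np.cos(phi + 1.7) + 10.0 * noise * rng.standard_normal(n_samples)

    tib_acc = np.empty((n_samples, 3))
    tib_acc[:, 0] = env * 0.5 * np.cos(phi + 0.7) + noise * rng.standard_normal(n_samples)
    vertical = g + env * (1.2 * np.cos(phi) + 0.5 * np.cos(2 * phi + 1.0))
    # planted bursts ride on the dominant (vertical) axis so the magnitude
    # inherits them nearly additively
    for eff in spec.effects:
        mean, sd = eff.amplitude_params(subject.group)
        f_burst = 0.5 * (eff.band_hz[0] + eff.band_hz[1])
        # a mean-amplitude effect is one burst at the slice midpoint; a
        # variability effect is a triplet of sub-bursts across the slice whose
        # amplitudes are drawn independently, so a large amplitude SD shows up
        # as within-region (and cycle-to-cycle) inconsistency of the signal
        m_sub = eff.resolved_sub_bursts()
        sub_fracs = tuple((i + 0.5) / m_sub for i in range(m_sub))
        for k in range(n):
            stance_k = to_times[k] - ic_times[k]
            slice_dur = stance_k / 6.0
            slice_start = ic_times[k] + (eff.slice_index - 1) * slice_dur
            # window SD = burst_window_frac of the slice duration for a lone
            # burst (wide enough to stay spectrally inside its band), shrunk
            # for sub-burst trains so neighbours stay distinguishable
            sigma = spec.burst_window_frac * slice_dur * 2.0 / (m_sub + 1)
            if eff.channel == "mean-amplitude":
                # uniform amplitude law (SD = sd): bounded tails keep the
                # range-normalized feature diffs informative downstream
                amps = mean + sd * np.sqrt(3.0) * rng.uniform(-1.0, 1.0, m_sub)
            else:
                # antithetic +/- offsets in random order: the amplitude SD
                # within every single cycle equals sd (up to clipping), so the
                # within-region variability signature is consistent per cycle
                signs = rng.permutation([1.0 if i % 2 == 0 else -1.0
                                         for i in range(m_sub)])
                amps = mean + sd * signs
            amps = np.maximum(amps, 0.0)
            for frac, a in zip(sub_fracs, amps):
                tc = slice_start + frac * slice_dur
                lo = np.searchsorted(t, tc - 5 * sigma)
                hi = np.searchsorted(t, tc + 5 * sigma)
                win = t[lo:hi] - tc
                vertical[lo:hi] += a * np.exp(-0.5 * (win / sigma) ** 2) * np.cos(
                    2 * np.pi * f_burst * win)
    tib_acc[:, 1] = vertical + noise * rng.standard_normal(n_samples)
    tib_acc[:, 2] = (env * (0.8 * np.cos(phi + 1.9) + 0.3 * np.cos(2 * phi + 0.5))
                     + noise * rng.standard_normal(n_samples))

    trial = ImuTrial(trial_id=trial_id, fs=fs,
                     lumbar=SensorStream(acc=lum_acc, gyr=lum_gyr),
                     tibial=SensorStream(acc=tib_acc, gyr=tib_gyr))
    truth = {"ic_indices": ic_idx, "to_indices": to_idx}
    return trial, truth


def generate_koos(group: str, params: KoosParams, label_cfg: LabelConfig,
                  rng: np.random.Generator) -> Tuple[KoosRecord, KoosRecord]:
    """Draw pre/post KOOS records whose MCID classification equals ``group``.

    For Good the number of responding subscales is drawn from {3, 4, 5}, for
    Poor from {0, 1, 2}; clipping to [0, 100] is never allowed to flip the
    intended label (resample on violation, bounded attempts).
    """
    if group not in ("Good", "Poor"):
        raise ValueError(f"group must be Good or Poor, got {group!r}")
    means = params.pre_mean_good if group == "Good" else params.pre_mean_poor
    choices = (3, 4, 5) if group == "Good" else (0, 1, 2)
    for _ in range(params.max_attempts):
        n_improve = int(rng.choice(choices))
        improving = set(rng.permutation(list(KOOS_SUBSCALES))[:n_improve])
        pre, post = {}, {}
        for s in KOOS_SUBSCALES:
            p = float(np.clip(means[s] + params.pre_sd * rng.standard_normal(), 0.0, 100.0))
            mcid = label_cfg.mcid[s]
            if s in improving:
                delta = mcid + rng.uniform(*params.improve_margin)
            else:
                delta = mcid + rng.uniform(*params.nonimprove_range)
            pre[s] = p
            post[s] = float(np.clip(p + delta, 0.0, 100.0))
        rec_pre = KoosRecord(subscales=pre, timepoint="pre")
        rec_post = KoosRecord(subscales=post, timepoint="post2y")
        if classify_outcome(rec_pre, rec_post, label_cfg).label == group:
            return rec_pre, rec_post
    raise ValueError(
        f"could not realize a {group} label in {params.max_attempts} attempts; "
        "pre-score means leave no room for the required improvement")


def generate_cohort(
    spec: CohortSpec,
    label_cfg: LabelConfig | None = None,
) -> Tuple[List[SubjectRecord], Dict]:
    """Generate a full cohort plus a ground-truth manifest.

    Deterministic under (spec, spec.seed); per-subject generators are
    derived from the master seed by the documented spawn-key scheme.
    """
    label_cfg = label_cfg or LabelConfig()
    subjects: List[SubjectRecord] = []
    manifest: Dict = {
        "seed": spec.seed,
        "seed_scheme": "default_rng(SeedSequence(seed, spawn_key=(subject_index, stream[, trial])))",
        "effects": [e.model_dump() for e in spec.effects],
        "subjects": [],
    }
    n_total = spec.n_good + spec.n_poor
    for i in range(n_total):
        group = "Good" if i < spec.n_good else "Poor"
        sid = f"sub{i:03d}"
        prng = _rng(spec.seed, i, 0)
        params = SubjectParams(
            subject_id=sid, group=group,
            stride_mean_s=max(0.5, spec.stride_mean_s + spec.stride_sd_s * prng.standard_normal()),
            stance_mean_s=max(0.3, spec.stance_mean_s + spec.stance_sd_s * prng.standard_normal()),
        )
        if params.stance_mean_s >= params.stride_mean_s:
            params = SubjectParams(sid, group, params.stride_mean_s,
                                   0.6 * params.stride_mean_s)
        trials, truths = [], []
        for tr in range(spec.trials_per_subject):
            trial, truth = generate_trial(spec, params, _rng(spec.seed, i, 1, tr),
                                          trial_id=f"{sid}_t{tr}")
            trials.append(trial)
            truths.append({k: v.tolist() for k, v in truth.items()})
        pre, post = generate_koos(group, spec.koos, label_cfg, _rng(spec.seed, i, 2))
        rec = SubjectRecord(subject_id=sid, trials=trials, koos_pre=pre, koos_post=post,
                            label=group)
        subjects.append(rec)
        manifest["subjects"].append({
            "subject_id": sid, "group": group,
            "stride_mean_s": params.stride_mean_s, "stance_mean_s": params.stance_mean_s,
            "events": truths,
        })
    return subjects, manifest
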