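"""Signal conditioning, gait-event detection and stance-phase segmentation.

The processing chain mirrors standard wearable gait practice: every raw
channel is low-pass filtered with a zero-phase 4th-order Butterworth (20 Hz
cutoff), initial contact (IC) is taken from the anterior peak of the lumbar
anteroposterior acceleration, toe-off (TO) from the anterior pitch peak of
the tibial angular velocity.  Each IC paired with the next TO bounds one
stance phase; the first two and last two cycles of a trial are discarded to
remove gait initiation/termination effects, and each retained stance is
time-normalized to 101 points with a cubic spline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .config import DetectionConfig, FilterConfig, PipelineConfig, SegmentationConfig
from .data import ImuTrial
from .features import magnitude

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitEvents:
    """Detected gait events of one trial, as ascending sample indices."""

    ic_indices: np.ndarray
    to_indices: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ic_indices", "to_indices"):
            arr = np.asarray(getattr(self, name), dtype=int)
            object.__setattr__(self, name, arr)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class StanceWaveform:
    """One gait cycle's stance-phase tibial acceleration.

    ``raw`` holds the (n, 3) tibial acceleration over [IC, TO] at native fs
    (both event samples included); ``normalized`` the 101-point magnitude
    over 0-100% of stance.
    """

    subject_id: str
    trial_id: str
    cycle_index: int
    raw: np.ndarray
    fs: float
    duration_s: float
    normalized: Optional[np.ndarray] = None


def lowpass_filter(x: np.ndarray, fs: float, cutoff_hz: float = 20.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    The bidirectional pass squares the magnitude response, so the effective
    attenuation at frequency f is 1/(1 + (f/cutoff)^(2*order)).
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2.0 * cutoff_hz:
        raise ValueError(f"fs={fs} must exceed twice the cutoff ({cutoff_hz} Hz)")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[-1] <= padlen:
        raise ValueError(f"series of length {x.shape[-1]} too short for zero-phase "
                         f"filtering (needs > {padlen} samples)")
    return filtfilt(b, a, x, axis=-1)


def filter_trial(trial: ImuTrial, cfg: FilterConfig | None = None) -> ImuTrial:
    """Return a copy of the trial with every channel low-pass filtered."""
    cfg = cfg or FilterConfig()

    def f(arr: np.ndarray) -> np.ndarray:
        return lowpass_filter(arr.T, trial.fs, cfg.cutoff_hz, cfg.order).T

    from .data import SensorStream  # local import avoids cycle at module load

    return ImuTrial(
        trial_id=trial.trial_id,
        fs=trial.fs,
        lumbar=SensorStream(acc=f(trial.lumbar.acc), gyr=f(trial.lumbar.gyr)),
        tibial=SensorStream(acc=f(trial.tibial.acc), gyr=f(trial.tibial.gyr)),
        acc_unit=trial.acc_unit,
    )


def estimate_stride_s(x: np.ndarray, fs: float, lo_s: float = 0.4, hi_s: float = 2.5) -> float:
    """Stride-period estimate from the autocorrelation's first dominant peak.

    The first local autocorrelation peak reaching at least 70% of the
    strongest peak in the search window is taken, so integer multiples of
    the stride (which can score comparably) are not mistaken for it.
    """
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = x.size
    lo, hi = int(lo_s * fs), min(int(hi_s * fs), n - 1)
    if hi <= lo:
        return 1.0
    ac = np.correlate(x, x, mode="full")[n - 1:]
    seg = ac[lo:hi + 1]
    peaks, props = find_peaks(seg, height=0.0)
    if peaks.size == 0:
        lag = lo + int(np.argmax(seg))
    else:
        heights = props["peak_heights"]
        good = peaks[heights >= 0.7 * heights.max()]
        lag = lo + int(good[0])
    return lag / fs


def _detect_peaks(signal: np.ndarray, fs: float, min_separation_s: Optional[float],
                  prominence_frac: float, anterior_is_positive: bool) -> np.ndarray:
    sig = np.asarray(signal, dtype=float)
    if not anterior_is_positive:
        sig = -sig
    scale = float(np.percentile(np.abs(sig), 95))
    if scale <= 0.0:
        return np.array([], dtype=int)
    if min_separation_s is None:
        min_separation_s = 0.5 * estimate_stride_s(sig, fs)
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, _ = find_peaks(sig, prominence=prominence_frac * scale, distance=distance)
    return peaks.astype(int)


def detect_initial_contacts(lumbar_ap: np.ndarray, fs: float,
                            min_separation_s: Optional[float] = None,
                            prominence_frac: float = 0.3,
                            anterior_is_positive: bool = True) -> np.ndarray:
    """IC = anterior peaks of the (filtered) lumbar anteroposterior acceleration."""
    return _detect_peaks(lumbar_ap, fs, min_separation_s, prominence_frac, anterior_is_positive)


def detect_toe_offs(tibial_gyr_pitch: np.ndarray, fs: float,
                    min_separation_s: Optional[float] = None,
                    prominence_frac: float = 0.3,
                    anterior_is_positive: bool = True) -> np.ndarray:
    """TO = anterior pitch peaks of the (filtered) tibial angular velocity."""
    return _detect_peaks(tibial_gyr_pitch, fs, min_separation_s, prominence_frac, anterior_is_positive)


def detect_gait_events(trial: ImuTrial, cfg: DetectionConfig | None = None) -> GaitEvents:
    """Detect IC and TO on an already-filtered trial."""
    cfg = cfg or DetectionConfig()
    ic = detect_initial_contacts(trial.channel("lumbar_ACC_Z"), trial.fs,
                                 cfg.min_separation_s, cfg.prominence_frac,
                                 cfg.anterior_is_positive_lumbar)
    to = detect_toe_offs(trial.channel("tibial_GYR_X"), trial.fs,
                         cfg.min_separation_s, cfg.prominence_frac,
                         cfg.anterior_is_positive_tibial)
    return GaitEvents(ic_indices=ic, to_indices=to)


def pair_events(events: GaitEvents) -> List[tuple]:
    """Pair each IC with the earliest TO strictly after it.

    A second IC arriving before any TO invalidates the earlier IC (logged);
    TOs preceding the first IC are dropped.
    """
    pairs: List[tuple] = []
    to = events.to_indices
    ic_list = list(events.ic_indices)
    ti = 0
    for j, ic in enumerate(ic_list):
        nxt_ic = ic_list[j + 1] if j + 1 < len(ic_list) else None
        while ti < len(to) and to[ti] <= ic:
            ti += 1
        if ti >= len(to):
            break
        if nxt_ic is not None and nxt_ic < to[ti]:
            log.warning("IC at %d invalidated by IC at %d before TO", ic, nxt_ic)
            continue
        pairs.append((int(ic), int(to[ti])))
        ti += 1
    return pairs


def segment_stances(events: GaitEvents, trial: ImuTrial, subject_id: str = "",
                    cfg: SegmentationConfig | None = None) -> List[StanceWaveform]:
    """Cut stance phases [IC, TO] and apply the edge-cycle exclusion rule.

    After pairing, the first ``n_exclude_edge`` and last ``n_exclude_edge``
    cycles are removed; trials with fewer than ``min_paired_cycles`` paired
    cycles contribute nothing (logged warning).
    """
    cfg = cfg or SegmentationConfig()
    pairs = pair_events(events)
    if len(pairs) < cfg.min_paired_cycles:
        log.warning("trial %s: only %d paired cycles (< %d); trial excluded",
                    trial.trial_id, len(pairs), cfg.min_paired_cycles)
        return []
    e = cfg.n_exclude_edge
    kept = pairs[e:len(pairs) - e] if e else pairs
    out: List[StanceWaveform] = []
    for idx, (ic, to) in enumerate(kept):
        raw = trial.tibial.acc[ic:to + 1]  # both event samples included
        duration = (to - ic) / trial.fs
        sw = StanceWaveform(subject_id=subject_id, trial_id=trial.trial_id,
                            cycle_index=idx, raw=raw, fs=trial.fs, duration_s=duration)
        mag = magnitude(raw[:, 0], raw[:, 1], raw[:, 2])
        if mag.size >= 4:
            sw.normalized = normalize_stance(mag, trial.fs)
        else:
            log.warning("trial %s cycle %d: %d samples (< 4), cycle rejected",
                        trial.trial_id, idx, mag.size)
            continue
        out.append(sw)
    return out


def normalize_stance(raw: np.ndarray, fs: float, n_points: int = 101) -> np.ndarray:
    """Resample a stance-phase series to ``n_points`` over 0-100% of its duration.

    Cubic-spline interpolation through the raw samples, evaluated on an
    equally spaced grid over [0, duration]; the endpoints are reproduced
    exactly.  Fewer than 4 samples cannot support a cubic spline.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 4:
        raise ValueError(f"stance of {raw.size} samples too short for cubic spline (needs >= 4)")
    t = np.arange(raw.size) / fs
    grid = np.linspace(0.0, t[-1], n_points)
    return CubicSpline(t, raw)(grid)


def segment_trial(trial: ImuTrial, subject_id: str = "",
                  cfg: PipelineConfig | None = None) -> List[StanceWaveform]:
    """Filter -> detect events -> segment, with one call."""
    cfg = cfg or PipelineConfig()
    filtered = filter_trial(trial, cfg.filter)
    events = detect_gait_events(filtered, cfg.detection)
    return segment_stances(events, filtered, subject_id=subject_id, cfg=cfg.segmentation)
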