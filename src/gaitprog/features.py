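"""Time-frequency feature engineering on the tibial acceleration magnitude.

Each stance phase is reduced to 60 features: the stance is divided into six
equal time slices (printed as 0-17, 17-33, 33-50, 50-67, 67-83 and 83-100%
of stance — rounded sixths), the 5-20 Hz range into five 3 Hz bands, and in
each of the 30 band x slice regions the mean and the standard deviation of
the absolute continuous-wavelet coefficients are taken.  The mean reflects
average oscillatory intensity in that region, the SD its within-region
variability.

The transform runs on the raw-time (un-normalized) stance segment at native
sampling rate, because the band edges are physical Hz, which have no meaning
on a percent-of-stance axis; the coefficient time axis is then mapped to
stance percent for slicing.  A config switch (``cwt.on_normalized``) moves
the transform onto the 101-point normalized waveform instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
import pywt

from .config import CwtConfig

log = logging.getLogger(__name__)


def band_edges(cfg: CwtConfig | None = None) -> np.ndarray:
    """Equal-width frequency-band edges, e.g. [5, 8, 11, 14, 17, 20] Hz."""
    cfg = cfg or CwtConfig()
    return np.linspace(cfg.f_min_hz, cfg.f_max_hz, cfg.n_bands + 1)


def feature_names(cfg: CwtConfig | None = None) -> List[str]:
    """Canonical feature names: ``<Mean|SD>_<lo>-<hi>Hz_s<k>`` in canonical order."""
    cfg = cfg or CwtConfig()
    edges = band_edges(cfg)
    names = []
    for stat in ("Mean", "SD"):
        for b in range(cfg.n_bands):
            lo, hi = edges[b], edges[b + 1]
            for s in range(1, cfg.n_slices + 1):
                names.append(f"{stat}_{lo:g}-{hi:g}Hz_s{s}")
    return names


#: Canonical 60 names under the default grid.
FEATURE_NAMES: List[str] = feature_names()


def parse_feature_name(name: str) -> tuple:
    """Split a canonical name into (stat, band_low, band_high, slice_index)."""
    stat, band, s = name.split("_")
    lo, hi = band[:-2].split("-")
    return stat, float(lo), float(hi), int(s[1:])


def magnitude(acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray) -> np.ndarray:
    """Euclidean norm of the three orthogonal acceleration components."""
    x, y, z = (np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("acceleration components must have equal length")
    return np.sqrt(x * x + y * y + z * z)


@dataclass
class TimeFrequencyMap:
    """Absolute CWT coefficients over a stance phase.

    ``coeffs`` has one row per analysis frequency (descending order recorded
    in ``freqs_hz``) and one column per time sample; ``time_pct`` maps each
    column to percent of stance.
    """

    coeffs: np.ndarray
    freqs_hz: np.ndarray
    time_pct: np.ndarray


def _wavelet(cfg: CwtConfig) -> pywt.ContinuousWavelet:
    return pywt.ContinuousWavelet(f"cmor{cfg.bandwidth:.6f}-{cfg.center_frequency:.10f}")


def analysis_frequencies(cfg: CwtConfig | None = None) -> np.ndarray:
    """Geometric frequency grid covering [f_min, f_max] at the voice density."""
    cfg = cfg or CwtConfig()
    n_octaves = np.log2(cfg.f_max_hz / cfg.f_min_hz)
    n = int(np.ceil(n_octaves * cfg.voices_per_octave)) + 1
    k = np.arange(n)
    return cfg.f_max_hz * 2.0 ** (-k / cfg.voices_per_octave)


def cwt_stance(x: np.ndarray, fs: float, cfg: CwtConfig | None = None) -> TimeFrequencyMap:
    """Analytic-Morlet CWT of one stance-phase magnitude series.

    No cone-of-influence masking is applied: all coefficients enter the
    downstream region statistics, because the loading-response slice abuts
    the segment edge and masking would empty it.  By default the segment is
    zero-extended beyond its edges (``pad_mode="zero"``), which attenuates
    edge coefficients uniformly across frequency; mirror padding
    (``pad_mode="reflect"``) is available but duplicates bursts that sit
    near an edge, and the interference of a burst with its reflection
    mislocalizes its frequency content.
    """
    cfg = cfg or CwtConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < cfg.min_samples:
        raise ValueError(f"stance of {n} samples below CWT minimum ({cfg.min_samples})")
    if fs <= 2.0 * cfg.f_max_hz:
        raise ValueError(f"fs={fs} must exceed twice the upper analysis frequency")
    # a Morlet atom has (numerically near-)zero mean, so the DC level carries
    # no information; removing it before the transform kills the residual
    # leakage of truncated wavelet tails at the segment edges
    x = x - np.mean(x)
    wav = _wavelet(cfg)
    freqs = analysis_frequencies(cfg)
    scales = pywt.frequency2scale(wav, freqs / fs)
    if cfg.pad_mode == "reflect":
        # half the longest wavelet length: 3 time-sigmas of the largest atom
        sigma_t = scales.max() * np.sqrt(cfg.bandwidth / 2.0)
        pad = int(min(n - 1, np.ceil(3.0 * sigma_t)))
    else:
        pad = 0  # the convolution itself zero-extends
    xp = np.pad(x, pad, mode="reflect") if pad else x
    coeffs, actual = pywt.cwt(xp, scales, wav, sampling_period=1.0 / fs, method="fft")
    if pad:
        coeffs = coeffs[:, pad:pad + n]
    time_pct = np.linspace(0.0, 100.0, n) if n > 1 else np.zeros(1)
    return TimeFrequencyMap(coeffs=np.abs(coeffs), freqs_hz=np.asarray(actual), time_pct=time_pct)


def band_slice_features(tfr: TimeFrequencyMap, cfg: CwtConfig | None = None) -> pd.Series:
    """Summarize a time-frequency map into the canonical Mean/SD features.

    Bands are half-open [lo, hi) except the top band, closed at the upper
    limit; slices are exact sixths of stance.  SD uses the n-1 denominator
    (configurable).  A band containing no frequency rows indicates a voice
    density too coarse for the grid and raises.
    """
    cfg = cfg or CwtConfig()
    edges = band_edges(cfg)
    n_slices = cfg.n_slices
    slice_idx = np.minimum((tfr.time_pct / (100.0 / n_slices)).astype(int), n_slices - 1)
    values = {}
    for b in range(cfg.n_bands):
        lo, hi = edges[b], edges[b + 1]
        if b == cfg.n_bands - 1:
            rows = (tfr.freqs_hz >= lo) & (tfr.freqs_hz <= hi)
        else:
            rows = (tfr.freqs_hz >= lo) & (tfr.freqs_hz < hi)
        if not rows.any():
            raise ValueError(f"no analysis frequencies fall in band [{lo:g}, {hi:g}) Hz; "
                             "increase voices_per_octave")
        sub = tfr.coeffs[rows]
        for s in range(n_slices):
            cols = slice_idx == s
            region = sub[:, cols].ravel()
            if region.size == 0:
                raise ValueError(f"empty time slice s{s + 1}: stance too short")
            mean = float(np.mean(region))
            sd = float(np.std(region, ddof=cfg.sd_ddof)) if region.size > cfg.sd_ddof else 0.0
            values[f"Mean_{lo:g}-{hi:g}Hz_s{s + 1}"] = mean
            values[f"SD_{lo:g}-{hi:g}Hz_s{s + 1}"] = sd
    names = feature_names(cfg)
    return pd.Series([values[n] for n in names], index=names, dtype=float)


def cycle_features(stance, cfg: CwtConfig | None = None) -> pd.Series:
    """60-feature vector for one :class:`~gaitprog.segment.StanceWaveform`."""
    cfg = cfg or CwtConfig()
    if cfg.on_normalized:
        if stance.normalized is None:
            raise ValueError("stance has no normalized waveform")
        # the 101-point axis spans the true stance duration
        fs_eff = 100.0 / stance.duration_s if stance.duration_s > 0 else float("nan")
        series, fs = stance.normalized, fs_eff
    else:
        series = magnitude(stance.raw[:, 0], stance.raw[:, 1], stance.raw[:, 2])
        fs = stance.fs
    tfr = cwt_stance(series, fs, cfg)
    return band_slice_features(tfr, cfg)


def extract_features(stances: Sequence, cfg: CwtConfig | None = None) -> pd.DataFrame:
    """Feature table for a list of stance waveforms, one row per usable cycle.

    Cycles too short for the transform are rejected with a logged reason.
    """
    cfg = cfg or CwtConfig()
    rows, keys = [], []
    for sw in stances:
        try:
            vec = cycle_features(sw, cfg)
        except ValueError as exc:
            log.warning("cycle (%s, %s, %d) rejected: %s",
                        sw.subject_id, sw.trial_id, sw.cycle_index, exc)
            continue
        keys.append((sw.subject_id, sw.trial_id, sw.cycle_index))
        rows.append(vec)
    if not rows:
        return pd.DataFrame(columns=["subject_id", "trial_id", "cycle_index", *feature_names(cfg)])
    feats = pd.DataFrame(rows).reset_index(drop=True)
    meta = pd.DataFrame(keys, columns=["subject_id", "trial_id", "cycle_index"])
    return pd.concat([meta, feats], axis=1)
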