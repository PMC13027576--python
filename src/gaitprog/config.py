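"""Run configuration for the gait-prognosis pipeline.

Every tunable knob of the pipeline lives here, with a validated default, so a
run can be replayed bit-identically from its logged configuration.  Unknown
keys are rejected outright (no silent typo tolerance) and out-of-range values
raise with the offending path.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

log = logging.getLogger(__name__)

#: Canonical KOOS subscale names, in reporting order.
KOOS_SUBSCALES: Tuple[str, ...] = ("Pain", "Symptoms", "ADL", "Sport/Rec", "QOL")

#: Canonical 12 sensor channels: two sensors x (3-axis accelerometer + gyroscope).
SENSOR_CHANNELS: Tuple[str, ...] = tuple(
    f"{sensor}_{kind}_{axis}"
    for sensor in ("lumbar", "tibial")
    for kind in ("ACC", "GYR")
    for axis in ("X", "Y", "Z")
)


class ConfigError(ValueError):
    """A configuration file or value failed validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FilterConfig(_Strict):
    """Zero-phase Butterworth low-pass applied to every raw channel."""

    order: int = Field(4, ge=1, le=12)
    cutoff_hz: float = Field(20.0, gt=0.0)


class DetectionConfig(_Strict):
    """Peak-picking rules for gait-event detection.

    ``min_separation_s=None`` means: estimate the stride period from the
    autocorrelation of the detection channel and use half of it.  The
    anterior-sign flags adapt the detector to the device mounting; with the
    default conventions the anterior direction is the positive half-axis of
    lumbar ACC_Z (anteroposterior) and of the tibial pitch gyroscope.
    """

    min_separation_s: Optional[float] = Field(None, gt=0.0)
    prominence_frac: float = Field(0.3, gt=0.0, le=1.0)
    anterior_is_positive_lumbar: bool = True
    anterior_is_positive_tibial: bool = True


class SegmentationConfig(_Strict):
    n_exclude_edge: int = Field(2, ge=0, description="cycles dropped at each trial end")
    min_paired_cycles: int = Field(5, ge=1)


class CwtConfig(_Strict):
    """Continuous wavelet transform and time-frequency grid settings.

    The analytic Morlet atom is exp(i*2*pi*C*t) * exp(-t^2/B); the defaults
    (B=2, C=6/2pi) reproduce the classic omega0=6 Morlet.  ``on_normalized``
    switches the transform from the native-time stance segment (default,
    physical Hz semantics) to the 101-point normalized waveform.
    """

    f_min_hz: float = Field(5.0, gt=0.0)
    f_max_hz: float = Field(20.0, gt=0.0)
    voices_per_octave: int = Field(12, ge=4, le=48)
    bandwidth: float = Field(2.0, gt=0.0)
    center_frequency: float = Field(0.9549296585513721, gt=0.0)
    n_bands: int = Field(5, ge=1)
    n_slices: int = Field(6, ge=1)
    sd_ddof: int = Field(1, ge=0, le=1)
    on_normalized: bool = False
    min_samples: int = Field(16, ge=4)
    pad_mode: Literal["zero", "reflect"] = "zero"

    @model_validator(mode="after")
    def _band_order(self) -> "CwtConfig":
        if self.f_max_hz <= self.f_min_hz:
            raise ValueError("f_max_hz must exceed f_min_hz")
        return self


class LabelConfig(_Strict):
    """MCID-based Good/Poor dichotomization of the KOOS change scores.

    The default 10-point threshold per subscale is a documented placeholder;
    any real analysis must supply the published per-subscale values.
    """

    mcid: Dict[str, float] = Field(
        default_factory=lambda: {s: 10.0 for s in KOOS_SUBSCALES}
    )
    strict_inequality: bool = True
    min_subscales_good: int = Field(3, ge=1, le=5)

    @model_validator(mode="after")
    def _check_mcid(self) -> "LabelConfig":
        if set(self.mcid) != set(KOOS_SUBSCALES):
            raise ValueError(f"mcid must define exactly the subscales {KOOS_SUBSCALES}")
        if any(v <= 0 for v in self.mcid.values()):
            raise ValueError("all MCID thresholds must be > 0")
        return self


class SelectionConfig(_Strict):
    """Fold-internal feature selection: mRMR reduction then ReliefF ranking."""

    n_mrmr: int = Field(30, ge=1)
    mrmr_variant: Literal["quotient", "difference"] = "quotient"
    mi_bins: Optional[int] = Field(None, ge=2, description="None: min(10, floor(sqrt(n)))")
    relieff_k: int = Field(10, ge=1)


class BoostConfig(_Strict):
    """Random-undersampling boosting ensemble hyperparameters."""

    n_learners: int = Field(100, ge=1)
    learning_rate: float = Field(0.1, gt=0.0, le=1.0)
    max_depth: int = Field(3, ge=1, le=8)
    min_leaf: int = Field(5, ge=1)
    target_ratio: float = Field(1.0, gt=0.0, le=1.0,
                                description="minority/majority count after undersampling")
    n_bins: int = Field(64, ge=4, le=256)
    max_retries: int = Field(10, ge=0)


class CvConfig(_Strict):
    """Nested leave-one-subject-out protocol settings."""

    k_min: int = Field(5, ge=1)
    k_max: int = Field(25, ge=1)
    stage1: Tuple[int, ...] = (7, 13, 19, 25)
    refine_offsets: Tuple[int, ...] = (-4, -2, 2, 4)
    aggregate: Literal["median", "mean", "max"] = "median"
    ci_method: Literal["delong", "bootstrap"] = "delong"
    n_bootstrap: int = Field(2000, ge=100)

    @model_validator(mode="after")
    def _grid(self) -> "CvConfig":
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        bad = [k for k in self.stage1 if not (self.k_min <= k <= self.k_max)]
        if bad:
            raise ValueError(f"stage1 candidates {bad} outside [k_min, k_max]")
        return self


class StatsConfig(_Strict):
    t_test: Literal["pooled", "welch"] = "pooled"
    chi2_continuity: bool = False
    or_ci: Literal["wald", "profile"] = "wald"


class PipelineConfig(_Strict):
    """Fully-resolved configuration for one pipeline run."""

    seed: int = Field(0, ge=0)
    fs_hz: float = Field(100.0, gt=0.0)
    acc_unit: Literal["m/s^2", "g"] = "m/s^2"
    sensor_map: Dict[str, str] = Field(
        default_factory=dict,
        description="canonical channel -> CSV column; empty = identity",
    )
    filter: FilterConfig = Field(default_factory=FilterConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    cwt: CwtConfig = Field(default_factory=CwtConfig)
    label: LabelConfig = Field(default_factory=LabelConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    boost: BoostConfig = Field(default_factory=BoostConfig)
    cv: CvConfig = Field(default_factory=CvConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @model_validator(mode="after")
    def _channels(self) -> "PipelineConfig":
        unknown = set(self.sensor_map) - set(SENSOR_CHANNELS)
        if unknown:
            raise ValueError(f"sensor_map keys are not canonical channels: {sorted(unknown)}")
        return self


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config, filling documented defaults for every unset knob.

    An empty or missing mapping yields the all-defaults configuration.  The
    fully-resolved config is echoed to the module logger so a run can be
    replayed exactly.
    """
    data = {}
    if path is not None:
        raw = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = PipelineConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    log.info("resolved configuration:\n%s", dump_config(cfg))
    return cfg


def dump_config(cfg: PipelineConfig) -> str:
    """Serialize a config to YAML; ``load`` of the dump is idempotent."""
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(dump_config(cfg), encoding="utf-8")
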