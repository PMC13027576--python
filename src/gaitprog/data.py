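"""Core domain types and the sensor-CSV dialect reader/writer.

A walking trial is a pair of sample-synchronized 6-channel streams (3-axis
accelerometer + 3-axis gyroscope) from a lumbar and a tibial inertial sensor,
sampled at a common rate (100 Hz by default).  Axis semantics follow the
acquisition convention: ACC_X mediolateral, ACC_Y vertical, ACC_Z
anteroposterior; GYR_* are the angular velocities about those axes, so the
tibial pitch (sagittal-plane) rate is GYR_X.

The CSV dialect is deliberately plain — comma separated, header row, UTF-8,
'.' decimal — and a column-name mapping adapts arbitrary vendor headers to
the canonical 12 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import KOOS_SUBSCALES, SENSOR_CHANNELS

AXES = ("X", "Y", "Z")


class FormatError(ValueError):
    """A data file does not conform to the expected layout."""


@dataclass
class SensorStream:
    """One 6-channel IMU stream: ``acc`` and ``gyr`` are (n, 3) arrays."""

    acc: np.ndarray
    gyr: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be an (n, 3) array")
        if self.gyr.shape != self.acc.shape:
            raise ValueError("gyr must match acc shape")


@dataclass
class ImuTrial:
    """One walking trial: two synchronized sensor streams plus sampling rate."""

    trial_id: str
    fs: float
    lumbar: SensorStream
    tibial: SensorStream
    acc_unit: str = "m/s^2"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.lumbar.acc.shape[0] != self.tibial.acc.shape[0]:
            raise ValueError("lumbar and tibial streams must be sample-synchronized")
        if self.n_samples < 1:
            raise ValueError("trial must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.lumbar.acc.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one canonical channel, e.g. ``"lumbar_ACC_Z"``."""
        sensor, kind, axis = name.split("_")
        stream = getattr(self, sensor)
        arr = stream.acc if kind == "ACC" else stream.gyr
        return arr[:, AXES.index(axis)]


@dataclass(frozen=True)
class KoosRecord:
    """Five KOOS subscale scores (0-100) at one timepoint."""

    subscales: Mapping[str, float]
    timepoint: str = "pre"  # "pre" | "post2y"

    def __post_init__(self) -> None:
        if set(self.subscales) != set(KOOS_SUBSCALES):
            missing = set(KOOS_SUBSCALES) - set(self.subscales)
            raise ValueError(f"KOOS record must have exactly 5 subscales; missing {sorted(missing)}")
        for name, v in self.subscales.items():
            if not 0.0 <= float(v) <= 100.0:
                raise ValueError(f"KOOS {name}={v} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.subscales[s] for s in KOOS_SUBSCALES], dtype=float)


@dataclass
class SubjectRecord:
    """One subject: trials, pre/post KOOS and (optionally) the outcome label."""

    subject_id: str
    trials: List[ImuTrial] = field(default_factory=list)
    koos_pre: Optional[KoosRecord] = None
    koos_post: Optional[KoosRecord] = None
    label: Optional[str] = None  # "Good" | "Poor" | None

    def __post_init__(self) -> None:
        if self.label not in (None, "Good", "Poor"):
            raise ValueError(f"label must be Good/Poor/None, got {self.label!r}")


# ---------------------------------------------------------------------------
# trial CSV IO


def _resolve_map(sensor_map: Optional[Mapping[str, str]]) -> Dict[str, str]:
    mapping = {ch: ch for ch in SENSOR_CHANNELS}
    if sensor_map:
        mapping.update(sensor_map)
    return mapping


def read_trial_csv(
    path: str | Path,
    fs: float = 100.0,
    sensor_map: Optional[Mapping[str, str]] = None,
    trial_id: Optional[str] = None,
    acc_unit: str = "m/s^2",
) -> ImuTrial:
    """Read one trial from CSV, mapping vendor columns onto the 12 canonical channels.

    Non-mapped columns are ignored; row order is preserved.  Missing mapped
    columns raise a :class:`FormatError` naming the channel; non-numeric
    cells and ragged rows raise parse errors.
    """
    path = Path(path)
    mapping = _resolve_map(sensor_map)
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows carry the line number
        raise FormatError(f"{path}: malformed CSV: {exc}") from exc
    cols: Dict[str, np.ndarray] = {}
    for canonical, column in mapping.items():
        if column not in df.columns:
            sensor, kind, axis = canonical.split("_")
            raise FormatError(f"{path}: missing column for {sensor} {kind}_{axis} (expected {column!r})")
        series = pd.to_numeric(df[column], errors="coerce")
        if series.isna().any():
            row = int(series.isna().idxmax()) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric or missing value in column {column!r} at line {row}")
        cols[canonical] = series.to_numpy(dtype=float)

    def stream(sensor: str) -> SensorStream:
        acc = np.column_stack([cols[f"{sensor}_ACC_{a}"] for a in AXES])
        gyr = np.column_stack([cols[f"{sensor}_GYR_{a}"] for a in AXES])
        return SensorStream(acc=acc, gyr=gyr)

    return ImuTrial(
        trial_id=trial_id or path.stem,
        fs=fs,
        lumbar=stream("lumbar"),
        tibial=stream("tibial"),
        acc_unit=acc_unit,
    )


def write_trial_csv(
    trial: ImuTrial,
    path: str | Path,
    sensor_map: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a trial in the reader's dialect; round-trips at full float precision."""
    mapping = _resolve_map(sensor_map)
    data = {mapping[ch]: trial.channel(ch) for ch in SENSOR_CHANNELS}
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# feature-table IO

#: index columns of every per-cycle feature table
CYCLE_KEYS = ("subject_id", "trial_id", "cycle_index")


def write_features_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write one row per gait cycle: the key columns then the canonical features.

    All rows must share the same feature columns (enforced by the DataFrame
    container); the key columns must be present.
    """
    missing = [k for k in CYCLE_KEYS if k not in features.columns]
    if missing:
        raise FormatError(f"feature table missing key columns {missing}")
    ordered = list(CYCLE_KEYS) + [c for c in features.columns if c not in CYCLE_KEYS]
    features[ordered].to_csv(path, index=False, float_format="%.17g")


def read_features_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [k for k in CYCLE_KEYS if k not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing key columns {missing}")
    return df


# ---------------------------------------------------------------------------
# KOOS CSV IO


def write_koos_csv(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    """Long-format KOOS table: subject_id, timepoint, then the 5 subscales."""
    rows = []
    for s in subjects:
        for rec in (s.koos_pre, s.koos_post):
            if rec is None:
                continue
            row = {"subject_id": s.subject_id, "timepoint": rec.timepoint}
            row.update({k: rec.subscales[k] for k in KOOS_SUBSCALES})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_koos_csv(path: str | Path) -> Dict[str, Dict[str, KoosRecord]]:
    """Read the long-format KOOS table into {subject_id: {timepoint: record}}."""
    df = pd.read_csv(path, encoding="utf-8")
    needed = ["subject_id", "timepoint", *KOOS_SUBSCALES]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: KOOS table missing columns {missing}")
    out: Dict[str, Dict[str, KoosRecord]] = {}
    for _, row in df.iterrows():
        rec = KoosRecord(
            subscales={s: float(row[s]) for s in KOOS_SUBSCALES},
            timepoint=str(row["timepoint"]),
        )
        out.setdefault(str(row["subject_id"]), {})[rec.timepoint] = rec
    return out
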