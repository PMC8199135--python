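"""Recording containers, CSV I/O, configuration, and the pre-detection low-pass filter.

A per-foot recording holds three synchronized channels sampled at a uniform
rate: time (s), sagittal-plane shank angular velocity from the x-axis of a
shoe-mounted gyroscope (deg/s), and a single fused pressure channel from two
force-sensing resistors wired as a voltage divider under heel and forefoot.
The pressure channel is stored offset-removed: negative when the heel is
loaded, positive when the forefoot is loaded, exactly zero while the foot is
off the ground.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import (
    ConfigError,
    EmptyRecordingError,
    FormatError,
    SamplingError,
)

#: Required CSV columns, in order.
CSV_COLUMNS = ("time_s", "gyro_dps", "pressure_au")

#: Maximum allowed deviation of the time step from its median, in seconds.
TIME_STEP_TOL = 1e-9

Side = Literal["left", "right"]


@dataclass(frozen=True)
class FootRecording:
    """Synchronized gyroscope + pressure time series for one foot."""

    side: Side
    time: np.ndarray
    gyro: np.ndarray
    pressure: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        for name in ("time", "gyro", "pressure"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if n < 2:
            raise EmptyRecordingError(f"recording needs >= 2 samples, got {n}")
        if self.gyro.size != n or self.pressure.size != n:
            raise FormatError("time, gyro and pressure must have equal length")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise SamplingError("time must be strictly increasing")
        step = float(np.median(steps))
        if np.max(np.abs(steps - step)) > TIME_STEP_TOL:
            raise SamplingError(
                f"non-uniform sampling: step deviates by more than {TIME_STEP_TOL} s"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Span of the time axis in seconds."""
        return float(self.time[-1] - self.time[0])

    @classmethod
    def from_arrays(
        cls, side: Side, time: np.ndarray, gyro: np.ndarray, pressure: np.ndarray
    ) -> "FootRecording":
        """Build a recording, inferring the rate from the time column."""
        time = np.asarray(time, dtype=float)
        if time.size < 2:
            raise EmptyRecordingError("recording needs >= 2 samples")
        rate = 1.0 / float(np.median(np.diff(time)))
        return cls(side=side, time=time, gyro=gyro, pressure=pressure, rate=rate)


@dataclass(frozen=True)
class WalkRecording:
    """Left and right foot recordings for one walk."""

    left: FootRecording
    right: FootRecording
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isclose(self.left.rate, self.right.rate):
            raise FormatError("left and right recordings must share the sampling rate")
        lo = max(self.left.time[0], self.right.time[0])
        hi = min(self.left.time[-1], self.right.time[-1])
        if hi <= lo:
            raise FormatError("left and right recordings must overlap in time")


@dataclass
class PipelineConfig:
    """Tunable parameters for the whole analysis pipeline.

    Event-detection thresholds follow the rule-based detector: the mid-swing
    peak is searched between crossings of ``msw_threshold`` (5 deg/s); the
    mid-stance point must lie within ``ms_band`` (+-1.5 deg/s) of zero with a
    backward sample-to-sample difference below ``ms_diff_threshold``
    (0.25 deg/s).
    """

    msw_threshold: float = 5.0
    ms_band: float = 1.5
    ms_diff_threshold: float = 0.25
    filter_cutoff: float = 10.0
    filter_order: int = 4
    resample_points: int = 101
    dtw_local_cost: Literal["squared", "absolute"] = "squared"
    si_form: Literal["log_ratio_x100"] = "log_ratio_x100"
    si_numerator: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.msw_threshold > self.ms_band > self.ms_diff_threshold > 0):
            raise ConfigError(
                "thresholds must satisfy msw_threshold > ms_band > ms_diff_threshold > 0"
            )
        if self.resample_points < 3:
            raise ConfigError("resample_points must be >= 3")
        if self.filter_cutoff <= 0 or self.filter_order < 1:
            raise ConfigError("filter_cutoff must be > 0 and filter_order >= 1")
        if self.dtw_local_cost not in ("squared", "absolute"):
            raise ConfigError(f"unknown dtw_local_cost {self.dtw_local_cost!r}")
        if self.si_numerator not in ("left", "right"):
            raise ConfigError(f"unknown si_numerator {self.si_numerator!r}")

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "PipelineConfig":
        """Load a config from YAML; missing file or keys fall back to defaults."""
        if path is None:
            return cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def read_recording(path: str | Path, side: Side) -> FootRecording:
    """Read a per-foot CSV (columns time_s, gyro_dps, pressure_au)."""
    try:
        # round_trip parser so write_recording -> read_recording is bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyRecordingError(f"{path}: empty file") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise EmptyRecordingError(f"{path}: fewer than 2 data rows")
    for c in CSV_COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number):
            raise FormatError(f"{path}: column {c} is not numeric")
    return FootRecording.from_arrays(
        side=side,
        time=df["time_s"].to_numpy(),
        gyro=df["gyro_dps"].to_numpy(),
        pressure=df["pressure_au"].to_numpy(),
    )


def write_recording(rec: FootRecording, path: str | Path) -> None:
    """Write a recording to CSV with full float precision (round-trip safe)."""
    df = pd.DataFrame(
        {"time_s": rec.time, "gyro_dps": rec.gyro, "pressure_au": rec.pressure}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def lowpass_filter(rec: FootRecording, cfg: PipelineConfig | None = None) -> FootRecording:
    """Zero-phase Butterworth low-pass of the gyro channel.

    Event detection locates extrema and threshold crossings, so the filter is
    applied forward-backward (``sosfiltfilt``) to avoid phase shift. Pressure
    and time are left untouched.
    """
    cfg = cfg or PipelineConfig()
    nyquist = rec.rate / 2.0
    if cfg.filter_cutoff >= nyquist:
        raise ConfigError(
            f"filter cutoff {cfg.filter_cutoff} Hz >= Nyquist {nyquist} Hz"
        )
    sos = sps.butter(cfg.filter_order, cfg.filter_cutoff, btype="low", fs=rec.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.gyro)
    return replace(rec, gyro=filtered)
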