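"""Stride extraction, cycle-grid resampling, standardization and channel fusion.

Strides (HS-to-HS intervals) are cut from a recording with the gyro-derived
events, resampled onto a common 0-100% gait-cycle grid with shape-preserving
PCHIP interpolation, averaged pointwise, z-standardized (Z = (X - mu) / sigma,
population sigma), and finally the standardized mean gyro and pressure
waveforms are fused by superposition (pointwise sum). The fused waveform is
the input to the DTW asymmetry distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import (
    ChannelError,
    ConfigError,
    DegenerateSignalError,
    GridError,
    NoStridesError,
)
from .event_detection import GaitEvents, detect_events
from .signal_io import FootRecording, PipelineConfig, Side, lowpass_filter

Channel = str  # "gyro" | "pressure"


@dataclass(frozen=True)
class StrideSegment:
    """One HS-to-HS stride of a single channel at the original rate.

    ``samples`` covers [HS_k, HS_{k+1}) so consecutive strides do not share
    samples; ``closing_value`` is the channel value at the closing HS, used as
    the right endpoint when interpolating.
    """

    channel: Channel
    samples: np.ndarray
    closing_value: float
    duration: float
    swing_duration: float
    max_angular_velocity: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stride duration must be positive")
        if not (0 < self.swing_duration < self.duration):
            raise ValueError("swing duration must lie inside the stride")


@dataclass(frozen=True)
class NormalizedStride:
    """A stride resampled onto an equally spaced 0-100% cycle grid."""

    grid: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class FusedStride:
    """Standardized mean gyro + pressure waveforms summed on the cycle grid."""

    grid: np.ndarray
    values: np.ndarray
    side: Side
    n_strides: int


def extract_strides(
    rec: FootRecording, ev: GaitEvents, channel: Channel
) -> list[StrideSegment]:
    """Cut one StrideSegment per complete consecutive HS pair."""
    if channel == "gyro":
        values = rec.gyro
    elif channel == "pressure":
        values = rec.pressure
    else:
        raise ChannelError(f"unknown channel {channel!r}")
    bounds = ev.stride_bounds()
    if not bounds:
        raise NoStridesError("no complete HS-to-HS stride available")
    out = []
    for hs0, to, hs1 in bounds:
        samples = values[hs0:hs1]
        seg = StrideSegment(
            channel=channel,
            samples=samples,
            closing_value=float(values[hs1]),
            duration=float(rec.time[hs1] - rec.time[hs0]),
            swing_duration=float(rec.time[hs1] - rec.time[to]),
            max_angular_velocity=float(np.max(values[hs0 : hs1 + 1]))
            if channel == "gyro"
            else None,
        )
        out.append(seg)
    return out


def resample_stride(seg: StrideSegment, n: int) -> NormalizedStride:
    """PCHIP-resample a stride onto ``n`` equally spaced 0-100% cycle points.

    PCHIP is monotone and shape-preserving: the interpolant never overshoots
    local data extrema, and endpoints are reproduced exactly.
    """
    if n < 3:
        raise ConfigError("resample_points must be >= 3")
    y = np.append(seg.samples, seg.closing_value)
    x = np.linspace(0.0, 100.0, y.size)
    grid = np.linspace(0.0, 100.0, n)
    values = PchipInterpolator(x, y)(grid)
    # pin endpoints against interpolation round-off
    values[0], values[-1] = y[0], y[-1]
    return NormalizedStride(grid=grid, values=values)


def mean_stride(strides: list[NormalizedStride]) -> NormalizedStride:
    """Pointwise arithmetic mean of resampled strides on a shared grid."""
    if not strides:
        raise NoStridesError("mean of zero strides")
    grid = strides[0].grid
    for s in strides[1:]:
        if s.grid.size != grid.size or not np.array_equal(s.grid, grid):
            raise GridError("strides are on different cycle grids")
    return NormalizedStride(
        grid=grid, values=np.mean([s.values for s in strides], axis=0)
    )


def standardize(w: NormalizedStride) -> NormalizedStride:
    """Z-transform to zero mean and unit population standard deviation."""
    mu = float(np.mean(w.values))
    sigma = float(np.std(w.values))  # population (divide-by-N) convention
    if sigma == 0.0:
        raise DegenerateSignalError("cannot standardize a constant signal")
    return NormalizedStride(grid=w.grid, values=(w.values - mu) / sigma)


def fuse(
    gyro_std: NormalizedStride,
    pressure_std: NormalizedStride,
    side: Side,
    n_strides: int = 0,
) -> FusedStride:
    """Superpose (sum) the standardized gyro and pressure mean strides."""
    if gyro_std.grid.size != pressure_std.grid.size or not np.array_equal(
        gyro_std.grid, pressure_std.grid
    ):
        raise GridError("gyro and pressure strides are on different grids")
    return FusedStride(
        grid=gyro_std.grid,
        values=gyro_std.values + pressure_std.values,
        side=side,
        n_strides=n_strides,
    )


def build_fused_stride(
    rec: FootRecording, cfg: PipelineConfig | None = None
) -> FusedStride:
    """Full per-foot pipeline: filter, detect, extract, resample, fuse.

    Standardization is applied to the per-foot *mean* stride, after averaging,
    so amplitude variability across strides is retained in the mean before the
    z-transform fixes the scale for fusion.
    """
    cfg = cfg or PipelineConfig()
    filtered = lowpass_filter(rec, cfg)
    ev = detect_events(filtered, cfg)
    fused_parts = {}
    n_strides = 0
    for channel in ("gyro", "pressure"):
        segs = extract_strides(filtered, ev, channel)
        n_strides = len(segs)
        resampled = [resample_stride(s, cfg.resample_points) for s in segs]
        fused_parts[channel] = standardize(mean_stride(resampled))
    return fuse(fused_parts["gyro"], fused_parts["pressure"], rec.side, n_strides)
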