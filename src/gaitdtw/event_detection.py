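"""Rule-based gait event detection on the filtered shank gyroscope signal.

The detector finds four events per gait cycle from the sagittal angular
velocity alone:

* **MSW** (mid-swing): maximum between an upward and the paired downward
  crossing of a fixed threshold (default 5 deg/s).
* **MS** (mid-stance, foot flat): first point between consecutive MSW peaks
  where the signal sits within a band around zero (default +-1.5 deg/s) and
  the backward difference is below a flatness threshold (default 0.25 deg/s).
* **HS** (heel-strike): minimum between an MSW and the following MS.
* **TO** (toe-off): minimum between an MS and the following MSW.

Within each retained cycle the event order is
``MSW_k < HS_k < MS_k < TO_k < MSW_{k+1}``; cycles where no MS qualifies are
dropped. A stride is the interval between consecutive heel-strikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoStridesError
from .signal_io import FootRecording, PipelineConfig


@dataclass(frozen=True)
class GaitEvents:
    """Sample indices of detected gait events.

    ``msw`` lists every mid-swing peak. ``hs``, ``ms`` and ``to`` are aligned
    per retained cycle; ``cycle_ids[k]`` is the index into ``msw`` of the peak
    that opens cycle ``k``, so consecutive cycles (``cycle_ids`` differing by
    one) bound a complete HS-to-HS stride.
    """

    rising: np.ndarray
    falling: np.ndarray
    msw: np.ndarray
    ms: np.ndarray
    hs: np.ndarray
    to: np.ndarray
    cycle_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def stride_bounds(self) -> list[tuple[int, int, int]]:
        """(opening HS, TO, closing HS) index triples for complete strides.

        Only cycles that are adjacent (no dropped cycle in between) form a
        stride; the TO is the one inside the stride, i.e. of the opening cycle.
        """
        out = []
        for k in range(len(self.hs) - 1):
            if self.cycle_ids[k + 1] == self.cycle_ids[k] + 1:
                out.append((int(self.hs[k]), int(self.to[k]), int(self.hs[k + 1])))
        return out


def find_threshold_crossings(
    gyro: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (rising, falling) crossing indices of ``threshold``.

    A rising index is the first sample of a maximal run with values
    >= threshold; the paired falling index is the first sample after the run
    back below threshold. An initial run already in progress and a trailing
    run that never ends are discarded.
    """
    gyro = np.asarray(gyro, dtype=float)
    above = gyro >= threshold
    d = np.diff(above.astype(np.int8))
    rising = np.flatnonzero(d == 1) + 1
    falling = np.flatnonzero(d == -1) + 1
    if falling.size and (not rising.size or falling[0] <= rising[0]):
        falling = falling[1:]  # run already in progress at sample 0
    n = min(rising.size, falling.size)
    return rising[:n], falling[:n]


def detect_msw(
    gyro: np.ndarray, rising: np.ndarray, falling: np.ndarray
) -> np.ndarray:
    """Mid-swing peaks: argmax on each [rising, falling] span (earliest tie)."""
    gyro = np.asarray(gyro, dtype=float)
    return np.array(
        [r + int(np.argmax(gyro[r : f + 1])) for r, f in zip(rising, falling)],
        dtype=int,
    )


def detect_ms(
    gyro: np.ndarray, msw: np.ndarray, cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Mid-stance per MSW pair; returns (ms indices, opening-msw cycle ids).

    The first index j strictly between consecutive peaks with
    |gyro[j]| <= ms_band and |gyro[j] - gyro[j-1]| < ms_diff_threshold
    qualifies; a cycle with no such point yields no MS and is dropped.
    """
    gyro = np.asarray(gyro, dtype=float)
    flat = np.abs(gyro) <= cfg.ms_band
    flat[1:] &= np.abs(np.diff(gyro)) < cfg.ms_diff_threshold
    flat[0] = False
    ms, cycle_ids = [], []
    for k in range(len(msw) - 1):
        span = np.flatnonzero(flat[msw[k] + 1 : msw[k + 1]])
        if span.size:
            ms.append(msw[k] + 1 + int(span[0]))
            cycle_ids.append(k)
    return np.array(ms, dtype=int), np.array(cycle_ids, dtype=int)


def detect_hs(gyro: np.ndarray, msw: np.ndarray, ms: np.ndarray) -> np.ndarray:
    """Heel-strikes: argmin strictly between each MSW and its following MS."""
    gyro = np.asarray(gyro, dtype=float)
    return np.array(
        [m + 1 + int(np.argmin(gyro[m + 1 : s])) for m, s in zip(msw, ms)],
        dtype=int,
    )


def detect_to(gyro: np.ndarray, ms: np.ndarray, msw: np.ndarray) -> np.ndarray:
    """Toe-offs: argmin strictly between each MS and its following MSW."""
    gyro = np.asarray(gyro, dtype=float)
    return np.array(
        [s + 1 + int(np.argmin(gyro[s + 1 : m])) for s, m in zip(ms, msw)],
        dtype=int,
    )


def detect_events(rec: FootRecording, cfg: PipelineConfig | None = None) -> GaitEvents:
    """Run the full rule-based detector on an (already filtered) recording.

    Raises
    ------
    NoStridesError
        If fewer than two heel-strikes survive, i.e. no stride exists.
    """
    cfg = cfg or PipelineConfig()
    gyro = rec.gyro
    rising, falling = find_threshold_crossings(gyro, cfg.msw_threshold)
    msw = detect_msw(gyro, rising, falling)
    ms, cycle_ids = detect_ms(gyro, msw, cfg)
    if len(ms) < 2:
        raise NoStridesError(f"only {len(ms)} complete cycles detected")
    opening_msw = msw[cycle_ids]
    closing_msw = msw[cycle_ids + 1]
    hs = detect_hs(gyro, opening_msw, ms)
    to = detect_to(gyro, ms, closing_msw)
    ev = GaitEvents(
        rising=rising, falling=falling, msw=msw, ms=ms, hs=hs, to=to,
        cycle_ids=cycle_ids,
    )
    if len(ev.stride_bounds()) < 1 or len(hs) < 2:
        raise NoStridesError("fewer than 2 heel-strikes in adjacent cycles")
    return ev


def events_to_times(ev: GaitEvents, rec: FootRecording) -> dict[str, list[float]]:
    """Map detected indices onto the recording's time axis (for export)."""
    t = rec.time
    return {
        name: [float(t[i]) for i in getattr(ev, name)]
        for name in ("msw", "ms", "hs", "to")
    }
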