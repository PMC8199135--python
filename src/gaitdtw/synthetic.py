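"""Parametric generator of gyro + pressure walking signals with ground truth.

The generator emulates the morphology of shank-mounted gyroscope and fused
heel/forefoot pressure recordings during walking, so the whole analysis
pipeline can be exercised and validated without recorded data. Each gait
cycle of the angular-velocity channel is built from C1-smooth cosine-eased
arcs between physiologic control points: a negative heel-strike trough, an
exactly flat near-zero mid-stance plateau, a negative toe-off trough and a
positive mid-swing peak. The pressure channel is a negative heel-load pulse
at heel contact transitioning to a positive forefoot-load pulse through
stance, and exactly zero during swing (an unloaded FSR voltage divider is
pinned at its offset voltage, so noise is only added where load is present).

Hemiplegic-like asymmetry is produced by a severity-scaled preset on one
foot: prolonged swing at preserved stride period, attenuated mid-swing peak
(limited ankle/knee rotation), and a pressure pulse whose onset leads the
gyro heel-strike trough (the foot touches down before the ankle has fully
rotated).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .signal_io import FootRecording, Side, WalkRecording

#: Gait-cycle phase fractions (of stance / of cycle) for the control points.
_FLAT_START = 0.25  # of stance: foot-flat onset
_FLAT_END = 0.75  # of stance: end of foot-flat plateau
_MSW_FRAC = 0.5  # of swing: mid-swing peak position
_HEEL_END = 0.30  # of stance: heel pulse ends / forefoot pulse begins
_LEAD_IN = 0.35  # of one stride: recording starts this far before the first HS
_LEAD_OUT = 0.95  # of one stride: recording ends this far after the last HS


@dataclass
class GaitParams:
    """Generator parameters for one foot's walking signal.

    Defaults describe normal adult gait at a plausible instrumented-shoe
    scale: 1.1 s strides at 100 Hz, 60/40 stance/swing split, a ~250 deg/s
    mid-swing peak with ~80 and ~60 deg/s heel-strike and toe-off troughs.
    ``pressure_lead`` shifts the heel-pulse onset relative to the gyro HS
    trough (0 for normal gait, negative when the foot lands early).
    """

    rate: float = 100.0
    n_strides: int = 10
    stride_duration: float = 1.1
    stride_jitter_sd: float = 0.02
    stance_fraction: float = 0.60
    swing_peak_amplitude: float = 250.0
    hs_trough_amplitude: float = 80.0
    to_trough_amplitude: float = 60.0
    heel_load_amplitude: float = 1.0
    forefoot_load_amplitude: float = 1.2
    pressure_lead: float = 0.0
    gyro_noise_sd: float = 0.5
    pressure_noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.stance_fraction < 1.0):
            raise ConfigError("stance_fraction must lie in (0, 1)")
        for name in (
            "swing_peak_amplitude",
            "hs_trough_amplitude",
            "to_trough_amplitude",
            "heel_load_amplitude",
            "forefoot_load_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_strides < 1:
            raise ConfigError("n_strides must be >= 1")
        if self.stride_duration <= 0 or self.rate <= 0:
            raise ConfigError("stride_duration and rate must be positive")


@dataclass
class AsymmetryPreset:
    """Severity-scaled hemiplegic-gait modification of the affected foot.

    At severity 0 both feet are statistically identical; all factors vary
    continuously with severity. ``swing_prolongation`` multiplies the
    affected swing fraction at preserved stride period, ``peak_attenuation``
    is the remaining fraction of the mid-swing peak at full severity, and
    ``pressure_lead`` (s) is the full-severity heel-pulse lead.
    """

    severity: float = 1.0
    affected_side: Side = "left"
    swing_prolongation: float = 1.35
    peak_attenuation: float = 0.55
    pressure_lead: float = -0.06

    def validate(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ConfigError("severity must lie in [0, 1]")
        if self.affected_side not in ("left", "right"):
            raise ConfigError("affected_side must be 'left' or 'right'")

    def apply(self, params: GaitParams) -> GaitParams:
        """Return the affected-side parameters at this severity."""
        self.validate()
        s = self.severity
        swing = (1.0 - params.stance_fraction) * (
            1.0 + s * (self.swing_prolongation - 1.0)
        )
        if swing >= 1.0:
            raise ConfigError("prolonged swing fraction must stay below 1")
        return replace(
            params,
            stance_fraction=1.0 - swing,
            swing_peak_amplitude=params.swing_peak_amplitude
            * (1.0 - s * (1.0 - self.peak_attenuation)),
            pressure_lead=s * self.pressure_lead,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted event times (s, on the recording's time axis).

    ``hs`` has n_strides + 1 entries bounding the strides; ``ms`` (foot-flat
    onset) and ``to`` cover every cycle present including the trailing
    partial one; ``msw`` additionally includes the lead-in partial cycle.
    """

    hs: np.ndarray
    ms: np.ndarray
    to: np.ndarray
    msw: np.ndarray
    pressure_onset: np.ndarray
    stride_duration: np.ndarray
    swing_duration: np.ndarray
    stance_fraction: float
    max_angular_velocity: float


def _cosine_arcs(t_rel: np.ndarray, nodes_t: np.ndarray, nodes_v: np.ndarray) -> np.ndarray:
    """Piecewise cosine-eased interpolation through (nodes_t, nodes_v).

    Each segment eases from v0 to v1 with zero slope at both ends, so the
    concatenation is C1-smooth and exactly flat wherever v0 == v1.
    """
    seg = np.clip(np.searchsorted(nodes_t, t_rel, side="right") - 1, 0, len(nodes_t) - 2)
    t0, t1 = nodes_t[seg], nodes_t[seg + 1]
    v0, v1 = nodes_v[seg], nodes_v[seg + 1]
    s = (t_rel - t0) / (t1 - t0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))


def _gyro_nodes(T: float, p: GaitParams) -> tuple[np.ndarray, np.ndarray]:
    f = p.stance_fraction
    ts = np.array(
        [0.0, _FLAT_START * f * T, _FLAT_END * f * T, f * T,
         (f + _MSW_FRAC * (1.0 - f)) * T, T]
    )
    vs = np.array(
        [-p.hs_trough_amplitude, 0.0, 0.0, -p.to_trough_amplitude,
         p.swing_peak_amplitude, -p.hs_trough_amplitude]
    )
    return ts, vs


def _pressure_pulses(
    time: np.ndarray, h: float, T: float, p: GaitParams
) -> np.ndarray:
    """Heel + forefoot load pulses of the stride with HS at time ``h``."""
    f = p.stance_fraction
    t0 = h + p.pressure_lead  # heel-pulse onset (leads HS when negative)
    t_c = h + _HEEL_END * f * T  # heel -> forefoot crossover
    t_to = h + f * T  # unloading complete at toe-off
    out = np.zeros_like(time)
    m = (time > t0) & (time < t_c)
    out[m] -= p.heel_load_amplitude * np.sin(
        np.pi * (time[m] - t0) / (t_c - t0)
    ) ** 2
    m = (time > t_c) & (time < t_to)
    out[m] += p.forefoot_load_amplitude * np.sin(
        np.pi * (time[m] - t_c) / (t_to - t_c)
    ) ** 2
    return out


def synth_foot(
    params: GaitParams,
    side: Side = "left",
    t0: float = 0.0,
    raw_voltage: bool = False,
) -> tuple[FootRecording, GroundTruth]:
    """Generate one foot's recording plus planted ground-truth event times.

    The recording covers a partial lead-in and lead-out cycle around the
    ``n_strides`` requested strides so that every bounding heel-strike is
    recoverable by the rule-based detector. With ``raw_voltage`` the pressure
    channel is emitted as the 5 V divider output (2.5 V offset not removed).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_strides
    # stride durations for lead-in partial (-1), full strides 0..n-1, lead-out (n)
    T = params.stride_duration + rng.normal(0.0, params.stride_jitter_sd, n + 2)
    T = np.clip(T, 0.5 * params.stride_duration, None)
    hs_all = np.empty(n + 2)  # HS times of strides -1..n
    hs_all[0] = t0 + _LEAD_IN * T[0]
    hs_all[1:] = hs_all[0] + np.cumsum(T[1:])
    # hs_all[1] is the first full-stride HS; index k in 0..n+1 is stride k-1
    start = t0
    end = hs_all[-1] + _LEAD_OUT * T[-1] - T[-1]  # lead-out after last bounding HS
    n_samp = int(np.floor((end - start) * params.rate)) + 1
    time = start + np.arange(n_samp) / params.rate

    # stride k-1 (k = 0 is the lead-in partial) spans [hs_all[k] - T[k], hs_all[k])
    gyro = np.zeros(n_samp)
    pressure = np.zeros(n_samp)
    for k in range(n + 2):
        h1 = hs_all[k]
        h0 = h1 - T[k]
        m = (time >= h0) & (time < h1)
        if np.any(m):
            ts, vs = _gyro_nodes(T[k], params)
            gyro[m] = _cosine_arcs(time[m] - h0, ts, vs)
        pressure += _pressure_pulses(time, h0, T[k], params)

    if params.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, params.gyro_noise_sd, n_samp)
    if params.pressure_noise_sd > 0:
        loaded = pressure != 0.0
        pressure = pressure + loaded * rng.normal(
            0.0, params.pressure_noise_sd, n_samp
        )
    if raw_voltage:
        pressure = to_divider_voltage(pressure)

    f = params.stance_fraction
    hs = hs_all[:-1]  # n + 1 bounding heel-strikes of the full strides
    stride_T = T[1 : n + 1]
    cyc_T = T[1:]  # strides 0..n (incl. trailing partial)
    cyc_h = hs_all[:-1]  # opening HS of strides 0..n
    truth = GroundTruth(
        hs=hs - start,
        ms=cyc_h + _FLAT_START * f * cyc_T - start,
        to=cyc_h + f * cyc_T - start,
        msw=np.concatenate(
            [[hs_all[0] - T[0] + (f + _MSW_FRAC * (1 - f)) * T[0]],
             cyc_h + (f + _MSW_FRAC * (1 - f)) * cyc_T]
        )
        - start,
        pressure_onset=cyc_h + params.pressure_lead - start,
        stride_duration=stride_T,
        swing_duration=(1.0 - f) * stride_T,
        stance_fraction=f,
        max_angular_velocity=params.swing_peak_amplitude,
    )
    return (
        FootRecording(
            side=side, time=time - start, gyro=gyro, pressure=pressure,
            rate=params.rate,
        ),
        truth,
    )


def synth_walk(
    params: GaitParams, preset: AsymmetryPreset | None = None
) -> WalkRecording:
    """Generate a two-foot walk; feet are half a cycle out of phase.

    The affected foot (per preset) is modified by the severity-scaled preset;
    at severity 0 the feet share parameters and differ only by noise draw.
    """
    params.validate()
    preset = preset or AsymmetryPreset(severity=0.0)
    preset.validate()
    seeds = np.random.SeedSequence(params.seed).generate_state(2) % (2**31)
    sides: dict[Side, GaitParams] = {
        "left": replace(params, seed=int(seeds[0])),
        "right": replace(params, seed=int(seeds[1])),
    }
    if preset.severity > 0:
        sides[preset.affected_side] = preset.apply(sides[preset.affected_side])
    offset = params.stride_duration / 2.0
    left, _ = synth_foot(sides["left"], side="left")
    right, _ = synth_foot(sides["right"], side="right", t0=offset)
    label = "symmetric" if preset.severity == 0 else f"asymmetric(s={preset.severity})"
    return WalkRecording(left=left, right=right, label=label)


def synth_cohort(
    n_walks: int,
    params: GaitParams | None = None,
    preset: AsymmetryPreset | None = None,
    seed: int = 0,
) -> list[WalkRecording]:
    """Generate independent walks with mild between-walk speed/amplitude variation.

    Each walk draws a common (both-feet) stride-duration and amplitude
    multiplier, emulating natural walk-to-walk variability within a subject.
    """
    if n_walks < 1:
        raise ConfigError("n_walks must be >= 1")
    params = params or GaitParams()
    rng = np.random.default_rng(seed)
    walks = []
    for _ in range(n_walks):
        dur_mult = float(rng.normal(1.0, 0.03))
        amp_mult = float(rng.normal(1.0, 0.05))
        walk_seed = int(rng.integers(0, 2**31))
        wp = replace(
            params,
            stride_duration=params.stride_duration * dur_mult,
            swing_peak_amplitude=params.swing_peak_amplitude * amp_mult,
            hs_trough_amplitude=params.hs_trough_amplitude * amp_mult,
            to_trough_amplitude=params.to_trough_amplitude * amp_mult,
            seed=walk_seed,
        )
        walks.append(synth_walk(wp, preset))
    return walks


def to_divider_voltage(
    pressure_au: np.ndarray | float, vin: float = 5.0, gain: float = 1.0
) -> np.ndarray | float:
    """Map offset-removed pressure to the raw FSR voltage-divider output.

    Two force-sensing resistors under heel and forefoot form a divider fed
    with ``vin``; with both sensors unloaded the output sits at ``vin / 2``
    (2.5 V for the 5 V supply). Output is clipped to the supply rails.
    """
    return np.clip(vin / 2.0 + gain * np.asarray(pressure_au, dtype=float), 0.0, vin)


def remove_offset(voltage: np.ndarray | float, vin: float = 5.0) -> np.ndarray | float:
    """Remove the divider's half-supply offset after acquisition."""
    return np.asarray(voltage, dtype=float) - vin / 2.0
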