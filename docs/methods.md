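# Methods

## Signal model and containers

A per-foot recording holds a uniformly sampled time axis (s), the sagittal
x-axis angular velocity of a shoe-tip gyroscope (deg/s), and one fused
pressure channel (arbitrary units). The pressure channel models two
force-sensing resistors under heel and forefoot wired as a voltage divider:
heel load pulls the output below the half-supply offset, forefoot load above
it, and with the foot off the ground the divider is pinned at the offset
(2.5 V of a 5 V supply), which is removed after acquisition so swing-phase
pressure is exactly zero. Absolute pressure calibration is deliberately out
of scope — only the waveform matters downstream, because both channels are
standardized before fusion.

CSV I/O is fixed to comma-separated, `.`-decimal, UTF-8 with columns
`time_s, gyro_dps, pressure_au`; floats are written at 17 significant digits
and parsed with pandas' round-trip parser so write→read is bit-exact.

## Event detection

Detection operates on the low-pass filtered gyro channel only. The filter is
a 4th-order Butterworth at 10 Hz applied forward-backward (`sosfiltfilt`):
the detector locates extrema and threshold crossings, so zero phase shift is
a hard requirement; family, order and cutoff are conventional choices for
100 Hz gait signals and are configurable. Idempotence of the filter holds on
band-limited signals away from the edge transients of the forward-backward
pass.

Rules, with defaults in `PipelineConfig`:

* **MSW** — argmax between a matched pair of upward/downward crossings of
  5 deg/s. Runs already in progress at the start of a recording, and runs
  that never close, are discarded.
* **MS** — first index strictly between consecutive MSW peaks with
  |gyro| ≤ 1.5 deg/s and backward difference |x[j] − x[j−1]| < 0.25 deg/s.
  A cycle with no qualifying point is dropped along with its stride.
* **HS** — argmin strictly between an MSW and its following MS.
* **TO** — argmin strictly between an MS and its following MSW.

All argmax/argmin and "first qualifying index" rules break ties to the
earliest index, making detection deterministic. Only complete cycles
(MSW < HS < MS < TO < next MSW) are retained; a stride requires two
heel-strikes from *adjacent* cycles, so a dropped cycle invalidates only the
strides it touches.

## Stride pipeline

Strides are half-open sample intervals [HS_k, HS_{k+1}); the closing HS value
is carried separately as the interpolation endpoint so consecutive strides
share no samples. Pressure strides are cut with the gyro-derived events — a
single event stream per foot. Per stride we record duration, swing duration
(TO to closing HS) and, for gyro, the peak angular velocity.

Resampling to the 0–100 % cycle grid uses PCHIP (101 points, i.e. 1 % steps):
monotone piecewise-cubic Hermite interpolation preserves endpoints and never
overshoots local extrema, which matters for waveforms with sharp troughs.
Strides are then averaged pointwise, and the *mean* stride is standardized
with the population (divide-by-N) standard deviation. Standardizing after
averaging (rather than per stride) keeps between-stride amplitude
variability in the mean before the z-transform fixes the scale; the
alternative order is a defensible choice but changes nothing for symmetric
inputs and was not adopted. Standardization of a constant signal is an
error (`DegenerateSignalError`) rather than a silent zero.

Fusion is the pointwise sum of the standardized mean gyro and pressure
strides ("superposition"): both addends have mean 0 and sd 1, so each
channel contributes equally regardless of physical units.

## DTW distance

Local cost defaults to the squared difference; the absolute difference is
available via `dtw_local_cost` (both satisfy the symmetry and identity
properties the tests rely on). The first row/column of the accumulated
matrix accumulate along their only predecessor; the distance is the raw
terminal cost with no path-length normalization and no warping window —
inputs are standardized, equal-length 101-point waveforms, so costs are
comparable across walks without either. Backtracing prefers the diagonal,
then the vertical, then the horizontal predecessor on ties; the distance is
tie-independent, the reported path is thereby deterministic. Correctness is
checked against an exhaustive enumeration of all monotone warp paths for
small problems (m·n ≤ 64), an oracle that shares no code with the
dynamic-programming implementation.

## Asymmetry metrics and statistics

The three classical indices use SI = 100·ln(left/right) of the per-foot
means (numerator side configurable): zero at symmetry, antisymmetric under a
foot swap. The proposed metric is a single DTW distance per walk between the
left and right fused mean strides — invariant under the swap and exactly
zero when the recordings are identical. Group comparisons run a two-sided
Mann–Whitney U test per metric: exact enumeration when both groups have at
most 10 untied observations (bit-reproducible p-values at the 10-walks-per-
condition study size; full separation of 10 vs 10 gives p = 2/184756 ≈
1.1·10⁻⁵), tie-corrected normal approximation otherwise, and p = 1 by
convention when the pooled sample carries no rank information at all.

## Synthetic gait generator

The generator is a signal-morphology emulator, not a biomechanical model.
Each gait cycle of the gyro channel is a chain of cosine-eased arcs through
control points: HS trough (−80 deg/s) → flat zero mid-stance plateau
(25–75 % of stance) → TO trough (−60 deg/s) → MSW peak (+250 deg/s at
mid-swing) → next HS trough. Cosine easing has zero slope at every control
point, so the chain is C¹-smooth, the plateau is exactly flat (as the MS
flatness rule requires), and the swing descends from peak to trough without
spurious near-zero flats that would fool the MS detector. Amplitudes are
plausible for a shoe-tip mount and are not calibrated to any recording.

Defaults define normal adult gait: 100 Hz, 1.1 s strides with 0.02 s jitter,
60/40 stance/swing, gyro noise 0.5 deg/s. Pressure is a negative heel lobe
(onset at HS) handing over to a positive forefoot lobe that unloads exactly
at TO; noise is added only where load is present, keeping swing samples
exactly at baseline. A `raw_voltage` option emits the un-offset divider
output for exercising the acquisition convention. Each recording carries a
partial lead-in/lead-out cycle so all `n_strides` requested strides are
recoverable; ground-truth HS/MS/TO/MSW times are returned alongside.

The hemiplegia preset scales three effects continuously with severity
s ∈ [0, 1] on the affected foot: swing fraction ×1.35 at s = 1 with the
stride period preserved (so the stride-duration index stays flat — the
clinical signature), mid-swing peak attenuated to 0.55× (limited ankle/knee
rotation), and a 60 ms heel-pulse lead ahead of the gyro HS trough (the foot
lands before the ankle has fully rotated). Walks pair two feet half a cycle
out of phase with independent noise; cohorts add per-walk common
stride-duration (σ = 3 %) and amplitude (σ = 5 %) multipliers to emulate
walk-to-walk variability within a subject.

What the generator does **not** emulate: soft-tissue and footwear artifacts,
drift and bias of real IMUs, double-support force transfer, turning or
speed changes within a walk, and between-subject morphology differences.
Passing tests therefore validate the pipeline's logic and its behavior under
the stated signal model, not clinical performance on recorded patients.

## Problem sizes and numerical choices

The test and acceptance runs use 8–55 strides per recording, cohorts of
10 walks per condition, 101-point cycle grids, a 459-stride randomized
ensemble for the detection-rate check (stride period 0.9–1.4 s, amplitude
scale 0.7–1.3, gyro noise 0.2–1.0 deg/s), 200 null replicates for the
Mann–Whitney type-I-error check, and 1000 random pairs for the DTW oracle
comparison. Detection accuracy against planted events is asserted within
±2 samples (HS/TO/MSW) and ±3 samples (MS) at low noise; the stance-phase
recovery band is ±2 percentage points around the canonical 60 %. Seeds are
fixed everywhere; `numpy.random.SeedSequence` derives per-foot and per-walk
streams so runs are bit-reproducible.

## Known limitations

* The MS rule's sample-difference threshold (0.25 deg/s per sample) is
  rate-dependent; at rates far from 100 Hz it should be rescaled.
* The detector assumes the MSW peak exceeds the 5 deg/s threshold by a wide
  margin; severely attenuated swing (beyond the preset's 0.55×) could drop
  below it.
* DTW is univariate on the fused waveform; multivariate DTW over (gyro,
  pressure) pairs, windowing, and path-length normalization are deliberate
  non-features.
* Symmetry-index sign conventions (which foot is the numerator) are
  configuration, not assertions about any particular dataset.
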