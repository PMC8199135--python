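# gaitdtw

Asymmetric gait analysis from a shoe-mounted gyroscope and a single fused
insole pressure channel, using a Dynamic Time Warping (DTW) distance between
the two feet's averaged stride waveforms.

## The problem

Hemiplegic and other pathological gaits are asymmetric: the affected leg
swings longer, rotates less, and lands differently. Classical screening
compares scalar spatiotemporal parameters (stride time, swing time, peak
angular velocity) between feet with a symmetry index, which discards the
shape of the movement and is sensitive to walking speed. `gaitdtw`
implements a whole-waveform alternative: each foot's strides are reduced to a
mean gait-cycle waveform that fuses angular velocity and plantar pressure,
and the asymmetry of a walk is the DTW distance between the left and right
waveforms — zero for perfectly symmetric gait, growing with asymmetry, and
robust to local timing differences because DTW warps the cycle axis.

The package is aimed at wearable-sensor and gait-rehabilitation researchers
who want the full pipeline (event detection → stride normalization → fusion →
DTW) plus the classical indices for comparison, without needing recorded
data: a parametric synthetic gait generator with planted ground-truth events
is included.

## Method

1. **Event detection** (rule-based, on the 4th-order zero-phase Butterworth
   low-pass filtered gyro signal, 10 Hz default cutoff): mid-swing (MSW) is
   the maximum between crossings of a 5 °/s threshold; mid-stance (MS) is the
   first point between MSW peaks inside ±1.5 °/s of zero whose backward
   difference is < 0.25 °/s; heel-strike (HS) is the minimum between MSW and
   MS; toe-off (TO) the minimum between MS and the next MSW.
2. **Stride pipeline**: HS-to-HS segments are resampled to a 0–100 % cycle
   grid (101 points) with shape-preserving PCHIP interpolation, averaged,
   standardized (Z = (X − μ)/σ), and the gyro and pressure means are fused by
   superposition (pointwise sum).
3. **DTW distance**: accumulated-cost dynamic programming
   D(i,j) = Dist(i,j) + min(D(i−1,j), D(i,j−1), D(i−1,j−1)) with squared
   local cost (absolute optional); the distance is the terminal cost D(m,n),
   unnormalized. The optimal warp path is recovered by backtracing.
4. **Asymmetry metrics**: per walk, three log-ratio symmetry indices
   SI = 100·ln(left/right) of mean stride duration, swing duration and peak
   angular velocity, plus the DTW distance between the fused left/right mean
   strides. Cohorts are compared per metric with a two-sided Mann–Whitney U
   test (exact for ≤ 10 untied observations per group).

## Worked example

```python
from gaitdtw import GaitParams, AsymmetryPreset, synth_walk, walk_metrics

walk = synth_walk(GaitParams(seed=3),
                  AsymmetryPreset(severity=1.0, affected_side="left"))
for name, value in walk_metrics(walk).as_dict().items():
    print(f"{name:28s} {value:8.2f}")
```

prints

```
stride_duration_si              -0.74
swing_duration_si               25.07
max_angular_velocity_si        -59.88
dtw_distance                     8.87
```

The stride-duration index stays near zero — a hemiplegic-like gait preserves
the stride period — while the swing-duration and peak-angular-velocity
indices are far from zero (the affected left foot swings ~28 % longer and
rotates ~45 % slower) and the DTW distance is an order of magnitude above the
~0.05–0.1 seen for symmetric walks. The same pipeline is available from the
shell:

```bash
gaitdtw simulate --out sym/  --n-walks 10 --severity 0.0 --seed 1
gaitdtw simulate --out asym/ --n-walks 10 --severity 1.0 --seed 2
gaitdtw compare --group-a sym/ --group-b asym/ --out table.json
```

which reports mean ± sd per group and the Mann–Whitney p-value for each of
the four metrics (`gaitdtw detect` and `gaitdtw analyze` cover single
recordings and single walks).

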