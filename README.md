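# swinghht

Time–frequency analysis of golf-swing motion capture with the
Hilbert–Huang transform: find *when* and *how fast* each joint moved, and
localize the unnecessary pre-impact movements (head-up, body opening) that
open the club face and slice the ball.

## Who this is for

Biomechanics and sports-science practitioners working with BVH motion
capture of golf swings (or similar short, non-stationary whole-body
movements). Fourier or wavelet decompositions of such movements need
hundreds of linear modes; empirical mode decomposition yields a handful of
physically interpretable oscillatory components, each with a well-defined
instantaneous frequency and amplitude.

## The method

Each joint carries three Euler angles θx, θy, θz (degrees, 120 Hz). Per
swing and joint:

1. **Multivariate EMD.** The three channels are decomposed jointly into
   intrinsic mode functions plus a trend, x(t) = Σᵢ IMFᵢ(t) + r(t), by
   sifting with cubic-spline envelopes over quasi-uniform projection
   directions, stopped by the Cauchy-style criterion
   SD = Σ(h₍ₖ₋₁₎ − hₖ)² / Σh₍ₖ₋₁₎² < 0.2. All channels receive the same,
   aligned set of modes.
2. **Hilbert layer.** Each mode is made analytic; its instantaneous
   amplitude A(t) = √(Re² + Im²) and frequency ω(t) = dθ/dt (phase
   derivative, reported in Hz) follow.
3. **Per-joint aggregation.** Amplitudes combine as the Euclidean norm
   over the three (orthogonal) Euler axes; frequencies average across
   axes.
4. **Impact synchronization & ensemble averaging.** All swings of one
   trajectory class (straight / slice) are aligned at the annotated impact
   frame, trimmed to the smallest shared window centered on impact, and
   averaged pointwise. Per-IMF frequency means, SDs and CV = SD/mean
   quantify whether the sample size was adequate (CV < 1).
5. **Spectra & excess report.** The Hilbert spectrum (time × frequency,
   color = amplitude, red line = impact) is built per joint and group; a
   slice group is compared against the straight group by the ratio of mean
   movement-band amplitude in the 0.25 s before impact. Joints with ratio
   above 1.5 are flagged as candidate trigger joints.

## Worked example

No real captures ship with the package; the seeded generator produces
study-shaped datasets (6 swings per trajectory class, ~1.9 s at 120 Hz,
impact near frame 137, faults planted as pre-impact 7 Hz bursts in the
fault-specific joints):

```python
from swinghht import SwingAnalysis, make_dataset

make_dataset("demo_ds", n_per_group=6, seed=1)
results = SwingAnalysis.from_dataset("demo_ds").fit()

print(results.sync_summary())
print(results.compare("straight", "slice_head_up").round(2))
```

prints (seed 1):

```
               n_swings  window_frames  impact_index  window_s
label
straight              6            215           130      1.79
slice_head_up         6            218           130      1.82
slice_opening         6            216           130      1.80

           baseline_amp_deg  candidate_amp_deg  ratio  flagged
joint
Neck                   9.06              17.50   1.93     True
LeftArm                8.76               8.74   1.00    False
LeftUpLeg              9.26               9.62   1.04    False
LeftLeg                8.88               9.26   1.04    False
```

Each group's six swings were aligned at impact and trimmed to their
smallest shared window (here 215/218/216 frames). In the pre-impact
quarter-second the head-up group's Neck carries twice the movement-band
amplitude of the straight group — exactly the planted fault — while the
lead-side arm and leg joints stay at ratio ≈ 1 and are not flagged.
`results.frequency_stats(label, joint)` gives the per-IMF frequency
mean/SD/CV table, `results.plot_spectrum(label, joint)` the impact-marked
Hilbert spectrum, and `results.summary()` a combined text report.

The same pipeline is scriptable from a shell:

```
swinghht synth --out demo_ds --n 6 --seed 1
swinghht analyze --bvh-dir demo_ds --out report/
swinghht compare --bvh-dir demo_ds --baseline straight --candidate slice_head_up
```

`analyze` writes per-joint spectra (CSV + PNG), the frequency-statistics
tables, the synchronization summary, the pre-impact excess reports and a
reproducibility manifest under `report/`.

## Layout

| module                | contents                                             |
| --------------------- | ---------------------------------------------------- |
| `swinghht.bvh`        | BVH read/write, joint selection, swing metadata      |
| `swinghht.emd`        | univariate sifting, envelopes, SD criterion, IMF check |
| `swinghht.memd`       | direction sets, multivariate envelopes, aligned modes |
| `swinghht.hht`        | analytic signal, instantaneous A(t)/ω(t), spectra    |
| `swinghht.pipeline`   | aggregation, synchronization, averaging, stats, comparison |
| `swinghht.model`      | `SwingAnalysis` / `SwingAnalysisResults` front end   |
| `swinghht.synthetic`  | seeded swing generator and dataset writer            |
| `swinghht.cli`        | `swinghht synth` / `analyze` / `compare` / `stats`   |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
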