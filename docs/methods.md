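# Methods

## Signal model

A captured joint angle is treated as a finite sum of intrinsic mode
functions (IMFs) plus a residual trend,

    x(t) = Σᵢ IMFᵢ(t) + r(t),

where an IMF is a locally zero-mean oscillation: its extrema and
zero-crossing counts differ by at most one, and the mean of its upper and
lower extrema envelopes is approximately zero. No basis is imposed; the
modes are found by sifting, which makes the decomposition appropriate for
short, non-stationary, non-linear movement data where Fourier or wavelet
expansions smear energy across hundreds of terms. The cost of this
adaptivity is that EMD is an algorithmic definition, not a projection:
results depend on the documented numerical choices below, all of which are
deterministic.

## Sifting (univariate)

* Extrema: strict interior local extrema; a flat plateau contributes the
  floor of its midpoint index. A series with fewer than two maxima or two
  minima is *monotone-like* and terminates extraction (it becomes the
  trend).
* Envelopes: natural cubic splines through the maxima (upper) and minima
  (lower). Before fitting, the `boundary_mirror_count = 2` nearest extrema
  are reflected about each end; without mirroring, natural splines swing
  wildly at the boundaries and corrupt the first/last fraction of every
  mode.
* Iteration: h ← h − (upper + lower)/2, stopped when the Cauchy-style
  ratio SD = Σ(h₍ₖ₋₁₎ − hₖ)²/Σh₍ₖ₋₁₎² drops below `sd_threshold = 0.2`
  (the range 0.2–0.3 is standard for this criterion) *and* the candidate
  passes the IMF definition check. A hard cap `max_sift_iters = 200`
  guards non-convergence; typical modes stop within ~10 sifts, and the
  high cap exists only for rare riding waves that need long sifting to
  gain their missing zero crossings.
* IMF check: |#extrema − #zero-crossings| ≤ 1, and RMS(mean envelope) ≤
  0.1 × RMS(signal). The strict "envelope mean is zero" condition is never
  met exactly in finite samples; 0.1 is loose enough to accept genuine
  modes and tight enough to reject trends and offset signals.
* Zero crossings: sign changes between consecutive samples after dropping
  exact zeros, so a run of zeros between opposite signs counts once.
* Completeness x = Σ IMFs + r holds to machine precision by construction
  (each mode is subtracted exactly).
* `max_imfs = 12` caps extraction; a 64–512-sample signal yields ≈
  log₂T + 2 modes at most, so the cap never binds on swing-length data.

## Multivariate decomposition

The three Euler channels of a joint are decomposed *jointly* so every
channel receives the same number of aligned modes — the property that later
lets per-mode amplitudes be combined across channels.

* Directions: a Hammersley low-discrepancy set on the unit sphere.
  For C = 2, evenly spaced angles; for C = 3 (the per-joint case) the
  area-preserving cylindrical map z = 2u − 1, φ = 2πv of the 2-D
  Hammersley set, whose nearest-neighbour spacing is far more uniform than
  generic sphere maps; for C > 3 the inverse-Gaussian-CDF map of the
  hypercube set. `n_directions` defaults to max(64, 8·C) — comfortably
  above the 2·C minimum, and the spectra proved stable when the input
  joint set (and hence C) changed.
* Local mean: for each direction, the signal is projected onto the
  direction; the full C-dimensional signal is spline-interpolated at the
  projection's maxima and at its minima (mirrored boundaries as above);
  the two envelopes are averaged per direction and then across directions.
  Directions whose projection lacks two maxima or two minima are skipped;
  when every direction is skipped the residual is the trend.
* Stopping: the same SD ratio, computed over the stacked channels
  (numerator and denominator summed over channels and time), shared with
  the univariate threshold. Mode alignment across channels is structural:
  modes are extracted as (T, C) blocks.
* Each swing is decomposed separately; swings are only ever combined at
  the spectral-averaging stage.
* Two stacking policies: `per_joint` (default) decomposes each joint's
  three channels in one call; `pooled` stacks all selected joints into a
  single call, reproducing the sensitivity-analysis variant in which the
  joint set shapes the common filter bank. Both are exposed because both
  are meaningful; the default keeps joints independent.

## Hilbert layer

* The analytic extension uses the standard FFT realisation of the
  principal-value convolution (scipy's `hilbert`).
* Amplitude A(t) = √(Re² + Im²); frequency is the derivative of the
  unwrapped four-quadrant phase, by central differences (one-sided at the
  ends), × fs/2π to give Hz. Central differences are the lowest-bias
  simple estimator; the first/last 5 % of samples are flagged as
  boundary-contaminated and excluded from interior assertions.
* Where the amplitude vanishes the phase is undefined; frequency is
  reported as NaN (missing), never fabricated.
* Negative instantaneous frequencies — numerical artifacts near amplitude
  nulls — are retained in raw output and *counted* (`n_negative_freq`);
  spectra simply do not deposit them below bin 0. Silent clipping would
  hide decomposition failures. For clean oscillatory modes ≥95 % of
  interior samples have ω ≥ 0; noise-floor modes near Nyquist and near-DC
  posture modes legitimately wobble more.
* Spectra: linear frequency bins, default 0–40 Hz at 0.5 Hz (swing-mode
  frequencies span ~1–35 Hz at 120 Hz sampling); each sample deposits its
  amplitude at (time, bin(ω)); deposited mass is conserved exactly, and
  out-of-range/undefined samples are counted per side.

## Swing pipeline

* Per-joint aggregation: amplitude = √(Ax² + Ay² + Az²) (the Euler axes
  are orthogonal), frequency = mean over the channels defined at t (NaN
  channels are skipped; the value is missing only if all three are).
* Synchronization: pre = min over swings of the impact index, post = min
  of (length − 1 − impact); every swing is trimmed to
  [impact − pre, impact + post], so all members share length pre+post+1
  with the impact at index pre. The impact frame itself is never
  discarded.
* Ensemble averaging: pointwise arithmetic mean of frequency and of
  amplitude across members, per mode; mode counts are reconciled by index
  from the fastest mode down to the shared minimum — index alignment is
  the natural pairing given the filter-bank ordering of modes.
* Frequency statistics: per mode, mean and SD pooled over time × members
  (their purpose is cross-swing variability, so pooling over both is the
  informative choice), CV = SD/mean, NaN when the mean is zero. Printed
  tables use round-half-up at 2 decimals, matching how such tables are
  conventionally typeset (1.925 → 1.93).
* Group comparison: per joint, the ratio of mean *movement-band*
  aggregated amplitude in the `pre_impact_window_s = 0.25` s before impact
  (candidate/baseline, on the averaged spectra); ratio > 1.5 flags the
  joint. The movement band (2–35 Hz) excludes the posture-drift modes:
  the slow trend peaks mid-swing, and whatever fraction of it leaks into
  the last modes varies between decompositions, which would otherwise
  dominate the statistic with noise unrelated to movement. Groups are
  trimmed independently (their windows legitimately differ by a few
  frames); the comparison only requires both windows to cover the
  pre-impact interval. The report is descriptive — ratios, no hypothesis
  test — because the question is localization, not significance.

## Synthetic data

The generator emulates the structure of real swing captures so every
pipeline stage is testable end to end:

* ~1.9 s at 120 Hz; swing lengths jitter in 227–231 frames and impact
  frames in 130–144, matching the bundled reference capture log.
* Per joint: a smooth posture trend (25° excursion, address → top →
  follow-through), a 2 Hz postural sway (1.5°), and impact-centered
  amplitude-modulated bursts at 3, 8 and 24 Hz (5°, 3°, 6°; widths 0.5,
  0.3, 0.1 s). A clean swing is pendulum-like — oscillatory energy
  concentrates at the hit, so the quarter-second before impact is
  comparatively quiet, which is precisely why an extra pre-impact burst is
  diagnostic.
* Channel weights are a random direction across (θx, θy, θz) with fixed
  overall magnitude (±7 % jitter): swings differ in axis mix and phase but
  carry comparable per-joint energy, as real repeated swings by one golfer
  do.
* Faults: an additive 7 Hz burst, 0.15 s wide, peaking 0.15 s before
  impact — a movement in the 5–10 Hz band of the fault-relevant modes.
  `head_up` plants it in the Neck; `opening` in LeftUpLeg + LeftLeg.
  Default amplitude 12° per channel (aggregated peak ≈ 16°), clearly above
  the >10° scale of movements these spectra resolve. Gaussian sensor noise
  0.3° (well above the ~0.02° resolution of inertial suits, to be
  conservative).
* Deterministic under a fixed seed; the exact per-component series are
  returned with every rendered clip.

What the generator does **not** emulate: kinematic coupling between joints
(each joint's channels are generated independently), gimbal-lock artifacts,
drift/soft-tissue sensor error, or golfer-to-golfer form differences.
Passing the planted-fault tests therefore shows the pipeline recovers
localized pre-impact bursts of the documented size under realistic
amplitude/noise conditions — not that it handles every pathology of real
inertial capture.

## Problem sizes used in tests and the acceptance script

Structural suites run on 64–512-sample signals (50–100 random seeds); the
filter-bank property uses 3-channel white noise, T = 512, 50 replicates in
the test suite and 20 in the acceptance script; fault recovery uses
study-sized datasets (6 swings × 3 groups × 4 joints, ~230 frames), 10
seeded replicates in the test suite and 5 in the acceptance script, with
the null (fault amplitude 0) checked on a smaller number of seeds. These
sizes give stable statistics for each property while keeping a full run in
the minutes range on one CPU.

## Known limitations

* EMD has no uniqueness theory; modes are defined by the algorithm.
  Mode *count* is data-dependent (swing data typically yields 5–8 modes
  plus trend) and is deliberately not forced.
* Boundary effects: despite extrema mirroring and edge guards, the
  first/last few percent of every mode and spectrum are less reliable.
* Instantaneous frequency is meaningful only for well-formed oscillatory
  modes; for noise-floor modes near Nyquist it fluctuates and can dip
  negative (counted, not hidden).
* Impact frames are metadata inputs; the package does not detect impacts
  from the signal.
* World-space kinematics (forward kinematics, positions) and gimbal-lock
  repair are out of scope; input BVH is assumed normalized upstream.
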