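# Methods

## Reporter model and activity inference

The pipeline treats a fluorescent transcriptional reporter as a two-stage
linear system: promoter activity `x(t)` (AU/hr²) drives reporter mRNA
`m(t)` with first-order decay (`dm/dt = x − m·ln2/t_half`), and the stable
protein accumulates as `dI/dt = c1·m`. Protein maturation and degradation
are absorbed into `c1` and assumed constant; photobleaching is neglected
(at 6-min sampling with the settings emulated here it is not a significant
factor). The inversion `c·x = I″ + I′·ln2/t_half` therefore recovers the
activity only up to the lumped constant `c` and with the time lag inherent
in transcription→fluorescence; comparisons are made within datasets, never
across them.

Derivatives are taken by second-order central differences on the uniform
sampling grid of the longest unmasked run of a processed track (at least 5
consecutive points, matching the rule that only features spanning ≥0.5 hr
are interpreted). The two run endpoints, where only one-sided stencils
exist, are excluded from the returned trace. No regularization beyond the
moving-average smoothing is applied, a deliberate trade of noise
suppression against temporal resolution.

Recovery error concentrates at discontinuities of the transcription
program, where the central second difference straddles the jump. With
continuous-time onsets the jumps generically fall inside sampling
intervals and the pooled relative RMSE of a boxcar recovery is ~3.5%
(interior points, noise-free, half-lives 1–5 hr); in the degenerate case of
a jump aligned exactly with a sample the two straddling points alone raise
it to ~10%. Step-program cohorts from the generator recover at ~4.5%
pooled.

## Half-life from heat-shock pulses

After a transcription pulse ends, `I_max − I(t)` decays as `e^(−kt)` with
`k = ln2/t_half`, so `−ln(1 − I/I_max)` is linear in `t`. Per cell, `I_max`
is the mean of the last 10% of time points; the line is fitted from the
pulse end up to the **first** time `I/I_max` reaches 0.95, and everything
later is discarded wholesale — near the plateau the transform amplifies
small fluctuations, and re-admitting individual late points that dip back
under the cut by noise flattens the line and biases `t_half` upward by
20–30% at 2% noise. Per-cell slopes are pooled by mean.

The default synthetic heat-shock acquisition runs to `pulse_end +
10·t_half` so the late-time plateau estimate is unbiased to <0.2%; with
shorter movies (8 half-lives) the plateau underestimate alone inflates the
slope by ~2.6%. With 20 cells and 2% multiplicative noise the fit recovers
a 3 hr half-life within ~2%.

## Preprocessing chain

Fixed order: saturation masking → bleed-through subtraction → smoothing →
trimming.

* **Saturation**: records with a saturated-pixel fraction strictly above
  0.05 are masked (kept in tables, excluded from every statistic).
* **Bleed-through**: a single ratio ρ per dataset. The estimator iterates:
  select records whose donor-corrected recipient signal lies in the lowest
  quartile (recipient expected basal), fit a robust Theil–Sen line of
  recipient on donor, repeat with the updated ρ. The intercept absorbs the
  autofluorescence floor (a through-origin ratio would be biased upward by
  floor/donor). Identifiability caveat: ρ is only estimable when the donor
  has dynamic range among recipient-basal records. When the fate reporter
  is expressed only in cells that also respond (as with an olig2-type
  reporter), intrinsic recipient signal rides on the donor and the
  estimate is an upper bound; the pipeline runs with it regardless, and
  `simulate.bleedthrough_calibration_config()` provides an identifiable
  design on which the estimator recovers ρ = 0.10 ± 0.02.
* **Smoothing**: centered moving average (even windows lean one point to
  the past), truncated at track edges — no reflection or zero padding, so
  no signal is fabricated at track ends. Masked points shrink the window
  rather than being interpolated. Default window 6 points (36 min), one
  iteration; the metric comparison is re-run over windows {3, 6, 9} and
  1–3 iterations to check robustness.
* **Trimming**: analysis restricted to 10–15 hpf, the interval with dense
  track coverage between first detectable response and fate specification;
  tracks left with <2 records are dropped with a warning.

Negative intensities after bleed-through subtraction are clipped to zero
(linearity of smoothing holds away from the clip regime).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
microscopy images. Transcription programs are continuous-time piecewise
constant (step, boxcar, adaptive pulse; ramps discretized at 0.02 hr), with
per-cell amplitude scatter and normally jittered onsets truncated to the
acquisition window. Integration uses the exact exponential propagator of
the linear ODE pair with steps split at program breakpoints, so solver
error is zero for the shapes used and forward–inverse tests probe only the
differencing scheme.

The measurement model applies, in order: bleed-through mixing (default
fate→response at ρ = 0.10), an additive autofluorescence floor, saturation
(intensities clipped at a ceiling; the emitted saturated-pixel fraction is
a logistic in intensity/ceiling, ~0.05 at 85% of the ceiling), then noise.

Multiplicative noise keeps a total per-point CV of 2% — consistent with
<5% re-tracking variation over 6-point windows — but its decomposition by
time scale matters enormously, because a second-difference estimator at
6-min sampling amplifies frame-to-frame noise by `2/(w·dt²)` (≈33× of the
intensity scale at window 6). The default splits the 2% into a per-track
gain error of 1.9% (segmentation-sphere placement, constant in time,
invisible to derivatives), a slow drift of 0.5% (AR(1), 3 hr correlation
time; sphere-following errors persist across frames), and frame jitter of
0.05% (photon shot noise averaged over hundreds of voxels), plus an
additive detector floor of 0.002 AU. Purely white noise at the full 2%
would bury the inferred activity of every cell far below the 0.05 AU/hr²
"on" threshold — a regime in which threshold-based response metrics could
not work at all — so the white component must be small for the measured
data to support the published style of analysis. This is the main respect
in which passing tests bound, rather than demonstrate, behaviour on real
data: real segmentation noise with a large fast component would degrade
activity inference more than the presets do.

Positions: LMDV (µm from the midline) fluctuates as an
Ornstein–Uhlenbeck process around a fate-band centre (MFP 2, LFP 8, pMN
18, dorsal 40 µm); AP combines a uniform per-cell station with a
fate-independent drift, so AP can serve as a negative control for the
fate-prediction statistic.

Two presets define the study conditions. *Anterior-like* (30 cells per
fate): sustained step programs with separated amplitudes (LFP 1.0, pMN
0.45, dorsal 0.01 AU/hr², CV 10–30%) and tight onsets (LFP 10.6 ± 0.25,
pMN 12.0 ± 0.25 hpf) — every response metric separates fates. 
*Posterior-like* (40 cells per fate): boxcar programs with overlapping
amplitudes (LFP 1.0 ± 8%, pMN 0.70 ± 10%), late variable onsets
(11.2/11.5 ± 1.2 hpf) and broadly variable durations (3.2 ± 1.5 hr for
both) — duration-weighted metrics (response time, window average) lose
discriminative power while the transient maximum, which reads amplitude
alone, retains most of it. Preset parameters were fixed once from pilot
forward runs to embody these two regimes and are not fitted to any real
dataset.

## Clustering, alignment, metrics, flag

* **Clustering**: tracks are truncated to time points observed in >80% of
  traces, then tracks observed at >80% of the remaining points are kept;
  surviving gaps are filled by linear interpolation (flat at the ends).
  K-means (scikit-learn, 10 restarts, seeded after canonical sorting by
  cell id, so input order is irrelevant) over k = 5…25; the elbow is the k
  with the largest positive second difference of the WCSS curve, and a
  fixed k can be forced. Raw (post-processing) intensity vectors are used
  by default, with a standardize switch.
* **Onset and alignment**: onset is the first point of a run of ≥3
  consecutive samples (18 min) with normalized activity above 0.025;
  normalization is by the dataset-wide activity maximum (per-dataset, not
  per-cell, so amplitude information survives). Traces are re-aligned by
  subtracting the onset; cross-cell SD is compared at matched coverage
  (time points held by ≥80% of traces, SD divisor n−1 throughout).
* **Response metrics** over 10–15 hpf: window maximum, window mean, and
  response time = (count of points with `x` > 0.05 AU/hr²) × sampling
  interval — disjoint supra-threshold runs all count. The 0.05 threshold
  applies to raw (un-normalized) activity and is configurable.
* **Position metrics**: LMDV/AP at 11.5 and 14.5 hpf (nearest sample
  within 0.25 hr) and speeds over 2-hr windows centered there; speed is
  3D path length over the window divided by its duration, with the
  net-displacement variant reported alongside.
* **French flag**: cells ranked by a metric, k−1 ordered thresholds placed
  by an exact dynamic program maximizing the number of cells whose fate
  matches their band (equivalent to exhaustive enumeration of cut
  placements, verified against it); ties broken toward the most balanced
  band sizes for determinism. Accuracy is invariant under monotone
  transforms of the metric and can never fall below the majority-class
  fraction (the one-band classifier is in the search space). Adjacent-pair
  accuracies are reported alongside the 3-fate headline number, and a
  label-permutation baseline (default 1000 shuffles, seeded) gives the
  chance level.

## Rule-based fate assignment

For synthetic cohorts only (real labels come from curation and are never
overwritten unless forced): at 16 hpf, |LMDV| ≤ 4.5 µm → MFP, ≤ 12 µm →
LFP; otherwise fate-reporter-positive (>3 AU) → pMN; otherwise beyond 40%
of the 60 µm ventral-dorsal extent → dorsal; anything else, or a track not
covering 16 hpf within 0.25 hr, → unknown. On zero-noise generator output
this recovers ≥95% of ground-truth labels.

## Numerical conventions and limitations

Time is float hours (hpf) throughout; sampling interval 6 min. SDs use
divisor n−1. Metric ranking sorts ties stably by input order, so tied
metric values can be split by a threshold. The inversion is undefined on
non-uniform grids (an error asks for resampling rather than silently
differencing). Known limitations: no cell growth or shape effects on
intensity, no division/lineage branching, no spatially explicit gradient,
no cross-correlation of the response and fate channels on a common real
time axis (the reporter lags differ), and the bleed-through
identifiability caveat above.
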