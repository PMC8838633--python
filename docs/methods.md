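# Methods

This note documents the generative model, the extraction chain, the
statistical procedures, and the design choices that were genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort model

Participants carry sex-stratified anatomy and physiology sampled from
independent truncated normal distributions (truncated at ±3 SD and at zero),
with means/SDs for supine jugular cross-sectional area (CSA), baseline
jugular venous attenuation (JVA), sternocleidomastoid thickness, and depth
to the IJV taken from published characteristics of healthy young adults
(women ~0.60±0.18 cm², 0.51±0.07 a.u., 0.81±0.14 cm, 1.17±0.12 cm; men
~0.44±0.25 cm², 0.61±0.09 a.u., 1.13±0.23 cm, 1.51±0.21 cm). Truncation
shifts the analytic mean by at most ~0.09 SD (male CSA); the sampler tests
compare against the truncated-normal analytic means. Between-field
covariance is not modelled — nothing reliable is published to parameterize
it. Relative hemoglobin (`hb_scale`) is 1.00±0.07 in women and 1.15±0.08 in
men, encoding the well-established ~15% sex difference.

**Venous attenuation gain.** Each participant has an explicit gain
(a.u. per cm² of CSA) because the published 4–5× sex difference in
attenuation-per-distension slope is not derivable from hemoglobin and depth
alone. Gains are lognormal, anchored at the published sex medians (men 0.23,
women 0.05 a.u./cm² under LBNP). The lognormal σ (0.70 men / 0.69 women) is
*narrower* than the published fitted-slope IQRs imply directly: printed
slopes estimated from 3–4 noisy points carry estimation noise on top of the
true between-person spread, so σ was chosen by deconvolution — simulating
the full pipeline and matching the IQR ratio of *fitted* slopes (3.1 men,
2.7 women) to the printed ones.

**Fluid-shift responses.** HDT distends the vein linearly with angle,
reaching a per-participant increment `hdt_delta` ~ TruncN(0.17, 0.11,
min 0.01) cm² at −6°; the mean sits at the low end of the 0.15–0.23 cm²
range reported for comparable tilts, and the spread deliberately admits
near-non-responders (studies of this design observe a few participants with
<0.15 cm² total change). LBNP shrinks the vein linearly with suction toward
a collapse floor of 0.05 cm² (halved for very small baselines), removing a
per-participant fraction `lbnp_max_reduction` ~ TruncN(0.70, 0.10, [0.30,
0.95]) of the baseline-minus-floor area at −40 mmHg. Heart rate (60–80 bpm)
and respiratory rate (12–16 /min) are uniform; neither is published for
this design.

**Schedules.** Each participant completes both condition blocks, block
order randomized per participant (fair coin), levels within a block in the
fixed printed sequence. Two emulated exclusions (default on) reproduce the
analysed-n structure: one woman removed entirely, one man's LBNP block
removed.

**Randomness.** One master seed; every sub-stream derives from
`numpy.random.SeedSequence` spawn keys `(seed, participant, trial, stage)`,
so any trial is reproducible in isolation, and all derived integer seeds
stay below 2³¹.

## Cardiac waveforms

A shared beat clock (cycle-length jitter 2%, R-spike at phase 0) drives
both signals. The arterial PPG peaks at phase 0.30 with a dicrotic bump at
0.55; the jugular venous volume waveform has a c-wave bump just after the
R-spike (0.08), an x-descent trough coinciding with the systolic PPG peak
(0.33), and a v-wave in diastole (0.72). The x-descent/systole overlap makes
venous attenuation anticorrelate with the PPG (r ≈ −0.9 on clean signals) —
the localization cue. The frame after each R-spike at 23 fps lands on the
rising c-wave, matching the ultrasound frame-selection convention.

## Optics

Reflection-mode modified Beer–Lambert model on a 64×64 grid at 0.05 cm/px
(row 0 superior; "inferior to the midline" means rows strictly greater than
`midline_row`):

    A(x,y,t) = μ_blood · hb · L_blood(x,y; CSA(t)) · D(depth)
               + 2 μ_myo · scm + background_μ
    I(x,y,t) = I₀ · 10^(−A) + shot + read noise

`L_blood` is the two-pass chord through a cylindrical vessel segment (1 cm
long, axis horizontal, centered and aligned to the 4×4 down-sampling grid);
summed over rows this is exactly `2·CSA/pitch` per column, so the
window-mean attenuation is linear in CSA. `D(d) = exp(−d/δ)` with δ = 1 cm
is the simplest monotone-decreasing depth kernel; no optical constants are
published for this system, so effective values are used: μ_myo = 0.03 /cm,
background 0.417 a.u., chosen analytically so the sex-mean baseline JVA of
the analytic forward model lands at 0.51 (women) and 0.61 (men) given the
median gains. `μ_blood` is set per participant as
`jva_gain / (D(1.3 cm) · dL̄/dCSA)`, i.e. the sampled gain holds exactly at
reference depth and hemoglobin, and hemoglobin/depth then modulate the
realized slope multiplicatively — the two confounds the model is built to
expose. The calibration patch (top-left, known reflectance 0.95) renders at
`I₀·R_ref` exactly; an arterial band between midline and vessel adds a small
attenuation term in phase with the PPG. Noise is shot-like
(variance ∝ intensity) plus Gaussian read noise, both small and configurable.

## Extraction chain

Fixed order: 4×4 mean down-sampling → reflectance calibration
`A = −log10(I/Î₀)` with `Î₀` = per-frame mean patch intensity / R_ref →
per-pixel scalar local-level Kalman filter (process and measurement
variances default equal, steady-state gain ≈ 0.62: passes the cardiac band
at video rates, roughly halves white-noise variance; the published chain
cites a hemodynamic Kalman filter whose internals live in prior work — this
filter is a documented stand-in) → Pearson correlation of each pixel's
attenuation series against the PPG (band-passed to 0.7–3 Hz to reduce
respiratory leakage) → threshold r < −0.3 (unpublished; configurable and
swept in tests), restrict to rows strictly inferior to the midline,
8-connected components, keep the largest (ties break to the smallest
row-major coordinate), trim along the vessel axis to ceil(1 cm / ds-pitch)
pixels about the centroid → JVA series = ROI-mean attenuation, outcome =
peak over the acquisition (no smoothing before the peak by default; a
window option exists rather than guessing an unpublished convention).

The pipeline localizes the ROI on the level-0 acquisition of each
(participant, condition) block and reuses it across the block, emulating
extraction from the same ~1 cm vessel segment. This also makes the
noise-free peak JVA exactly monotone across levels; per-trial
re-localization can break strict monotonicity at down-sampling row
quantization boundaries when the ROI grows by a row while CSA grows a few
percent.

## Simulated ultrasound

A 5-s cine loop at 23 fps of ground-truth CSA(t); the frame at
`floor(spike·fps)+1` after each R-spike (~the c-wave); measurement = maximum
over the selected frames of truth plus Gaussian operator noise (SD
0.02 cm², truncated positive) — ellipse fitting on speckle is out of scope,
so operator/ellipse variability is collapsed into this one term.

## Two forward paths

`run_experiment` renders video for every trial (imaging-faithful);
`simulate_trial_table` evaluates the same model analytically:
`JVA = background + 2 μ_myo·scm + g·(CSA·(1+peak modulation) + ε_vol) + ε_sensor`,
where `g` is the realized gain and `ε_vol` (SD 0.06 cm², CSA-equivalent) is
venous-volume fluctuation between the non-simultaneous optical and
ultrasound snapshots. Scaling the residual by the gain matters: a flat
additive JVA noise would leave high-gain participants reliable at
arbitrarily small ΔCSA, which contradicts the observed collapse of
individual-fit reliability below ΔCSA ≈ 0.15 cm²; published within-person r
medians (0.70–0.91) imply residual noise roughly proportional to gain. The
rendered and analytic paths agree to within an ROI-geometry factor near one
(the rendered ROI-mean slope depends mildly on how many down-sampled rows
the localized region spans).

Monte-Carlo statistics (100 cohorts) use the analytic path; rendered checks
use 10-s acquisitions at 30 fps on 64×64 scenes — sizes chosen so the whole
battery runs in about a minute on one CPU. A full-scale run (19
participants × 7 levels, 30 s at 60 fps) is `ExperimentConfig()` defaults
and completes in a few minutes.

## Statistics

- **Repeated-measures correlation**: ANCOVA with participant intercepts and
  a common slope, fit by least squares;
  `r_rm = sign(b)·sqrt(SS_x/(SS_x+SS_err))`, df = N_obs − N_participants − 1,
  p from the F test of the covariate, CI by Fisher z with that df.
  Participants with a constant covariate are excluded with a warning.
  Verified to 1e-10 against an independent within-participant-centering
  decomposition and against `pingouin.rm_corr`.
- **Mixed models**: `response ~ level × sex + (1|participant)` by REML
  (statsmodels MixedLM; singular lbfgs fits fall back to powell/cg). Level
  is categorical with sum coding and sex a ±0.5 contrast, so main effects
  average over the other factor. Wald F tests use between-within
  denominator df (sex: N−2; level and interaction: (N−2)(k−1)) — the
  numerical backend provides no Satterthwaite approximation; the df method
  is stamped in the result. Estimated marginal means come from the fitted
  design (covariate at its mean); per-level sex contrasts are adjusted via
  the studentized range over the family of all 2k sex×level cell means.
  A variant adds the level-0 HDT (supine) CSA as `baseline_csa` covariate
  for both condition models.
- **Individual fits**: OLS of JVA on CSA per (participant, condition),
  ≥3 points and non-constant covariate required; negative slopes are
  retained. Summaries are medians and IQRs with linear-interpolation
  (type-7) quantiles — no quantile convention is published.
- **Slope comparison**: two-sided Wilcoxon rank-sum via Mann–Whitney U;
  exact enumeration when the combined sample is ≤20 and tie-free, otherwise
  the tie-corrected normal approximation.
- **Reliability stratification**: IQR of individual r pooled over
  conditions and sexes, split at ΔCSA = 0.15 cm²; empty strata are flagged,
  not fatal.
- **Anthropometric correlations**: pooled Pearson r (t-distribution p) of
  baseline JVA against muscle thickness and vessel depth.

## What the generator does and does not emulate

It reproduces the *structure* of the measurement problem: sex-specific
anatomy driving a sex-specific optical gain, anti-phase venous/arterial
pulsatility, calibration against a known reflectance, down-sampling noise
economics, non-simultaneous optical and ultrasound snapshots, and
participant-level response heterogeneity. It does not model photon
transport (no Monte-Carlo scattering, no melanin/skin-tone axis, no
cross-polarization), motion or repositioning error between conditions,
left-right vessel asymmetry (both stages read the same ground-truth
vessel), speckle or operator interaction in ultrasound, or safety-driven
early termination. Passing tests therefore demonstrate the correctness and
statistical behaviour of the *pipeline* under a faithful structural model —
not the optical realism of any specific tissue.

## Numerical notes and limitations

- Attenuation is computed in float64; the render→calibrate round trip is
  exact to machine precision with noise off, and the 1e-6 tolerance used in
  tests is generous.
- The rendered JVA-vs-CSA relation carries tiny nonlinearity from row
  discretization of the chord integral and from log-of-block-mean (Jensen)
  averaging; noise-free within-participant correlations are ~0.9999 rather
  than exactly 1 (the analytic path is exactly linear).
- Non-positive intensities (possible only with noise) are masked out of the
  calibrated stack and excluded from correlation maps.
- With all pixels below the anticorrelation threshold inferior to the
  midline, localization returns an explicit no-ROI signal and the trial is
  dropped, mirroring excluded acquisitions.
- The Tukey family (all sex×level cells) is a deliberate choice; adjusting
  only within each level with two means would reduce to no adjustment.
- Lognormal gains make the cohort-mean baseline JVA exceed the value implied
  by median gains (lognormal mean > median), so a sampled cohort's mean
  male-female baseline JVA contrast lands a few points above the ~19.6%
  implied by the configured population means.
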