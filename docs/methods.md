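# Methods

This note documents the models, parameters, and numerical choices of
the package, and what the synthetic-data experiments do and do not
establish.

## Task model

A session is eight 40-s blocks, two per condition (fixation, 0-back,
1-back, 2-back), in the fixed order 0-back, 2-back, 1-back, fixation /
2-back, 1-back, fixation, 0-back. Each block is preceded by a 6-s
instruction period and holds 16 trials at 2.5-s spacing (0.5 s letter +
2.0 s fixation cross). Active blocks contain exactly four targets
(25%). Letters come from {B, C, D, G, P, T, W}; in n-back conditions a
target letter equals the letter n steps earlier and non-targets never
do; the 0-back target is the prespecified "W"; fixation blocks show
"X". Target positions are uniform over the positions with n available
predecessors. The session clock starts at the first instruction onset;
the first trial of a block starts at the block onset.

Scoring: a press counts for a trial iff it falls in [onset,
onset + 1.5 s) — stimulus onset until 1 s after stimulus offset. We
follow this single window throughout; whether the original acquisition
also recorded presses in the last 0.5 s of that span is ambiguous, but
the scoring definition governs. RT = press − onset for hits and false
alarms. Accuracy = (hits + correct rejections) / trials per condition;
a condition without hits has its mean RT flagged missing, never zero.
Presses during instructions or fixation blocks are ignored.

## Pupil preprocessing

Order is fixed: blink interpolation → 200-ms centered sliding-mean
smoothing → whole-recording z-transform. The derivative ("pupil
change") and all downsampling act on the z-scored trace.

* Interpolation is linear between the last sample of the saccade
  preceding blink onset and the first sample of the saccade following
  blink offset; missing anchors fall back to the nearest valid sample
  (logged), and blinks at the recording edge are filled with the
  nearest value. The interpolation mask *is* the missing-data measure:
  per-block missing fraction equals interpolated fraction.
* The smoothing window is centered (round(0.2 s × 250 Hz) = 50
  samples, truncated at edges). Centered, because a causal window
  would phase-lag every peak latency.
* The z-transform uses the population SD over the full recording; the
  normalization exists to remove between-subject scale, so no
  per-block variant is used.
* QC: a subject fails if any block has > 20% interpolated samples, or
  > 20% of samples outside a gaze window of 3.3 reference SDs
  (defaults sd_x = 105.34, sd_y = 91.40 screen units, i.e. half-widths
  347.622 and 301.62) around the subject's median gaze. The reference
  SDs are cohort-level constants by default; `recompute_sds=True`
  estimates them from the recording for synthetic cohorts.
* Pupil change is the first difference, timestamped at the latter
  sample, in z per sample by default (a flag rescales to z/s).
  Downsampling takes non-overlapping bin means on the session clock
  (bins of 1/rate s, stamped at bin start); the target rate must
  divide the sample rate.
* Trial features: baseline = mean over [onset, onset + 0.5 s); peak =
  max over the search window [onset + 1.0, onset + 2.5 s) (after the
  stimulus and the light reflex — implemented as a fixed window, not a
  per-trial adaptive bound); peak amplitude = peak − baseline. The
  trial mean for the RT correlation uses the 10-Hz-downsampled trace
  over the full 2.5 s.

## Statistics

One-way within-subject ANOVA with the classical subject/condition/error
decomposition. Greenhouse–Geisser epsilon comes from the orthonormal-
contrast covariance; Mauchly's test uses the standard first-order
chi-square approximation (a second-order correction changes p by
< 0.01 in our cross-checks). The GG-corrected p is reported when
Mauchly rejects at .05, mirroring conditional usage.

Bayes factors are **approximate** throughout: BF10 =
exp((BIC_null − BIC_alt)/2) from the corresponding fixed-effects fits.
This is monotone in the evidence but is not a Cauchy-prior Bayes
factor; exact parity with JASP or SPM's Bayesian machinery is a
non-goal. Post-hoc pairwise t tests use Holm correction as a
frequentist stand-in for prior-adjusted posterior odds.

The trial-wise pupil–RT correlation pools hits on target trials across
subjects into a single Pearson r, as in the original analysis; a
within-subject (random-effect) variant would generally differ and is
not computed.

## First-level design

* HRF: canonical double-gamma (shape-6 peak gamma minus shape-16
  undershoot gamma / 6, unit dispersions, 32-s support), sampled at a
  0.1-s microtime grid and scaled to unit peak. Regressors are built
  as boxcars on the microtime grid, convolved, and sampled at volume
  onsets t = i × TR (TR 2.5 s; the first four volumes are discarded
  and the task clock starts at the first kept volume).
* Parametric modulation: modulators are mean-centered across events;
  the modulated column is additionally residualized against its
  unmodulated parent (serial-orthogonalization convention), so the
  pair spans main effect ⊕ modulation. A zero-variance modulator
  produces an all-zero modulated column with a warning; such a design
  can be constructed but not fitted.
* Drift: discrete-cosine basis with a 128-s high-pass cutoff in every
  design, plus a constant.
* Nuisance: six motion parameters + backward-difference derivatives
  (first element 0), one 0/1 dummy column per DVARS-flagged volume,
  and five aCompCor components (SVD of the temporally demeaned
  WM+CSF voxel × time matrix — read as five from the *combined* mask,
  not five per tissue — unit variance, mutually orthogonal).
* DVARS: RMS intensity difference between consecutive kept volumes
  over in-brain voxels (DVARS_0 = 0); volumes above Q3 + 1.5 IQR of
  the DVARS distribution are flagged. Note the boxplot rule flags a
  small baseline fraction (~0.4%) of frames of any continuous
  distribution; a single-volume spike elevates both adjacent
  differences, so a spike typically flags itself and its successor.
* Estimation is OLS via QR (numerically stable for mixed-scale
  columns); AR(1) prewhitening is omitted — the quantities of interest
  are spatial patterns and planted-truth recovery, not single-subject
  error calibration. Nuisance and task columns are estimated jointly
  in one OLS, which is orthogonalization-order-invariant.
* The trial-peak GLM includes fixation-condition trials by default
  (`include_fixation` switches them off).

## Second level

Per voxel: one-sample t across subjects, Cohen's d = mean/SD, and
logBF via the BIC transform above (natural log). Maps are thresholded
jointly at (d ≥ 0.2, logBF ≥ 3) and (d ≥ 0.5, logBF ≥ 3); the
0.5-mask is nested in the 0.2-mask by construction. The natural-log
reading of the threshold (BF ≈ 20) is deliberate and documented; the
stricter reading (log10, BF = 1000) corresponds to logBF ≈ 6.9 and can
be requested via `logbf_min`. Zero-between-subject-variance voxels get
a capped d and are flagged. The condition ANOVA reuses the
within-subject F machinery voxel-wise; the conjunction is the
minimum-statistic ("conjunction null") convention tested at the
single-map threshold. Voxel-wise FWE and anatomical cluster labeling
are out of scope; masks are reported as voxel counts per label set.
The published d = 0.5 re-thresholding of merged clusters is a manual
judgment step; both thresholds are exposed, the merge decision is not
automated.

## Synthetic-data generator

The generator defines the study conditions the recovery experiments
run under.

Pupil (250 Hz, 430 s to cover 172 kept volumes): trace = tonic +
phasic + AR(1) noise.

* Tonic levels (z): fixation −0.5, 0-back −0.2, 1-back +0.1, 2-back
  +0.5 — free parameters chosen to reproduce the reported load
  ordering, piecewise constant per block (baseline −0.5 outside
  blocks). An optional per-condition linear ramp across the block
  (default 0) gives block-mean pupil-change structure where a scenario
  needs it.
* Phasic response: gamma density scaled to unit peak, shape 12, mode
  at 1.3 s (inside the 1.0–2.5 s search window); shape 12 keeps the
  kernel compact so baseline windows and neighboring trials are barely
  contaminated (< 3% of peak at ±1.3 s from the mode). Cell
  amplitudes default to the reported group means (targets
  0.72/0.66/0.57; non-targets 0.13/0.26/0.34 z) with per-subject
  Gaussian variation at the reported per-cell SDs.
* Light reflex: negative unit-peak gamma (shape 8) peaking 0.35 s
  after a 0.3-s latency, amplitude 0.15 z, on every stimulus including
  fixation letters.
* Noise: AR(1) with coefficient 0.97 at 250 Hz (a modeling choice —
  no within-block spectrum is published) and marginal SD 0.05 z,
  i.e. ≈ 0.04 z after smoothing.
* Blinks: Poisson 15/min, 0.1–0.4 s, non-overlapping, inserted as NaN
  gaps with 40-ms synthetic saccades flanking each gap (saccade
  detection itself is out of scope — markers are taken as given, as
  from vendor software). Gaze: slow drift (SD 30 units) around a
  center plus ~2/min excursions of 0.5–2 s and 400–800 units.
* Behavior: per target trial a hit with the condition's accuracy; per
  non-target a false alarm with 1 − accuracy (so expected accuracy
  equals the parameter exactly); RTs truncated-normal inside the
  response window with per-condition means 0.400/0.432/0.498 s,
  between-subject SDs 0.045/0.087/0.082, within-subject SD 0.1 s.
  Accuracy cohort parameters: 0.980/0.970/0.929 with SDs
  0.037/0.034/0.066. The positive trial-wise pupil–RT correlation is
  *emergent* — both tonic pupil and RT rise with load — not a planted
  per-trial coupling.
* BOLD (12 × 12 × 6 abstract grid, not MNI; 176 volumes, 4 dummies):
  voxel signal = planted β × the *standardized* modulated regressor
  built by the package's own design code from the true (gap-free)
  pupil trace, so a planted β is a per-frame contrast-to-noise ratio
  and the noiseless OLS identity is exact. Defaults: FPN +0.5 on the
  pupil-size modulation, salience +0.5 on the pooled pupil-change
  modulation, DMN −0.5 on pupil size; noise SD 1.0; per-voxel
  random-phase cosine drift (amplitude 0.5, periods 100–300 s); three
  shared AR(1) latent series loaded onto WM/CSF voxels (amplitude 1.0)
  for aCompCor to find; spike volumes with probability 0.02 per frame
  (global +6σ intensity jumps coupled to 2×-magnitude motion jumps);
  smooth sinusoidal motion (amplitude 0.3) plus jitter.

What the generator does **not** emulate: pupil units in mm or
foreshortening geometry, eyelid occlusion, cardiac/respiratory
physiological noise, EPI artifacts, spatial autocorrelation or
anatomical realism of the BOLD grid, randomized block orders, loads
above 2-back. Passing recovery tests therefore shows the *analysis
logic* is correct under the assumed signal structure; it does not
certify performance on real scanner data.

## Recovery experiments and their scope

* Planted-network recovery (20 subjects, defaults): sensitivity and
  false-positive rates of the two headline contrasts at the joint
  thresholds; specificity is checked by regenerating with one coupling
  removed at matched noise.
* Separation: scenarios couple salience voxels *either* to the
  block-mean pupil-change regressor *or* to the demeaned within-block
  regressors (with load-ordered tonic ramps so block means vary);
  each scenario is analyzed with both control GLMs. Detection for the
  demeaned GLM averages the three active-condition contrasts — the
  fixation block carries almost no within-block pupil change, so its
  modulator only dilutes. Cohorts of 12 per scenario give the
  logBF ≥ 3 threshold (t ≳ 3.3) comfortable per-voxel power.
* Peak recovery: measured on the interpolated+smoothed trace on the
  generator's own z-unit scale. The whole-recording z-transform
  divides by the trace SD, a quantity set by the generator's condition
  structure, which would deterministically rescale all planted
  amplitudes; skipping it for this comparison isolates the estimator.
  Known property: the max-in-window statistic is *positively biased*
  for weak responses — the maximum of signal plus noise over a 1.5-s
  window exceeds the signal peak when the signal is nearly flat, and
  subjects whose sampled amplitude is near zero are floored at the
  noise-maximum level. Target-cell means recover well; the weakest
  non-target cell sits above its reference by roughly this bias (the
  recovery suite reports the per-cell means and SEMs). Any published
  non-target value measured with this estimator carries the analogous
  bias of its own data.
* rmANOVA calibration: 1000 Gaussian null cohorts (n = 30, k = 4) with
  the conditional GG correction.

## Numerical choices

Population (n) SD in the z-transform; bin assignment by
floor(t × rate + 1e-9); boxcar edges rounded to the 0.1-s microtime
grid; QR-based OLS; Holm step-down implemented directly (cross-checked
against statsmodels); seeds everywhere derived via `SeedSequence` and
kept below 2^31. Degenerate inputs: zero-variance z-transform is an
error; a zero-variance modulator warns and zeroes the column;
constant rmANOVA data is an error; paired t with zero-variance
differences returns a signed infinite statistic with p ∈ {0, 1}.
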