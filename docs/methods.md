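# Methods

This note records the models, conventions and design choices behind
`tvconn`, in enough detail that every number the package produces can be
re-derived by hand.

## Experimental design and grids

The default `checkerboard_design()` is a block-designed run: 20 s rest,
then three repetitions of (20 s task + 20 s rest), closing with a 35 s
rest — 155 s in total, sampled as 240 volumes at TR = 0.645 s (154.8 s).
The first 14 volumes (~9 s) are discarded before analysis, leaving 226
samples starting at t₀ = 9.03 s; the first block onset sits 10.97 s into
the retained series.

All index conventions live in `TaskDesign`:

* volume i is sampled at i·TR from scan start;
* an onset maps to its **nearest** retained sample, which is relative
  time 0 of every epoch;
* interval selections are half-open `[lo, hi)` everywhere. At TR 0.645 s
  this makes the epoch grid [−10, +30) s the offsets {−15, …, +46}
  (62 samples), the baseline [−10, 0) exactly 15 samples, and an on-sample
  [0, 10) sub-period 16 samples.

## TVCC: kernel and estimator

The windowed correlation uses the kernel `K_h(u) = exp(−u²/h)` with u the
integer sample offset and h the window size **in samples** (h = 24 for the
16 s default; `KernelSpec.from_seconds` maps the 14/16/18 s sweep to
h = window/TR). Two conventions deserve emphasis because plausible
alternatives exist:

* the divisor is **h, not h²** — the weight at the window edge u = 12,
  h = 24 is exp(−144/24) = exp(−6), and the support `|u| ≤ h/2` ties the
  same h (in samples) to the window half-width;
* the support is the **symmetric** 25-point set |u| ≤ ⌊h/2⌋. A window of
  exactly 24 samples cannot be symmetric about its centre; symmetry wins
  so that the estimate has no phase lag.

Weights are not pre-normalized; the weighted moments normalize by Σw, so
truncated edge windows renormalize automatically. Edge policy is
**truncate, never pad or reflect** — imputed samples would bias exactly the
pre/post-onset epochs the analysis cares about. Samples whose (possibly
truncated) window holds fewer than 3 points, or where a weighted variance
vanishes, are marked invalid (NaN) rather than raising. The per-sample
estimate is computed by six moving weighted sums (direct convolutions), and
a test pins the convolution path to the per-sample formula.

A rectangular kernel on the same support is provided for comparison; with
h = series length it reduces to the full-series Pearson correlation (we
allow equality `length = h` so this documented limit is computable).

Fisher's transform z = atanh(r) is applied after clipping |r| ≤ 1 − 10⁻⁷,
and all averaging and group testing happens on z.

### Bias and the sub-period validation

A 16 s window centred at t uses samples up to 8 s away, so estimates
within ~8 s of a transition mix regimes: the window *smears* any true
change. This is why the pipeline also computes plain Pearson correlations
in four non-overlapping sub-periods (PRE [−10, 0), EARLY [0, 10),
LATE [10, 20), POST [20, 30) s), cycle-averaged on the z scale — an
estimate free of cross-boundary contamination — and validates dynamics with
a repeated-measures ANOVA over those four values.

## Preprocessing

Order of operations: discard volumes → build one joint nuisance matrix →
single OLS residualization → zero-phase Butterworth low-pass → TVCC. A
single joint regression is used because sequential regressions are
order-dependent; the joint fit is not.

Nuisance columns (all on the retained grid):

* **task**: unit boxcar convolved with the canonical double-gamma HRF
  (peak gamma: delay 6 s, dispersion 1 s; undershoot: delay 16 s,
  dispersion 1 s, ratio 6; length 32 s; peak-normalized to 1). The
  convolution runs on the full volume grid and is truncated afterwards, so
  the initial transient is exact. The task column is **included for the FC
  analysis and excluded for the BOLD analysis** — the whole point of the
  BOLD epochs is the evoked response, while windowed correlation is only
  meaningful on the stochastic residual (see the demonstration below).
* **motion**: the six rigid-body parameters and their backward-difference
  derivatives (first row 0). Rotation units default to degrees,
  configurable to radians.
* **WM/CSF eigenvariates**: accepted as opaque extra columns; in synthetic
  mode they are absent (nothing in the phantom generates them).
* **drift**: discrete-cosine columns below 1/128 Hz — `floor(2·n·TR·f_c)`
  columns, which is 2 for the 226-sample grid. The high-pass is embedded in
  the joint regression, not applied as a second filter; it can be switched
  off.
* an intercept is always added at fit time.

The low-pass is a 2nd-order Butterworth at 0.75 Hz applied
forward-backward (zero phase, squared magnitude response, so the gain at
the cutoff is 1/2). At TR = 0.645 s the cutoff sits at 97 % of the
0.775 Hz Nyquist and is realizable; for slower sampling where it is not,
the filter warns and passes the data through unchanged.

**Framewise displacement** summarises head motion as the mean of the three
absolute frame-to-frame translation differences (mm), and the rotational
analogue in degrees. The cited formulation admits variants (summed vs
mean differences, rotations mapped to arc length); we use the
mean-absolute-difference form and report the across-frame mean over the
N−1 difference frames, with the first frame shown as 0.

## Group statistics

* Point-wise tests are two-tailed one-sample t-tests across subjects
  (value − subject baseline, or slope vs 0), with BH-FDR applied **across
  the post-onset samples of one signal** — one ROI's BOLD panel or one
  pair's FC panel. This per-panel family is the narrowest reading
  consistent with a per-panel presentation of results; nothing is
  corrected across panels.
* A sample with zero across-subject variance (up to the rounding noise of
  the mean) yields p = 1 with a degenerate flag rather than an error, so
  pathological synthetic inputs complete.
* The slope at each epoch sample is the OLS slope (units/s) over a centred
  16 s rectangular window, truncated at the epoch edges, invalid below 3
  samples.
* The sub-period ANOVA is the classical one-way within-subject partition
  SS_total = SS_subjects + SS_conditions + SS_error, F on (k−1), (n−1)(k−1)
  df, **no sphericity correction** (none is applied in the motivating
  analysis; with k = 4 mild non-sphericity inflates the nominal p
  slightly — a caveat, not a correction we silently add). Post-hoc
  adjacent-pair paired t-tests run only when the ANOVA p < 0.05, with
  BH-FDR over the three comparisons within the pair.

## Synthetic cohorts

The generator's job is to produce data whose *ground truth is known
exactly*, not to be a biophysical forward model.

* **Correlation trajectories.** Each tracked pair carries a piecewise-
  linear ρ(t) (edge-held beyond its knots). Noise is built as
  `x_i = √λ(t)·c_p + √(1−Σλ)·e_i` from a shared AR(1) process c_p per pair
  and a unique AR(1) process e_i per ROI, all with identical
  autocovariance (stationary, unit variance, AR coefficient 0.3 by
  default), λ(t) = |ρ(t)|, the sign applied to the second member's shared
  term. Because the mixed processes share their autocovariance, the
  construction gives instantaneous correlation exactly ρ(t) at every
  sample — this is why mixing is used rather than a per-sample Cholesky on
  AR output, which would distort the target under temporal smoothing. The
  construction requires Σ_pairs |ρ(t)| ≤ 0.95 at every ROI; the config
  validates this, and the default truth therefore prescribes the dip on
  one lower↔higher visual pair per hemisphere (LMOG–LFuG, RMOG–RFuG)
  rather than all four cross pairs.
* **Default dip.** The motivating experiment reports the effect
  qualitatively (a transient FC decrease in the late stimulation period)
  but no effect size; the default trajectory is the package's choice:
  hold ρ = 0.6, decline linearly to 0.2 between onset+5 s and onset+15 s,
  hold until onset+20 s, recover to 0.6 by onset+25 s, each cycle.
* **Activation.** Activated ROIs receive amplitude × (boxcar ⊗ HRF),
  peak-normalized, amplitude drawn per subject (default mean 1, SD 0.2 —
  peak SNR 1 against unit noise). Between-subject variability also jitters
  each subject's trajectory level (SD 0.05, clipped to the feasible range).
* **Drift** is a second-order polynomial with standard-normal coefficients
  scaled by 0.5 — enough to exercise the DCT columns, with no claim to
  scanner physics. **Motion** tables are Gaussian random walks whose step
  SD (0.0752 mm, 0.0376°) is calibrated so the expected mean FD matches
  the reported cohort head-motion level (0.06 mm, 0.03°); they are
  nuisance theater for the regression path, not a motion-artifact model.
* Per-subject RNG streams derive from `SeedSequence((seed, subject_index))`,
  so cohorts are bit-reproducible and parallel-safe.
* `embed_in_volumes` writes each subject's series into small 4D NIfTI
  phantoms (sphere voxels = ROI series + i.i.d. voxel noise, background =
  noise) to exercise the mask/extraction path end to end.

What the generator does **not** emulate: spatial structure beyond disjoint
spheres, physiological (cardiac/respiratory) noise, nonlinear HRF effects,
inter-regional lags, and realistic motion artifacts. Passing tests
therefore demonstrate that the estimation chain recovers what it is pointed
at under its own assumptions — not that those assumptions hold in any real
dataset.

## ROI extraction

Spheres are defined in world (MNI, mm) coordinates; a voxel belongs to a
sphere when its centre, mapped through the image affine, lies within the
radius (≤). On a 3 mm grid an interior 8 mm sphere holds 81 voxels. Two
summaries are provided: the voxel mean, and the first eigenvariate — the
leading left singular vector of the (nuisance-adjusted) voxel matrix,
scaled to the ROI's root-mean-square amplitude (s₁/√v) and sign-aligned to
correlate positively with the ROI-mean residual (tie broken by the first
voxel). The motivating description names both summaries without fixing
which fed the FC results; both are exposed, with
eigenvariate-with-adjustment as the pipeline default.

## Validation experiments (`tvconn.experiments`)

Problem sizes are the package's chosen study conditions:

* **Recovery** (n = 20): group-mean cycle-averaged TVCC-z tracks the
  cycle-averaged z(ρ(t)) with MAE ≈ 0.05–0.08, tested below 0.15 z — the
  tolerance reflects ~12-effective-sample window variance and the smearing
  of the 10 s dip by the 16 s window.
* **Power** (100 replicate cohorts, n = 20, dip 0.6→0.2, amplitude 1,
  AR 0.3): the ANOVA + EARLY>LATE post-hoc and the negative in-block slope
  test each detect the dip in ≥ 80 % of replicates (observed: 100 %).
  With constant ρ and activation kept, detection stays ≤ 10 %
  (observed: 0 %).
* **Null calibration** (500 cohorts, constant ρ = 0.4, activation present,
  task removed): pooled per-sample uncorrected type-I error 0.05 ± 0.02
  (observed ≈ 0.050). The fraction of per-panel BH families with any FDR
  rejection stays ≤ 10 % (observed ≈ 3 %) — the per-panel family is the
  unit BH controls (weak FWER ≤ α under a complete null). The union over
  all 15 panels of a cohort is also reported (≈ 35–40 %, essentially
  1 − 0.95¹⁵ under near-independence); it is a statement about 15
  uncorrected families jointly, not about the procedure's calibration, and
  is reported rather than bounded.
* **Task-removal demonstration** (n = 100, amplitude 5, constant ρ = 0.4):
  analyzing with the task regressor left in manufactures time-locked TVCC
  modulation with ≥ 3× (observed 5–9×) the range of the task-removed
  curve. The experiment's parameters are part of its design: the artifact
  comes from evoked variance *within* the window, which a plateaued
  response barely produces — it scales with amplitude² and concentrates at
  block transitions — so a strong response makes the mechanism visible,
  and the large cohort keeps the reference curve's sampling noise from
  masking the ratio. At amplitude 1 and n = 20 the same artifact exists
  but sits inside the noise floor.
* **Window-length robustness**: the EARLY > LATE direction of the
  recovered effect is identical for 14/16/18 s windows in ≥ 95 % of
  replicates (observed: 100 %).
* **BOLD/FC disassociation** (same recovery runs): activated-ROI BOLD
  deviations are positive and sustained across the block interior while FC
  deviations are negative and transient — the FC curve dips mid-block and
  returns to baseline by the epoch end. The contrast is asserted on signs
  and curve shape rather than on rejected-sample *counts*: at the default
  effect size and n = 20 the group SEM is ~0.04 z, so the baseline test
  rejects wherever the smeared FC curve deviates at all, and rejection
  counts saturate for BOLD and FC alike; count ratios only discriminate in
  low-SNR regimes.

## Numerical and degenerate-input conventions

* Weighted variance ≤ 0, or fewer than 3 in-window samples → NaN estimate
  with a validity flag; downstream cycle means propagate NaN.
* |r| is clipped to 1 − 10⁻⁷ before atanh; r from the convolution path is
  clipped to [−1, 1] against rounding.
* Rank-deficient nuisance matrices raise, naming the collinear columns
  (greedy rank-growth scan).
* RM-ANOVA with zero condition variance returns F = 0, p = 1; a saturated
  error term returns F = ∞, p = 0.
* BH-FDR is order-stable; the reject set at level α is contained in the
  reject set at any α′ > α.

## Known limitations

* Real-image spatial preprocessing (motion correction, normalization,
  smoothing) is out of scope; images fed to the extractor are assumed
  co-registered in a common space.
* The window length (16 s) trades variance against temporal resolution;
  features much shorter than ~half the window are attenuated, which the
  sub-period analysis partially compensates but does not eliminate.
* No sphericity correction, no cluster/permutation correction over time,
  no mixed-effects modeling, and no alternative dynamic-FC estimators
  (DCC-GARCH, HMM, phase synchrony).
* The real-data path (`tvconn extract` + `analyze_cohort`) is exercised
  against synthetic phantoms only.
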