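# tvconn — task-related dynamic functional connectivity

`tvconn` asks whether the functional connectivity (FC) between brain regions
is really *sustained* across a block of identical stimuli, or whether it
changes within the block. It implements a point-wise, sliding-window
analysis of regional BOLD fMRI time series for block-designed experiments
with sub-second sampling (the motivating case: a flickering-checkerboard
experiment at TR = 0.645 s, 240 volumes, three 20 s task blocks), together
with a synthetic-data generator that reproduces that experiment with known
ground truth, so every stage of the chain is testable without access to the
original scans.

The audience is fMRI methods researchers and analysts who want a
dynamic-FC pipeline whose every arithmetic step — window weights, epoch
grids, test families — is pinned down by tests.

## The estimator

The **time-varying correlation coefficient (TVCC)** between two ROI series
x, y is the weighted Pearson correlation computed at every sample t, with
Gaussian window weights

```
K_h(u) = exp(-u² / h),   |u| ≤ ⌊h/2⌋,
```

where u is the integer sample offset from t and h is the window size in
samples (h = 24 ≈ 16 s at TR 0.645 s, so the edge weight is e⁻⁶). Windows
at the series edges are truncated and renormalized, never padded. Because
correlation is a statistic of the *stochastic* BOLD fluctuation, the
deterministic evoked response (boxcar ⊗ canonical double-gamma HRF) is
regressed out — jointly with motion parameters, their derivatives, optional
WM/CSF eigenvariates and discrete-cosine drift terms (1/128 Hz high-pass) —
before any correlation is estimated; a 2nd-order zero-phase Butterworth
low-pass (0.75 Hz) follows.

Downstream, all correlations are Fisher z-transformed (z = atanh r) and:

1. **Point-wise baseline tests** — per subject the TVCC-z (or BOLD) epoch
   is averaged over the three task cycles on a [−10, +30) s grid around
   block onset; each post-onset sample is compared to the subject's
   pre-stimulus ([−10, 0) s) baseline with a two-tailed one-sample t-test,
   Benjamini–Hochberg FDR-corrected across the tested samples.
2. **Point-wise trend tests** — least-squares slopes in a centred 16 s
   rectangular window at every epoch sample, tested against zero the same
   way.
3. **Sub-period validation** — plain Pearson correlations in the four
   sub-periods PRE [−10, 0), EARLY [0, 10), LATE [10, 20), POST [20, 30) s,
   Fisher-z cycle-averaged, compared with a one-way repeated-measures ANOVA
   and, when p < 0.05, adjacent-pair paired t-tests (FDR over the three
   comparisons).

The synthetic generator imposes a prescribed correlation trajectory ρ(t) on
AR(1) noise by mixing shared and unique processes with identical
autocovariance (`x_i = √λ(t)·c + √(1−λ(t))·e_i` gives instantaneous
correlation exactly λ(t)), adds boxcar⊗HRF activation, polynomial drift and
random-walk motion tables, and records the realized ground truth per
subject. Details and caveats are in `docs/methods.md`.

## Worked example

Twenty synthetic subjects with the default ground truth (FC between a
lower- and a higher-visual ROI dips from ρ ≈ 0.6 to ≈ 0.2 during the late
part of each block, recovering afterwards):

```python
from tvconn import SyntheticConfig, checkerboard_design, simulate_cohort
from tvconn.pipeline import analyze_cohort, preprocess_subject
from tvconn.tvcc import SUBPERIOD_NAMES

design = checkerboard_design()
cohort = simulate_cohort(SyntheticConfig(n_subjects=20, seed=1))
bold, fc = zip(*(preprocess_subject(s, design, motion=m)
                 for s, m in zip(cohort.subjects, cohort.motion)))
res = analyze_cohort(list(bold), list(fc), design,
                     pairs=[("LMOG", "LFuG")], rois=["LMOG"])

pair = res.fc[("LMOG", "LFuG")]
for name, z in zip(SUBPERIOD_NAMES, pair.subperiod.mean(axis=0)):
    print(f"{name:>5s}-STIM mean FC (Fisher z): {z:.3f}")
print(f"RM-ANOVA: F({pair.anova.df_condition},{pair.anova.df_error}) = "
      f"{pair.anova.f_stat:.2f}, p = {pair.anova.p_value:.2e}")
for rec in pair.anova.posthoc:
    print(f"post-hoc {rec.comparison}: t = {rec.t_stat:+.2f}, "
          f"p = {rec.p_value:.4f}, FDR reject = {rec.reject}")
```

prints

```
  PRE-STIM mean FC (Fisher z): 0.714
EARLY-STIM mean FC (Fisher z): 0.740
 LATE-STIM mean FC (Fisher z): 0.385
 POST-STIM mean FC (Fisher z): 0.674
RM-ANOVA: F(3,57) = 15.11, p = 2.38e-07
post-hoc PRE-EARLY: t = -0.35, p = 0.7276, FDR reject = False
post-hoc EARLY-LATE: t = +6.02, p = 0.0000, FDR reject = True
post-hoc LATE-POST: t = -5.35, p = 0.0000, FDR reject = True
```

i.e. the pipeline recovers the prescribed dynamics: FC in the LATE-STIM
sub-period is significantly lower than EARLY-STIM and recovers by
POST-STIM, while the PRE→EARLY change is not significant. The trend test
on the same cohort flags FDR-significant *negative* FC slopes from roughly
4 to 14 s after onset — the decline happens inside the block.

## Command line

```bash
tvconn init-config --out run.yaml     # template configuration
tvconn run --config run.yaml --seed 1 --out runs/demo
tvconn report runs/demo               # summary table + figures
tvconn simulate --seed 1 --out sim/   # cohort as TSV + truth + motion text
tvconn extract --images sub.nii.gz --roi-table rois.tsv --out extracted/
```

`tvconn run` writes tidy tab-delimited tables (epochs, slopes, sub-periods,
ANOVA, framewise displacement) plus a `manifest.yaml` with the config hash
and per-stage counts; a completed run re-invoked with the same config is a
no-op. A window sweep (`window_s: [14, 16, 18]` in the config) produces
parallel TVCC result sets from one shared preprocessing pass.

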