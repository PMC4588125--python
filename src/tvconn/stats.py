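"""Group-level inference: point-wise baseline/trend tests, BH-FDR,
one-way repeated-measures ANOVA with adjacent-pair post-hoc tests.

All FC quantities entering these tests are Fisher-z values.  FDR families
follow the per-panel presentation: point-wise tests are corrected across
the tested samples of one signal (one ROI's BOLD or one pair's FC), and the
three adjacent post-hoc comparisons are corrected together within one pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PointwiseStatResult",
    "RmAnovaResult",
    "PosthocRecord",
    "bh_fdr",
    "baseline_per_subject",
    "pointwise_baseline_test",
    "pointwise_trend_test",
    "rm_anova_oneway",
    "posthoc_adjacent",
    "anova_with_posthoc",
]


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: reject flags and the admitted threshold.

    Classical step-up at level ``alpha``: sort the m p-values, find the
    largest rank i with p(i) <= i*alpha/m and reject all ranks <= i.  Input
    order is preserved in the returned flags; the second element is the
    largest rejected p-value (0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


@dataclass
class PointwiseStatResult:
    """Per-sample group test: t, two-tailed p, FDR rejection and direction."""

    rel_times: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    reject: np.ndarray
    direction: np.ndarray
    degenerate: np.ndarray
    alpha: float = 0.05
    fdr_threshold: float = 0.0


def baseline_per_subject(rel_times: np.ndarray, per_subject: np.ndarray,
                         baseline_interval: tuple = (-10.0, 0.0)) -> np.ndarray:
    """Per-subject mean over the baseline samples of a cycle-averaged epoch.

    ``per_subject`` is (subjects x rel_time); the baseline is the mean over
    samples with rel_time in the half-open interval (default [-10, 0) s).
    """
    rel_times = np.asarray(rel_times, float)
    per_subject = np.atleast_2d(np.asarray(per_subject, float))
    lo, hi = baseline_interval
    sel = (rel_times >= lo) & (rel_times < hi)
    if not sel.any():
        raise ValueError(f"no epoch samples fall in the baseline interval [{lo}, {hi})")
    return per_subject[:, sel].mean(axis=1)


def _one_sample_tests(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-tailed one-sample t vs 0 per column; zero variance -> p = 1."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    # zero variance up to the rounding noise of the mean computation
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    t = np.zeros(diffs.shape[1])
    p = np.ones(diffs.shape[1])
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df=n - 1)
    return t, p, degenerate


def _pointwise(rel_times, diffs, alpha, test_mask) -> PointwiseStatResult:
    t, p, degenerate = _one_sample_tests(diffs[:, test_mask])
    reject, thr = bh_fdr(p, alpha)
    return PointwiseStatResult(
        rel_times=np.asarray(rel_times, float)[test_mask],
        t_stat=t,
        p_value=p,
        reject=reject,
        direction=np.sign(diffs[:, test_mask].mean(axis=0)),
        degenerate=degenerate,
        alpha=alpha,
        fdr_threshold=thr,
    )


def pointwise_baseline_test(rel_times: np.ndarray, per_subject: np.ndarray,
                            baselines: np.ndarray | None = None,
                            alpha: float = 0.05,
                            baseline_interval: tuple = (-10.0, 0.0)) -> PointwiseStatResult:
    """Is the signal at each post-onset sample above/below its baseline?

    For each sample with rel_time >= 0, a two-tailed one-sample t-test across
    subjects on (value - subject baseline); BH-FDR jointly over the tested
    samples.  Zero across-subject variance at a sample gives p = 1 with the
    degenerate flag set.
    """
    rel_times = np.asarray(rel_times, float)
    per_subject = np.atleast_2d(np.asarray(per_subject, float))
    if per_subject.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if baselines is None:
        baselines = baseline_per_subject(rel_times, per_subject, baseline_interval)
    diffs = per_subject - np.asarray(baselines, float)[:, None]
    return _pointwise(rel_times, diffs, alpha, rel_times >= 0)


def pointwise_trend_test(rel_times: np.ndarray, slopes: np.ndarray,
                         alpha: float = 0.05,
                         post_onset_only: bool = True) -> PointwiseStatResult:
    """Is the slope at each sample significantly non-zero across subjects?

    Two-tailed one-sample t vs 0 per sample, BH-FDR across the tested
    samples (post-onset by default, matching the baseline-test family).
    """
    rel_times = np.asarray(rel_times, float)
    slopes = np.atleast_2d(np.asarray(slopes, float))
    if slopes.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    mask = (rel_times >= 0) if post_onset_only else np.ones(rel_times.size, bool)
    mask &= ~np.any(np.isnan(slopes), axis=0)
    return _pointwise(rel_times, slopes, alpha, mask)


@dataclass
class PosthocRecord:
    """One adjacent-pair paired t-test (e.g. EARLY vs LATE)."""

    comparison: str
    t_stat: float
    p_value: float
    reject: bool


@dataclass
class RmAnovaResult:
    """One-way repeated-measures ANOVA over the four sub-periods."""

    f_stat: float
    df_condition: int
    df_error: int
    p_value: float
    posthoc: list = field(default_factory=list)
    posthoc_gated: bool = False


def rm_anova_oneway(data: np.ndarray) -> RmAnovaResult:
    """One-way within-subject ANOVA on a (subjects x conditions) matrix.

    SS_total is partitioned into SS_subjects + SS_conditions + SS_error;
    F = MS_conditions / MS_error with df (k-1) and (n-1)(k-1).  No
    sphericity correction is applied.
    """
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    if np.any(np.isnan(data)):
        raise ValueError("missing cells are not allowed")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = data.mean()
    ss_total = ((data - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ss_cond <= 0 or ms_err <= 0:
        # no condition variance (or a saturated fit): nothing to detect
        f = 0.0 if ss_cond <= 0 else float("inf")
        p = 1.0 if ss_cond <= 0 else 0.0
    else:
        f = (ss_cond / df_cond) / ms_err
        p = float(sps.f.sf(f, df_cond, df_err))
    return RmAnovaResult(f_stat=float(f), df_condition=df_cond,
                         df_error=df_err, p_value=p)


def posthoc_adjacent(data: np.ndarray, gate_p: float, alpha: float = 0.05,
                     names: tuple = ("PRE", "EARLY", "LATE", "POST")) -> tuple[list, bool]:
    """Adjacent-pair paired t-tests, gated on the ANOVA p-value.

    Run only when ``gate_p`` < 0.05: paired two-tailed t-tests for each
    adjacent condition pair, BH-FDR over those comparisons.  Returns
    ``(records, gated)`` where ``gated`` is True when the ANOVA gate was
    passed and the tests were run.
    """
    data = np.asarray(data, float)
    if gate_p >= 0.05:
        return [], False
    k = data.shape[1]
    ts, ps, labels = [], [], []
    for j in range(k - 1):
        d = data[:, j] - data[:, j + 1]
        sd = d.std(ddof=1)
        if sd == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(data[:, j], data[:, j + 1])
        ts.append(float(t))
        ps.append(float(p))
        labels.append(f"{names[j]}-{names[j + 1]}")
    reject, _ = bh_fdr(np.asarray(ps), alpha)
    records = [PosthocRecord(comparison=lbl, t_stat=t, p_value=p, reject=bool(rj))
               for lbl, t, p, rj in zip(labels, ts, ps, reject)]
    return records, True


def anova_with_posthoc(data: np.ndarray, alpha: float = 0.05) -> RmAnovaResult:
    """RM-ANOVA followed by gated adjacent-pair post-hoc tests."""
    res = rm_anova_oneway(data)
    records, gated = posthoc_adjacent(data, res.p_value, alpha)
    res.posthoc = records
    res.posthoc_gated = gated
    return res
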