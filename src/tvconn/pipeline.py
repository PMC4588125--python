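"""End-to-end orchestration: simulate/extract -> preprocess -> TVCC -> stats.

Two preprocessed variants of every subject are carried through the chain:

* the *BOLD* series (motion, drift and optional WM/CSF columns removed but
  the evoked response kept), used for the point-wise BOLD analyses;
* the *FC* series (the task regressor removed as well), used for every
  correlation estimate — windowed correlation is a statistic of the
  stochastic fluctuation, and a deterministic evoked component common to two
  ROIs masquerades as time-locked connectivity.

Group results per signal: point-wise baseline tests, point-wise trend tests
on the 16 s rectangular-window slopes, and per pair the four-sub-period
repeated-measures ANOVA with gated adjacent post-hoc tests.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import TaskDesign, checkerboard_design
from .extract import RoiTimeSeries, write_roi_timeseries
from .preprocess import (build_nuisance, butterworth_lowpass,
                         framewise_displacement, residualize)
from .stats import (PointwiseStatResult, RmAnovaResult, anova_with_posthoc,
                    baseline_per_subject, pointwise_baseline_test,
                    pointwise_trend_test)
from .synthetic import SyntheticConfig, simulate_cohort
from .tvcc import (DEFAULT_SUBPERIODS, SUBPERIOD_NAMES, KernelSpec,
                   epoch_average, pointwise_slope, subperiod_fc, tvcc)

__all__ = [
    "PreprocessOptions",
    "preprocess_subject",
    "SignalAnalysis",
    "PairAnalysis",
    "CohortResult",
    "analyze_cohort",
    "RunConfig",
    "run_pipeline",
    "report",
]


@dataclass(frozen=True)
class PreprocessOptions:
    """Toggles for the joint nuisance regression and temporal filtering."""

    remove_task_for_fc: bool = True
    include_dct: bool = True
    highpass_cutoff: float = 1.0 / 128.0
    lowpass_cutoff: float = 0.75
    lowpass_order: int = 2
    rotation_unit: str = "deg"


def _discard(series: RoiTimeSeries, design: TaskDesign) -> RoiTimeSeries:
    if series.n_samples == design.n_volumes and series.t0 == 0.0:
        return RoiTimeSeries(subject_id=series.subject_id,
                             roi_names=list(series.roi_names), tr=series.tr,
                             values=series.values[design.n_discard:],
                             t0=design.t0)
    if series.n_samples == design.n_retained:
        return series
    raise ValueError("series length matches neither the full nor the retained grid")


def preprocess_subject(series: RoiTimeSeries, design: TaskDesign,
                       motion: np.ndarray | None = None,
                       extra: np.ndarray | None = None,
                       options: PreprocessOptions = PreprocessOptions()
                       ) -> tuple[RoiTimeSeries, RoiTimeSeries]:
    """Discard, jointly residualize and low-pass one subject.

    Returns ``(bold_series, fc_series)`` on the retained grid: the first with
    the task regressor *kept* (for evoked-response analyses), the second with
    it removed (for all correlation estimates).
    """
    kept = _discard(series, design)

    def _clean(include_task: bool) -> np.ndarray:
        nuis = build_nuisance(design, motion=motion, extra=extra,
                              include_task=include_task,
                              include_dct=options.include_dct,
                              highpass_cutoff=options.highpass_cutoff)
        resid = residualize(kept.values, nuis)
        return butterworth_lowpass(resid, order=options.lowpass_order,
                                   cutoff=options.lowpass_cutoff, tr=design.tr)

    bold = _clean(include_task=False)
    fc = _clean(include_task=True) if options.remove_task_for_fc else bold
    mk = lambda v: RoiTimeSeries(subject_id=kept.subject_id,
                                 roi_names=list(kept.roi_names), tr=kept.tr,
                                 values=v, t0=kept.t0)
    return mk(bold), mk(fc)


@dataclass
class SignalAnalysis:
    """Group results for one signal (a ROI's BOLD or a pair's FC-z)."""

    name: str
    rel_times: np.ndarray
    epochs: np.ndarray            # subjects x rel_time, cycle-averaged
    slopes: np.ndarray            # subjects x rel_time, units/s
    baseline_test: PointwiseStatResult
    trend_test: PointwiseStatResult


@dataclass
class PairAnalysis(SignalAnalysis):
    """FC results for one ROI pair, plus the sub-period validation."""

    subperiod: np.ndarray = None  # subjects x 4 Fisher-z
    anova: RmAnovaResult = None


@dataclass
class CohortResult:
    design: TaskDesign
    kernel: KernelSpec
    bold: dict = field(default_factory=dict)   # roi -> SignalAnalysis
    fc: dict = field(default_factory=dict)     # pair -> PairAnalysis


def _signal_analysis(name, epoch_rows, rel_times, design, slope_window_s,
                     alpha, baseline_interval) -> tuple:
    epochs = np.asarray(epoch_rows)
    slopes = np.asarray([pointwise_slope(rel_times, row, slope_window_s)
                         for row in epochs])
    baselines = baseline_per_subject(rel_times, epochs, baseline_interval)
    btest = pointwise_baseline_test(rel_times, epochs, baselines, alpha,
                                    baseline_interval)
    ttest = pointwise_trend_test(rel_times, slopes, alpha)
    return epochs, slopes, btest, ttest


def analyze_cohort(bold_series: list, fc_series: list, design: TaskDesign,
                   kernel: KernelSpec = KernelSpec(),
                   pairs: list | None = None, rois: list | None = None,
                   epoch_window: tuple = (-10.0, 30.0),
                   slope_window_s: float = 16.0,
                   baseline_interval: tuple = (-10.0, 0.0),
                   subperiods: tuple = DEFAULT_SUBPERIODS,
                   alpha: float = 0.05) -> CohortResult:
    """Full group analysis of a preprocessed cohort.

    ``bold_series``/``fc_series`` are per-subject :class:`RoiTimeSeries` on
    the retained grid (task kept / task removed).  ``pairs`` defaults to all
    ROI pairs, ``rois`` to all ROIs.
    """
    if len(bold_series) != len(fc_series) or not bold_series:
        raise ValueError("need matching non-empty BOLD and FC series lists")
    roi_names = list(bold_series[0].roi_names)
    rois = list(rois) if rois is not None else roi_names
    pairs = ([tuple(p) for p in pairs] if pairs is not None
             else list(itertools.combinations(roi_names, 2)))

    result = CohortResult(design=design, kernel=kernel)

    for roi in rois:
        rows = []
        rel_times = None
        for subj in bold_series:
            rel_times, row = epoch_average(subj.column(roi), design, epoch_window)
            rows.append(row)
        epochs, slopes, btest, ttest = _signal_analysis(
            roi, rows, rel_times, design, slope_window_s, alpha, baseline_interval)
        result.bold[roi] = SignalAnalysis(name=roi, rel_times=rel_times,
                                          epochs=epochs, slopes=slopes,
                                          baseline_test=btest, trend_test=ttest)

    for pair in pairs:
        rows, sub_rows = [], []
        rel_times = None
        for subj in fc_series:
            x = subj.column(pair[0])
            y = subj.column(pair[1])
            series = tvcc(x, y, kernel, pair=pair)
            rel_times, row = epoch_average(series.z, design, epoch_window)
            rows.append(row)
            sub_rows.append(subperiod_fc(x, y, design, subperiods))
        epochs, slopes, btest, ttest = _signal_analysis(
            pair, rows, rel_times, design, slope_window_s, alpha, baseline_interval)
        sub = np.asarray(sub_rows)
        anova = anova_with_posthoc(sub, alpha)
        result.fc[pair] = PairAnalysis(name="-".join(pair), rel_times=rel_times,
                                       epochs=epochs, slopes=slopes,
                                       baseline_test=btest, trend_test=ttest,
                                       subperiod=sub, anova=anova)
    return result


# ---------------------------------------------------------------------------
# run configuration, orchestration, manifest
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "mode": "synthetic",
    "seed": 0,
    "n_subjects": 20,
    "window_s": [16.0],
    "kernel_shape": "gaussian",
    "alpha": 0.05,
    "epoch_window": [-10.0, 30.0],
    "slope_window_s": 16.0,
    "remove_task_for_fc": True,
    "include_dct": True,
    "lowpass_cutoff": 0.75,
    "rotation_unit": "deg",
    "write_subject_series": True,
    "paths": {"images": [], "roi_table": None, "motion": []},
    "synthetic": {},   # overrides forwarded to SyntheticConfig
}


@dataclass
class RunConfig:
    """Validated run configuration (see ``_DEFAULT_CONFIG`` for keys)."""

    options: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        merged = {k: (dict(v) if isinstance(v, dict) else v)
                  for k, v in _DEFAULT_CONFIG.items()}
        unknown = set(d) - set(_DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(merged.get(k), dict) and isinstance(v, dict):
                merged[k].update(v)
            else:
                merged[k] = v
        if merged["mode"] not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        synth_unknown = set(merged["synthetic"]) - {
            "n_subjects", "activation_amplitude", "ar_coefficient", "noise_sd",
            "drift_amplitude", "motion_sd", "rho_subject_sd", "rho_high",
            "rho_low", "constant_rho", "pairs"}
        if synth_unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(synth_unknown)}")
        return cls(options=merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.options, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _synthetic_config(run: RunConfig) -> SyntheticConfig:
    from .synthetic import (constant_trajectory, default_trajectories,
                            transient_decrease_trajectory)
    o = run.options
    s = o["synthetic"]
    design = checkerboard_design()
    kwargs = dict(n_subjects=int(s.get("n_subjects", o["n_subjects"])),
                  seed=int(o["seed"]), design=design)
    for key in ("activation_amplitude", "ar_coefficient", "noise_sd",
                "drift_amplitude", "motion_sd", "rho_subject_sd"):
        if key in s:
            val = s[key]
            kwargs[key] = tuple(val) if isinstance(val, (list, tuple)) else val
    pairs = [tuple(p) for p in s.get("pairs", [["LMOG", "LFuG"], ["RMOG", "RFuG"]])]
    if "constant_rho" in s:
        trajectories = [constant_trajectory(p, design, float(s["constant_rho"]))
                        for p in pairs]
    elif "rho_high" in s or "rho_low" in s:
        trajectories = [transient_decrease_trajectory(
            p, design, high=float(s.get("rho_high", 0.6)),
            low=float(s.get("rho_low", 0.2))) for p in pairs]
    else:
        trajectories = default_trajectories(design)
    kwargs["trajectories"] = trajectories
    return SyntheticConfig(**kwargs)


def _write_pointwise(rows, path):
    pd.DataFrame(rows, columns=["signal", "rel_time", "mean", "sem", "t",
                                "p", "reject", "direction"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def _pointwise_rows(name, rel_times, epochs, test: PointwiseStatResult):
    n = epochs.shape[0]
    mean = np.nanmean(epochs, axis=0)
    sem = np.nanstd(epochs, axis=0, ddof=1) / np.sqrt(n)
    tested = {t: i for i, t in enumerate(test.rel_times)}
    rows = []
    for j, t in enumerate(rel_times):
        i = tested.get(t)
        rows.append([name, t, mean[j], sem[j],
                     test.t_stat[i] if i is not None else np.nan,
                     test.p_value[i] if i is not None else np.nan,
                     bool(test.reject[i]) if i is not None else False,
                     test.direction[i] if i is not None else 0.0])
    return rows


def run_pipeline(run: RunConfig, out_dir) -> Path:
    """Execute the configured analysis end to end into ``out_dir``.

    Deterministic given (config, seed).  A completed run directory with a
    matching config hash is left untouched (no-op resume).  Returns the run
    directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.yaml"
    chash = run.config_hash()
    if manifest_path.exists():
        prev = yaml.safe_load(manifest_path.read_text())
        if (prev or {}).get("config_hash") == chash and \
                all((out / f).exists() for f in (prev or {}).get("outputs", [])):
            return out

    o = run.options
    design = checkerboard_design()
    if o["mode"] == "synthetic":
        cfg = _synthetic_config(run)
        dataset = simulate_cohort(cfg)
        bold_list, fc_list, fd_rows = [], [], []
        for series, motion in zip(dataset.subjects, dataset.motion):
            fd = framewise_displacement(motion, o["rotation_unit"])
            fd_rows.append([series.subject_id, fd.mean_translational,
                            fd.mean_rotational])
            b, f = preprocess_subject(series, design, motion=motion,
                                      options=PreprocessOptions(
                                          remove_task_for_fc=o["remove_task_for_fc"],
                                          include_dct=o["include_dct"],
                                          lowpass_cutoff=o["lowpass_cutoff"],
                                          rotation_unit=o["rotation_unit"]))
            bold_list.append(b)
            fc_list.append(f)
    else:
        raise NotImplementedError(
            "real mode: extract ROI series with tvconn.extract and feed them "
            "to analyze_cohort; the all-in-one runner covers synthetic mode")

    outputs = []
    fd_df = pd.DataFrame(fd_rows, columns=["subject", "mean_fd_translation_mm",
                                           "mean_fd_rotation_deg"])
    fd_df.to_csv(out / "framewise_displacement.tsv", sep="\t", index=False,
                 float_format="%.6g")
    outputs.append("framewise_displacement.tsv")

    if o["write_subject_series"]:
        (out / "series").mkdir(exist_ok=True)
        for b in fc_list:
            write_roi_timeseries(b, out / "series" / f"{b.subject_id}_fc.tsv")
            outputs.append(f"series/{b.subject_id}_fc.tsv")

    results = {}
    for window_s in o["window_s"]:
        kernel = KernelSpec.from_seconds(float(window_s), design.tr,
                                         o["kernel_shape"])
        res = analyze_cohort(bold_list, fc_list, design, kernel,
                             epoch_window=tuple(o["epoch_window"]),
                             slope_window_s=o["slope_window_s"],
                             alpha=o["alpha"])
        results[float(window_s)] = res
        tag = f"w{window_s:g}s"
        ep_rows, sl_rows, sp_rows, an_rows = [], [], [], []
        for roi, sig in res.bold.items():
            ep_rows += _pointwise_rows(f"bold:{roi}", sig.rel_times, sig.epochs,
                                       sig.baseline_test)
            sl_rows += _pointwise_rows(f"bold:{roi}", sig.rel_times, sig.slopes,
                                       sig.trend_test)
        for pair, sig in res.fc.items():
            label = "fc:" + "-".join(pair)
            ep_rows += _pointwise_rows(label, sig.rel_times, sig.epochs,
                                       sig.baseline_test)
            sl_rows += _pointwise_rows(label, sig.rel_times, sig.slopes,
                                       sig.trend_test)
            for s_idx in range(sig.subperiod.shape[0]):
                for p_idx, pname in enumerate(SUBPERIOD_NAMES):
                    sp_rows.append([label, s_idx, pname,
                                    sig.subperiod[s_idx, p_idx]])
            row = [label, sig.anova.f_stat, sig.anova.df_condition,
                   sig.anova.df_error, sig.anova.p_value,
                   sig.anova.posthoc_gated]
            for rec in sig.anova.posthoc or []:
                row += [rec.t_stat, rec.p_value, rec.reject]
            row += [np.nan] * (15 - len(row))
            an_rows.append(row)
        _write_pointwise(ep_rows, out / f"epochs_{tag}.tsv")
        _write_pointwise(sl_rows, out / f"slopes_{tag}.tsv")
        pd.DataFrame(sp_rows, columns=["signal", "subject", "subperiod", "z"]
                     ).to_csv(out / f"subperiods_{tag}.tsv", sep="\t",
                              index=False, float_format="%.8g")
        pd.DataFrame(an_rows, columns=[
            "signal", "F", "df_cond", "df_err", "p", "posthoc_gated",
            "t_pre_early", "p_pre_early", "rej_pre_early",
            "t_early_late", "p_early_late", "rej_early_late",
            "t_late_post", "p_late_post", "rej_late_post"]
        ).to_csv(out / f"anova_{tag}.tsv", sep="\t", index=False,
                 float_format="%.8g")
        outputs += [f"epochs_{tag}.tsv", f"slopes_{tag}.tsv",
                    f"subperiods_{tag}.tsv", f"anova_{tag}.tsv"]

    manifest = {
        "package_version": __version__,
        "config_hash": chash,
        "seed": int(o["seed"]),
        "mode": o["mode"],
        "n_subjects": len(bold_list),
        "n_pairs": len(next(iter(results.values())).fc),
        "windows_s": [float(w) for w in o["window_s"]],
        "outputs": outputs,
        "config": o,
    }
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def report(run_dir, figures: bool = True) -> pd.DataFrame:
    """Summary tables (and optional figures) for a completed run.

    Returns the per-pair sub-period summary (ANOVA p, post-hoc flags) and,
    when ``figures`` is set, writes one PDF per analysis with the group mean
    +/- SEM curve and FDR-rejection shading.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError("no manifest.yaml: run the pipeline first")
    manifest = yaml.safe_load(manifest_path.read_text())
    missing = [f for f in manifest["outputs"] if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages/files: {missing}")

    summaries = []
    for w in manifest["windows_s"]:
        tag = f"w{w:g}s"
        an = pd.read_csv(run_dir / f"anova_{tag}.tsv", sep="\t")
        an.insert(0, "window_s", w)
        summaries.append(an)
        if figures:
            _figures_for(run_dir, tag)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(run_dir / "summary.tsv", sep="\t", index=False)
    return summary


def _figures_for(run_dir: Path, tag: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for stem in (f"epochs_{tag}", f"slopes_{tag}"):
        df = pd.read_csv(run_dir / f"{stem}.tsv", sep="\t")
        signals = df["signal"].unique()
        n = len(signals)
        if n == 0:
            continue
        ncol = 3
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.5 * nrow),
                                 squeeze=False)
        for ax, sig in zip(axes.flat, signals):
            d = df[df["signal"] == sig]
            ax.fill_between(d["rel_time"], d["mean"] - d["sem"],
                            d["mean"] + d["sem"], alpha=0.3)
            ax.plot(d["rel_time"], d["mean"], lw=1)
            rej = d[d["reject"] == True]  # noqa: E712
            for _, r in rej.iterrows():
                color = "red" if r["direction"] > 0 else "blue"
                ax.axvspan(r["rel_time"], r["rel_time"] + 0.645, color=color,
                           alpha=0.15, lw=0)
            ax.axvspan(0, 20, color="gray", alpha=0.08, lw=0)
            ax.set_title(sig, fontsize=8)
            ax.set_xlabel("time from onset (s)", fontsize=7)
        for ax in axes.flat[n:]:
            ax.set_visible(False)
        fig.tight_layout()
        fig.savefig(run_dir / f"{stem}.pdf")
        plt.close(fig)
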