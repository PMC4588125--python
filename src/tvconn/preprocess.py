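"""Regressors, filters and motion summaries for ROI BOLD series.

The analysis chain treats correlation as a statistic of the *stochastic*
BOLD fluctuation, so the deterministic evoked response (boxcar convolved
with the canonical HRF) must be regressed out before any windowed
correlation is computed, together with head-motion parameters, their
derivatives, optional WM/CSF eigenvariate columns and low-frequency
discrete-cosine drift terms.  All nuisance columns are removed in a single
joint ordinary-least-squares fit, followed by a zero-phase Butterworth
low-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .design import TaskDesign

__all__ = [
    "HrfParams",
    "NuisanceSet",
    "FdSummary",
    "canonical_hrf",
    "task_regressor",
    "dct_highpass_basis",
    "butterworth_lowpass",
    "motion_derivatives",
    "framewise_displacement",
    "build_nuisance",
    "residualize",
]


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self):
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "undershoot_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_length <= self.peak_delay:
            raise ValueError("kernel_length must exceed peak_delay")


def canonical_hrf(params: HrfParams = HrfParams(), tr: float = 0.645) -> np.ndarray:
    """Sample the canonical HRF (difference of two gamma densities) at ``tr``.

    The kernel is the peak gamma density minus the undershoot density divided
    by ``undershoot_ratio``, sampled on ``[0, kernel_length)`` and scaled so
    its maximum is 1.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, params.kernel_length, tr)
    peak = stats.gamma.pdf(t, a=params.peak_delay / params.peak_dispersion,
                           scale=params.peak_dispersion)
    under = stats.gamma.pdf(t, a=params.undershoot_delay / params.undershoot_dispersion,
                            scale=params.undershoot_dispersion)
    h = peak - under / params.undershoot_ratio
    return h / h.max()


def task_regressor(design: TaskDesign, hrf: np.ndarray | None = None) -> np.ndarray:
    """Boxcar convolved with the HRF, truncated to the retained samples.

    The convolution is carried out on the *full* volume grid so that the
    initial transient is handled exactly, then the first ``n_discard``
    samples are dropped.
    """
    if hrf is None:
        hrf = canonical_hrf(tr=design.tr)
    full = np.convolve(design.boxcar(), np.asarray(hrf, float))[: design.n_volumes]
    return full[design.n_discard:]


def dct_highpass_basis(n_samples: int, tr: float, cutoff: float = 1.0 / 128.0) -> np.ndarray:
    """Discrete-cosine drift columns with frequency below ``cutoff`` Hz.

    Returns ``floor(2 * n * tr * cutoff)`` columns (the constant term is
    excluded; an intercept is added separately during residualization).
    Columns follow the usual DCT-II convention and are mutually orthogonal.
    """
    if n_samples <= 2:
        raise ValueError("need more than 2 samples")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_cols = int(np.floor(2.0 * n_samples * tr * cutoff))
    t = np.arange(n_samples)
    cols = [np.sqrt(2.0 / n_samples) * np.cos(np.pi * (2 * t + 1) * k / (2 * n_samples))
            for k in range(1, n_cols + 1)]
    return np.column_stack(cols) if cols else np.empty((n_samples, 0))


def butterworth_lowpass(series: np.ndarray, order: int = 2,
                        cutoff: float = 0.75, tr: float = 0.645) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0.

    If the requested cutoff is at or above Nyquist the filter is
    unrealizable: a warning is emitted and the input is returned unchanged.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    series = np.asarray(series, float)
    nyquist = 1.0 / (2.0 * tr)
    if cutoff >= nyquist:
        warnings.warn(
            f"low-pass cutoff {cutoff} Hz is not below Nyquist {nyquist:.3f} Hz; "
            "returning input unfiltered", RuntimeWarning, stacklevel=2)
        return series.copy()
    b, a = signal.butter(order, cutoff / nyquist)
    return signal.filtfilt(b, a, series, axis=0)


def motion_derivatives(motion: np.ndarray) -> np.ndarray:
    """Backward differences of the six rigid-body parameters; first row 0."""
    motion = np.asarray(motion, float)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    out = np.zeros_like(motion)
    out[1:] = np.diff(motion, axis=0)
    return out


@dataclass(frozen=True)
class FdSummary:
    """Framewise displacement: per-frame values and across-frame means.

    ``translational_fd`` is the mean of the three absolute frame-to-frame
    translation differences (mm); ``rotational_fd`` the analogue in degrees.
    The first frame has no predecessor and is reported as 0; the summary
    means average the remaining N-1 difference frames.
    """

    translational_fd: np.ndarray
    rotational_fd: np.ndarray
    mean_translational: float
    mean_rotational: float


def framewise_displacement(motion: np.ndarray, rotation_unit: str = "deg") -> FdSummary:
    """Per-frame and mean FD from a 6-column motion table.

    Columns 0-2 are translations in mm, columns 3-5 rotations in
    ``rotation_unit`` ("deg" or "rad"; radians are converted to degrees).
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    trans = motion[:, :3]
    rot = motion[:, 3:]
    if rotation_unit == "rad":
        rot = np.degrees(rot)
    elif rotation_unit != "deg":
        raise ValueError("rotation_unit must be 'deg' or 'rad'")
    n = motion.shape[0]
    t_fd = np.zeros(n)
    r_fd = np.zeros(n)
    t_fd[1:] = np.mean(np.abs(np.diff(trans, axis=0)), axis=1)
    r_fd[1:] = np.mean(np.abs(np.diff(rot, axis=0)), axis=1)
    return FdSummary(
        translational_fd=t_fd,
        rotational_fd=r_fd,
        mean_translational=float(t_fd[1:].mean()) if n > 1 else 0.0,
        mean_rotational=float(r_fd[1:].mean()) if n > 1 else 0.0,
    )


@dataclass
class NuisanceSet:
    """Nuisance design matrix plus a label per column."""

    columns: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.columns = np.atleast_2d(np.asarray(self.columns, float))
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("one label per column required")

    @property
    def n_samples(self) -> int:
        return self.columns.shape[0]


def build_nuisance(design: TaskDesign, motion: np.ndarray | None = None,
                   extra: np.ndarray | None = None,
                   extra_labels: list | None = None,
                   include_task: bool = True,
                   include_dct: bool = True,
                   hrf: np.ndarray | None = None,
                   highpass_cutoff: float = 1.0 / 128.0) -> NuisanceSet:
    """Assemble the joint nuisance matrix on the retained grid.

    Columns: task regressor (boxcar (x) HRF), six motion parameters and their
    backward-difference derivatives (if a motion table is given; it may cover
    the full acquisition, in which case the discarded frames are dropped),
    caller-supplied extra columns (e.g. WM/CSF eigenvariates), and DCT
    high-pass drift columns.  The intercept is added inside
    :func:`residualize`.
    """
    n = design.n_retained
    cols, labels = [], []
    if include_task:
        cols.append(task_regressor(design, hrf)[:, None])
        labels.append("task")
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape[0] == design.n_volumes:
            motion = motion[design.n_discard:]
        if motion.shape != (n, 6):
            raise ValueError("motion table shape does not match the retained grid")
        cols.append(motion)
        labels += [f"motion{i}" for i in range(6)]
        cols.append(motion_derivatives(motion))
        labels += [f"motion_deriv{i}" for i in range(6)]
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, float))
        if extra.shape[0] != n:
            raise ValueError("extra nuisance rows do not match the retained grid")
        cols.append(extra)
        labels += list(extra_labels or [f"extra{i}" for i in range(extra.shape[1])])
    if include_dct:
        dct = dct_highpass_basis(n, design.tr, highpass_cutoff)
        cols.append(dct)
        labels += [f"dct{i}" for i in range(dct.shape[1])]
    columns = np.hstack(cols) if cols else np.empty((n, 0))
    return NuisanceSet(columns=columns, labels=labels)


def residualize(values: np.ndarray, nuisance: NuisanceSet | np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``values`` against the nuisance set.

    An intercept is always included, so residuals are mean-free and
    orthogonal to every nuisance column to machine precision.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    values = np.asarray(values, float)
    one_d = values.ndim == 1
    if one_d:
        values = values[:, None]
    if isinstance(nuisance, NuisanceSet):
        cols, labels = nuisance.columns, list(nuisance.labels)
    else:
        cols = np.atleast_2d(np.asarray(nuisance, float))
        labels = [f"col{i}" for i in range(cols.shape[1])]
    if cols.size == 0:
        cols = np.empty((values.shape[0], 0))
    if cols.shape[0] != values.shape[0]:
        raise ValueError("nuisance rows do not match the series")
    X = np.column_stack([np.ones(values.shape[0]), cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = np.ones((values.shape[0], 1))
        for j in range(cols.shape[1]):
            trial = np.column_stack([kept, cols[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(labels[j])
            else:
                kept = trial
        raise np.linalg.LinAlgError(
            f"nuisance design is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    return resid[:, 0] if one_d else resid
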