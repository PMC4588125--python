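"""Time-varying correlation (TVCC), epoching, slopes and sub-period FC.

The estimator is a kernel-weighted Pearson correlation computed at every
sample: at time t the samples in a window centred on t contribute with
Gaussian weights

    K_h(u) = exp(-u^2 / h),   |u| <= floor(h / 2),

where u is the integer sample offset and h the window size in samples
(h = 24 at TR 0.645 s is a 16 s window; the weight at the window edge
u = 12 is exp(-6)).  A rectangular kernel (all weights 1 on the same
support) is available for comparison; with a rectangular window spanning
the whole series the estimate reduces to the ordinary full-series Pearson r.

Windows at the series edges are truncated to the available samples and the
weights renormalized — no padding or reflection, since invented samples
would bias exactly the epochs the analysis cares about.  Correlations are
Fisher z-transformed (z = atanh r) before any averaging or group testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import TaskDesign

__all__ = [
    "KernelSpec",
    "TvccSeries",
    "kernel_weights",
    "weighted_correlation",
    "tvcc",
    "fisher_z",
    "inverse_fisher_z",
    "epoch_offsets",
    "epoch_average",
    "pointwise_slope",
    "subperiod_fc",
    "DEFAULT_SUBPERIODS",
    "SUBPERIOD_NAMES",
]

_R_CLIP = 1.0 - 1e-7

#: PRE-STIM, EARLY-STIM, LATE-STIM, POST-STIM boundaries, seconds relative
#: to block onset, half-open [lo, hi).
DEFAULT_SUBPERIODS = ((-10.0, 0.0), (0.0, 10.0), (10.0, 20.0), (20.0, 30.0))
SUBPERIOD_NAMES = ("PRE", "EARLY", "LATE", "POST")


@dataclass(frozen=True)
class KernelSpec:
    """Sliding-window kernel: size ``h`` in samples, gaussian or rectangular.

    The support is the symmetric set of integer offsets |u| <= floor(h/2).
    """

    h: float = 24.0
    shape: str = "gaussian"

    def __post_init__(self):
        if self.h < 3:
            raise ValueError("window size h must be at least 3 samples")
        if self.shape not in ("gaussian", "rectangular"):
            raise ValueError("shape must be 'gaussian' or 'rectangular'")

    @property
    def half_width(self) -> int:
        return int(np.floor(self.h / 2.0))

    @classmethod
    def from_seconds(cls, window_s: float, tr: float, shape: str = "gaussian") -> "KernelSpec":
        """Kernel whose size in samples corresponds to ``window_s`` seconds."""
        return cls(h=window_s / tr, shape=shape)


def kernel_weights(spec: KernelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets u in [-floor(h/2), floor(h/2)] and their weights.

    Gaussian: w(u) = exp(-u^2/h); rectangular: w(u) = 1.  Weights are not
    pre-normalized — normalization happens inside the weighted moments, so
    truncated edge windows renormalize automatically.
    """
    hw = spec.half_width
    u = np.arange(-hw, hw + 1)
    if spec.shape == "gaussian":
        w = np.exp(-(u.astype(float) ** 2) / spec.h)
    else:
        w = np.ones_like(u, dtype=float)
    return u, w


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with weight-normalized means.

    r = sum w (x - xbar_w)(y - ybar_w)
        / sqrt( sum w (x - xbar_w)^2 * sum w (y - ybar_w)^2 )

    Requires at least 3 samples with positive weight.  A zero weighted
    variance makes the correlation undefined: NaN is returned (callers mark
    the sample invalid rather than raising).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y, w must have identical shapes")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.count_nonzero(w > 0) < 3:
        raise ValueError("need at least 3 samples with positive weight")
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    dx = x - xm
    dy = y - ym
    vx = (w * dx * dx).sum()
    vy = (w * dy * dy).sum()
    if vx <= 0 or vy <= 0:
        return float("nan")
    r = (w * dx * dy).sum() / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class TvccSeries:
    """Per-sample correlation r(t) and Fisher z(t) for one ROI pair."""

    pair: tuple
    r: np.ndarray
    z: np.ndarray
    kernel: KernelSpec
    valid_mask: np.ndarray


def _window_sums(a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Centered moving weighted sum with truncation at the edges."""
    # 'same' convolution with the (odd-length, symmetric) kernel; samples
    # outside the series simply contribute nothing.  scipy's 'same' keeps
    # the length of the first argument even when the kernel is longer.
    from scipy.signal import convolve
    return convolve(a, w, mode="same", method="direct")


def tvcc(x: np.ndarray, y: np.ndarray, spec: KernelSpec = KernelSpec(),
         pair: tuple = ("x", "y")) -> TvccSeries:
    """Sliding-window time-varying correlation at every sample.

    At each sample the kernel is centred there, truncated to the available
    samples, and the weighted correlation computed.  ``valid_mask`` is False
    where fewer than 3 samples fall in the (truncated) window or a weighted
    variance vanishes; r is NaN there.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    hw = spec.half_width
    if n < spec.h:
        raise ValueError(f"series length {n} is shorter than window size h={spec.h}")
    _, w = kernel_weights(spec)
    ones = np.ones(n)
    sw = _window_sums(ones, w)
    sx = _window_sums(x, w)
    sy = _window_sums(y, w)
    sxx = _window_sums(x * x, w)
    syy = _window_sums(y * y, w)
    sxy = _window_sums(x * y, w)
    mx = sx / sw
    my = sy / sw
    cov = sxy / sw - mx * my
    vx = sxx / sw - mx * mx
    vy = syy / sw - my * my
    # number of samples actually inside each truncated window
    counts = _window_sums(ones, np.ones(2 * hw + 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    valid = (counts >= 3) & (vx > 1e-300) & (vy > 1e-300) & np.isfinite(r)
    r = np.where(valid, np.clip(r, -1.0, 1.0), np.nan)
    z = fisher_z(r)
    return TvccSeries(pair=tuple(pair), r=r, z=z, kernel=spec, valid_mask=valid)


def fisher_z(r):
    """Fisher z-transform, z = atanh(r), with |r| clipped to 1 - 1e-7."""
    r = np.asarray(r, float)
    with np.errstate(invalid="ignore"):
        z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return z if z.ndim else float(z)


def inverse_fisher_z(z):
    """Inverse Fisher transform, r = tanh(z)."""
    out = np.tanh(np.asarray(z, float))
    return out if out.ndim else float(out)


def epoch_offsets(tr: float, window: tuple = (-10.0, 30.0)) -> np.ndarray:
    """Integer sample offsets k with window_lo <= k*tr < window_hi."""
    lo, hi = window
    k_lo = int(np.ceil(lo / tr - 1e-9))
    k_hi = int(np.ceil(hi / tr - 1e-9)) - 1
    return np.arange(k_lo, k_hi + 1)


def epoch_average(series: np.ndarray, design: TaskDesign,
                  window: tuple = (-10.0, 30.0)) -> tuple[np.ndarray, np.ndarray]:
    """Average a retained-grid series across block cycles.

    Each onset maps to its nearest retained sample; the segment at offsets
    ``epoch_offsets(tr, window)`` is extracted per cycle and the cycles are
    averaged element-wise.  Returns ``(rel_times, mean_segment)`` where
    ``rel_times = offsets * tr`` (0 = onset sample).
    """
    series = np.asarray(series, float)
    offsets = epoch_offsets(design.tr, window)
    segments = []
    for c, onset_idx in enumerate(design.onset_indices()):
        idx = onset_idx + offsets
        if idx[0] < 0 or idx[-1] >= series.shape[0]:
            raise ValueError(
                f"epoch window {window} for cycle {c + 1} (onset sample "
                f"{onset_idx}) falls outside the retained series")
        segments.append(series[idx])
    return offsets * design.tr, np.mean(segments, axis=0)


def pointwise_slope(rel_times: np.ndarray, values: np.ndarray,
                    fit_window_s: float = 16.0) -> np.ndarray:
    """Least-squares slope (units per second) in a centred rectangular window.

    At each sample the ordinary least-squares slope of value against time is
    fitted over the samples within the centred window of ``fit_window_s``
    seconds (support floor(window/tr/2) samples each side, truncated at the
    epoch edges).  Windows with fewer than 3 samples yield NaN.
    """
    rel_times = np.asarray(rel_times, float)
    values = np.asarray(values, float)
    if rel_times.shape != values.shape:
        raise ValueError("rel_times and values must match")
    tr = float(np.median(np.diff(rel_times)))
    hw = int(np.floor(fit_window_s / tr / 2.0))
    n = values.size
    out = np.full(n, np.nan)
    for i in range(n):
        lo = max(0, i - hw)
        hi = min(n, i + hw + 1)
        if hi - lo < 3:
            continue
        t = rel_times[lo:hi]
        v = values[lo:hi]
        tc = t - t.mean()
        denom = (tc * tc).sum()
        if denom <= 0:
            continue
        out[i] = (tc * (v - v.mean())).sum() / denom
    return out


def subperiod_fc(x: np.ndarray, y: np.ndarray, design: TaskDesign,
                 boundaries: tuple = DEFAULT_SUBPERIODS) -> np.ndarray:
    """Cycle-averaged Fisher-z FC in each experimental sub-period.

    For every cycle and sub-period the *plain* (unweighted) Pearson
    correlation is computed over the samples whose relative time falls in the
    half-open interval, Fisher z-transformed, and the three cycle values are
    averaged, giving one z per sub-period.  A zero-variance window yields NaN
    for that cell (propagating to the cycle mean).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    onsets = design.onset_indices()
    out = np.full(len(boundaries), np.nan)
    for j, (lo, hi) in enumerate(boundaries):
        zs = []
        for c, onset_idx in enumerate(onsets):
            idx = onset_idx + epoch_offsets(design.tr, (lo, hi))
            if idx[0] < 0 or idx[-1] >= x.shape[0]:
                raise ValueError(
                    f"sub-period [{lo}, {hi}) s of cycle {c + 1} falls outside "
                    "the retained series")
            xi, yi = x[idx], y[idx]
            if xi.std() == 0 or yi.std() == 0:
                zs.append(np.nan)
                continue
            r = np.corrcoef(xi, yi)[0, 1]
            zs.append(fisher_z(r))
        out[j] = np.mean(zs)
    return out
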