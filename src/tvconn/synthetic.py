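"""Synthetic multi-subject ROI BOLD cohorts with known ground truth.

The generator emulates the block-designed checkerboard experiment: sustained
boxcar-convolved-HRF activation in the "visual" ROIs, AR(1) noise whose
instantaneous between-ROI correlation follows a prescribed trajectory
rho(t), second-order polynomial drift, and motion-parameter tables realized
as Gaussian random walks.

Time-varying correlation is imposed by mixing a shared and a unique AR
process with identical autocovariance,

    x_i(t) = sqrt(lam(t)) * c(t) + sqrt(1 - lam(t)) * e_i(t),

which gives instantaneous correlation exactly lam(t) = |rho(t)| (the sign of
rho is applied to the shared component of the pair's second member).  Because
the shared and unique processes have the same autocovariance, the mixture's
marginal variance is 1 at every sample and AR smoothing does not distort the
target correlation.  Each ROI may carry the shared component of at most a
few pairs; the per-ROI mixing weights must sum below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import TaskDesign, checkerboard_design
from .extract import RoiTimeSeries
from .preprocess import HrfParams, canonical_hrf

__all__ = [
    "CorrelationTrajectory",
    "SyntheticConfig",
    "SyntheticDataset",
    "mixing_weight_from_rho",
    "constant_trajectory",
    "transient_decrease_trajectory",
    "default_trajectories",
    "simulate_subject",
    "simulate_cohort",
    "embed_in_volumes",
    "fitting_geometry",
]

DEFAULT_ROI_NAMES = ("LMOG", "RMOG", "LFuG", "RFuG", "mPFC", "PCC")

_RHO_MAX = 0.95


@dataclass(frozen=True)
class CorrelationTrajectory:
    """Target instantaneous correlation rho(t) for one ROI pair.

    ``times`` (seconds from scan start) and ``rho`` define knots; the
    trajectory is piecewise-linear between knots and held constant beyond
    the first/last knot.
    """

    pair: tuple
    times: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "rho", np.asarray(self.rho, float))
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ValueError("pair must name two distinct ROIs")
        if self.times.shape != self.rho.shape or self.times.ndim != 1:
            raise ValueError("times and rho must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(np.abs(self.rho) >= 1):
            raise ValueError("|rho| must be < 1 everywhere")

    def rho_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation, edge-held outside the knots."""
        return np.interp(np.asarray(t, float), self.times, self.rho)


def mixing_weight_from_rho(rho: float) -> float:
    """Mixing weight lam with shared/unique construction correlation = rho.

    Two standardized series ``x_i = sqrt(lam)*c + sqrt(1-lam)*e_i`` with
    independent unit-variance c, e_i of identical autocovariance have
    instantaneous correlation lam.  For a negative target the weight is
    |rho| and the sign is applied to one member's shared component.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    return abs(float(rho))


def constant_trajectory(pair: tuple, design: TaskDesign, rho: float) -> CorrelationTrajectory:
    """A flat rho(t) spanning the whole scan."""
    total = design.n_volumes * design.tr
    return CorrelationTrajectory(pair=tuple(pair), times=np.array([0.0, total]),
                                 rho=np.array([rho, rho]))


def transient_decrease_trajectory(pair: tuple, design: TaskDesign,
                                  high: float = 0.6, low: float = 0.2,
                                  decline: tuple = (5.0, 15.0),
                                  hold_until: float = 20.0,
                                  recover_at: float = 25.0) -> CorrelationTrajectory:
    """rho(t) that dips within each task block and recovers afterwards.

    Per cycle: hold ``high`` until onset+decline[0], decline linearly to
    ``low`` by onset+decline[1], hold until onset+hold_until, recover to
    ``high`` by onset+recover_at.  Emulates the observed transient FC
    decrease during the late stimulation period.
    """
    times = [0.0]
    rho = [high]
    for onset in design.onsets:
        times += [onset + decline[0], onset + decline[1],
                  onset + hold_until, onset + recover_at]
        rho += [high, low, low, high]
    total = design.n_volumes * design.tr
    times.append(total)
    rho.append(high)
    return CorrelationTrajectory(pair=tuple(pair), times=np.array(times),
                                 rho=np.array(rho))


def default_trajectories(design: TaskDesign) -> list:
    """Default ground truth: a transient dip on one MOG-FuG pair per
    hemisphere (each ROI carries one shared component, so the mixing
    weights stay within bounds)."""
    return [
        transient_decrease_trajectory(("LMOG", "LFuG"), design),
        transient_decrease_trajectory(("RMOG", "RFuG"), design),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to generate one cohort reproducibly.

    ``activation_amplitude`` and ``motion_sd`` are (mean, between-subject
    s.d.) and (translation mm, rotation deg) pairs respectively;
    ``rho_subject_sd`` jitters each subject's trajectory level (clipped to
    the valid correlation range).
    """

    n_subjects: int = 20
    seed: int = 0
    design: TaskDesign = field(default_factory=checkerboard_design)
    roi_names: tuple = DEFAULT_ROI_NAMES
    activated_rois: tuple = DEFAULT_ROI_NAMES[:4]
    activation_amplitude: tuple = (1.0, 0.2)
    trajectories: tuple | None = None
    ar_coefficient: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    motion_sd: tuple = (0.0752, 0.0376)
    rho_subject_sd: float = 0.05
    hrf: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self):
        object.__setattr__(self, "roi_names", tuple(self.roi_names))
        object.__setattr__(self, "activated_rois", tuple(self.activated_rois))
        if self.trajectories is None:
            object.__setattr__(self, "trajectories",
                               tuple(default_trajectories(self.design)))
        else:
            object.__setattr__(self, "trajectories", tuple(self.trajectories))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not set(self.activated_rois) <= set(self.roi_names):
            raise ValueError("activated_rois must be a subset of roi_names")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for name, val in [("noise_sd", self.noise_sd),
                          ("drift_amplitude", self.drift_amplitude),
                          ("rho_subject_sd", self.rho_subject_sd),
                          ("activation amplitude s.d.", self.activation_amplitude[1])]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.motion_sd):
            raise ValueError("motion_sd values must be >= 0")
        for traj in self.trajectories:
            for roi in traj.pair:
                if roi not in self.roi_names:
                    raise ValueError(
                        f"trajectory pair {traj.pair} names unknown ROI '{roi}'")
        # the mixing construction needs sum_p |rho_p(t)| < 1 at every ROI
        t = self.design.times_full()
        for roi in self.roi_names:
            total = np.zeros_like(t)
            for traj in self.trajectories:
                if roi in traj.pair:
                    total += np.abs(traj.rho_at(t))
            if np.any(total > _RHO_MAX):
                raise ValueError(
                    f"summed |rho(t)| at ROI '{roi}' exceeds {_RHO_MAX}; the "
                    "shared/unique mixing construction cannot realize it")

    def pair_count_bound(self, roi: str) -> int:
        return sum(roi in traj.pair for traj in self.trajectories)


@dataclass
class SyntheticDataset:
    """A simulated cohort plus its per-subject ground truth."""

    subjects: list
    truth: list
    motion: list
    config: SyntheticConfig

    def __post_init__(self):
        if not (len(self.subjects) == len(self.truth) == len(self.motion)):
            raise ValueError("one truth and motion record per subject required")


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series of length n."""
    e = rng.standard_normal(n) * np.sqrt(1.0 - phi * phi)
    e[0] = rng.standard_normal()  # stationary start
    return lfilter([1.0], [1.0, -phi], e)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(subject_index))))


def evoked_response(design: TaskDesign, hrf_params: HrfParams = HrfParams()) -> np.ndarray:
    """Unit-peak evoked waveform (boxcar (x) HRF) on the full volume grid."""
    h = canonical_hrf(hrf_params, design.tr)
    resp = np.convolve(design.boxcar(), h)[: design.n_volumes]
    peak = resp.max()
    return resp / peak if peak > 0 else resp


def simulate_subject(config: SyntheticConfig, subject_index: int):
    """One subject's ROI series plus the realized ground-truth record.

    Deterministic given (config.seed, subject_index).  Returns
    ``(RoiTimeSeries, truth, motion)`` where truth holds the realized
    activation amplitudes and each pair's realized rho(t) on the full grid,
    and motion is the (n_volumes x 6) random-walk parameter table.
    """
    rng = _subject_rng(config.seed, subject_index)
    design = config.design
    n = design.n_volumes
    rois = config.roi_names

    # per-subject activation amplitudes
    amp_mean, amp_sd = config.activation_amplitude
    amplitudes = {roi: (amp_mean + amp_sd * rng.standard_normal()
                        if roi in config.activated_rois else 0.0)
                  for roi in rois}

    # per-subject trajectory levels, clipped so the mixing stays feasible
    t_full = design.times_full()
    realized = {}
    for traj in config.trajectories:
        delta = config.rho_subject_sd * rng.standard_normal()
        bound = _RHO_MAX / max(config.pair_count_bound(r) for r in traj.pair)
        rho_t = np.clip(traj.rho_at(t_full) + delta, -bound, bound)
        realized[traj.pair] = rho_t

    # noise: one shared AR process per trajectory pair, one unique per ROI,
    # mixed sample-wise so the instantaneous correlation equals rho(t)
    shared = {pair: _ar1(rng, n, config.ar_coefficient) for pair in realized}
    unique = {roi: _ar1(rng, n, config.ar_coefficient) for roi in rois}
    noise = {}
    for roi in rois:
        lam_total = np.zeros(n)
        contrib = np.zeros(n)
        for pair, rho_t in realized.items():
            if roi not in pair:
                continue
            lam = np.abs(rho_t)
            sign = np.where(rho_t < 0, -1.0, 1.0) if roi == pair[1] else 1.0
            contrib += sign * np.sqrt(lam) * shared[pair]
            lam_total += lam
        noise[roi] = np.sqrt(np.clip(1.0 - lam_total, 0.0, None)) * unique[roi] + contrib

    evoked = evoked_response(design, config.hrf)
    tau = np.linspace(-1.0, 1.0, n)
    values = np.empty((n, len(rois)))
    for j, roi in enumerate(rois):
        coeffs = rng.standard_normal(3)
        drift = config.drift_amplitude * (coeffs[0] + coeffs[1] * tau
                                          + coeffs[2] * tau ** 2)
        values[:, j] = (amplitudes[roi] * evoked
                        + config.noise_sd * noise[roi] + drift)

    # motion: Gaussian random walk, first frame at the origin
    steps = rng.standard_normal((n, 6))
    steps[:, :3] *= config.motion_sd[0]
    steps[:, 3:] *= config.motion_sd[1]
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)

    series = RoiTimeSeries(subject_id=f"sub-{subject_index:03d}",
                           roi_names=list(rois), tr=design.tr,
                           values=values, t0=0.0)
    truth = {
        "subject_id": series.subject_id,
        "amplitudes": amplitudes,
        "rho": realized,
    }
    return series, truth, motion


def simulate_cohort(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate ``config.n_subjects`` independent subjects."""
    subjects, truths, motions = [], [], []
    for i in range(config.n_subjects):
        series, truth, motion = simulate_subject(config, i)
        subjects.append(series)
        truths.append(truth)
        motions.append(motion)
    return SyntheticDataset(subjects=subjects, truth=truths, motion=motions,
                            config=config)


# -- optional 4D-volume embedding -----------------------------------------

def fitting_geometry(specs, voxel_size: float = 3.0, pad: float = 9.0):
    """A grid (shape, affine) whose field of view covers all the spheres."""
    centers = np.array([[s.x, s.y, s.z] for s in specs])
    radii = np.array([s.radius for s in specs])
    lo = (centers - (radii + pad)[:, None]).min(axis=0)
    hi = (centers + (radii + pad)[:, None]).max(axis=0)
    shape = tuple(int(np.ceil((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = lo
    return shape, affine


def embed_in_volumes(dataset: SyntheticDataset, roi_specs, shape=None,
                     affine=None, voxel_noise_sd: float = 0.1,
                     seed: int | None = None):
    """Embed each subject's ROI series into a small 4D NIfTI image.

    Every voxel inside an ROI sphere carries that ROI's series plus i.i.d.
    Gaussian voxel noise; background voxels carry pure noise.  Spheres must
    not overlap.  Returns ``(images, coord_table)`` where images is one
    ``Nifti1Image`` per subject (TR recorded in the header) and coord_table
    a DataFrame with columns name, x, y, z, radius.
    """
    import nibabel as nib
    from .extract import make_sphere_mask

    if shape is None or affine is None:
        shape, affine = fitting_geometry(roi_specs)
    masks = {s.name: make_sphere_mask(s, shape, affine) for s in roi_specs}
    combined = np.zeros(shape, dtype=int)
    for m in masks.values():
        combined += m.astype(int)
    if np.any(combined > 1):
        raise ValueError("ROI spheres overlap on this grid")

    base_seed = dataset.config.seed if seed is None else seed
    tr = dataset.config.design.tr
    images = []
    for i, series in enumerate(dataset.subjects):
        rng = np.random.default_rng(np.random.SeedSequence((int(base_seed), 7919, i)))
        n_t = series.n_samples
        data = rng.standard_normal((*shape, n_t)) * voxel_noise_sd
        for spec in roi_specs:
            if spec.name not in series.roi_names:
                raise ValueError(f"ROI '{spec.name}' not present in the dataset")
            col = series.column(spec.name)
            data[masks[spec.name]] += col[None, :]
        img = nib.Nifti1Image(data.astype(np.float32), affine)
        img.header.set_zooms((*np.diag(affine)[:3], tr))
        images.append(img)
    coord_table = pd.DataFrame(
        [(s.name, s.x, s.y, s.z, s.radius) for s in roi_specs],
        columns=["name", "x", "y", "z", "radius"])
    return images, coord_table


# -- structured-text truth round trip --------------------------------------

def write_truth(dataset: SyntheticDataset, path) -> None:
    """Truth as key/value lines plus per-pair knot tables (plain text)."""
    design = dataset.config.design
    t_ret = design.times_retained()
    with open(path, "w") as fh:
        fh.write(f"n_subjects={len(dataset.subjects)}\n")
        for truth in dataset.truth:
            fh.write(f"[subject {truth['subject_id']}]\n")
            for roi, amp in truth["amplitudes"].items():
                fh.write(f"amplitude.{roi}={amp!r}\n")
            for pair, rho_t in truth["rho"].items():
                rho_ret = np.interp(t_ret, design.times_full(), rho_t)
                vals = ",".join(f"{v:.6f}" for v in rho_ret)
                fh.write(f"rho.{pair[0]}-{pair[1]}={vals}\n")


def truth_rho_on_retained_grid(dataset: SyntheticDataset, pair: tuple) -> np.ndarray:
    """(subjects x retained samples) realized rho(t) for one pair."""
    design = dataset.config.design
    t_ret = design.times_retained()
    rows = []
    for truth in dataset.truth:
        rho_t = truth["rho"][tuple(pair)]
        rows.append(np.interp(t_ret, design.times_full(), rho_t))
    return np.asarray(rows)
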