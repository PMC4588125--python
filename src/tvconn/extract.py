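"""ROI definitions, spherical masks and time-series extraction from 4D images.

ROIs are spheres given by a world-space (MNI, mm) centre and radius; a voxel
belongs to the sphere when its *centre*, mapped through the image affine,
lies within the radius (<=).  Two summary series are available per ROI: the
arithmetic mean over voxels, and the first eigenvariate (dominant left
singular vector of the voxel matrix after nuisance adjustment, scaled to the
ROI's root-mean-square amplitude).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "RoiSpec",
    "RoiTimeSeries",
    "read_roi_table",
    "write_roi_table",
    "make_sphere_mask",
    "extract_mean",
    "extract_first_eigenvariate",
    "extract_roi_series",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_motion_table",
]

#: The six-ROI set of the checkerboard experiment: four activated visual
#: regions (bilateral middle occipital and fusiform gyri) and two inactivated
#: default-mode regions (mPFC, PCC), 8 mm spheres at MNI coordinates.
CHECKERBOARD_ROIS = (
    ("LMOG", -21.0, -91.0, -5.0, 8.0),
    ("RMOG", 24.0, -91.0, 1.0, 8.0),
    ("LFuG", -33.0, -61.0, -14.0, 8.0),
    ("RFuG", 36.0, -58.0, -11.0, 8.0),
    ("mPFC", 0.0, 51.0, 32.0, 8.0),
    ("PCC", -5.0, -49.0, 40.0, 8.0),
)


@dataclass(frozen=True)
class RoiSpec:
    """A spherical ROI: name, world-space centre (mm) and radius (mm)."""

    name: str
    x: float
    y: float
    z: float
    radius: float = 8.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], float)


@dataclass
class RoiTimeSeries:
    """Per-subject ROI time-series matrix on a uniform TR grid.

    ``values`` is (time x ROI); ``t0`` is the time in seconds of the first
    row relative to the scan start (0 for a raw acquisition, n_discard*tr
    after volume discarding).
    """

    subject_id: str
    roi_names: list
    tr: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.values.shape[0] < 2:
            raise ValueError("need more than one time sample")
        if self.values.shape[1] != len(self.roi_names):
            raise ValueError("one column per ROI name required")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing or non-finite values are not allowed")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.tr

    def column(self, roi: str) -> np.ndarray:
        return self.values[:, self.roi_names.index(roi)]


def read_roi_table(path) -> list:
    """ROI table (tab- or comma-delimited, header name,x,y,z,radius)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "x", "y", "z", "radius"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table must have columns {sorted(required)}")
    specs = [RoiSpec(str(r.name), float(r.x), float(r.y), float(r.z),
                     float(r.radius)) for r in df.itertuples(index=False)]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("ROI names must be unique")
    return specs


def write_roi_table(specs, path) -> None:
    pd.DataFrame(
        [(s.name, s.x, s.y, s.z, s.radius) for s in specs],
        columns=["name", "x", "y", "z", "radius"],
    ).to_csv(path, sep="\t", index=False)


def make_sphere_mask(spec: RoiSpec, shape, affine) -> np.ndarray:
    """Boolean voxel mask of the sphere on the image grid.

    A voxel is included when its world-space centre (affine applied to the
    0-based voxel index) lies within Euclidean distance ``radius`` of the
    sphere centre.  Raises if the mask would be empty (sphere outside the
    field of view).
    """
    affine = np.asarray(affine, float)
    inv = np.linalg.inv(affine)  # raises for a singular affine
    del inv
    shape = tuple(shape[:3])
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    world = vox @ affine.T
    d2 = ((world[:, :3] - spec.center) ** 2).sum(axis=1)
    mask = (d2 <= spec.radius ** 2).reshape(shape)
    if not mask.any():
        raise ValueError(f"ROI '{spec.name}' produced an empty mask "
                         "(sphere outside the field of view)")
    return mask


def _voxel_matrix(series_4d, mask: np.ndarray) -> np.ndarray:
    """(time x voxel) matrix for the masked voxels of a 4D image or array."""
    if isinstance(series_4d, (nib.Nifti1Image, nib.Nifti2Image)):
        data = np.asarray(series_4d.dataobj)
    else:
        data = np.asarray(series_4d)
    if data.ndim != 4:
        raise ValueError("expected a 4D image (x, y, z, time)")
    return data[mask].T


def extract_mean(series_4d, mask: np.ndarray) -> np.ndarray:
    """Per-time arithmetic mean over the masked voxels."""
    return _voxel_matrix(series_4d, mask).mean(axis=1)


def extract_first_eigenvariate(series_4d, mask: np.ndarray,
                               adjust: np.ndarray | None = None) -> np.ndarray:
    """First eigenvariate of the ROI's voxel matrix after nuisance adjustment.

    The nuisance matrix (plus an intercept) is regressed from every voxel
    series; the first left singular vector of the residual matrix is scaled
    to the root-mean-square amplitude of the ROI (singular value / sqrt(n
    voxels)) and sign-aligned so that its correlation with the ROI-mean
    residual series is non-negative (ties broken by positive correlation
    with the first voxel's residual).
    """
    Y = _voxel_matrix(series_4d, mask)
    n_t, n_v = Y.shape
    X = np.ones((n_t, 1))
    if adjust is not None:
        adjust = np.atleast_2d(np.asarray(adjust, float))
        if adjust.shape[0] != n_t:
            raise ValueError("nuisance rows must match the time dimension")
        X = np.column_stack([X, adjust])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("nuisance matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    eig = U[:, 0] * s[0] / np.sqrt(n_v)
    ref = R.mean(axis=1)
    c = float(eig @ ref)
    if c == 0:
        c = float(eig @ R[:, 0])
    if c < 0:
        eig = -eig
    return eig


def extract_roi_series(img, specs, method: str = "eigenvariate",
                       adjust: np.ndarray | None = None,
                       subject_id: str = "subject", tr: float | None = None,
                       t0: float = 0.0) -> RoiTimeSeries:
    """Extract all ROIs from one 4D image into a :class:`RoiTimeSeries`."""
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    cols = []
    for spec in specs:
        mask = make_sphere_mask(spec, img.shape[:3], img.affine)
        if method == "mean":
            cols.append(extract_mean(img, mask))
        elif method == "eigenvariate":
            cols.append(extract_first_eigenvariate(img, mask, adjust))
        else:
            raise ValueError("method must be 'mean' or 'eigenvariate'")
    return RoiTimeSeries(subject_id=subject_id,
                         roi_names=[s.name for s in specs], tr=tr,
                         values=np.column_stack(cols), t0=t0)


# -- plain-text round trip -------------------------------------------------

def write_roi_timeseries(series: RoiTimeSeries, path) -> None:
    """Tab-delimited text: a time column (seconds) plus one column per ROI."""
    df = pd.DataFrame(series.values, columns=series.roi_names)
    df.insert(0, "time", series.times())
    with open(path, "w") as fh:
        fh.write(f"# subject_id={series.subject_id}\ttr={series.tr!r}\t"
                 f"t0={series.t0!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_roi_timeseries(path) -> RoiTimeSeries:
    with open(path) as fh:
        header = fh.readline()
        body = fh.read()
    meta = dict(item.split("=", 1) for item in header.lstrip("# ").strip().split("\t"))
    df = pd.read_csv(io.StringIO(body), sep="\t")
    return RoiTimeSeries(
        subject_id=meta.get("subject_id", "subject"),
        roi_names=[c for c in df.columns if c != "time"],
        tr=float(meta["tr"]),
        values=df.drop(columns="time").to_numpy(),
        t0=float(meta.get("t0", 0.0)),
    )


def read_motion_table(path) -> np.ndarray:
    """Whitespace-delimited 6-column motion-parameter table."""
    table = np.loadtxt(path)
    table = np.atleast_2d(table)
    if table.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns")
    return table
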