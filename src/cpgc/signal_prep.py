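"""Temporal preprocessing of ROI time series and head-motion QC.

Covers the steps that are defined analytically rather than by an external
imaging tool: band-pass filtering (0.01-0.08 Hz), nuisance regression
(motion, drift, tissue signals, optional global signal), ROI extraction from
4D volumes, per-column standardization, and framewise displacement (FD).

The canonical pipeline order is filter -> nuisance regression -> standardize.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .defaults import DEFAULTS


class PreprocessError(ValueError):
    pass


@dataclass
class RoiTimeSeriesSet:
    """Multivariate ROI series for one subject: T frames x k ROIs.

    ``data[t, j]`` is the value of ROI ``labels[j]`` at frame ``t``;
    ``tr`` is the sampling interval in seconds.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    labels: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be T x k")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeriesSet":
        return replace(self, data=np.asarray(data, dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.labels).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subject_id: str, tr: float) -> "RoiTimeSeriesSet":
        df = pd.read_csv(path, sep="\t")
        return cls(subject_id, df.to_numpy(dtype=float), tr, list(df.columns))


@dataclass
class FdResult:
    """Per-frame framewise displacement (mm) and its mean over all frames."""

    fd: np.ndarray
    mean_fd: float


# ---------------------------------------------------------------------------
# filtering

def bandpass_array(data: np.ndarray, tr: float,
                   low: float | None = None, high: float | None = None) -> np.ndarray:
    """Ideal (frequency-domain) band-pass: zero every FFT bin outside [low, high].

    Deterministic and exact at any length; bins with low <= f <= high are
    kept, everything else (including DC when low > 0) is removed.
    """
    low = DEFAULTS["band_low"] if low is None else float(low)
    high = DEFAULTS["band_high"] if high is None else float(high)
    nyquist = 0.5 / tr
    if not (0 <= low < high):
        raise PreprocessError("need 0 <= low < high")
    if high >= nyquist:
        raise PreprocessError(
            f"high cutoff {high} Hz >= Nyquist {nyquist} Hz at TR {tr}")
    data = np.asarray(data, dtype=float)
    T = data.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(data, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def bandpass_filter(ts: RoiTimeSeriesSet, low: float | None = None,
                    high: float | None = None) -> RoiTimeSeriesSet:
    return ts.with_data(bandpass_array(ts.data, ts.tr, low, high))


# ---------------------------------------------------------------------------
# nuisance regression

def regress_nuisance_array(data: np.ndarray,
                           confounds: np.ndarray | None) -> np.ndarray:
    """Residualize each column on the confound columns plus an intercept.

    Residuals are orthogonal to every confound column.  A rank-deficient
    confound matrix is rejected, naming the collinear columns.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[0]
    if confounds is None or (hasattr(confounds, "size") and confounds.size == 0):
        return data - data.mean(axis=0)
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != T:
        raise PreprocessError("confound rows do not match series length")
    if C.shape[1] >= T:
        raise PreprocessError("more confounds than time points")
    X = np.c_[np.ones(T), C]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = np.ones((T, 1))
        for j in range(C.shape[1]):
            cand = np.c_[kept, C[:, j]]
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(j)
            else:
                kept = cand
        raise PreprocessError(
            f"confound matrix rank-deficient; collinear column(s) {bad}")
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    return data - X @ beta


def regress_nuisance(ts: RoiTimeSeriesSet,
                     confounds: np.ndarray | None) -> RoiTimeSeriesSet:
    return ts.with_data(regress_nuisance_array(ts.data, confounds))


def linear_drift(T: int) -> np.ndarray:
    """Unit-scaled linear drift regressor over T frames."""
    return np.linspace(-1.0, 1.0, T)


# ---------------------------------------------------------------------------
# extraction and standardization

def extract_roi_series(volume4d: np.ndarray, masks,
                       tr: float, subject_id: str = "") -> RoiTimeSeriesSet:
    """Mean signal within each ROI mask at every frame.

    ``volume4d`` is an (nx, ny, nz, T) array on the same grid as the masks.
    """
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4:
        raise PreprocessError("expected a 4D array (x, y, z, t)")
    cols, labels = [], []
    for m in masks:
        if m.empty:
            raise PreprocessError(f"ROI {m.name!r}: empty mask")
        if m.shape != vol.shape[:3]:
            raise PreprocessError(f"ROI {m.name!r}: mask grid does not match volume")
        vox = vol[tuple(m.indices.T)]  # (n_vox, T)
        cols.append(vox.mean(axis=0))
        labels.append(m.name)
    return RoiTimeSeriesSet(subject_id, np.stack(cols, axis=1), tr, labels)


def extract_from_nifti(path, masks, subject_id: str = "") -> RoiTimeSeriesSet:
    import nibabel as nib

    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else DEFAULTS["tr"]
    return extract_roi_series(np.asarray(img.dataobj), masks, tr, subject_id)


def standardize_array(data: np.ndarray, labels=None) -> np.ndarray:
    """Columnwise z-scoring with sample (T-1) variance; rejects constants."""
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=0, ddof=1)
    zero = np.where(sd < 1e-300)[0]
    if len(zero):
        names = [labels[i] for i in zero] if labels else list(zero)
        raise PreprocessError(f"zero-variance column(s): {names}")
    return (data - data.mean(axis=0)) / sd


def standardize(ts: RoiTimeSeriesSet) -> RoiTimeSeriesSet:
    return ts.with_data(standardize_array(ts.data, ts.labels))


# ---------------------------------------------------------------------------
# framewise displacement

def framewise_displacement(motion: np.ndarray,
                           head_radius: float | None = None) -> FdResult:
    """FD_i = |Δdx| + |Δdy| + |Δdz| + |Δα| + |Δβ| + |Δγ| per frame.

    ``motion`` is T x 6: three translations in mm and three rotations in
    degrees.  Rotational differences are converted to millimetres as arc
    length on a sphere of ``head_radius`` (default 50 mm) before summation.
    The first frame has no predecessor: FD_1 := 0, and the mean is taken
    over all T frames including it.
    """
    head_radius = DEFAULTS["head_radius_mm"] if head_radius is None else float(head_radius)
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise PreprocessError("motion must be T x 6 (3 translations mm, 3 rotations deg)")
    if motion.shape[0] < 2:
        raise PreprocessError("need at least 2 frames for framewise displacement")
    d = np.diff(motion, axis=0)
    trans = np.abs(d[:, :3]).sum(axis=1)
    rot = (head_radius * np.pi / 180.0) * np.abs(d[:, 3:]).sum(axis=1)
    fd = np.r_[0.0, trans + rot]
    return FdResult(fd=fd, mean_fd=float(fd.mean()))


def load_motion(path) -> np.ndarray:
    """Read a 6-column realignment-parameter file (whitespace or tab)."""
    return np.loadtxt(path)
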