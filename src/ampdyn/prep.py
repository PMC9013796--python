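"""Subject-level preprocessing of resting-state 4D time-series images.

Implements the stages applied after spatial standardisation, in fixed order:

1. discard of initial volumes (scanner equilibration),
2. gross-motion exclusion check (translation/rotation range limits),
3. nuisance regression (intercept, linear trend, Friston-24 motion
   expansion, white-matter and CSF mean signals; no global signal),
4. motion scrubbing by framewise displacement (Jenkinson) with
   cubic-spline replacement of flagged timepoints,
5. ideal (frequency-domain) band-pass filtering,
6. isotropic Gaussian spatial smoothing.

Images are held as :class:`TimeSeriesImage` (x, y, z, t arrays plus voxel
size and repetition time); motion traces as :class:`MotionTrace` with
translations in millimetres and rotations in radians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

log = logging.getLogger("ampdyn")

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# data containers


@dataclass
class TimeSeriesImage:
    """A 4D voxel grid: spatial axes first, time last."""

    data: np.ndarray  # (x, y, z, t), float
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    mask: np.ndarray | None = None  # (x, y, z) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def timeseries_matrix(self) -> np.ndarray:
        """Return the data as (t, n_voxels), C-ordered voxels."""
        return self.data.reshape(-1, self.n_timepoints).T


@dataclass
class MotionTrace:
    """Rigid-body motion parameters per timepoint.

    Columns 0-2 are translations in mm (x, y, z); columns 3-5 are rotations
    in radians about the x, y and z axes.
    """

    params: np.ndarray  # (t, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (timepoints, 6)")
        if not np.isfinite(self.params).all():
            raise ValueError("motion parameters must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class FDSeries:
    """Framewise displacement (mm) per timepoint plus a scrub-flag mask."""

    fd_mm: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.fd_mm.shape, dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)


@dataclass
class PrepConfig:
    """Preprocessing parameters.

    Defaults reproduce the acquisition protocol this package targets: 10
    discarded volumes, 0.01-0.08 Hz pass band, FD-Jenkinson scrub threshold
    0.5 mm with 2 timepoints flagged before and 1 after each bad frame,
    6 mm FWHM smoothing, and exclusion limits of 1.5 mm translation / 1.5
    degrees rotation.
    """

    n_discard: int = 10
    band_hz: tuple[float, float] = (0.01, 0.08)
    fd_threshold_mm: float = 0.5
    scrub_before: int = 2
    scrub_after: int = 1
    fwhm_mm: float = 6.0
    max_trans_mm: float = 1.5
    max_rot_deg: float = 1.5
    fd_sphere_radius_mm: float = 80.0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0.0 <= lo < hi):
            raise ValueError("band must satisfy 0 <= low < high")
        for name in ("n_discard", "scrub_before", "scrub_after"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ExclusionResult:
    passed: bool
    offending_axes: list[str]
    max_trans_mm: np.ndarray  # per-axis max deviation
    max_rot_deg: np.ndarray


# ---------------------------------------------------------------------------
# NIfTI / text IO


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_nifti(path, data: np.ndarray, voxel_size_mm=(3.0, 3.0, 3.0), tr_s: float | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm))
    zooms = list(voxel_size_mm) + ([tr_s] if (tr_s and data.ndim == 4) else [])
    if len(zooms) == data.ndim:
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_timeseries(path, tr_s: float | None = None) -> TimeSeriesImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return TimeSeriesImage(data, tuple(float(z) for z in zooms[:3]), tr_s)


def load_mask(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj) > 0


def load_motion(path) -> MotionTrace:
    return MotionTrace(np.loadtxt(str(path)))


def save_motion(path, trace: MotionTrace) -> None:
    np.savetxt(str(path), trace.params, fmt="%.8f")


# ---------------------------------------------------------------------------
# stages


def discard_initial_volumes(
    img: TimeSeriesImage, trace: MotionTrace, n_discard: int = 10
) -> tuple[TimeSeriesImage, MotionTrace]:
    """Drop the first `n_discard` volumes from the image and motion trace."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= img.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {img.n_timepoints} timepoints"
        )
    out_img = replace(img, data=img.data[..., n_discard:].copy())
    out_trace = MotionTrace(trace.params[n_discard:].copy())
    return out_img, out_trace


def check_exclusion(
    trace: MotionTrace, max_trans_mm: float = 1.5, max_rot_deg: float = 1.5
) -> ExclusionResult:
    """Flag subjects whose head motion exceeds the study limits.

    Motion is measured as the maximum absolute deviation from the first
    retained frame, per axis.  A subject fails if any translation axis
    exceeds `max_trans_mm` or any rotation axis exceeds `max_rot_deg`;
    values exactly at the limit pass (exclusion requires "more than").
    """
    if trace.n_timepoints == 0:
        raise ValueError("empty motion trace")
    dev = trace.params - trace.params[0]
    max_trans = np.abs(dev[:, :3]).max(axis=0)
    max_rot = np.degrees(np.abs(dev[:, 3:]).max(axis=0))
    # strict "more than", with a relative guard so unit round-trips (deg ->
    # rad -> deg) of a value exactly at the limit still pass
    def over(value, limit):
        return value > limit * (1.0 + 1e-9) + 1e-12

    axes = []
    for ax, name in enumerate(("x-translation", "y-translation", "z-translation")):
        if over(max_trans[ax], max_trans_mm):
            axes.append(name)
    for ax, name in enumerate(("x-rotation", "y-rotation", "z-rotation")):
        if over(max_rot[ax], max_rot_deg):
            axes.append(name)
    return ExclusionResult(not axes, axes, max_trans, max_rot)


def _rigid_transform(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz); rotations in rad."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rx @ Ry @ Rz
    T[:3, 3] = (tx, ty, tz)
    return T


def compute_fd_jenkinson(trace: MotionTrace, sphere_radius_mm: float = 80.0) -> FDSeries:
    """Framewise displacement as RMS voxel displacement over an 80 mm sphere.

    For consecutive frames with rigid transforms T_i, the relative motion is
    M = T_i T_{i-1}^{-1} - I = [A | b], and

        FD_i = sqrt( R^2/5 * trace(A'A) + b'b ),

    the root-mean-square displacement of points uniformly distributed in a
    ball of radius R.  FD of the first frame is 0 by convention.
    """
    n = trace.n_timepoints
    if n < 2:
        raise ValueError("need at least 2 timepoints for FD")
    fd = np.zeros(n)
    prev = _rigid_transform(trace.params[0])
    for i in range(1, n):
        cur = _rigid_transform(trace.params[i])
        M = cur @ np.linalg.inv(prev) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[i] = np.sqrt(sphere_radius_mm**2 / 5.0 * np.trace(A.T @ A) + b @ b)
        prev = cur
    return FDSeries(fd)


def flag_timepoints(fd: FDSeries, threshold_mm: float, before: int, after: int) -> np.ndarray:
    """Boolean mask of scrubbed timepoints: FD above threshold plus margins."""
    bad = fd.fd_mm > threshold_mm
    flags = bad.copy()
    n = len(bad)
    for i in np.flatnonzero(bad):
        flags[max(0, i - before): min(n, i + after + 1)] = True
    return flags


def scrub_interpolate(
    img: TimeSeriesImage, fd: FDSeries, cfg: PrepConfig
) -> tuple[TimeSeriesImage, np.ndarray]:
    """Replace high-motion timepoints by cubic-spline interpolation.

    Timepoints with FD above the threshold, plus `scrub_before` preceding and
    `scrub_after` following frames, are flagged; each voxel's flagged values
    are replaced by a natural cubic spline fitted through the unflagged
    samples.  Unflagged values are returned unchanged.
    """
    flags = flag_timepoints(fd, cfg.fd_threshold_mm, cfg.scrub_before, cfg.scrub_after)
    n_good = int((~flags).sum())
    if not flags.any():
        return replace(img, data=img.data.copy()), flags
    if n_good < 4:
        raise ValueError(
            f"only {n_good} unflagged timepoints; >= 4 required for cubic spline"
        )
    t = np.arange(img.n_timepoints)
    good = ~flags
    Y = img.timeseries_matrix()  # (t, v)
    spline = CubicSpline(t[good], Y[good], axis=0)
    out = Y.copy()
    out[flags] = spline(t[flags])
    data = out.T.reshape(img.data.shape)
    return replace(img, data=data), flags


def build_friston24(trace: MotionTrace) -> np.ndarray:
    """Friston 24-parameter motion expansion: [p, p_lag1, p^2, p_lag1^2].

    The lagged parameters at the first timepoint are defined as 0.
    """
    p = trace.params
    lag = np.vstack([np.zeros(6), p[:-1]])
    return np.hstack([p, lag, p**2, lag**2])


def regress_nuisance(
    img: TimeSeriesImage,
    regressors: np.ndarray | None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
) -> TimeSeriesImage:
    """Voxel-wise OLS removal of nuisance signals.

    The design is [intercept, linear trend, regressors..., WM mean, CSF
    mean]; residuals are returned with each voxel's temporal mean added
    back.  The global (whole-brain) signal is deliberately never included.
    Collinear columns are dropped with a warning.
    """
    T = img.n_timepoints
    cols = [np.ones(T), np.linspace(-1.0, 1.0, T)]
    names = ["intercept", "trend"]
    if regressors is not None:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.shape[0] != T:
            raise ValueError("regressor rows must match timepoints")
        for k in range(regressors.shape[1]):
            cols.append(regressors[:, k])
            names.append(f"reg{k}")
    Y = img.timeseries_matrix()
    for mask, label in ((wm_mask, "wm_mean"), (csf_mask, "csf_mean")):
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != img.grid_shape:
                raise ValueError(f"{label} mask shape does not match grid")
            flat = mask.reshape(-1)
            cols.append(Y[:, flat].mean(axis=1))
            names.append(label)
    X = np.column_stack(cols)

    # drop collinear columns greedily (intercept always kept)
    keep: list[int] = []
    rank = 0
    for k in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [k]])
        if r > rank:
            keep.append(k)
            rank = r
        else:
            log.warning("regress_nuisance: dropping collinear column %s", names[k])
    X = X[:, keep]

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    resid += Y.mean(axis=0, keepdims=True)
    return replace(img, data=resid.T.reshape(img.data.shape))


def _band_bins(T: int, tr_s: float, band_hz) -> np.ndarray:
    freqs = np.fft.rfftfreq(T, d=tr_s)
    lo, hi = band_hz
    eps = 1e-12
    sel = (freqs >= lo - eps) & (freqs <= hi + eps) & (freqs > 0)
    return sel


def bandpass(img: TimeSeriesImage, band_hz=(0.01, 0.08)) -> TimeSeriesImage:
    """Ideal frequency-domain band-pass filter (inclusive bin selection).

    DFT bins with frequency inside [low, high] are retained, all others
    (including the zero-frequency bin) are zeroed; the voxel temporal mean is
    re-added after the inverse transform.  Applying the filter twice gives
    the same result as applying it once.
    """
    lo, hi = band_hz
    if hi >= img.nyquist_hz:
        raise ValueError(
            f"band high edge {hi} Hz must be below Nyquist {img.nyquist_hz} Hz"
        )
    if lo < 0 or lo >= hi:
        raise ValueError("invalid band")
    Y = img.timeseries_matrix()
    mean = Y.mean(axis=0, keepdims=True)
    spec = np.fft.rfft(Y - mean, axis=0)
    sel = _band_bins(img.n_timepoints, img.tr_s, band_hz)
    spec[~sel] = 0.0
    out = np.fft.irfft(spec, n=img.n_timepoints, axis=0) + mean
    return replace(img, data=out.T.reshape(img.data.shape))


def smooth_gaussian(img: TimeSeriesImage, fwhm_mm: float = 6.0) -> TimeSeriesImage:
    """Per-volume 3D Gaussian smoothing; sigma = FWHM / (2*sqrt(2*ln 2))."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return replace(img, data=img.data.copy())
    sigma_vox = [
        fwhm_mm * GAUSS_FWHM_TO_SIGMA / v for v in img.voxel_size_mm
    ]
    out = ndimage.gaussian_filter(
        img.data, sigma=sigma_vox + [0.0], mode="reflect"
    )
    return replace(img, data=out)


def preprocess(
    img: TimeSeriesImage,
    trace: MotionTrace,
    cfg: PrepConfig | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
) -> tuple[TimeSeriesImage, dict]:
    """Run the full subject-level preprocessing chain in fixed order.

    discard -> exclusion check -> nuisance regression -> FD scrubbing ->
    band-pass -> smoothing.  Returns the preprocessed image and a provenance
    record (parameters and per-stage summaries).  Raises if the subject
    fails the motion-exclusion check.
    """
    cfg = cfg or PrepConfig()
    img, trace = discard_initial_volumes(img, trace, cfg.n_discard)
    excl = check_exclusion(trace, cfg.max_trans_mm, cfg.max_rot_deg)
    if not excl.passed:
        raise RuntimeError(f"subject excluded for motion: {excl.offending_axes}")
    reg = build_friston24(trace)
    img = regress_nuisance(img, reg, wm_mask, csf_mask)
    fd = compute_fd_jenkinson(trace, cfg.fd_sphere_radius_mm)
    img, flags = scrub_interpolate(img, fd, cfg)
    img = bandpass(img, cfg.band_hz)
    img = smooth_gaussian(img, cfg.fwhm_mm)
    prov = {
        "n_discard": cfg.n_discard,
        "band_hz": list(cfg.band_hz),
        "fd_threshold_mm": cfg.fd_threshold_mm,
        "scrub_before": cfg.scrub_before,
        "scrub_after": cfg.scrub_after,
        "fwhm_mm": cfg.fwhm_mm,
        "n_timepoints": img.n_timepoints,
        "n_scrubbed": int(flags.sum()),
        "mean_fd_mm": float(fd.fd_mm.mean()),
        "stage_order": [
            "discard", "exclusion_check", "nuisance_regression",
            "scrubbing", "bandpass", "smoothing",
        ],
    }
    return img, prov
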