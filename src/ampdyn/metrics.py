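"""Static and dynamic amplitude of low-frequency fluctuation (ALFF) maps.

Static ALFF is the mean single-sided spectral amplitude of a voxel's
time series over a low-frequency band (0.01-0.08 Hz by default).  The
dynamic variant (dALFF) recomputes ALFF inside rectangular sliding
windows and takes the variance of the per-window values, indexing the
temporal variability of spontaneous activity.  Both maps are z-scored
across an analysis mask before group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prep import PrepConfig, TimeSeriesImage, preprocess


@dataclass
class WindowSpec:
    """Sliding-window parameters in units of TR (default 22 TR, step 1)."""

    window_len_tr: int = 22
    step_tr: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.step_tr <= self.window_len_tr):
            raise ValueError("need 1 <= step <= window length")

    def n_windows(self, n_timepoints: int) -> int:
        if n_timepoints < self.window_len_tr:
            raise ValueError("series shorter than window")
        return (n_timepoints - self.window_len_tr) // self.step_tr + 1


@dataclass
class AmplitudeMap:
    """A 3D per-voxel metric map with its generating parameters."""

    data: np.ndarray  # (x, y, z)
    kind: str  # alff | zalff | dalff_var | dalff_var_z
    band_hz: tuple[float, float]
    tr_s: float
    window: WindowSpec | None = None
    n_windows: int | None = None
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("amplitude map must be 3D")


def _amplitude_spectrum(Y: np.ndarray) -> np.ndarray:
    """Single-sided amplitude spectrum of (t, v) series: a_k = 2|X_k|/N.

    The zero-frequency term and (for even N) the Nyquist term are not
    doubled; the band used here never includes them.
    """
    T = Y.shape[0]
    spec = np.abs(np.fft.rfft(Y - Y.mean(axis=0, keepdims=True), axis=0)) / T
    spec[1:] *= 2.0
    if T % 2 == 0:
        spec[-1] /= 2.0
    return spec


def _band_selector(T: int, tr_s: float, band_hz) -> np.ndarray:
    freqs = np.fft.rfftfreq(T, d=tr_s)
    lo, hi = band_hz
    eps = 1e-12
    sel = (freqs >= lo - eps) & (freqs <= hi + eps) & (freqs > 0)
    if not sel.any():
        raise ValueError(
            f"no DFT bin inside band [{lo}, {hi}] Hz; bin spacing is "
            f"{1.0 / (T * tr_s):.6g} Hz for {T} timepoints at TR {tr_s} s"
        )
    return sel


def compute_alff(
    img: TimeSeriesImage,
    band_hz=(0.01, 0.08),
    mask: np.ndarray | None = None,
) -> AmplitudeMap:
    """Static ALFF: mean square-root power over the low-frequency band.

    Per voxel the temporal mean is removed, the discrete Fourier transform
    taken, and the single-sided amplitudes 2|X_k|/N averaged over the bins
    whose frequency falls inside [low, high] (inclusive).
    """
    if img.n_timepoints < 8:
        raise ValueError("need at least 8 timepoints")
    sel = _band_selector(img.n_timepoints, img.tr_s, band_hz)
    Y = img.timeseries_matrix()
    alff = _amplitude_spectrum(Y)[sel].mean(axis=0)
    data = alff.reshape(img.grid_shape)
    if mask is not None:
        data = np.where(mask, data, 0.0)
    return AmplitudeMap(data, "alff", tuple(band_hz), img.tr_s, mask=mask)


def zscore_map(amap: AmplitudeMap, mask: np.ndarray | None = None) -> AmplitudeMap:
    """Z-score map values within the analysis mask (sample sd, ddof=1).

    Outside-mask voxels are set to 0.  The z-scored kind is `zalff` for
    static input and `dalff_var_z` for dynamic input.
    """
    if mask is None:
        mask = amap.mask
    if mask is None:
        mask = np.ones(amap.data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    vals = amap.data[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance within mask; cannot z-score")
    out = np.zeros_like(amap.data)
    out[mask] = (vals - vals.mean()) / sd
    kind = {"alff": "zalff", "dalff_var": "dalff_var_z"}.get(amap.kind, amap.kind + "_z")
    return AmplitudeMap(
        out, kind, amap.band_hz, amap.tr_s,
        window=amap.window, n_windows=amap.n_windows, mask=mask, meta=dict(amap.meta),
    )


def compute_dalff(
    img: TimeSeriesImage,
    band_hz=(0.01, 0.08),
    wspec: WindowSpec | None = None,
    mask: np.ndarray | None = None,
) -> AmplitudeMap:
    """Dynamic ALFF variance over rectangular sliding windows.

    W = floor((T - window_len) / step) + 1 windows are taken; ALFF is
    computed on each windowed segment with the window's own DFT bin grid
    (no taper), and the per-voxel sample variance (W - 1 denominator)
    across windows is returned.
    """
    wspec = wspec or WindowSpec()
    W = wspec.n_windows(img.n_timepoints)
    if W < 2:
        raise ValueError(f"only {W} window(s); variance needs at least 2")
    sel = _band_selector(wspec.window_len_tr, img.tr_s, band_hz)
    Y = img.timeseries_matrix()
    n_vox = Y.shape[1]
    window_alff = np.empty((W, n_vox))
    for w in range(W):
        start = w * wspec.step_tr
        seg = Y[start: start + wspec.window_len_tr]
        window_alff[w] = _amplitude_spectrum(seg)[sel].mean(axis=0)
    var = window_alff.var(axis=0, ddof=1)
    data = var.reshape(img.grid_shape)
    if mask is not None:
        data = np.where(mask, data, 0.0)
    return AmplitudeMap(
        data, "dalff_var", tuple(band_hz), img.tr_s,
        window=wspec, n_windows=W, mask=mask,
    )


def metric_pipeline(
    subjects,
    cfg: PrepConfig | None = None,
    window_specs=(WindowSpec(22, 1),),
    band_hz=(0.01, 0.08),
    mask: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
):
    """Preprocess each subject and compute z-scored static and dynamic maps.

    `subjects` is an iterable of (TimeSeriesImage, MotionTrace).  Returns a
    dict with per-subject `zalff` maps and, per window spec, z-scored dALFF
    variance maps, plus provenance records.
    """
    cfg = cfg or PrepConfig()
    window_specs = list(window_specs)
    out = {
        "zalff": [],
        "dalff_z": {ws.window_len_tr: [] for ws in window_specs},
        "provenance": [],
    }
    for img, trace in subjects:
        pimg, prov = preprocess(img, trace, cfg, wm_mask, csf_mask)
        out["zalff"].append(zscore_map(compute_alff(pimg, band_hz, mask), mask))
        for ws in window_specs:
            dmap = compute_dalff(pimg, band_hz, ws, mask)
            out["dalff_z"][ws.window_len_tr].append(zscore_map(dmap, mask))
        out["provenance"].append(prov)
    return out


def stack_maps(maps) -> np.ndarray:
    """Stack a list of AmplitudeMaps into an (n_subjects, x, y, z) array."""
    return np.stack([m.data for m in maps], axis=0)
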