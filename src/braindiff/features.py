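"""Imaging feature computation: filtered BOLD, ReHo, and Fisher-z FC.

The stated pipeline order is band-pass filter -> nuisance regression ->
(ReHo | region means -> FC); ReHo maps are then standardized to an
in-brain mean of 1 and Gaussian-smoothed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .types import BoldRun, FCMatrix, VolumeMap

__all__ = [
    "bandpass_filter",
    "regress_nuisance",
    "compute_reho",
    "standardize_reho",
    "smooth_volume",
    "region_timeseries",
    "fc_matrix",
    "neighbor_offsets",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM * this factor
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_R_CLAMP = 1.0 - 1e-7


def bandpass_filter(run: BoldRun, low_hz: float, high_hz: float) -> BoldRun:
    """Zero-phase frequency-domain band-pass along the time axis.

    Frequency bins outside [low_hz, high_hz] (inclusive) are zeroed;
    the DC bin is always removed, so the output series have zero mean.
    """
    nyquist = 1.0 / (2.0 * run.tr_seconds)
    if not (0.0 <= low_hz < high_hz <= nyquist + 1e-12):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside [0, Nyquist={nyquist:.4g}] Hz"
        )
    T = run.n_timepoints
    freqs = np.fft.rfftfreq(T, d=run.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False  # remove mean even when low_hz == 0
    spec = np.fft.rfft(run.values, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=-1)
    return BoldRun(out, run.tr_seconds)


def regress_nuisance(run: BoldRun, regressors: np.ndarray) -> BoldRun:
    """Remove nuisance signals by least squares; returns the residuals.

    An intercept column is always appended, so residuals are demeaned.
    """
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T = run.n_timepoints
    if X.shape[0] != T:
        raise ValueError("regressor rows must equal number of time points")
    X = np.column_stack([np.ones(T), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("nuisance design is rank deficient")
    Y = run.values.reshape(-1, T).T  # T x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return BoldRun(resid.T.reshape(run.values.shape), run.tr_seconds)


def neighbor_offsets(neighborhood: int) -> np.ndarray:
    """Voxel offsets for a 6-, 18- or 26-connected neighborhood."""
    if neighborhood not in (6, 18, 26):
        raise ValueError("neighborhood must be one of 6, 18, 26")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                m = abs(dx) + abs(dy) + abs(dz)
                if m == 0:
                    continue
                if neighborhood == 6 and m > 1:
                    continue
                if neighborhood == 18 and m > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs, dtype=int)


def _shift3d(vol: np.ndarray, off: np.ndarray) -> np.ndarray:
    """Shift a (x,y,z,...) array by a voxel offset, zero-filling edges."""
    out = np.zeros_like(vol)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for a in range(3):
        o = int(off[a])
        n = vol.shape[a]
        if o >= 0:
            dst[a] = slice(o, n)
            src[a] = slice(0, n - o)
        else:
            dst[a] = slice(0, n + o)
            src[a] = slice(-o, n)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance for a K x n series block.

    W = 12 * sum_i (R_i - Rbar)^2 / (K^2 * (n^3 - n)) with average ranks
    for ties and no tie-correction term.
    """
    series = np.asarray(series, dtype=float)
    K, n = series.shape
    ranks = rankdata(series, axis=1)
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    return float(12.0 * S / (K**2 * (n**3 - n)))


def compute_reho(
    run: BoldRun, mask: np.ndarray, neighborhood: int = 26
) -> VolumeMap:
    """Voxel-wise Kendall's W between each voxel and its in-mask neighbors.

    K shrinks to 1 + (available in-mask neighbors) at mask edges so every
    mask voxel gets a value; isolated voxels (K == 1) are undefined and
    set to NaN with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.values.shape[:3]:
        raise ValueError("mask shape must match run grid")
    T = run.n_timepoints
    if T < 2:
        raise ValueError("need at least 2 time points")

    data = run.values[mask]  # V x T
    ranks = rankdata(data, axis=1)
    rankvol = np.zeros(run.values.shape)
    rankvol[mask] = ranks
    maskf = mask.astype(float)

    rank_sum = rankvol.copy()
    k_count = maskf.copy()
    for off in neighbor_offsets(neighborhood):
        rank_sum += _shift3d(rankvol, off)
        k_count += _shift3d(maskf, off)

    K = k_count[mask]
    R = rank_sum[mask]  # V x T
    Rbar = K[:, None] * (T + 1) / 2.0
    S = ((R - Rbar) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = 12.0 * S / (K**2 * (T**3 - T))
    isolated = K <= 1
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} mask voxel(s) have no in-mask neighbor; "
            "ReHo set to NaN there"
        )
        W[isolated] = np.nan
    out = np.zeros(mask.shape)
    out[mask] = W
    return VolumeMap(out, mask)


def standardize_reho(vmap: VolumeMap) -> VolumeMap:
    """Divide by the in-mask mean so the in-mask mean becomes 1."""
    vals = vmap.in_mask()
    mean = np.nanmean(vals)
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("in-mask mean must be positive to standardize")
    out = vmap.values.copy()
    out[vmap.mask] = vals / mean
    return vmap.with_values(out)


def smooth_volume(vmap: VolumeMap, fwhm_mm: float) -> VolumeMap:
    """Mask-renormalized Gaussian smoothing.

    Kernel weights falling outside the mask are discarded and the rest
    rescaled, so constant in-mask maps are preserved. fwhm 0 is identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return vmap.with_values(vmap.values.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vmap.voxel_size_mm
    maskf = vmap.mask.astype(float)
    num = ndimage.gaussian_filter(vmap.values * maskf, sigma_vox)
    den = ndimage.gaussian_filter(maskf, sigma_vox)
    out = np.zeros_like(num)
    inside = vmap.mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return vmap.with_values(out)


def region_timeseries(
    run: BoldRun, atlas: VolumeMap, gm_mask: np.ndarray | None = None
) -> tuple[np.ndarray, list[int]]:
    """Mean time series per atlas region over in-mask GM voxels.

    Returns an (R, T) matrix and the sorted region labels defining its
    row order.
    """
    labels = atlas.values.astype(int)
    mask = atlas.mask if gm_mask is None else (atlas.mask & np.asarray(gm_mask, bool))
    region_ids = np.unique(labels[labels > 0])
    T = run.n_timepoints
    ts = np.empty((len(region_ids), T))
    data = run.values
    for r, rid in enumerate(region_ids):
        sel = (labels == rid) & mask
        if not sel.any():
            raise ValueError(f"region {rid} has no in-mask voxel")
        ts[r] = data[sel].mean(axis=0)
    return ts, region_ids.tolist()


def fc_matrix(region_ts: np.ndarray, region_labels: list | None = None) -> FCMatrix:
    """Pearson correlation between region series, Fisher r-to-z transformed.

    r is clamped to +/-(1 - 1e-7) before atanh so z stays finite; the
    diagonal is set to zero.
    """
    ts = np.asarray(region_ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need an (R, T) matrix with T >= 3")
    sd = ts.std(axis=1)
    degenerate = sd <= 1e-12 * (np.abs(ts).max(axis=1) + 1.0)
    if np.any(degenerate):
        bad = np.nonzero(degenerate)[0].tolist()
        raise ValueError(f"zero-variance region time series at rows {bad}")
    r = np.corrcoef(ts)
    r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return FCMatrix(z, list(region_labels) if region_labels is not None else [])
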