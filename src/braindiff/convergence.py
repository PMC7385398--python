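"""Structural/functional convergence: overlap counts and spatial correlation."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .stats import TMap
from .types import VolumeMap

__all__ = ["OverlapReport", "overlap_analysis", "spatial_correlation"]


@dataclass
class OverlapReport:
    """Voxel overlap between two thresholded difference maps.

    ``n_overlap_corrected`` counts voxels significant in both maps at the
    corrected threshold; the trend fields count relaxed-threshold
    (uncorrected) voxels of one modality inside the other's corrected
    mask.  Percentages are NaN when the denominator mask is empty.
    """

    n_overlap_corrected: int
    pct_of_A: float
    pct_of_B: float
    n_trendB_in_sigA: int
    pct_trendB_in_sigA: float
    n_trendA_in_sigB: int
    pct_trendA_in_sigB: float
    n_sign_agree_overlap: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _as_bool(m: VolumeMap | np.ndarray) -> np.ndarray:
    if isinstance(m, VolumeMap):
        return m.values.astype(bool) & m.mask
    return np.asarray(m, dtype=bool)


def _pct(num: int, den: int) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def overlap_analysis(
    sigA: VolumeMap | np.ndarray,
    sigB: VolumeMap | np.ndarray,
    trendA: VolumeMap | np.ndarray | None = None,
    trendB: VolumeMap | np.ndarray | None = None,
    tA: np.ndarray | None = None,
    tB: np.ndarray | None = None,
) -> OverlapReport:
    """Quantify overlap between two binarized difference maps.

    Trend masks (relaxed, uncorrected threshold) must be supersets of the
    corresponding corrected masks.  If the unthresholded t grids are
    supplied, the count of overlap voxels whose effects agree in sign is
    reported too.
    """
    A = _as_bool(sigA)
    B = _as_bool(sigB)
    if A.shape != B.shape:
        raise ValueError("maps must share the grid")
    trA = A if trendA is None else _as_bool(trendA)
    trB = B if trendB is None else _as_bool(trendB)
    if (A & ~trA).any() or (B & ~trB).any():
        raise ValueError("corrected masks must be subsets of trend masks")

    inter = A & B
    n = int(inter.sum())
    n_trendB_in_sigA = int((A & trB).sum())
    n_trendA_in_sigB = int((B & trA).sum())
    n_agree = 0
    if tA is not None and tB is not None and n > 0:
        n_agree = int((np.sign(tA[inter]) == np.sign(tB[inter])).sum())
    return OverlapReport(
        n_overlap_corrected=n,
        pct_of_A=_pct(n, int(A.sum())),
        pct_of_B=_pct(n, int(B.sum())),
        n_trendB_in_sigA=n_trendB_in_sigA,
        pct_trendB_in_sigA=_pct(n_trendB_in_sigA, int(A.sum())),
        n_trendA_in_sigB=n_trendA_in_sigB,
        pct_trendA_in_sigB=_pct(n_trendA_in_sigB, int(B.sum())),
        n_sign_agree_overlap=n_agree,
    )


def spatial_correlation(
    tmapA: TMap | VolumeMap,
    tmapB: TMap | VolumeMap,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation of two unthresholded maps across in-mask voxels."""
    va = tmapA.t_values if isinstance(tmapA, TMap) else tmapA
    vb = tmapB.t_values if isinstance(tmapB, TMap) else tmapB
    if va.shape != vb.shape:
        raise ValueError("maps must share the grid")
    m = va.mask if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    a = va.values[m]
    b = vb.values[m]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance within the mask")
    return float(np.corrcoef(a, b)[0, 1])
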