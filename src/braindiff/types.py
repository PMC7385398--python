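"""Core container types shared across the pipeline.

All volumes are plain numpy arrays on a regular grid.  Voxel indices are
0-based; no world-coordinate mapping is attempted for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeMap", "BoldRun", "FCMatrix", "edge_index_pairs", "n_edges"]


@dataclass
class VolumeMap:
    """A 3D scalar map with an analysis mask.

    Parameters
    ----------
    values
        3D float array.  Values outside the mask are carried along but
        never interpreted.
    mask
        3D boolean array of the same shape; must contain at least one
        True voxel.
    voxel_size_mm
        Isotropic voxel edge length in millimetres.
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask(self) -> np.ndarray:
        """In-mask values as a 1D vector (fixed C-order of mask voxels)."""
        return self.values[self.mask]

    def with_values(self, values: np.ndarray) -> "VolumeMap":
        return VolumeMap(values, self.mask, self.voxel_size_mm)

    def from_vector(self, vec: np.ndarray, fill: float = 0.0) -> "VolumeMap":
        """Embed a 1D in-mask vector back into the 3D grid."""
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_mask_voxels,):
            raise ValueError("vector length must equal number of mask voxels")
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = vec
        return self.with_values(out)


@dataclass
class BoldRun:
    """A 4D BOLD run (x, y, z, t) with its repetition time in seconds."""

    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be a 4D (x, y, z, t) array")
        if self.values.shape[-1] < 8:
            raise ValueError("a BOLD run needs at least 8 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[-1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class FCMatrix:
    """Fisher-z functional connectivity matrix over R regions."""

    z_values: np.ndarray
    region_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        z = self.z_values
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_values must be square")
        if not self.region_labels:
            self.region_labels = list(range(1, z.shape[0] + 1))
        if len(self.region_labels) != z.shape[0]:
            raise ValueError("region_labels length must match matrix size")
        if not np.allclose(z, z.T, equal_nan=True):
            raise ValueError("z_values must be symmetric")
        if not np.allclose(np.diag(z), 0.0):
            raise ValueError("diagonal must be zero")
        off = z[~np.eye(z.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal z values must be finite")

    @property
    def n_regions(self) -> int:
        return self.z_values.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle edge values in canonical (i < j) order."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.z_values[iu]


def edge_index_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Canonical unordered region-pair list: (0,1), (0,2), ... row-major."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def n_edges(n_regions: int) -> int:
    """Number of unique undirected region pairs, R(R-1)/2."""
    return n_regions * (n_regions - 1) // 2
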