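"""Synthetic cohort generator with known ground truth.

Produces subject tables, per-subject gray-matter-volume maps with planted
cluster effects, and 4D BOLD runs whose local temporal coherence and
inter-regional correlation structure differ between groups in planted
locations.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BoldRun, VolumeMap, edge_index_pairs, n_edges

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "ellipsoid_mask",
    "make_atlas",
    "cluster_mask",
    "generate_subject_table",
    "generate_gmv_maps",
    "generate_bold_runs",
    "generate_motion_params",
]

MALE = "M"
FEMALE = "F"

# Group education summaries used as generator defaults (years).
_EDU_MEAN = {MALE: 15.1, FEMALE: 15.9}
_EDU_SD = {MALE: 2.3, FEMALE: 2.6}


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort.

    ``gmv_effect_clusters`` and ``reho_effect_clusters`` are lists of
    ``(center, radius_voxels, effect)`` triples: ``center`` is a voxel
    index triple, the effect applies to females (positive effect means
    female > male).  For GMV the effect is a Cohen's d relative to
    ``noise_sd``; for ReHo it is an additive increment to the local
    coherence weight.  ``fc_effect_edges`` lists ``(i, j, delta)`` where
    delta is added to the female latent correlation on that region pair.
    """

    n_male: int = 20
    n_female: int = 20
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_regions: int = 12
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    gmv_effect_clusters: list = field(default_factory=list)
    reho_effect_clusters: list = field(default_factory=list)
    fc_effect_edges: list = field(default_factory=list)
    confound_slopes: dict = field(
        default_factory=lambda: {"age": 0.0, "education": 0.0}
    )
    noise_sd: float = 1.0
    local_coherence_base: float = 0.2
    fc_base_corr: float = 0.2
    region_signal_weight: float = 1.0
    gmv_baseline: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male <= 0 or self.n_female <= 0:
            raise ValueError("group counts must be positive")
        if self.n_regions < 2:
            raise ValueError("need at least two regions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.noise_sd == 0 and any(
            d != 0 for _, _, d in self.gmv_effect_clusters
        ):
            raise ValueError("gmv effects are scaled by noise_sd; it must be > 0")
        if not (0.0 <= self.local_coherence_base < 1.0):
            raise ValueError("local_coherence_base must be in [0, 1)")
        if self.n_timepoints < 8:
            raise ValueError("need at least 8 time points")
        for i, j, delta in self.fc_effect_edges:
            if not (-1.0 < self.fc_base_corr + delta < 1.0):
                raise ValueError(
                    f"fc target correlation out of (-1, 1) on edge ({i}, {j})"
                )
        shape = tuple(self.grid_shape)
        for name in ("gmv_effect_clusters", "reho_effect_clusters"):
            for center, radius, _ in getattr(self, name):
                if any(not (0 <= c < s) for c, s in zip(center, shape)):
                    raise ValueError(f"cluster center {center} outside grid {shape}")
                if radius <= 0:
                    raise ValueError("cluster radius must be positive")

    @property
    def n_subjects(self) -> int:
        return self.n_male + self.n_female

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream derived from the master seed."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Planted effect locations, for validating downstream detection."""

    gmv_effect_mask: VolumeMap | None = None
    reho_effect_mask: VolumeMap | None = None
    fc_effect_edges: list = field(default_factory=list)

    def fc_edge_indices(self, n_regions: int) -> list[int]:
        pairs = edge_index_pairs(n_regions)
        lookup = {p: k for k, p in enumerate(pairs)}
        return [lookup[(min(i, j), max(i, j))] for i, j, _ in self.fc_effect_edges]


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Centered ellipsoidal brain mask with semi-axes 0.45 * shape."""
    idx = np.indices(grid_shape, dtype=float)
    center = [(s - 1) / 2.0 for s in grid_shape]
    semi = [0.45 * s for s in grid_shape]
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def cluster_mask(
    grid_shape: tuple[int, int, int],
    center: tuple[int, int, int],
    radius: float,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Spherical voxel cluster, intersected with the brain mask if given."""
    idx = np.indices(grid_shape, dtype=float)
    r2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    out = r2 <= radius**2
    if brain_mask is not None:
        out &= brain_mask
        if not out.any():
            raise ValueError(f"cluster at {center} lies entirely outside the mask")
    return out


def make_atlas(
    mask: np.ndarray, n_regions: int, voxel_size_mm: float = 3.0, seed: int = 0
) -> VolumeMap:
    """Partition the mask into spatially compact integer-labelled regions.

    K-means on voxel coordinates gives roughly equal-sized contiguous-ish
    parcels; labels are 1..n_regions, 0 outside the mask.
    """
    coords = np.argwhere(mask).astype(float)
    if n_regions > coords.shape[0]:
        raise ValueError("more regions than mask voxels")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_regions, n_init=1, random_state=seed)
    labels = km.fit_predict(coords) + 1
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask] = labels
    return VolumeMap(vol, mask, voxel_size_mm)


def generate_subject_table(spec: CohortSpec) -> pd.DataFrame:
    """Subject table: id, gender, age (uniform 18-29), education (years).

    Males come first; ids are stable across calls with the same spec.
    """
    rng = spec.rng("subjects")
    n = spec.n_subjects
    genders = [MALE] * spec.n_male + [FEMALE] * spec.n_female
    ages = rng.uniform(18.0, 29.0, size=n)
    edu = np.empty(n)
    for g in (MALE, FEMALE):
        sel = np.array([x == g for x in genders])
        edu[sel] = rng.normal(_EDU_MEAN[g], _EDU_SD[g], size=int(sel.sum()))
    edu = np.clip(edu, 9.0, 22.0)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "gender": genders,
            "age": np.round(ages, 2),
            "education": np.round(edu, 2),
        }
    )


def _check_table(spec: CohortSpec, table: pd.DataFrame) -> None:
    if (table["gender"] == MALE).sum() != spec.n_male or (
        table["gender"] == FEMALE
    ).sum() != spec.n_female:
        raise ValueError("subject table group counts do not match spec")


def generate_gmv_maps(
    spec: CohortSpec,
    table: pd.DataFrame,
    mask: np.ndarray | None = None,
) -> tuple[dict[str, VolumeMap], GroundTruth]:
    """Per-subject GMV maps with planted cluster effects and confounds.

    Voxel value = baseline + female_indicator * d * noise_sd (inside
    planted clusters) + age/education confound terms + N(0, noise_sd),
    clipped at zero.
    """
    _check_table(spec, table)
    if mask is None:
        mask = ellipsoid_mask(spec.grid_shape)
    effect = np.zeros(spec.grid_shape)
    truth_mask = np.zeros(spec.grid_shape, dtype=bool)
    for center, radius, d in spec.gmv_effect_clusters:
        cm = cluster_mask(spec.grid_shape, center, radius, mask)
        effect[cm] += d * spec.noise_sd
        truth_mask |= cm

    rng = spec.rng("gmv")
    age_slope = spec.confound_slopes.get("age", 0.0)
    edu_slope = spec.confound_slopes.get("education", 0.0)
    age0 = table["age"].mean()
    edu0 = table["education"].mean()

    maps: dict[str, VolumeMap] = {}
    for _, row in table.iterrows():
        female = 1.0 if row["gender"] == FEMALE else 0.0
        vol = (
            spec.gmv_baseline
            + female * effect
            + age_slope * (row["age"] - age0)
            + edu_slope * (row["education"] - edu0)
            + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        )
        np.clip(vol, 0.0, None, out=vol)
        vol[~mask] = 0.0
        maps[row["subject_id"]] = VolumeMap(vol, mask, spec.voxel_size_mm)

    truth = GroundTruth(
        gmv_effect_mask=VolumeMap(truth_mask.astype(float), mask, spec.voxel_size_mm)
        if truth_mask.any()
        else None
    )
    return maps, truth


def _nearest_pd(corr: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping with unit-diagonal renormalization."""
    w, v = np.linalg.eigh(corr)
    if w.min() > 1e-10:
        return corr
    w = np.clip(w, 1e-6, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _latent_correlation(spec: CohortSpec, female: bool) -> np.ndarray:
    corr = np.full((spec.n_regions, spec.n_regions), spec.fc_base_corr)
    np.fill_diagonal(corr, 1.0)
    if female:
        for i, j, delta in spec.fc_effect_edges:
            corr[i, j] += delta
            corr[j, i] += delta
    return _nearest_pd(corr)


def _local_shared_field(
    rng: np.random.Generator, grid_shape: tuple[int, int, int], T: int,
    sigma_vox: float = 1.0,
) -> np.ndarray:
    """Unit-variance spatially smooth noise field: neighbors share signal."""
    from scipy.ndimage import gaussian_filter

    raw = rng.standard_normal(grid_shape + (T,))
    smooth = gaussian_filter(raw, sigma=(sigma_vox,) * 3 + (0.0,), mode="wrap")
    # white noise smoothed with kernel k has variance sum(k^2)
    probe = np.zeros(grid_shape)
    probe[tuple(s // 2 for s in grid_shape)] = 1.0
    kernel = gaussian_filter(probe, sigma=sigma_vox, mode="wrap")
    return smooth / np.sqrt((kernel**2).sum())


def generate_motion_params(spec: CohortSpec, n_subjects: int) -> list[pd.DataFrame]:
    """Six smooth random walks per subject (3 translations, 3 rotations)."""
    rng = spec.rng("motion")
    out = []
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    for _ in range(n_subjects):
        steps = rng.normal(0.0, 0.02, size=(spec.n_timepoints, 6))
        out.append(pd.DataFrame(np.cumsum(steps, axis=0), columns=cols))
    return out


def generate_bold_runs(
    spec: CohortSpec,
    table: pd.DataFrame,
    atlas: VolumeMap,
) -> tuple[dict[str, BoldRun], GroundTruth, list[pd.DataFrame]]:
    """Per-subject BOLD runs with planted FC and local-coherence effects.

    Each voxel series is ``w * region_latent + c * local_shared + noise``
    where region latents have gender-specific pairwise correlations,
    ``local_shared`` is a spatially smooth unit-variance noise field
    (neighboring voxels share it), and the coherence weight ``c`` is
    raised for females inside the planted clusters.  Motion-parameter
    tables (random walks) are returned so nuisance regression can be
    exercised.
    """
    _check_table(spec, table)
    mask = atlas.mask
    labels = atlas.values.astype(int)
    present = np.unique(labels[mask])
    present = present[present > 0]
    if len(present) != spec.n_regions:
        raise ValueError("atlas does not partition the mask into n_regions")

    chol = {
        False: np.linalg.cholesky(_latent_correlation(spec, female=False)),
        True: np.linalg.cholesky(_latent_correlation(spec, female=True)),
    }

    coh_extra = np.zeros(spec.grid_shape)
    truth_mask = np.zeros(spec.grid_shape, dtype=bool)
    for center, radius, dc in spec.reho_effect_clusters:
        cm = cluster_mask(spec.grid_shape, center, radius, mask)
        coh_extra[cm] += dc
        truth_mask |= cm
    if np.any(spec.local_coherence_base + coh_extra >= 1.0):
        warnings.warn("coherence weight reaches 1; clipping to 0.99")
        coh_extra = np.minimum(coh_extra, 0.99 - spec.local_coherence_base)

    region_of_voxel = labels[mask] - 1
    T = spec.n_timepoints
    V = int(mask.sum())
    w = spec.region_signal_weight

    rng = spec.rng("bold")
    runs: dict[str, BoldRun] = {}
    motion = generate_motion_params(spec, spec.n_subjects)
    for _, row in table.iterrows():
        female = row["gender"] == FEMALE
        c_field = np.full(spec.grid_shape, spec.local_coherence_base)
        if female:
            c_field += coh_extra
        c_vox = c_field[mask]
        latents = chol[female] @ rng.standard_normal((spec.n_regions, T))
        shared = _local_shared_field(rng, spec.grid_shape, T)[mask]
        noise = rng.standard_normal((V, T))
        series = (
            w * latents[region_of_voxel]
            + c_vox[:, None] * shared
            + noise
        )
        vol = np.zeros(spec.grid_shape + (T,))
        vol[mask] = series
        runs[row["subject_id"]] = BoldRun(vol, spec.tr_seconds)

    truth = GroundTruth(
        reho_effect_mask=VolumeMap(truth_mask.astype(float), mask, spec.voxel_size_mm)
        if truth_mask.any()
        else None,
        fc_effect_edges=[(i, j, np.sign(d)) for i, j, d in spec.fc_effect_edges],
    )
    return runs, truth, motion
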