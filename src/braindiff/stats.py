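"""Mass-univariate group statistics with covariates and FWE control.

Sign convention throughout: the group regressor codes female = 1,
male = 0, so positive t means female > male.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import FCMatrix, VolumeMap, edge_index_pairs, n_edges

__all__ = [
    "TMap",
    "EdgeStats",
    "glm_group_tmap",
    "fwe_correct",
    "edge_group_tests",
    "weighted_degree",
    "demographics_test",
    "group_design",
    "fit_glm_t",
]

FEMALE = "F"


@dataclass
class TMap:
    """Voxel-wise t statistics with matching p values and significance mask."""

    t_values: VolumeMap
    dof: int
    p_values: VolumeMap
    sig_mask: VolumeMap | None = None
    contrast_sign_convention: str = "female-minus-male"


@dataclass
class EdgeStats:
    """Edge-wise t/p values over the R(R-1)/2 region pairs."""

    t_values: np.ndarray
    p_values: np.ndarray
    sig_mask: np.ndarray
    edge_index: list
    dof: int = 0

    def __post_init__(self) -> None:
        E = len(self.edge_index)
        for name in ("t_values", "p_values", "sig_mask"):
            if len(getattr(self, name)) != E:
                raise ValueError(f"{name} length must equal number of edges")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_i": [i for i, _ in self.edge_index],
                "region_j": [j for _, j in self.edge_index],
                "t": self.t_values,
                "p": self.p_values,
                "significant": self.sig_mask.astype(int),
            }
        )


def group_design(
    gender: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> np.ndarray:
    """Design matrix [intercept, female indicator, centered covariates]."""
    gender = np.asarray(gender)
    female = (gender == FEMALE).astype(float) if gender.dtype.kind in "UOS" else (
        np.asarray(gender, dtype=float)
    )
    n = female.shape[0]
    cols = [np.ones(n), female]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows must match number of subjects")
        cols.extend((C - C.mean(axis=0)).T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def fit_glm_t(Y: np.ndarray, X: np.ndarray, coef: int = 1) -> tuple[np.ndarray, int]:
    """Vectorized OLS t statistic for one coefficient across many targets.

    Y is (n, V); returns (t over V, dof).  Targets with zero residual
    variance get t = 0 with a warning.
    """
    n, p = X.shape
    dof = n - p
    if dof < 1:
        raise ValueError("not enough subjects for the design")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[coef, coef])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[coef] / se
    # relative floor catches analytically-zero residual variance despite
    # floating-point crumbs
    scale = (Y**2).mean(axis=0) + 1e-300
    degenerate = ~np.isfinite(t) | (sigma2 <= 1e-20 * scale)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} target(s) with zero residual variance; t set to 0"
        )
        t[degenerate] = 0.0
    return t, dof


def _stack_maps(maps: list[VolumeMap]) -> tuple[np.ndarray, VolumeMap]:
    ref = maps[0]
    Y = np.stack([m.in_mask() for m in maps])  # n x V
    return Y, ref


def glm_group_tmap(
    maps: list[VolumeMap],
    gender: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> TMap:
    """Voxel-wise two-sample comparison via a GLM with partialled covariates.

    Per voxel: value ~ intercept + female + covariates; t is the female
    coefficient over its standard error (positive t => female > male).
    """
    gender = np.asarray(gender)
    if len(maps) != len(gender):
        raise ValueError("one map per subject required")
    for g in np.unique(gender):
        if (gender == g).sum() < 2:
            raise ValueError("need at least 2 subjects per group")
    Y, ref = _stack_maps(maps)
    X = group_design(gender, covariates)
    t, dof = fit_glm_t(Y, X)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return TMap(
        t_values=ref.from_vector(t),
        dof=dof,
        p_values=ref.from_vector(p, fill=1.0),
    )


def fwe_correct(
    tmap: TMap,
    method: str = "max_t_permutation",
    alpha: float = 0.05,
    *,
    maps: list[VolumeMap] | None = None,
    gender: np.ndarray | None = None,
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> TMap:
    """Attach a family-wise-error-controlled significance mask.

    ``bonferroni`` thresholds p at alpha / V.  ``max_t_permutation``
    shuffles the group labels wholesale, recording the maximum |t| per
    permutation; voxels with |t| at or above the (1 - alpha) quantile of
    that null are significant (two-sided).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    mask = tmap.t_values.mask
    V = int(mask.sum())
    t_obs = tmap.t_values.in_mask()

    if method == "bonferroni":
        sig = tmap.p_values.in_mask() <= alpha / V
    elif method == "max_t_permutation":
        if maps is None or gender is None:
            raise ValueError("max_t_permutation needs maps and gender labels")
        if n_perm < int(np.ceil(1.0 / alpha)):
            raise ValueError("n_perm too small for the requested alpha")
        rng = np.random.default_rng(seed)
        Y, _ = _stack_maps(maps)
        gender = np.asarray(gender)
        max_ts = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(len(gender))
            Xp = group_design(gender[perm], covariates)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tp, _ = fit_glm_t(Y, Xp)
            max_ts[b] = np.abs(tp).max()
        thr = np.quantile(max_ts, 1.0 - alpha, method="higher")
        sig = np.abs(t_obs) >= thr
    else:
        raise ValueError(f"unknown FWE method: {method}")

    out = TMap(
        t_values=tmap.t_values,
        dof=tmap.dof,
        p_values=tmap.p_values,
        sig_mask=tmap.t_values.from_vector(sig.astype(float)),
        contrast_sign_convention=tmap.contrast_sign_convention,
    )
    return out


def edge_group_tests(
    fcs: list[FCMatrix],
    gender: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    alpha_family: float = 0.05,
) -> EdgeStats:
    """Per-edge GLM on Fisher-z values with Bonferroni control at alpha/E.

    Pass ``covariates=None`` for the plain two-sample variant.
    """
    R = fcs[0].n_regions
    labels0 = fcs[0].region_labels
    for fc in fcs:
        if fc.n_regions != R or fc.region_labels != labels0:
            raise ValueError("all subjects must share the same region set/order")
    E = n_edges(R)
    Y = np.stack([fc.edge_vector() for fc in fcs])  # n x E
    X = group_design(np.asarray(gender), covariates)
    t, dof = fit_glm_t(Y, X)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    sig = p <= alpha_family / E
    return EdgeStats(
        t_values=t,
        p_values=p,
        sig_mask=sig,
        edge_index=edge_index_pairs(R),
        dof=dof,
    )


def weighted_degree(edges: EdgeStats, n_regions: int | None = None) -> pd.DataFrame:
    """Positive and negative weighted degree per region.

    Only significant edges contribute: positive degree sums the positive
    t values of a region's significant edges, negative degree the
    negative ones.
    """
    if n_regions is None:
        n_regions = max(max(i, j) for i, j in edges.edge_index) + 1
    pos = np.zeros(n_regions)
    neg = np.zeros(n_regions)
    for (i, j), t, s in zip(edges.edge_index, edges.t_values, edges.sig_mask):
        if not s:
            continue
        if t > 0:
            pos[i] += t
            pos[j] += t
        elif t < 0:
            neg[i] += t
            neg[j] += t
    return pd.DataFrame(
        {
            "region": np.arange(n_regions),
            "positive_weighted_degree": pos,
            "negative_weighted_degree": neg,
        }
    )


def demographics_test(
    table: pd.DataFrame, field: str
) -> tuple[float, float]:
    """Pooled-variance two-sample t test (male minus female), two-sided p."""
    if field not in table.columns:
        raise ValueError(f"unknown field: {field}")
    a = table.loc[table["gender"] == "M", field].to_numpy(dtype=float)
    b = table.loc[table["gender"] == "F", field].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    na, nb = len(a), len(b)
    dof = na + nb - 2
    diff = a.mean() - b.mean()
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / dof
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se <= 1e-12 * (np.abs(np.concatenate([a, b])).max() + 1.0):
        # degenerate noise-free input
        if abs(diff) <= 1e-12 * (abs(a.mean()) + abs(b.mean()) + 1.0):
            return 0.0, 1.0
        t = np.inf * np.sign(diff)
        return float(t), 0.0
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), dof)
    return float(t), float(p)
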