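"""Cross-validated linear-SVM classification with embedded feature selection.

Protocol: per training fold, rank all features by |SVM weight| (ties by
ascending feature index), retrain on each top-k subset of a feature-count
grid, score the held-out fold, and average fold accuracies per grid
point.  Significance comes from a permutation null built by shuffling
training labels within each fold and re-running the embedded-selection
procedure at the chosen grid point.

Convention: the positive class is male — sensitivity is the fraction of
males classified male, specificity the fraction of females classified
female.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "FoldSpec",
    "CVResult",
    "PermutationNull",
    "residualize_features",
    "znorm_per_subject",
    "concat_modalities",
    "make_folds",
    "make_feature_grid",
    "cv_classify",
    "roc_auc",
    "permutation_test",
]


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with per-column provenance tags."""

    values: np.ndarray
    feature_ids: list = field(default_factory=list)
    modality: str = "unknown"
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if not self.feature_ids:
            self.feature_ids = [
                (self.modality, j) for j in range(self.values.shape[1])
            ]
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length must equal number of columns")
        if not self.subject_ids:
            self.subject_ids = list(range(self.values.shape[0]))
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must equal number of rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class FoldSpec:
    """Partition of subjects into k folds with per-fold group composition."""

    k: int
    assignments: np.ndarray
    per_fold_composition: list

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments != fold)[0]


@dataclass
class CVResult:
    """Cross-validation results across a feature-count grid."""

    grid: list
    fold_accuracies: np.ndarray  # (n_grid, k)
    mean_accuracy: np.ndarray  # (n_grid,)
    pooled_accuracy: np.ndarray  # (n_grid,)
    sensitivity: np.ndarray  # (n_grid,), fold-averaged
    specificity: np.ndarray  # (n_grid,), fold-averaged
    decision_values: np.ndarray  # (n_grid, n_subjects), pooled over test folds
    auc: np.ndarray  # (n_grid,)
    best_grid_point: int

    @property
    def best_n_features(self) -> int:
        return self.grid[self.best_grid_point]

    @property
    def best_mean_accuracy(self) -> float:
        return float(self.mean_accuracy[self.best_grid_point])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": self.grid,
                "mean_accuracy": self.mean_accuracy,
                "pooled_accuracy": self.pooled_accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "auc": self.auc,
            }
        )


@dataclass
class PermutationNull:
    """Permutation null distribution of mean accuracies with its p value."""

    n_perm: int
    null_accuracies: np.ndarray
    p_value: float
    bonferroni_factor: int = 1

    @property
    def p_bonferroni(self) -> float:
        return min(1.0, self.p_value * self.bonferroni_factor)


def _is_male(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UOS":
        return y == "M"
    return y.astype(bool)


def residualize_features(
    X: FeatureMatrix, covariates: np.ndarray | pd.DataFrame
) -> FeatureMatrix:
    """Replace each column by its residual after regressing out covariates.

    The fit uses ALL subjects (the protocol's choice; note this leaks
    test-set covariate information into training when done before CV —
    restrict to training rows yourself for a strict variant).
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = X.n_subjects
    if C.shape[0] != n:
        raise ValueError("covariate rows must match subjects")
    D = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate design is rank deficient")
    beta, *_ = np.linalg.lstsq(D, X.values, rcond=None)
    resid = X.values - D @ beta
    return FeatureMatrix(resid, list(X.feature_ids), X.modality, list(X.subject_ids))


def znorm_per_subject(X: FeatureMatrix) -> FeatureMatrix:
    """Standardize each subject's row to mean 0, SD 1 across features.

    Population SD convention (divide by the number of features).
    """
    mu = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, keepdims=True)  # ddof=0
    if np.any(sd == 0):
        bad = np.nonzero(sd.ravel() == 0)[0].tolist()
        raise ValueError(f"zero feature variance for subject rows {bad}")
    return FeatureMatrix(
        (X.values - mu) / sd, list(X.feature_ids), X.modality, list(X.subject_ids)
    )


def concat_modalities(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate modality matrices column-wise, preserving provenance."""
    if not parts:
        raise ValueError("no parts to concatenate")
    if len(parts) == 1:
        p = parts[0]
        return FeatureMatrix(
            p.values.copy(), list(p.feature_ids), p.modality, list(p.subject_ids)
        )
    subj = parts[0].subject_ids
    for p in parts[1:]:
        if p.subject_ids != subj:
            raise ValueError("subject ordering differs between parts")
    values = np.hstack([p.values for p in parts])
    ids = [fid for p in parts for fid in p.feature_ids]
    return FeatureMatrix(values, ids, "combined", list(subj))


def make_folds(n_male: int, n_female: int, k: int, seed: int = 0) -> FoldSpec:
    """Group-stratified folds: k-1 equal folds plus a remainder fold.

    The first k-1 folds each hold floor(n_g / k) randomly chosen subjects
    of group g; the last fold takes everyone left over.  Assignments
    assume subjects ordered males first (indices 0..n_male-1), then
    females.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_male < k or n_female < k:
        raise ValueError("each group must have at least k subjects")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n_male + n_female, dtype=int)
    comp = np.zeros((k, 2), dtype=int)
    for col, (n_g, offset) in enumerate([(n_male, 0), (n_female, n_male)]):
        per = n_g // k
        order = rng.permutation(n_g) + offset
        pos = 0
        for f in range(k - 1):
            assignments[order[pos : pos + per]] = f
            comp[f, col] += per
            pos += per
        assignments[order[pos:]] = k - 1
        comp[k - 1, col] += n_g - pos
    return FoldSpec(
        k=k,
        assignments=assignments,
        per_fold_composition=[(int(m), int(f)) for m, f in comp],
    )


def make_feature_grid(step: int, total: int) -> tuple[int, ...]:
    """(step, 2*step, ..., largest multiple < total, total)."""
    if step <= 0 or total <= 0:
        raise ValueError("step and total must be positive")
    if step > total:
        return (total,)
    grid = list(range(step, total, step))
    grid.append(total)
    return tuple(grid)


def _fit_svm(Xtr: np.ndarray, ytr: np.ndarray, C: float) -> SVC:
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xtr, ytr.astype(int))
    return clf


def _rank_features(w: np.ndarray) -> np.ndarray:
    """Descending |weight| order; ties broken by ascending feature index."""
    return np.argsort(-np.abs(w), kind="stable")


def cv_classify(
    X: FeatureMatrix,
    y: np.ndarray,
    folds: FoldSpec,
    grid: tuple[int, ...] | list[int],
    C: float = 1.0,
) -> CVResult:
    """Run the full embedded-selection cross-validation.

    Per fold: fit a linear SVM on all training features, rank by
    |weight|, then for each grid point retrain on the top-k features and
    score the held-out fold.  The overall accuracy per grid point is the
    unweighted mean of fold accuracies; a pooled-count accuracy is also
    reported.  Decision values are pooled over test folds (one value per
    subject per grid point).
    """
    male = _is_male(y)
    n = X.n_subjects
    if len(male) != n or len(folds.assignments) != n:
        raise ValueError("y and folds must align with the feature matrix")
    grid = tuple(int(g) for g in grid)
    if any(g <= 0 or g > X.n_features for g in grid):
        raise ValueError("grid points must lie in [1, n_features]")
    if list(grid) != sorted(set(grid)):
        raise ValueError("grid must be strictly increasing")

    G, k = len(grid), folds.k
    fold_acc = np.zeros((G, k))
    decisions = np.zeros((G, n))
    correct = np.zeros((G, n), dtype=bool)
    sens = np.zeros((G, k))
    spec_ = np.zeros((G, k))

    for f in range(k):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        ytr, yte = male[tr], male[te]
        if len(np.unique(ytr)) < 2 or min((ytr).sum(), (~ytr).sum()) < 2:
            raise ValueError(f"degenerate training set for fold {f}")
        base = _fit_svm(X.values[tr], ytr, C)
        order = _rank_features(base.coef_.ravel())
        for gi, ng in enumerate(grid):
            if ng == X.n_features:
                clf = base
                cols = slice(None)
            else:
                cols = order[:ng]
                clf = _fit_svm(X.values[np.ix_(tr, cols)], ytr, C)
            dec = clf.decision_function(X.values[te][:, cols])
            pred = dec > 0  # positive class = male (label 1)
            decisions[gi, te] = dec
            correct[gi, te] = pred == yte
            fold_acc[gi, f] = (pred == yte).mean()
            sens[gi, f] = pred[yte].mean() if yte.any() else np.nan
            spec_[gi, f] = (~pred[~yte]).mean() if (~yte).any() else np.nan

    mean_acc = fold_acc.mean(axis=1)
    auc = np.array([roc_auc(decisions[gi], male)[1] for gi in range(G)])
    return CVResult(
        grid=list(grid),
        fold_accuracies=fold_acc,
        mean_accuracy=mean_acc,
        pooled_accuracy=correct.mean(axis=1),
        sensitivity=np.nanmean(sens, axis=1),
        specificity=np.nanmean(spec_, axis=1),
        decision_values=decisions,
        auc=auc,
        best_grid_point=int(np.argmax(mean_acc)),
    )


def roc_auc(
    decision_values: np.ndarray, y: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC with males as the positive class.

    AUC equals the probability that a random male's decision value
    exceeds a random female's, counting ties as one half (rank formula).
    """
    male = _is_male(y)
    d = np.asarray(decision_values, dtype=float)
    n_pos = int(male.sum())
    n_neg = int((~male).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(d)
    auc = (ranks[male].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(d)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        tpr.append((d[male] >= thr).mean())
        fpr.append((d[~male] >= thr).mean())
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return curve, float(auc)


def permutation_test(
    X: FeatureMatrix,
    y: np.ndarray,
    folds: FoldSpec,
    n_selected: int,
    n_perm: int,
    actual_accuracy: float,
    seed: int = 0,
    C: float = 1.0,
    bonferroni_factor: int = 1,
) -> PermutationNull:
    """Permutation null for the mean accuracy at one grid point.

    Each permutation shuffles the training labels within every fold's
    training set, re-runs ranking plus top-``n_selected`` retraining, and
    scores the held-out fold against the TRUE labels; the mean fold
    accuracy enters the null.  p = #(null >= actual) / n_perm, floored at
    1 / n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    male = _is_male(y)
    rng = np.random.default_rng(seed)
    n_feat = X.n_features
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        accs = np.empty(folds.k)
        for f in range(folds.k):
            tr = folds.train_indices(f)
            te = folds.test_indices(f)
            ytr = male[tr][rng.permutation(len(tr))]
            base = _fit_svm(X.values[tr], ytr, C)
            if n_selected == n_feat:
                clf, cols = base, slice(None)
            else:
                cols = _rank_features(base.coef_.ravel())[:n_selected]
                clf = _fit_svm(X.values[np.ix_(tr, cols)], ytr, C)
            pred = clf.decision_function(X.values[te][:, cols]) > 0
            accs[f] = (pred == male[te]).mean()
        nulls[b] = accs.mean()
    p = max(float((nulls >= actual_accuracy).sum()) / n_perm, 1.0 / n_perm)
    return PermutationNull(
        n_perm=n_perm,
        null_accuracies=nulls,
        p_value=p,
        bonferroni_factor=bonferroni_factor,
    )
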