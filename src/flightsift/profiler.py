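"""DAPC-based binary flight-class profiling.

A discriminant analysis of principal components: PCA on training
genotype dosages, linear discriminant on the retained scores (one axis
for two classes), nearest-centroid assignment on that axis.  The
replicated profiling procedure trains on a stratified 50/50 subset,
selects the retained PC count by cross-validation on the training set
only, predicts all remaining samples, and repeats; per-replicate
success is tested against chance with a one-tailed binomial test.

Test samples never influence PCA centering, loadings, imputation, or
the discriminant fit (the leakage guard): all statistics are estimated
from the training partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .dataio import MISSING, GenotypeMatrix

__all__ = [
    "DAPCClassifier",
    "xval_npcs",
    "replicate_profiling",
    "binomial_success_test",
    "ProfilingReport",
]


class DAPCClassifier(ClassifierMixin, BaseEstimator):
    """Discriminant analysis of principal components for two classes.

    Parameters
    ----------
    n_pcs : int
        Number of principal components retained before the discriminant.
    scale : bool
        Scale dosages to unit variance before the PCA (centering always
        applies).
    ridge : float
        Regularization added if the within-class scatter is singular.

    Attributes (set by :meth:`fit`)
    ----------
    classes_ : ndarray of the two class labels
    pca_ : fitted PCA on training dosages
    lda_ : fitted linear discriminant on the retained scores
    col_mean_ : training column means used to impute missing dosages
    """

    def __init__(self, n_pcs: int = 2, scale: bool = False, ridge: float = 1e-8):
        self.n_pcs = n_pcs
        self.scale = scale
        self.ridge = ridge

    def _impute(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = x.copy()
        miss = x == MISSING
        if miss.any():
            out[miss] = np.take(self.col_mean_, np.nonzero(miss)[1])
        return out

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("DAPC profiling is binary; got "
                             f"{self.classes_.size} classes")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("each class needs at least 2 training samples")
        obs = X != MISSING
        self.col_mean_ = np.where(obs, X, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
        xi = self._impute(X)
        if self.scale:
            self.col_scale_ = xi.std(axis=0)
            self.col_scale_[self.col_scale_ == 0] = 1.0
            xi = xi / self.col_scale_
        n_pcs = min(self.n_pcs, min(xi.shape) - 1) or 1
        self.pca_ = PCA(n_components=n_pcs).fit(xi)
        scores = self.pca_.transform(xi)
        try:
            self.lda_ = LinearDiscriminantAnalysis(solver="svd").fit(scores, y)
            self.lda_.predict(scores)
        except np.linalg.LinAlgError:
            self.lda_ = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=self.ridge).fit(scores, y)
        self.training_accuracy_ = float((self.lda_.predict(scores) == y).mean())
        return self

    def _transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        xi = self._impute(X)
        if self.scale:
            xi = xi / self.col_scale_
        return self.pca_.transform(xi)

    def predict(self, X):
        return self.lda_.predict(self._transform(X))

    def predict_proba(self, X):
        return self.lda_.predict_proba(self._transform(X))


def xval_npcs(
    X, y, grid, reps: int = 30, train_frac: float = 0.9, seed: int = 0
) -> int:
    """Select the retained PC count by repeated stratified validation.

    Mean validation success is computed per grid value over ``reps``
    random ``train_frac`` splits; the argmax wins, ties going to the
    smallest PC count.
    """
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValueError("empty PC grid")
    if len(grid) == 1:
        return grid[0]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    success = np.zeros(len(grid))
    for _ in range(reps):
        train_idx: list[int] = []
        for c in classes:
            members = np.flatnonzero(y == c)
            n_train = max(2, int(round(train_frac * members.size)))
            if n_train >= members.size:
                n_train = members.size - 1
            if n_train < 2:
                raise ValueError(f"class {c!r} too small to stratify")
            train_idx.extend(rng.choice(members, size=n_train, replace=False))
        train = np.zeros(len(y), dtype=bool)
        train[train_idx] = True
        for gi, k in enumerate(grid):
            model = DAPCClassifier(n_pcs=k).fit(X[train], y[train])
            success[gi] += (model.predict(X[~train]) == y[~train]).mean()
    return grid[int(np.argmax(success))]  # argmax takes the first (smallest) on ties


def binomial_success_test(k: int, n: int, p0: float) -> float:
    """One-tailed upper binomial p-value: P(Binomial(n, p0) >= k)."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass
class ProfilingReport:
    """Replicated train/hold-out assignment success."""

    replicates: list[dict] = field(default_factory=list)
    mean_success: float = np.nan
    se_success: float = np.nan
    chance_model: str = "majority"

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def replicate_profiling(
    matrix: GenotypeMatrix,
    labels: np.ndarray,
    loci_subset,
    n_train_per_class: int = 50,
    n_reps: int = 10,
    seed: int = 0,
    pc_grid=None,
    chance: str = "majority",
    xval_reps: int = 30,
) -> ProfilingReport:
    """The replicated DAPC profiling procedure.

    Per replicate: draw a stratified training set (``n_train_per_class``
    per class), select the PC count by cross-validation within the
    training set, fit the DAPC, predict every remaining sample, and test
    the success count against chance.  ``chance="majority"`` uses each
    replicate's test-set majority-class proportion as the null success
    probability (conservative); ``chance="uniform"`` uses 0.5.

    ``loci_subset`` indexes the marker panel (column indices or
    "contig:position" ids).  ``pc_grid=None`` uses a doubling grid
    (1, 2, 4, ...) extended to the panel rank, so the search space is
    never truncated below the number of markers.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_samples:
        raise ValueError("labels length must match sample count")
    cols = []
    id_of = {f"{l.contig}:{l.position}": j for j, l in enumerate(matrix.loci)}
    for item in loci_subset:
        if isinstance(item, str):
            if item not in id_of:
                raise KeyError(f"locus {item!r} not in matrix")
            cols.append(id_of[item])
        else:
            cols.append(int(item))
    X = matrix.dosage[:, cols].astype(float)

    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("profiling needs exactly 2 classes")
    for c in classes:
        if (labels == c).sum() < n_train_per_class + 1:
            raise ValueError(f"class {c!r} has fewer than {n_train_per_class + 1} samples")

    if pc_grid is None:
        cap = min(len(cols), 2 * n_train_per_class - len(classes))
        grid = [1]
        while grid[-1] * 2 < cap:
            grid.append(grid[-1] * 2)
        if grid[-1] != cap:
            grid.append(cap)
        pc_grid = tuple(grid)

    rng = np.random.default_rng(seed)
    report = ProfilingReport(chance_model=chance)
    successes = []
    for rep in range(n_reps):
        train = np.zeros(len(labels), dtype=bool)
        for c in classes:
            members = np.flatnonzero(labels == c)
            train[rng.choice(members, size=n_train_per_class, replace=False)] = True
        test = ~train
        k_pcs = xval_npcs(X[train], labels[train], pc_grid, reps=xval_reps,
                          seed=int(rng.integers(2**31)))
        model = DAPCClassifier(n_pcs=k_pcs).fit(X[train], labels[train])
        pred = model.predict(X[test])
        n_test = int(test.sum())
        n_correct = int((pred == labels[test]).sum())
        success = n_correct / n_test
        if chance == "majority":
            p0 = max((labels[test] == c).mean() for c in classes)
            p0 = min(max(p0, 1e-9), 1 - 1e-9)
        else:
            p0 = 0.5
        p = binomial_success_test(n_correct, n_test, p0)
        successes.append(success)
        report.replicates.append({
            "replicate": rep,
            "n_pcs": k_pcs,
            "n_train": int(train.sum()),
            "n_test": n_test,
            "n_correct": n_correct,
            "success": success,
            "chance_p0": float(p0),
            "binomial_p": p,
        })
    arr = np.array(successes)
    report.mean_success = float(arr.mean())
    report.se_success = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return report
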