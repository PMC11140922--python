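"""Population and family structure: the GWAS covariate machinery.

Implements the KING-robust pairwise kinship estimator, a greedy
kinship-threshold partition into unrelated/related sample sets, PCA fit
on the unrelated set with projection of relatives (PC-AiR style), and
PC-adjusted residual kinship from individual-specific allele
frequencies (PC-Relate style).  Downstream GWAS models use the leading
PCs and, optionally, leading eigenvectors of the PC-adjusted kinship
matrix as fixed-effect covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import MISSING, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "StructureModel",
    "king_kinship",
    "partition_unrelated",
    "pca_unrelated_project",
    "pc_adjusted_kinship",
    "kinship_factors",
]

#: Default kinship threshold separating unrelated from related pairs
#: (between 3rd- and 4th-degree relatives).
DEFAULT_KINSHIP_THRESHOLD = 0.025


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric; NaN where no informative loci were shared
    estimator: str  # {"king_robust", "pc_adjusted"}

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape mismatch")

    def pair(self, i: str, j: str) -> float:
        a = self.sample_ids.index(i)
        b = self.sample_ids.index(j)
        return float(self.values[a, b])


@dataclass
class StructureModel:
    """PCA of genome-wide structure fit on unrelateds, projected to all."""

    n_pcs: int
    scores: np.ndarray  # n_samples x n_pcs, ordered as the input matrix samples
    loadings: np.ndarray  # n_used_loci x n_pcs
    eigenvalues: np.ndarray  # all eigenvalues of the unrelated-set covariance
    unrelated: np.ndarray  # bool per sample
    sample_ids: list[str]
    used_loci: np.ndarray  # indices of loci kept (polymorphic in unrelateds)
    allele_freq: np.ndarray  # p-hat per used locus, from unrelateds
    proportion_structure_explained: float = field(default=0.0)


def king_kinship(matrix: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust kinship over pairwise-complete loci.

    phi_ij = (N_het,het - 2 N_opposite-hom) / (N_het(i) + N_het(j)),
    het counts taken over loci observed in both samples.  Self-kinship
    is 0.5 by convention.  Pairs with a zero denominator (no shared
    heterozygous loci) get NaN.
    """
    if matrix.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    d = matrix.dosage
    obs = (d != MISSING).astype(np.float64)
    het = ((d == 1) & (d != MISSING)).astype(np.float64)
    hom0 = (d == 0).astype(np.float64)
    hom2 = (d == 2).astype(np.float64)

    n_het_het = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_shared_i = het @ obs.T  # loci where i is het and j observed
    denom = het_shared_i + het_shared_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_het_het - 2.0 * n_opp) / denom, np.nan)
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(sample_ids=list(matrix.samples), values=phi, estimator="king_robust")


def partition_unrelated(kinship: KinshipMatrix, threshold: float = DEFAULT_KINSHIP_THRESHOLD) -> np.ndarray:
    """Greedy partition into a maximal unrelated set.

    While any remaining pair exceeds the threshold, the sample with the
    most above-threshold partners is moved to the related set (ties:
    larger mean kinship among remaining samples, then lexicographically
    smaller id).  Returns a boolean array: True = unrelated.
    """
    n = len(kinship.sample_ids)
    phi = kinship.values.copy()
    np.fill_diagonal(phi, 0.0)
    phi = np.nan_to_num(phi, nan=0.0)
    active = np.ones(n, dtype=bool)
    ids = np.array(kinship.sample_ids)
    while True:
        sub = phi[np.ix_(active, active)]
        over = sub > threshold
        if not over.any():
            break
        counts = over.sum(axis=1)
        means = sub.mean(axis=1)
        active_idx = np.flatnonzero(active)
        # ties: larger mean kinship, then lexicographically smaller id
        order = sorted(
            range(len(active_idx)),
            key=lambda k: (-counts[k], -means[k], ids[active_idx[k]]),
        )
        active[active_idx[order[0]]] = False
    return active


def pca_unrelated_project(matrix: GenotypeMatrix, unrelated: np.ndarray, n_pcs: int) -> StructureModel:
    """PCA on the unrelated set with projection of related samples.

    Loci are centered at 2*p-hat and scaled by sqrt(2 p (1-p)) with
    p-hat estimated from unrelateds; missing dosages are mean-imputed
    for the decomposition only.  Loci monomorphic in the unrelated set
    are dropped.  proportion_structure_explained is the retained share
    of total variance on the unrelated set.
    """
    unrelated = np.asarray(unrelated, dtype=bool)
    if not unrelated.any():
        raise ValueError("unrelated set is empty")
    d = matrix.dosage.astype(float)
    obs = matrix.dosage != MISSING
    du = d[unrelated]
    obsu = obs[unrelated]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obsu.sum(axis=0) > 0,
                     np.where(obsu, du, 0).sum(axis=0) / (2.0 * obsu.sum(axis=0)), np.nan)
    used = np.flatnonzero((p > 0) & (p < 1))
    p = p[used]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    x = (d[:, used] - 2.0 * p) / scale
    x[~obs[:, used]] = 0.0  # mean imputation after standardization

    xu = x[unrelated]
    n_u = xu.shape[0]
    max_pcs = min(n_u, xu.shape[1])
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds available rank {max_pcs}")
    _, s, vt = np.linalg.svd(xu, full_matrices=False)
    eigenvalues = s**2 / max(n_u - 1, 1)
    loadings = vt[:n_pcs].T
    scores = x @ loadings
    total = eigenvalues.sum()
    proportion = float(eigenvalues[:n_pcs].sum() / total) if total > 0 else 0.0
    return StructureModel(
        n_pcs=n_pcs,
        scores=scores,
        loadings=loadings,
        eigenvalues=eigenvalues,
        unrelated=unrelated,
        sample_ids=list(matrix.samples),
        used_loci=used,
        allele_freq=p,
        proportion_structure_explained=proportion,
    )


def pc_adjusted_kinship(
    matrix: GenotypeMatrix, structure: StructureModel, n_pcs: int | None = None,
    clamp: tuple[float, float] = (0.01, 0.99),
) -> KinshipMatrix:
    """Residual kinship conditional on population structure.

    Individual-specific frequencies mu_il come from a per-locus linear
    regression of dosage/2 on the PC scores; the kinship estimate is

        phi_ij = sum_l (g_il - 2 mu_il)(g_jl - 2 mu_jl)
                 / sum_l 4 sqrt(mu_il (1-mu_il) mu_jl (1-mu_jl))

    with sums over loci observed in both samples.
    """
    k = structure.n_pcs if n_pcs is None else n_pcs
    if k > structure.scores.shape[1]:
        raise ValueError("n_pcs exceeds PCs available in the structure model")
    z = np.column_stack([np.ones(len(structure.sample_ids)), structure.scores[:, :k]])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("degenerate regression design: constant PC columns")

    used = structure.used_loci
    d = matrix.dosage[:, used].astype(float)
    obs = matrix.dosage[:, used] != MISSING
    # mean-impute missing dosages for the frequency regressions only
    col_mean = np.where(obs, d, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    d_fit = np.where(obs, d, col_mean)
    beta, *_ = np.linalg.lstsq(z, d_fit / 2.0, rcond=None)
    mu = np.clip(z @ beta, clamp[0], clamp[1])

    resid = np.where(obs, d - 2.0 * mu, 0.0)
    scale = np.where(obs, 2.0 * np.sqrt(mu * (1.0 - mu)), 0.0)
    num = resid @ resid.T
    den = scale @ scale.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, np.nan)
    return KinshipMatrix(sample_ids=list(matrix.samples), values=phi, estimator="pc_adjusted")


def kinship_factors(kinship: KinshipMatrix, n_factors: int = 2) -> np.ndarray:
    """Leading eigenvectors of a kinship matrix, for use as fixed-effect
    covariates in the association models."""
    phi = np.nan_to_num(kinship.values, nan=0.0)
    phi = (phi + phi.T) / 2.0
    w, v = np.linalg.eigh(phi)
    order = np.argsort(w)[::-1]
    return v[:, order[:n_factors]]
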