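"""Score-test association scans with structure covariates.

For each phenotype (binary flight class via a binomial link, forewing
length in mm via a gaussian link) a single null model with fixed-effect
covariates (intercept + leading PCs + optional kinship factors) is fit,
and every locus is tested with a 1-df score test:

    U = x' (y - mu0) / a,    V = x'Wx - x'WZ (Z'WZ)^-1 Z'Wx,
    U^2 / V ~ chi-square(1),

with W the variance-function weights and a the dispersion from the null
fit (binomial: W = mu(1-mu), a = 1; gaussian: W = I, a = sigma^2), and
both U and V scaled by 1/a.  Model diagnostics (AIC, genomic
inflation factor, QQ data) support the grid-based PC-count selection.
Candidate genes are assigned to outlier loci through strong LD
(|r| >= 0.90 by default) with loci lying inside annotated gene spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import MISSING, GeneModel, GenotypeMatrix

__all__ = [
    "AssocResult",
    "CandidateGeneSet",
    "bin_flight",
    "score_test_scan",
    "model_grid",
    "backward_select_pcs",
    "adjust_p",
    "ld_annotate",
    "candidate_overlap",
]

#: Median of the 1-df chi-square distribution, the GIF denominator.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def bin_flight(scores) -> np.ndarray:
    """Bin ordinal 0-5 flight scores: 0-2 -> 0 (no flight), 3-5 -> 1 (flight)."""
    arr = np.asarray(scores, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("flight scores contain missing values; drop them first")
    if ((arr < 0) | (arr > 5) | (arr % 1 != 0)).any():
        raise ValueError("flight scores must be integers in 0..5")
    return (arr >= 3).astype(int)


@dataclass
class AssocResult:
    """Per-locus score statistics plus model-level diagnostics."""

    link: str  # {"binomial", "gaussian"}
    covariate_spec: str
    table: pd.DataFrame  # contig, position, stat, p, p_adj, sign
    aic: float
    gif: float
    converged: bool
    n_samples: int
    qq: pd.DataFrame = field(default_factory=pd.DataFrame)

    def outliers(self, p_max: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "p_adj" if adjusted else "p"
        return self.table[self.table[col] < p_max]


def _null_fit(y: np.ndarray, z: np.ndarray, link: str):
    """Fit the covariates-only model; return (mu, w, a, aic, converged)."""
    if link == "binomial":
        model = sm.GLM(y, z, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
        mu = res.fittedvalues
        w = mu * (1.0 - mu)
        a = 1.0
    elif link == "gaussian":
        model = sm.GLM(y, z, family=sm.families.Gaussian())
        res = model.fit()
        mu = res.fittedvalues
        sigma2 = float(np.sum((y - mu) ** 2) / len(y))  # MLE dispersion
        w = np.ones(len(y))  # unit variance function; dispersion enters via a
        a = sigma2
    else:
        raise ValueError(f"unknown link {link!r}")
    converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(res.params))
    # degenerate fits (fitted probabilities pinned at 0/1) are not resolved
    if link == "binomial" and (w < 1e-10).all():
        converged = False
    return mu, w, a, float(res.aic), converged


def _score_stats(x: np.ndarray, y: np.ndarray, z: np.ndarray, mu, w, a) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1-df score statistics for genotype columns ``x``."""
    r = (y - mu) / a
    u = x.T @ r
    wx = x * w[:, None]
    zwz = z.T @ (z * w[:, None])
    zwx = z.T @ wx
    solved = np.linalg.solve(zwz, zwx)
    v = np.einsum("ij,ij->j", x, wx) - np.einsum("ij,ij->j", zwx, solved)
    v = v / a
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(v > 1e-12, u**2 / v, np.nan)
    return stat, np.sign(u)


def score_test_scan(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    link: str,
    covariate_spec: str = "",
    p_adjust: str = "bh",
) -> AssocResult:
    """Scan every locus with the score test against the shared null fit.

    Samples with missing phenotype are dropped.  Loci with missing
    genotypes use their observed subset, with the null refit on that
    subset (fits are cached per missingness pattern).
    """
    if link not in ("binomial", "gaussian"):
        raise ValueError(f"unknown link {link!r}")
    phenotype = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(phenotype)
    y = phenotype[keep]
    cov = None if covariates is None else np.asarray(covariates, float)[keep]
    z = np.ones((len(y), 1)) if cov is None or cov.size == 0 else np.column_stack([np.ones(len(y)), cov])
    d = matrix.dosage[keep, :].astype(float)
    obs = matrix.dosage[keep, :] != MISSING

    try:
        mu0, w0, a0, aic, converged = _null_fit(y, z, link)
    except Exception:
        converged, aic = False, np.nan
    if not converged:
        return AssocResult(link=link, covariate_spec=covariate_spec, table=pd.DataFrame(),
                           aic=aic if np.isfinite(aic) else np.nan, gif=np.nan,
                           converged=False, n_samples=int(keep.sum()))

    stat = np.full(matrix.n_loci, np.nan)
    sign = np.full(matrix.n_loci, np.nan)

    complete = obs.all(axis=0)
    if complete.any():
        s, g = _score_stats(d[:, complete], y, z, mu0, w0, a0)
        stat[complete] = s
        sign[complete] = g

    # group incomplete loci by missingness pattern; refit null per pattern
    incomplete = np.flatnonzero(~complete)
    patterns: dict[bytes, list[int]] = {}
    for j in incomplete:
        patterns.setdefault(obs[:, j].tobytes(), []).append(j)
    for key, cols in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        if mask.sum() < z.shape[1] + 2:
            continue  # too few observed calls to test
        try:
            mu, w, a, _, ok = _null_fit(y[mask], z[mask], link)
        except Exception:
            ok = False
        if not ok:
            continue
        s, g = _score_stats(d[np.ix_(mask, cols)], y[mask], z[mask], mu, w, a)
        stat[cols] = s
        sign[cols] = g

    with np.errstate(invalid="ignore"):
        p = stats.chi2.sf(stat, df=1)
    valid = np.isfinite(stat)
    gif = float(np.median(stat[valid]) / CHI2_1DF_MEDIAN) if valid.any() else np.nan
    p_adj = np.full_like(p, np.nan)
    if valid.any():
        p_adj[valid] = adjust_p(p[valid], method=p_adjust)

    table = pd.DataFrame({
        "contig": [l.contig for l in matrix.loci],
        "position": [l.position for l in matrix.loci],
        "stat": stat,
        "p": p,
        "p_adj": p_adj,
        "sign": sign,
    })
    n_obs = int(valid.sum())
    expected = -np.log10((np.arange(1, n_obs + 1) - 0.5) / n_obs) if n_obs else np.array([])
    observed = -np.log10(np.sort(p[valid])[::-1])[::-1] if n_obs else np.array([])
    qq = pd.DataFrame({"expected": expected, "observed": observed})
    return AssocResult(link=link, covariate_spec=covariate_spec, table=table,
                       aic=aic, gif=gif, converged=True, n_samples=len(y), qq=qq)


def model_grid(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray,
    pc_scores: np.ndarray,
    pc_grid,
    link: str,
    kinship_covariates: np.ndarray | None = None,
) -> tuple[list[AssocResult], int]:
    """One scan per candidate PC count.

    Returns the results and the index of the default selection: the
    largest PC count whose model converged ("resolved").  AIC, GIF and
    QQ data are attached to every result for manual override.
    """
    pc_grid = list(pc_grid)
    if not pc_grid:
        raise ValueError("empty PC grid")
    results = []
    for k in pc_grid:
        cov = pc_scores[:, :k] if k > 0 else None
        if kinship_covariates is not None:
            kc = np.asarray(kinship_covariates, float)
            cov = kc if cov is None else np.column_stack([cov, kc])
        spec = f"{k} PCs" + ("" if kinship_covariates is None else " + kinship factors")
        results.append(score_test_scan(matrix, phenotype, cov, link, covariate_spec=spec))
    converged = [i for i, r in enumerate(results) if r.converged]
    if not converged:
        raise RuntimeError("no model in the PC grid resolved statistically")
    selected = max(converged, key=lambda i: pc_grid[i])
    return results, selected


def backward_select_pcs(
    phenotype: np.ndarray, pc_scores: np.ndarray, link: str, max_pcs: int | None = None
) -> list[int]:
    """Backwards stepwise PC selection on the null (covariates-only) model.

    Starting from the largest PC set, repeatedly drop the PC with the
    largest coefficient p-value while the AIC improves.  Returns the
    retained PC column indices.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(phenotype)
    y = phenotype[keep]
    k = pc_scores.shape[1] if max_pcs is None else max_pcs
    current = list(range(k))
    family = sm.families.Binomial() if link == "binomial" else sm.families.Gaussian()

    def fit(cols):
        z = np.column_stack([np.ones(len(y))] + [pc_scores[keep, c] for c in cols])
        return sm.GLM(y, z, family=family).fit()

    res = fit(current)
    while current:
        pvals = res.pvalues[1:]
        worst = int(np.argmax(pvals))
        trial = current[:worst] + current[worst + 1:]
        res_trial = fit(trial)
        if res_trial.aic < res.aic:
            current, res = trial, res_trial
        else:
            break
    return current


def adjust_p(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg (default) or Bonferroni."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


def _abs_corr_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| between vector ``x`` and each column of ``y`` on
    pairwise-complete dosages."""
    out = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        ok = (x != MISSING) & (y[:, j] != MISSING)
        if ok.sum() < 2:
            continue
        xv = x[ok].astype(float)
        yv = y[ok, j].astype(float)
        if xv.std() == 0 or yv.std() == 0:
            out[j] = 1.0 if np.array_equal(xv, yv) else 0.0
            continue
        out[j] = abs(float(np.corrcoef(xv, yv)[0, 1]))
    return out


@dataclass
class CandidateGeneSet:
    """Genes assigned to one flight analysis, with supporting markers."""

    tag: str  # {"flight_capability", "forewing_length", "inbred", "expression"}
    genes: dict = field(default_factory=dict)  # gene_id -> {"marker": str, "p": float, "r": float}

    @property
    def gene_ids(self) -> set:
        return set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def ld_annotate(
    matrix: GenotypeMatrix,
    assoc: AssocResult,
    genes: list[GeneModel],
    tag: str,
    r_min: float = 0.90,
    p_max: float = 0.05,
    use_adjusted: bool = False,
) -> CandidateGeneSet:
    """Assign candidate genes to association outliers via strong LD.

    For each locus with p < ``p_max``, dosage correlation is computed to
    every locus lying within a gene span on the same contig; the gene is
    a candidate iff any |r| >= ``r_min``.  An outlier inside a gene span
    annotates it trivially (r = 1 with itself).  Each candidate gene
    records its best (smallest-p) supporting outlier.
    """
    col = "p_adj" if use_adjusted else "p"
    pvals = assoc.table[col].to_numpy()
    contigs = np.array(matrix.contigs())
    positions = np.array([l.position for l in matrix.loci])
    sig = np.flatnonzero(pvals < p_max)

    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)

    result = CandidateGeneSet(tag=tag)
    for i in sig:
        contig = contigs[i]
        here = genes_by_contig.get(contig)
        if not here:
            continue
        on_contig = np.flatnonzero(contigs == contig)
        for gene in here:
            in_gene = on_contig[(positions[on_contig] >= gene.start)
                                & (positions[on_contig] <= gene.end)]
            if in_gene.size == 0:
                continue
            if i in in_gene:
                best_r = 1.0
            else:
                best_r = float(
                    _abs_corr_columns(matrix.dosage[:, i], matrix.dosage[:, in_gene]).max()
                )
            if best_r >= r_min:
                prev = result.genes.get(gene.gene_id)
                if prev is None or pvals[i] < prev["p"]:
                    result.genes[gene.gene_id] = {
                        "marker": f"{contig}:{positions[i]}",
                        "p": float(pvals[i]),
                        "r": best_r,
                    }
    return result


def candidate_overlap(sets: list[CandidateGeneSet]) -> pd.DataFrame:
    """Pairwise and all-way intersection counts of candidate gene ids."""
    if len(sets) < 2:
        raise ValueError("need at least two candidate sets")
    rows = []
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            rows.append({
                "set_a": sets[a].tag,
                "set_b": sets[b].tag,
                "n_a": len(sets[a]),
                "n_b": len(sets[b]),
                "intersection": len(sets[a].gene_ids & sets[b].gene_ids),
            })
    allway = set.intersection(*(s.gene_ids for s in sets))
    rows.append({"set_a": "ALL", "set_b": "ALL", "n_a": None, "n_b": None,
                 "intersection": len(allway)})
    return pd.DataFrame(rows)
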