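"""The six-rule GWAS-track variant/sample QC cascade.

Rules are applied in this fixed order: (1) biallelic SNPs or indels
only, (2) exact Hardy-Weinberg test in the flight-capable (ASM,
'control') samples at p < 1e-6, (3) minor allele frequency below 0.10
globally AND below 0.30 in ESM samples, (4) missingness > 0.5 or mean
depth < 5, (5) random pruning of within-contig locus pairs in complete
LD (|r| = 1), and (6) removal of samples with > 0.5 missing data.
Permuting rules (3) and (5) can change the output; the pipeline fixes
the printed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .dataio import MISSING, GenotypeMatrix

__all__ = [
    "QCConfig",
    "QCReport",
    "hwe_exact_pvalue",
    "filter_biallelic",
    "hwe_filter",
    "maf_filter",
    "missing_depth_filter",
    "ld_prune_complete",
    "sample_filter",
    "run_qc",
]

#: |r| within this tolerance of 1 counts as complete LD.
_COMPLETE_LD_TOL = 1e-12


@dataclass
class QCConfig:
    hwe_alpha: float = 1e-6
    hwe_per_colony: bool = False
    maf_global_min: float = 0.10
    maf_esm_min: float = 0.30
    locus_max_missing: float = 0.5
    min_mean_depth: float = 5.0
    sample_max_missing: float = 0.5
    snps_only: bool = False  # GWAS track retains biallelic SNPs or indels
    seed: int = 0


@dataclass
class QCReport:
    """Bookkeeping for the cascade: per-rule discard counts and log."""

    seed: int
    n_loci_in: int = 0
    n_samples_in: int = 0
    loci_discarded: dict = field(default_factory=dict)
    samples_discarded: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def record(self, rule: str, before: GenotypeMatrix, after: GenotypeMatrix) -> None:
        dl = before.n_loci - after.n_loci
        ds = before.n_samples - after.n_samples
        if dl:
            self.loci_discarded[rule] = self.loci_discarded.get(rule, 0) + dl
        if ds:
            self.samples_discarded[rule] = self.samples_discarded.get(rule, 0) + ds
        self.log.append(f"{rule}: -{dl} loci, -{ds} samples "
                        f"({after.n_loci} loci x {after.n_samples} samples remain)")

    def check_totals(self, out: GenotypeMatrix) -> None:
        assert self.n_loci_in - sum(self.loci_discarded.values()) == out.n_loci
        assert self.n_samples_in - sum(self.samples_discarded.values()) == out.n_samples


# ----------------------------------------------------------------------
# rule (1): biallelic
# ----------------------------------------------------------------------


def filter_biallelic(matrix: GenotypeMatrix, snps_only: bool = False) -> GenotypeMatrix:
    """Re-validate the biallelic invariant; optionally drop indels.

    Multiallelic records are rejected at read time, so loci here are
    biallelic by construction; monomorphic loci are retained (frequency
    is rule 3's business).
    """
    if not snps_only:
        return matrix.take_loci(np.arange(matrix.n_loci))
    keep = np.array([l.is_snp for l in matrix.loci], dtype=bool)
    return matrix.take_loci(keep)


# ----------------------------------------------------------------------
# rule (2): exact HWE in controls
# ----------------------------------------------------------------------


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Full enumeration of heterozygote counts conditional on the observed
    allele counts; the p-value sums the probabilities of all genotype
    configurations no more probable than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.flatnonzero(hets == n_het)[0]]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    obs = dosage != MISSING
    p = np.ones(dosage.shape[1])
    for j in range(dosage.shape[1]):
        col = dosage[obs[:, j], j]
        n_hom1 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom2 = int((col == 2).sum())
        p[j] = hwe_exact_pvalue(n_het, n_hom1, n_hom2)
    return p


def hwe_filter(
    matrix: GenotypeMatrix,
    control_sample_ids,
    alpha: float = 1e-6,
    per_colony: dict | None = None,
) -> GenotypeMatrix:
    """Drop loci violating HWE (exact test p < alpha) among controls.

    Controls are the flight-capable (ASM) samples.  Pooled by default;
    pass ``per_colony`` as {colony: [sample ids]} to discard a locus if
    any single colony violates.
    """
    ids = list(control_sample_ids)
    if not ids:
        raise ValueError("empty control sample set")
    if per_colony:
        violate = np.zeros(matrix.n_loci, dtype=bool)
        for colony_ids in per_colony.values():
            sub = matrix.dosage[matrix.sample_index(colony_ids), :]
            violate |= _hwe_pvalues(sub) < alpha
    else:
        sub = matrix.dosage[matrix.sample_index(ids), :]
        violate = _hwe_pvalues(sub) < alpha
    return matrix.take_loci(~violate)


# ----------------------------------------------------------------------
# rule (3): conjunctive MAF
# ----------------------------------------------------------------------


def _maf(dosage: np.ndarray) -> np.ndarray:
    obs = dosage != MISSING
    alt = np.where(obs, dosage, 0).sum(axis=0).astype(float)
    n = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, 0.0)  # all-missing -> MAF 0, discarded
    return np.minimum(p, 1.0 - p)


def maf_filter(
    matrix: GenotypeMatrix,
    esm_sample_ids,
    global_min: float = 0.10,
    esm_min: float = 0.30,
) -> GenotypeMatrix:
    """Drop loci with global MAF < ``global_min`` AND ESM MAF < ``esm_min``.

    The conjunction keeps loci that are globally rare but common in the
    less-replicated ESM group, where flight-related directional
    selection may concentrate signal.
    """
    maf_global = _maf(matrix.dosage)
    esm = matrix.dosage[matrix.sample_index(list(esm_sample_ids)), :]
    maf_esm = _maf(esm)
    drop = (maf_global < global_min) & (maf_esm < esm_min)
    return matrix.take_loci(~drop)


# ----------------------------------------------------------------------
# rule (4): missingness / depth
# ----------------------------------------------------------------------


def missing_depth_filter(
    matrix: GenotypeMatrix, max_missing: float = 0.5, min_mean_depth: float = 5.0
) -> GenotypeMatrix:
    """Drop loci with missing proportion > ``max_missing`` OR mean depth
    < ``min_mean_depth`` (mean over all samples, missing calls included
    at their recorded depth); both bounds are strict as printed."""
    missing_prop = (matrix.dosage == MISSING).mean(axis=0)
    mean_depth = matrix.depth.mean(axis=0)
    drop = (missing_prop > max_missing) | (mean_depth < min_mean_depth)
    return matrix.take_loci(~drop)


# ----------------------------------------------------------------------
# rule (5): complete-LD pruning
# ----------------------------------------------------------------------


def _pairwise_complete_r(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1])


def ld_prune_complete(matrix: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Randomly discard one member of every within-contig pair in
    complete LD (|r| = 1 on pairwise-complete dosages), iterating until
    no such pair remains."""
    rng = np.random.default_rng(seed)
    contigs = np.array(matrix.contigs())
    keep = np.ones(matrix.n_loci, dtype=bool)
    for contig in dict.fromkeys(contigs):  # preserve order
        idx = list(np.flatnonzero(contigs == contig))
        changed = True
        while changed:
            changed = False
            alive = [i for i in idx if keep[i]]
            for a in range(len(alive)):
                for b in range(a + 1, len(alive)):
                    r = _pairwise_complete_r(matrix.dosage[:, alive[a]],
                                             matrix.dosage[:, alive[b]])
                    if abs(r) >= 1.0 - _COMPLETE_LD_TOL:
                        victim = alive[a] if rng.random() < 0.5 else alive[b]
                        keep[victim] = False
                        changed = True
                        break
                if changed:
                    break
    return matrix.take_loci(keep)


# ----------------------------------------------------------------------
# rule (6): sample missingness
# ----------------------------------------------------------------------


def sample_filter(matrix: GenotypeMatrix, max_missing: float = 0.5) -> GenotypeMatrix:
    """Remove samples with missing proportion > ``max_missing`` (strict)."""
    if matrix.n_loci == 0:
        return matrix.take_samples(np.arange(matrix.n_samples))
    missing_prop = (matrix.dosage == MISSING).mean(axis=1)
    keep = missing_prop <= max_missing
    if not keep.any():
        raise ValueError("sample filter would remove every sample")
    return matrix.take_samples(keep)


# ----------------------------------------------------------------------
# cascade
# ----------------------------------------------------------------------


def run_qc(
    matrix: GenotypeMatrix, sample_table, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply rules (1)-(6) in order; the report accounts for every
    discarded locus and sample."""
    config = config or QCConfig()
    report = QCReport(seed=config.seed, n_loci_in=matrix.n_loci, n_samples_in=matrix.n_samples)

    in_matrix = set(matrix.samples)
    table = sample_table[sample_table["sample_id"].isin(in_matrix)]
    asm_ids = table.loc[table["lineage"] == "ASM", "sample_id"].tolist()
    esm_ids = table.loc[table["lineage"] == "ESM", "sample_id"].tolist()

    m = filter_biallelic(matrix, snps_only=config.snps_only)
    report.record("biallelic", matrix, m)

    per_colony = None
    if config.hwe_per_colony:
        asm = table[table["lineage"] == "ASM"]
        per_colony = {c: g["sample_id"].tolist() for c, g in asm.groupby("colony")}
    m2 = hwe_filter(m, asm_ids, alpha=config.hwe_alpha, per_colony=per_colony)
    report.record("hwe_control", m, m2)

    m3 = maf_filter(m2, esm_ids, global_min=config.maf_global_min, esm_min=config.maf_esm_min)
    report.record("maf", m2, m3)

    m4 = missing_depth_filter(m3, max_missing=config.locus_max_missing,
                              min_mean_depth=config.min_mean_depth)
    report.record("missing_depth", m3, m4)

    m5 = ld_prune_complete(m4, seed=config.seed)
    report.record("complete_ld", m4, m5)

    m6 = sample_filter(m5, max_missing=config.sample_max_missing)
    report.record("sample_missing", m5, m6)

    report.check_totals(m6)
    return m6, report
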