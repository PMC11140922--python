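"""Inbred-line QC and flight co-segregation filtering.

Whole-genome genotypes from an ESM x ASM full-sib pedigree (2 parents,
4 strong flyers, 4 non-flyers) are screened for loci whose genotypes
partition between the phenotype-extreme groups: parents opposite-
homozygous, all flyers homozygous for one allele, and every non-flyer
heterozygous or homozygous for the opposite allele.  Occasional
heterozygotes are tolerated only in the non-flyer group.  Assignment to
groups comes from the phenotype table (parents included in their
phenotype groups); a purely additive allele effect is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeMatrix

__all__ = [
    "InbredQCConfig",
    "SegregationReport",
    "inbred_qc",
    "segregating_candidates",
    "segregation_summary",
]


@dataclass
class InbredQCConfig:
    min_depth: int = 10  # calls below this depth are set missing (boundary inclusive)
    max_heterozygosity: float = 0.93  # above: paralog suspicion, locus discarded
    min_genotyping_rate: float = 0.70  # below: locus discarded
    snps_only: bool = True


def inbred_qc(matrix: GenotypeMatrix, config: InbredQCConfig | None = None) -> GenotypeMatrix:
    """Whole-genome track QC: biallelic SNPs only, calls with fewer than
    ``min_depth`` reads set missing, then loci with heterozygosity above
    ``max_heterozygosity`` (among non-missing calls) or genotyping rate
    below ``min_genotyping_rate`` discarded."""
    config = config or InbredQCConfig()
    if config.snps_only:
        matrix = matrix.take_loci(np.array([l.is_snp for l in matrix.loci], dtype=bool))
    dosage = matrix.dosage.copy()
    dosage[matrix.depth < config.min_depth] = MISSING
    matrix = GenotypeMatrix(samples=list(matrix.samples), loci=list(matrix.loci),
                            dosage=dosage, depth=matrix.depth.copy())
    obs = matrix.observed()
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_obs > 0, ((dosage == 1) & obs).sum(axis=0) / n_obs, 0.0)
    rate = n_obs / matrix.n_samples
    keep = (het <= config.max_heterozygosity) & (rate >= config.min_genotyping_rate)
    return matrix.take_loci(keep)


@dataclass
class SegregationReport:
    """Per-locus co-segregation flags and allele-frequency differences."""

    mode: str
    candidate_loci: list[int]  # column indices into the input matrix
    candidate_ids: list[str]  # "contig:position"
    flags: pd.DataFrame  # per-locus boolean pattern components
    freq_diff: np.ndarray  # per-candidate |freq(flyer allele): flyers - non-flyers|
    flyer_ids: list[str]
    nonflyer_ids: list[str]

    @property
    def n_loci(self) -> int:
        return len(self.candidate_loci)

    @property
    def n_contigs(self) -> int:
        return len({i.split(":")[0] for i in self.candidate_ids})


def _groups_from_table(matrix: GenotypeMatrix, sample_table: pd.DataFrame,
                       flyer_min_score: int = 5, nonflyer_max_score: int = 2):
    table = sample_table[sample_table["sample_id"].isin(set(matrix.samples))]
    parents = table[table["role"] == "parent"]
    if len(parents) != 2:
        raise ValueError(f"expected exactly 2 parents in the matrix, found {len(parents)}")
    scores = table.set_index("sample_id")["flight_score"]
    flyers = [s for s in matrix.samples
              if s in scores.index and pd.notna(scores[s]) and scores[s] >= flyer_min_score]
    nonflyers = [s for s in matrix.samples
                 if s in scores.index and pd.notna(scores[s]) and scores[s] <= nonflyer_max_score]
    if not flyers or not nonflyers:
        raise ValueError("empty flyer or non-flyer group")
    return parents["sample_id"].tolist(), flyers, nonflyers


def segregating_candidates(
    matrix: GenotypeMatrix,
    sample_table: pd.DataFrame,
    mode: str = "conjunction",
    flyer_min_score: int = 5,
    nonflyer_max_score: int = 2,
) -> SegregationReport:
    """Select loci co-segregating with flight between inbred groups.

    Pattern components per locus:

    * ``parents_opposite_hom`` -- the two parents carry opposite
      homozygous genotypes;
    * ``flyers_hom`` -- every flyer (flight score 5, parents included in
      their group) is homozygous for one and the same allele;
    * ``nonflyers_het_or_opposite`` -- every non-flyer is heterozygous
      or homozygous for the opposite allele.

    ``mode="conjunction"`` (default) requires all three components;
    ``mode="union"`` accepts parents-opposite-homozygous OR the
    flyer/non-flyer pattern.  Any missing genotype in a group member
    makes the locus ineligible.  The per-locus allele-frequency
    difference counts the flyer-fixed allele in both groups.
    """
    if mode not in ("conjunction", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    parent_ids, flyer_ids, nonflyer_ids = _groups_from_table(
        matrix, sample_table, flyer_min_score, nonflyer_max_score)

    par = matrix.dosage[matrix.sample_index(parent_ids), :]
    fly = matrix.dosage[matrix.sample_index(flyer_ids), :]
    non = matrix.dosage[matrix.sample_index(nonflyer_ids), :]

    eligible = ((par != MISSING).all(axis=0) & (fly != MISSING).all(axis=0)
                & (non != MISSING).all(axis=0))
    parents_opp = np.isin(par[0], (0, 2)) & np.isin(par[1], (0, 2)) & (par[0] != par[1])
    flyers_hom = np.isin(fly[0], (0, 2)) & (fly == fly[0][None, :]).all(axis=0)
    opposite = 2 - fly[0]
    non_ok = ((non == 1) | (non == opposite[None, :])).all(axis=0)

    if mode == "conjunction":
        candidate = eligible & parents_opp & flyers_hom & non_ok
    else:
        candidate = eligible & (parents_opp | (flyers_hom & non_ok))

    idx = np.flatnonzero(candidate)
    # allele-frequency difference of the flyer-fixed allele between groups;
    # for union-mode candidates without a flyer-fixed allele, use the
    # parent-2 allele as reference
    ref_dosage = np.where(flyers_hom, fly[0], par[1])
    diffs = np.empty(idx.size)
    for k, j in enumerate(idx):
        a = ref_dosage[j]  # 0 or 2: dosage of the reference allele carrier
        def freq(group):
            g = group[:, j].astype(float)
            count = g.sum() if a == 2 else (2.0 * g.size - g.sum())
            return count / (2.0 * g.size)
        diffs[k] = abs(freq(fly) - freq(non))

    flags = pd.DataFrame({
        "locus": [f"{matrix.loci[j].contig}:{matrix.loci[j].position}" for j in range(matrix.n_loci)],
        "eligible": eligible,
        "parents_opposite_hom": parents_opp,
        "flyers_hom": flyers_hom,
        "nonflyers_het_or_opposite": non_ok,
        "candidate": candidate,
    })
    return SegregationReport(
        mode=mode,
        candidate_loci=idx.tolist(),
        candidate_ids=[f"{matrix.loci[j].contig}:{matrix.loci[j].position}" for j in idx],
        flags=flags,
        freq_diff=diffs,
        flyer_ids=flyer_ids,
        nonflyer_ids=nonflyer_ids,
    )


def segregation_summary(report: SegregationReport) -> tuple[float, float, int, int]:
    """(mean, sample SD, n loci, n contigs) of the allele-frequency
    differences across candidate loci."""
    if report.n_loci == 0:
        raise ValueError("no candidate loci to summarize")
    diffs = report.freq_diff
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return mean, sd, report.n_loci, report.n_contigs
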