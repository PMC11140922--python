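"""Canonical in-memory data model and readers/writers.

Every downstream stage consumes the containers defined here; no other
module re-parses files.  Genotypes are stored as alt-allele dosage
(0/1/2) with a reserved missing sentinel, alongside per-call read depth.
Coordinates are 1-based inclusive throughout (VCF/GFF convention); BED
input is converted on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved dosage value marking a missing genotype call.  Depth 0 does
#: not imply a missing genotype (calls may be imputed upstream).
MISSING = -9

LINEAGES = ("ESM", "ASM")
ROLES = ("cohort", "parent", "progeny")

#: The 12 flight-relevant functional category names used throughout.
DEFAULT_CATEGORY_NAMES = (
    "cognition",
    "growth",
    "metabolism",
    "morphology",
    "movement",
    "mutation",
    "neural",
    "rhythm",
    "reproduction",
    "sensory",
    "sexual_dimorphism",
    "social",
)


class DataValidationError(ValueError):
    """Raised when an input file violates the documented contracts."""


@dataclass(frozen=True)
class Locus:
    """A biallelic variant site.

    ``position`` is 1-based.  ``ref_allele``/``alt_allele`` are upper-case
    nucleotide strings; sites where either allele is longer than one base
    are indels and are flagged rather than rejected (association modules
    operate on SNPs only by default).
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataValidationError(f"locus position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise DataValidationError(
                f"ref and alt alleles identical at {self.contig}:{self.position}"
            )

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass
class GenotypeMatrix:
    """Samples x loci alt-allele dosages with per-call depth.

    ``dosage`` holds values in {0, 1, 2} or :data:`MISSING`; ``depth``
    holds non-negative read counts of identical shape.
    """

    samples: list[str]
    loci: list[Locus]
    dosage: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        shape = (len(self.samples), len(self.loci))
        if self.dosage.shape != shape or self.depth.shape != shape:
            raise DataValidationError(
                f"dosage/depth shapes {self.dosage.shape}/{self.depth.shape} "
                f"do not match (samples, loci) = {shape}"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise DataValidationError("dosage values must be in {0,1,2} or MISSING")
        if (self.depth < 0).any():
            raise DataValidationError("depth must be non-negative")
        if len(set(self.samples)) != len(self.samples):
            raise DataValidationError("duplicate sample ids")
        keys = {(l.contig, l.position) for l in self.loci}
        if len(keys) != len(self.loci):
            raise DataValidationError("duplicate (contig, position) among loci")

    # -- basic geometry ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.dosage != MISSING

    def contigs(self) -> list[str]:
        return [l.contig for l in self.loci]

    # -- subsetting ----------------------------------------------------

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            depth=self.depth[:, idx].copy(),
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            dosage=self.dosage[idx, :].copy(),
            depth=self.depth[idx, :].copy(),
        )

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise DataValidationError(f"unknown sample id {exc.args[0]!r}") from exc

    # -- summaries -----------------------------------------------------

    def alt_freq(self) -> np.ndarray:
        """Per-locus alt-allele frequency over non-missing calls (NaN if none)."""
        obs = self.observed()
        d = np.where(obs, self.dosage, 0).astype(float)
        n = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, d.sum(axis=0) / n, np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.depth, other.depth)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its GO Biological Process annotations."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    go_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataValidationError(f"gene {self.gene_id}: start > end")
        object.__setattr__(self, "go_terms", frozenset(self.go_terms))


@dataclass(frozen=True)
class GOTerm:
    term_id: str
    name: str
    definition: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class CategoryScheme:
    """Ordered keyword lists defining flight-relevant functional categories."""

    categories: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, kws in self.categories:
            if not kws:
                raise DataValidationError(f"category {name!r} has no keywords")
            if any(k != k.lower() for k in kws):
                raise DataValidationError(f"category {name!r} keywords must be lower-case")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.categories]

    def __len__(self) -> int:
        return len(self.categories)


# ----------------------------------------------------------------------
# Sample phenotype table
# ----------------------------------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "colony", "lineage", "flight_score", "forewing_length_mm", "role"]


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a phenotype table.

    Required columns: sample_id, colony, lineage; optional: flight_score
    (integer 0-5 or NA), forewing_length_mm (positive or NA), role.
    """
    table = table.copy()
    for col in ("sample_id", "colony", "lineage"):
        if col not in table.columns:
            raise DataValidationError(f"sample table missing column {col!r}")
    if table["sample_id"].duplicated().any():
        raise DataValidationError("duplicate sample_id in phenotype table")
    bad_lineage = ~table["lineage"].isin(LINEAGES)
    if bad_lineage.any():
        raise DataValidationError(
            f"unknown lineage code(s): {sorted(table.loc[bad_lineage, 'lineage'].unique())}"
        )
    if "flight_score" not in table.columns:
        table["flight_score"] = pd.NA
    fs = pd.to_numeric(table["flight_score"], errors="coerce")
    present = fs.notna()
    if ((fs[present] < 0) | (fs[present] > 5) | (fs[present] % 1 != 0)).any():
        raise DataValidationError("flight_score must be an integer in 0..5 when present")
    table["flight_score"] = fs.astype("Int64")
    if "forewing_length_mm" not in table.columns:
        table["forewing_length_mm"] = np.nan
    fw = pd.to_numeric(table["forewing_length_mm"], errors="coerce")
    if (fw.dropna() <= 0).any():
        raise DataValidationError("forewing_length_mm must be positive when present")
    table["forewing_length_mm"] = fw
    if "role" not in table.columns:
        table["role"] = "cohort"
    bad_role = ~table["role"].isin(ROLES)
    if bad_role.any():
        raise DataValidationError(f"unknown role(s): {sorted(table.loc[bad_role, 'role'].unique())}")
    return table[SAMPLE_COLUMNS]


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    GT is required; DP is optional (absent depth maps to 0).  "./."
    maps to the missing sentinel.  Multiallelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    loci: list[Locus] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    for i, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise DataValidationError(
                f"{path}: record {i} ({variant.CHROM}:{variant.POS}) is not biallelic"
            )
        loci.append(Locus(variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
        # with gts012=True: 0/1/2 dosage, 3 = unknown
        gt = np.asarray(variant.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        try:
            dp = variant.format("DP")
        except KeyError:  # DP absent from the header entirely
            dp = None
        if dp is None:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))
        else:
            dp = dp.reshape(-1).astype(np.int64)
            dp[dp < 0] = 0  # cyvcf2 encodes missing DP as a negative sentinel
            depth_cols.append(dp.astype(np.int32))
    if loci:
        dosage = np.column_stack(dosage_cols)
        depth = np.column_stack(depth_cols)
    else:
        dosage = np.zeros((len(samples), 0), dtype=np.int16)
        depth = np.zeros((len(samples), 0), dtype=np.int32)
    return GenotypeMatrix(samples=samples, loci=loci, dosage=dosage, depth=depth)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a VCF 4.2 file with GT:DP that round-trips via :func:`read_vcf`."""
    contig_order: list[str] = []
    for locus in matrix.loci:
        if locus.contig not in contig_order:
            contig_order.append(locus.contig)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=flightsift\n")
        for contig in contig_order:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:-1] + ["INFO", "FORMAT"] + matrix.samples) + "\n")
        for j, locus in enumerate(matrix.loci):
            calls = [
                f"{_GT_STRINGS[int(matrix.dosage[i, j])]}:{int(matrix.depth[i, j])}"
                for i in range(matrix.n_samples)
            ]
            row = [
                locus.contig,
                str(locus.position),
                ".",
                locus.ref_allele,
                locus.alt_allele,
                ".",
                "PASS",
                ".",
                "GT:DP",
            ] + calls
            fh.write("\t".join(row) + "\n")


# ----------------------------------------------------------------------
# Table I/O
# ----------------------------------------------------------------------


def read_sample_table(path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t"))


def write_sample_table(table: pd.DataFrame, path) -> None:
    validate_sample_table(table).to_csv(path, sep="\t", index=False)


def read_gene_table(path, go_map: dict[str, set] | None = None, *, bed: bool = False) -> list[GeneModel]:
    """Read gene spans from TSV (gene_id, contig, start, end) or BED.

    BED half-open 0-based coordinates are converted to the internal
    1-based inclusive convention.
    """
    if bed:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["contig", "start", "end", "gene_id"], usecols=range(4))
        df["start"] = df["start"] + 1
    else:
        df = pd.read_csv(path, sep="\t")
        for col in ("gene_id", "contig", "start", "end"):
            if col not in df.columns:
                raise DataValidationError(f"gene table missing column {col!r}")
    go_map = go_map or {}
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            contig=str(r.contig),
            start=int(r.start),
            end=int(r.end),
            go_terms=frozenset(go_map.get(str(r.gene_id), ())),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "contig": [g.contig for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_go_tables(map_path, term_path, gene_ids: set[str]) -> list[GOTerm]:
    """Read gene->term map and term definitions; validate cross-references."""
    gmap = pd.read_csv(map_path, sep="\t")
    terms = pd.read_csv(term_path, sep="\t")
    for col in ("gene_id", "term_id"):
        if col not in gmap.columns:
            raise DataValidationError(f"GO map missing column {col!r}")
    for col in ("term_id", "name", "definition"):
        if col not in terms.columns:
            raise DataValidationError(f"GO term table missing column {col!r}")
    unknown = set(gmap["gene_id"].astype(str)) - gene_ids
    if unknown:
        raise DataValidationError(f"GO map names unknown gene id(s): {sorted(unknown)[:5]}")
    by_term: dict[str, set] = {}
    for r in gmap.itertuples():
        by_term.setdefault(str(r.term_id), set()).add(str(r.gene_id))
    return [
        GOTerm(
            term_id=str(r.term_id),
            name=str(r.name),
            definition=str(r.definition),
            genes=frozenset(by_term.get(str(r.term_id), ())),
        )
        for r in terms.itertuples()
    ]


def write_go_tables(terms: list[GOTerm], map_path, term_path) -> None:
    rows = [(g, t.term_id) for t in terms for g in sorted(t.genes)]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(map_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "term_id": [t.term_id for t in terms],
            "name": [t.name for t in terms],
            "definition": [t.definition for t in terms],
        }
    ).to_csv(term_path, sep="\t", index=False)


def read_category_scheme(path) -> CategoryScheme:
    """Read a category keyword scheme from JSON: {name: [keywords]}."""
    with open(path) as fh:
        raw = json.load(fh)
    return CategoryScheme(categories=[(name, list(kws)) for name, kws in raw.items()])


def write_category_scheme(scheme: CategoryScheme, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(scheme.categories), fh, indent=1)


def read_tables(phenopath, genepath, gopath, termpath, catpath):
    """Read all annotation-side inputs with cross-reference validation."""
    samples = read_sample_table(phenopath)
    genes = read_gene_table(genepath)
    terms = read_go_tables(gopath, termpath, {g.gene_id for g in genes})
    # attach term sets back onto genes
    by_gene: dict[str, set] = {}
    for t in terms:
        for g in t.genes:
            by_gene.setdefault(g, set()).add(t.term_id)
    genes = [
        GeneModel(g.gene_id, g.contig, g.start, g.end, frozenset(by_gene.get(g.gene_id, ())))
        for g in genes
    ]
    scheme = read_category_scheme(catpath)
    return samples, genes, terms, scheme
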