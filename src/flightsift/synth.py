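"""Synthetic cohort, inbred-pedigree, and annotation generators.

The generators emulate the statistical design of a two-lineage,
multi-colony spongy-moth study: hierarchically drifted allele
frequencies (Balding-Nichols at each level), full-sib family structure
within colonies, an ordinal 0-5 flight score concentrated at the
extremes driven by a logistic liability with planted causal loci, a
Gaussian forewing-length trait, an ESM x ASM full-sib inbred pedigree
carried to F5 with phenotype-extreme selection, and a GO-annotated gene
set whose term vocabulary exercises keyword categorization.

Every generator returns a truth record sufficient to score recovery in
the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import (
    MISSING,
    CategoryScheme,
    GeneModel,
    GenotypeMatrix,
    GOTerm,
    Locus,
    validate_sample_table,
    DEFAULT_CATEGORY_NAMES,
)

__all__ = [
    "SynthConfig",
    "simulate_cohort",
    "simulate_inbred_lines",
    "simulate_annotation",
    "default_category_scheme",
]

#: Colony codes by lineage: two European (flightless-female) colonies and
#: six Asian (flight-capable) colonies.
ESM_COLONIES = ("UC", "KG")
ASM_COLONIES = ("CJ", "CR", "CN", "RS", "RM", "JN")

#: Keyword lists for the 12 flight-relevant functional categories.
DEFAULT_CATEGORY_KEYWORDS: dict[str, list[str]] = {
    "cognition": ["cognition", "learning", "memory", "brain"],
    "growth": ["growth", "development", "differentiation", "morphogenesis", "proliferation"],
    "metabolism": ["metabolic", "metabolism", "catabolic", "biosynthetic", "glycolysis"],
    "morphology": ["muscle", "wing", "cuticle", "tissue", "skeletal", "vessel"],
    "movement": ["movement", "locomotion", "motility", "transport", "flight"],
    "mutation": ["mutation", "repair", "recombination", "viral", "transposon"],
    "neural": ["neuron", "neural", "synaptic", "nervous", "axon"],
    "rhythm": ["circadian", "rhythm", "clock", "photoperiod"],
    "reproduction": ["reproduction", "mating", "oviposition", "egg", "gamete"],
    "sensory": ["sensory", "perception", "olfactory", "smell", "vision"],
    "sexual_dimorphism": ["dimorphism", "dosage compensation", "sex determination"],
    "social": ["social", "aggregation", "pheromone"],
}

_FILLER_WORDS = (
    "regulation process cellular protein positive negative pathway response "
    "signaling binding activity organization assembly transition maintenance "
    "localization complex membrane nuclear"
).split()


def default_category_scheme() -> CategoryScheme:
    """The 12-category flight-relevance keyword scheme."""
    return CategoryScheme(
        categories=[(name, list(DEFAULT_CATEGORY_KEYWORDS[name])) for name in DEFAULT_CATEGORY_NAMES]
    )


@dataclass
class SynthConfig:
    """Generator configuration.

    Defaults reflect the study design the package targets: ~300 samples
    in 8 colonies over 2 lineages, full-sib families of 5, several
    thousand loci on a few hundred contigs, flight scores bimodal at 0
    and 5 with a strong lineage baseline, and a 5-generation full-sib
    inbred pedigree from an ESM x ASM cross.
    """

    seed: int = 0
    # cohort
    samples_per_colony: tuple[int, ...] = (40, 40, 60, 50, 30, 30, 30, 20)
    sibs_per_family: int = 5
    n_loci: int = 5000
    n_contigs: int = 250
    fst_lineage: float = 0.15
    fst_colony: float = 0.05
    n_causal_flight: int = 12
    n_causal_wing: int = 10
    flight_effect: float = 1.0  # log-odds per alt allele at each causal locus
    wing_effect_mm: float = 0.4  # mm per alt allele at each causal locus
    lineage_flight_offset: float = 2.0  # liability: +offset for ASM, -offset for ESM
    forewing_mean_mm: tuple[float, float] = (24.0, 30.0)  # (ESM, ASM)
    forewing_sd_mm: float = 1.5
    missing_rate: float = 0.08
    mean_depth: float = 20.0
    flight_pheno_missing: float = 0.02
    wing_pheno_missing: float = 0.15
    # annotation
    n_genes: int = 500
    n_terms: int = 300
    terms_per_gene: float = 3.0
    # inbred pedigree
    inbred_n_loci: int = 2000
    inbred_n_contigs: int = 100
    inbred_informative_frac: float = 0.6
    inbred_n_causal: int = 2
    inbred_generations: int = 5
    inbred_progeny: int = 40
    inbred_crossover_rate: float = 0.1
    inbred_mean_depth: float = 39.0
    inbred_missing_rate: float = 0.0
    inbred_causal_effect: float = 1.0  # 0 disables phenotype-genotype coupling
    max_tries: int = 10

    def __post_init__(self) -> None:
        for name in ("fst_lineage", "fst_colony", "missing_rate", "flight_pheno_missing",
                     "wing_pheno_missing", "inbred_missing_rate", "inbred_informative_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_causal_flight > self.n_loci or self.n_causal_wing > self.n_loci:
            raise ValueError("causal loci exceed n_loci")
        if self.inbred_n_causal > self.inbred_n_contigs:
            raise ValueError("inbred causal loci must fit on distinct contigs")
        for colony_n in self.samples_per_colony:
            if colony_n % self.sibs_per_family != 0:
                raise ValueError(
                    f"colony size {colony_n} is not a multiple of sibs_per_family="
                    f"{self.sibs_per_family}: families x sibs must equal colony size"
                )


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Draw descendant allele frequencies around ``p`` at divergence ``fst``."""
    if fst <= 0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _tile_loci(rng: np.random.Generator, n_loci: int, n_contigs: int,
               contig_span: int = 100_000) -> list[Locus]:
    """Place loci at sorted random positions across contigs."""
    contig_of = np.sort(rng.integers(0, n_contigs, size=n_loci))
    loci: list[Locus] = []
    bases = np.array(list("ACGT"))
    for c in range(n_contigs):
        n_here = int((contig_of == c).sum())
        if n_here == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, contig_span + 1), size=n_here, replace=False))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            loci.append(Locus(f"ctg{c:04d}", int(p), str(bases[ref]), str(bases[alt])))
    return loci


def _sib_genotypes(rng: np.random.Generator, mother: np.ndarray, father: np.ndarray,
                   n_sibs: int) -> np.ndarray:
    """Full-sib dosages from parental dosage vectors (independent gametes)."""
    pm = mother / 2.0
    pf = father / 2.0
    gm = rng.random((n_sibs, mother.size)) < pm
    gf = rng.random((n_sibs, father.size)) < pf
    return (gm.astype(np.int16) + gf.astype(np.int16))


def simulate_cohort(config: SynthConfig) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Simulate the multi-colony GWAS cohort.

    Allele frequencies are drawn ancestral -> lineage -> colony; samples
    are full-sib groups within colonies; the flight score is an ordinal
    mapping of a logistic liability (lineage baseline plus planted
    additive effects); forewing length is Gaussian with its own planted
    loci.  Missingness is Bernoulli and depth Poisson.
    """
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_loci
    loci = _tile_loci(rng, n_loci, config.n_contigs)

    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    p_lineage = {lin: _balding_nichols(rng, p_anc, config.fst_lineage) for lin in ("ESM", "ASM")}
    colonies = list(ESM_COLONIES) + list(ASM_COLONIES)
    lineage_of = {c: ("ESM" if c in ESM_COLONIES else "ASM") for c in colonies}
    p_colony = {c: _balding_nichols(rng, p_lineage[lineage_of[c]], config.fst_colony)
                for c in colonies}

    if len(config.samples_per_colony) != len(colonies):
        raise ValueError(f"samples_per_colony must have {len(colonies)} entries")

    sample_ids: list[str] = []
    colony_col: list[str] = []
    lineage_col: list[str] = []
    family_col: list[int] = []
    blocks: list[np.ndarray] = []
    fam_counter = 0
    for colony, n_col in zip(colonies, config.samples_per_colony):
        p = p_colony[colony]
        n_fam = n_col // config.sibs_per_family
        for _ in range(n_fam):
            mother = rng.binomial(2, p).astype(np.int16)
            father = rng.binomial(2, p).astype(np.int16)
            sibs = _sib_genotypes(rng, mother, father, config.sibs_per_family)
            blocks.append(sibs)
            for _ in range(config.sibs_per_family):
                sample_ids.append(f"{colony}{len(sample_ids):04d}")
                colony_col.append(colony)
                lineage_col.append(lineage_of[colony])
                family_col.append(fam_counter)
            fam_counter += 1
    dosage = np.vstack(blocks)
    n_samples = dosage.shape[0]

    # planted effects: causal loci drawn among common variants for signal
    common = np.flatnonzero((p_anc >= 0.2) & (p_anc <= 0.8))
    causal_flight = rng.choice(common, size=config.n_causal_flight, replace=False)
    remaining = np.setdiff1d(common, causal_flight)
    causal_wing = rng.choice(remaining, size=config.n_causal_wing, replace=False)
    beta_flight = np.full(config.n_causal_flight, config.flight_effect)
    beta_wing = np.full(config.n_causal_wing, config.wing_effect_mm)

    lin_arr = np.array(lineage_col)
    offset = np.where(lin_arr == "ASM", config.lineage_flight_offset,
                      -config.lineage_flight_offset)
    centered = dosage[:, causal_flight] - 2.0 * p_anc[causal_flight]
    liability = offset + centered @ beta_flight + rng.standard_normal(n_samples)
    fly = rng.random(n_samples) < 1.0 / (1.0 + np.exp(-liability))
    score = np.where(
        fly,
        rng.choice([3, 4, 5], size=n_samples, p=[0.08, 0.12, 0.80]),
        rng.choice([0, 1, 2], size=n_samples, p=[0.80, 0.12, 0.08]),
    )

    base = np.where(lin_arr == "ASM", config.forewing_mean_mm[1], config.forewing_mean_mm[0])
    wing_centered = dosage[:, causal_wing] - 2.0 * p_anc[causal_wing]
    forewing = base + wing_centered @ beta_wing + config.forewing_sd_mm * rng.standard_normal(n_samples)

    score_out = score.astype(object)
    score_out[rng.random(n_samples) < config.flight_pheno_missing] = pd.NA
    forewing_out = forewing.copy()
    forewing_out[rng.random(n_samples) < config.wing_pheno_missing] = np.nan

    dosage_out = dosage.copy()
    miss = rng.random(dosage.shape) < config.missing_rate
    dosage_out[miss] = MISSING
    depth = rng.poisson(config.mean_depth, size=dosage.shape).astype(np.int32)

    matrix = GenotypeMatrix(samples=sample_ids, loci=loci, dosage=dosage_out, depth=depth)
    table = validate_sample_table(pd.DataFrame({
        "sample_id": sample_ids,
        "colony": colony_col,
        "lineage": lineage_col,
        "flight_score": score_out,
        "forewing_length_mm": forewing_out,
        "role": "cohort",
    }))
    truth = {
        "causal_flight": causal_flight.tolist(),
        "causal_flight_loci": [f"{loci[i].contig}:{loci[i].position}" for i in causal_flight],
        "beta_flight": beta_flight.tolist(),
        "causal_wing": causal_wing.tolist(),
        "causal_wing_loci": [f"{loci[i].contig}:{loci[i].position}" for i in causal_wing],
        "beta_wing": beta_wing.tolist(),
        "family": family_col,
        "lineage_flight_offset": config.lineage_flight_offset,
        "colony_alt_freq": {c: p_colony[c].tolist() for c in colonies},
    }
    return matrix, table, truth


# ----------------------------------------------------------------------
# Inbred pedigree
# ----------------------------------------------------------------------


def _gamete(rng: np.random.Generator, hapA: np.ndarray, hapB: np.ndarray,
            contig_slices: list[slice], crossover_rate: float) -> np.ndarray:
    """One gamete under per-contig block inheritance with rare crossovers."""
    out = np.empty_like(hapA)
    for sl in contig_slices:
        a, b = (hapA, hapB) if rng.random() < 0.5 else (hapB, hapA)
        n = sl.stop - sl.start
        if n > 1 and rng.random() < crossover_rate:
            cut = rng.integers(1, n)
            out[sl.start:sl.start + cut] = a[sl.start:sl.start + cut]
            out[sl.start + cut:sl.stop] = b[sl.start + cut:sl.stop]
        else:
            out[sl] = a[sl]
    return out


def _inbred_score(rng: np.random.Generator, causal_dosage: np.ndarray, effect: float) -> int:
    """Flight score of one inbred female from its causal genotypes.

    With a positive effect the score is a deterministic staircase in the
    fraction of flight (alt) alleles carried: fully homozygous-alt
    individuals fly strongly (5), individuals carrying at most half the
    flight alleles do not fly (0/1), intermediates are mid-scale.  With
    effect 0 the score is drawn independently of genotype.
    """
    if effect <= 0:
        return int(rng.choice([0, 1, 2, 3, 4, 5]))
    frac = causal_dosage.sum() / (2.0 * causal_dosage.size)
    if frac >= 1.0:
        return 5
    if frac <= 0.5:
        return int(rng.choice([0, 1]))
    return int(rng.choice([2, 3, 4]))


def simulate_inbred_lines(config: SynthConfig) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Simulate an ESM x ASM full-sib pedigree and its sequenced subset.

    Two founder parents diverge at a configurable fraction of loci
    (opposite homozygotes); descent is per-contig block inheritance with
    a small crossover probability, giving the high within-line LD such a
    design produces.  After F1, a flight-selected and a non-flight-
    selected sub-line are bred by picking phenotype-extreme full-sib
    pairs each generation.  The sequenced output holds the 2 parents,
    4 strong flyers (score 5: one F2, one F3, two F5) and 4 non-flyers
    (score <= 1, same generation layout).

    The truth record lists, from haplotype bookkeeping rather than from
    the emitted genotype matrix, the loci whose genotypes co-segregate
    with flight across the sequenced individuals.
    """
    n_loci = config.inbred_n_loci
    n_contigs = config.inbred_n_contigs

    for attempt in range(config.max_tries):
        rng = np.random.default_rng((config.seed, 7, attempt))
        loci = _tile_loci(rng, n_loci, n_contigs)
        contig_names = [l.contig for l in loci]
        contig_slices: list[slice] = []
        start = 0
        for i in range(1, len(loci) + 1):
            if i == len(loci) or contig_names[i] != contig_names[start]:
                contig_slices.append(slice(start, i))
                start = i

        informative = rng.random(n_loci) < config.inbred_informative_frac
        # ESM mother fixed ref (0), ASM father fixed alt (1) at informative loci;
        # elsewhere both parents share a random genotype.
        shared = rng.integers(0, 2, size=(2, n_loci)).astype(np.int8)
        mother_haps = shared.copy()
        father_haps = shared.copy()
        mother_haps[:, informative] = 0
        father_haps[:, informative] = 1

        # causal loci on distinct contigs, informative by construction
        inf_idx = np.flatnonzero(informative)
        by_contig: dict[str, list[int]] = {}
        for i in inf_idx:
            by_contig.setdefault(contig_names[i], []).append(int(i))
        contig_pool = sorted(by_contig)
        if len(contig_pool) < config.inbred_n_causal:
            continue
        chosen = rng.choice(len(contig_pool), size=config.inbred_n_causal, replace=False)
        causal = np.array([int(rng.choice(by_contig[contig_pool[c]])) for c in chosen])

        def breed(parents, select_high: bool, generations: int):
            """Breed one selected sub-line; yield (gen, haplotype pairs, score)."""
            sequenced = {}
            mother, father = parents
            for gen in range(2, generations + 1):
                kids = []
                for _ in range(config.inbred_progeny):
                    h1 = _gamete(rng, mother[0], mother[1], contig_slices,
                                 config.inbred_crossover_rate)
                    h2 = _gamete(rng, father[0], father[1], contig_slices,
                                 config.inbred_crossover_rate)
                    dos = (h1[causal].astype(int) + h2[causal].astype(int))
                    score = _inbred_score(rng, dos, config.inbred_causal_effect)
                    kids.append(((h1, h2), score))
                want = (lambda s: s == 5) if select_high else (lambda s: s <= 1)
                qualifying = [k for k in kids if want(k[1])]
                n_needed = 2 if gen == generations else 1
                if gen in (2, 3, generations) and len(qualifying) < n_needed:
                    return None
                if gen in (2, 3):
                    sequenced[f"F{gen}"] = [qualifying[0]]
                if gen == generations:
                    sequenced[f"F{gen}"] = qualifying[:2]
                # next-generation full-sib pair: phenotype-extreme female, random sib male
                key = (lambda k: k[1]) if select_high else (lambda k: -k[1])
                kids_sorted = sorted(kids, key=key, reverse=True)
                mother = kids_sorted[0][0]
                father = kids[int(rng.integers(len(kids)))][0]
            return sequenced

        # F1: all offspring of the founder cross (both sub-lines share F1)
        f1_mother = (
            _gamete(rng, mother_haps[0], mother_haps[1], contig_slices, config.inbred_crossover_rate),
            _gamete(rng, father_haps[0], father_haps[1], contig_slices, config.inbred_crossover_rate),
        )
        f1_father = (
            _gamete(rng, mother_haps[0], mother_haps[1], contig_slices, config.inbred_crossover_rate),
            _gamete(rng, father_haps[0], father_haps[1], contig_slices, config.inbred_crossover_rate),
        )
        fly_line = breed((f1_mother, f1_father), True, config.inbred_generations)
        nofly_line = breed((f1_mother, f1_father), False, config.inbred_generations)
        if fly_line is None or nofly_line is None:
            continue

        rows = []
        haps = []
        rows.append(("ESM_parent_UC", "UC", "ESM", 0, "parent"))
        haps.append((mother_haps[0], mother_haps[1]))
        rows.append(("ASM_parent_RM", "RM", "ASM", 5, "parent"))
        haps.append((father_haps[0], father_haps[1]))
        for tag, line in (("fly", fly_line), ("nofly", nofly_line)):
            for gen in sorted(line):
                for k, (pair, score) in enumerate(line[gen]):
                    rows.append((f"{tag}_{gen}_{k}", "XL", "ESM" if tag == "nofly" else "ASM",
                                 score, "progeny"))
                    haps.append(pair)

        dosage = np.array([h1.astype(np.int16) + h2.astype(np.int16) for h1, h2 in haps])
        miss = np.random.default_rng((config.seed, 11, attempt)).random(dosage.shape)
        dosage_out = dosage.copy()
        dosage_out[miss < config.inbred_missing_rate] = MISSING
        depth = np.random.default_rng((config.seed, 13, attempt)).poisson(
            config.inbred_mean_depth, size=dosage.shape).astype(np.int32)

        sample_ids = [r[0] for r in rows]
        matrix = GenotypeMatrix(samples=sample_ids, loci=loci, dosage=dosage_out, depth=depth)
        table = validate_sample_table(pd.DataFrame(
            rows, columns=["sample_id", "colony", "lineage", "flight_score", "role"]
        ).assign(forewing_length_mm=np.nan)[
            ["sample_id", "colony", "lineage", "flight_score", "forewing_length_mm", "role"]
        ])

        # truth from haplotype bookkeeping (parents included in their groups)
        scores = np.array([r[3] for r in rows])
        flyer = scores == 5
        nonflyer = scores <= 1
        geno = dosage  # noiseless genotypes, pre-masking
        opp = informative  # parents opposite homozygous exactly at informative loci
        fly_g = geno[flyer]
        non_g = geno[nonflyer]
        flyers_fixed = (fly_g == fly_g[0]).all(axis=0) & np.isin(fly_g[0], (0, 2))
        opposite = 2 - fly_g[0]
        non_ok = ((non_g == 1) | (non_g == opposite[None, :])).all(axis=0)
        pattern = opp & flyers_fixed & non_ok
        truth = {
            "informative": np.flatnonzero(informative).tolist(),
            "causal": causal.tolist(),
            "pattern_loci": np.flatnonzero(pattern).tolist(),
            "flyer_ids": [r[0] for r, f in zip(rows, flyer) if f],
            "nonflyer_ids": [r[0] for r, f in zip(rows, nonflyer) if f],
            "attempt": attempt,
        }
        return matrix, table, truth

    raise RuntimeError(
        "could not produce 4 flying + 4 non-flying sequenced progeny within "
        f"{config.max_tries} pedigree draws; increase inbred_progeny"
    )


# ----------------------------------------------------------------------
# Annotation
# ----------------------------------------------------------------------


def simulate_annotation(config: SynthConfig) -> tuple[list[GeneModel], list[GOTerm], CategoryScheme]:
    """Generate non-overlapping gene models and a skewed GO annotation.

    Genes are tiled across the cohort contigs; terms receive genes with
    a power-law size distribution; term names and definitions are
    composed from a word pool that includes the category keywords so the
    keyword categorizer is exercised.
    """
    rng = np.random.default_rng((config.seed, 17))
    scheme = default_category_scheme()
    if config.terms_per_gene > config.n_terms:
        raise ValueError("term universe smaller than terms per gene")

    gene_len, gap = 3000, 1000
    genes_raw = []
    for g in range(config.n_genes):
        contig = f"ctg{g % config.n_contigs:04d}"
        slot = g // config.n_contigs
        start = 1 + slot * (gene_len + gap)
        genes_raw.append((f"Lda.{g + 1}", contig, start, start + gene_len - 1))

    # skewed term popularity (Zipf-like weights)
    weights = 1.0 / np.arange(1, config.n_terms + 1) ** 1.2
    weights /= weights.sum()
    term_genes: list[set] = [set() for _ in range(config.n_terms)]
    gene_terms: dict[str, set] = {}
    for gene_id, *_ in genes_raw:
        k = min(config.n_terms, max(1, int(rng.poisson(config.terms_per_gene))))
        picks = rng.choice(config.n_terms, size=k, replace=False, p=weights)
        gene_terms[gene_id] = {f"GO:{t + 1:07d}" for t in picks}
        for t in picks:
            term_genes[t].add(gene_id)

    keyword_pool = [kw for _, kws in scheme.categories for kw in kws]
    word_pool = keyword_pool + list(_FILLER_WORDS)
    terms: list[GOTerm] = []
    for t in range(config.n_terms):
        # roughly half the terms carry a category keyword in their text
        n_words = 8
        words = list(rng.choice(_FILLER_WORDS, size=n_words))
        if rng.random() < 0.5:
            words[int(rng.integers(n_words))] = word_pool[int(rng.integers(len(keyword_pool)))]
        name = " ".join(rng.choice(word_pool, size=3))
        terms.append(GOTerm(
            term_id=f"GO:{t + 1:07d}",
            name=name,
            definition=" ".join(words) + ".",
            genes=frozenset(term_genes[t]),
        ))

    genes = [
        GeneModel(gene_id, contig, start, end, frozenset(gene_terms[gene_id]))
        for gene_id, contig, start, end in genes_raw
    ]
    return genes, terms, scheme
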