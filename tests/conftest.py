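from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from flightsift.dataio import MISSING, GenotypeMatrix, Locus, validate_sample_table


def hwe_exact_fraction(n_het: int, n_hom1: int, n_hom2: int) -> Fraction:
    """Exact-rational reference for the HWE exact test (Wigginton enumeration)."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return Fraction(1)
    n_rare = 2 * min(n_hom1, n_hom2) + n_het

    def prob(h: int) -> Fraction:
        r = (n_rare - h) // 2
        c = n - h - r
        assert c >= 0
        # multinomial genotype count x 2^h over the allele-count arrangements
        return Fraction(2**h) * comb(n, h) * comb(n - h, r) / comb(2 * n, n_rare)

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    observed = prob(n_het)
    return sum((p for h in hets if (p := prob(h)) <= observed), Fraction(0))


def make_matrix(dosage, depth=None, contig="ctg0", samples=None, start_pos=100, spacing=50,
                contigs=None):
    """Build a GenotypeMatrix from a dosage array (helper for fixtures)."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    if depth is None:
        depth = np.full((n, m), 30, dtype=np.int32)
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    bases = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    loci = []
    for j in range(m):
        c = contigs[j] if contigs is not None else contig
        ref, alt = bases[j % 4]
        loci.append(Locus(c, start_pos + j * spacing, ref, alt))
    return GenotypeMatrix(samples=samples, loci=loci, dosage=dosage, depth=np.asarray(depth))


def random_matrix(rng, n=20, m=50, missing_rate=0.1, n_contigs=5):
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int16)
    dosage[rng.random((n, m)) < missing_rate] = MISSING
    depth = rng.poisson(12, size=(n, m)).astype(np.int32)
    contigs = [f"ctg{j % n_contigs}" for j in range(m)]
    return make_matrix(dosage, depth, contigs=contigs)


def make_table(samples, lineage=None, flight=None, forewing=None, role=None, colony=None):
    n = len(samples)
    return validate_sample_table(pd.DataFrame({
        "sample_id": samples,
        "colony": colony if colony is not None else ["UC"] * n,
        "lineage": lineage if lineage is not None else ["ASM"] * n,
        "flight_score": flight if flight is not None else [5] * n,
        "forewing_length_mm": forewing if forewing is not None else [np.nan] * n,
        "role": role if role is not None else ["cohort"] * n,
    }))


@pytest.fixture(scope="session")
def small_cohort():
    from flightsift.synth import SynthConfig, simulate_cohort

    cfg = SynthConfig(seed=11, n_loci=800, n_contigs=80,
                      samples_per_colony=(20, 20, 30, 25, 15, 15, 15, 10))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_inbred():
    from flightsift.synth import SynthConfig, simulate_inbred_lines

    cfg = SynthConfig(seed=5, inbred_n_loci=500, inbred_n_contigs=50)
    return simulate_inbred_lines(cfg)
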