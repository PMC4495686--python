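from __future__ import annotations

import numpy as np
import pytest

from radortho.preprocess import RadLocus

# 60-mer slice of a de Bruijn B(4,3) sequence: all 58 triplets distinct
DEBRUIJN_60 = "AAACAAGAATACCACGACTAGCAGGAGTATCATGATTCCCGCCTCGGCGTCTGCTTGGGT"


def random_seq(rng: np.random.Generator, length: int = 60) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Apply exactly n_sub substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)


def make_locus(lid: str, seq: str, species: str | None = None,
               study: str = "s1", mask=None) -> RadLocus:
    return RadLocus(lid, species or lid.split("|")[0], study, seq, mask)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def related_locus_fixture():
    """50 loci in two 'species': 10 ancestral families x 5 mutated copies
    per species, plus unrelated singletons; used for aligner oracle checks."""
    rng = np.random.default_rng(42)
    loci_a, loci_b = [], []
    for fam in range(10):
        anc = random_seq(rng)
        for copy in range(2):
            loci_a.append(make_locus(f"A|s1|F{fam}c{copy}",
                                     mutate(anc, rng.integers(0, 5), rng)))
        for copy in range(2):
            loci_b.append(make_locus(f"B|s1|F{fam}c{copy}",
                                     mutate(anc, rng.integers(0, 5), rng)))
    for i in range(5):
        loci_a.append(make_locus(f"A|s1|R{i}", random_seq(rng)))
        loci_b.append(make_locus(f"B|s1|R{i}", random_seq(rng)))
    return loci_a, loci_b
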