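import itertools

import numpy as np
import pytest

from poescan.family_pat import Origin


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def hwe_probs(genotypes: np.ndarray) -> np.ndarray:
    """Degenerate probability triples for an array of hard calls."""
    probs = np.zeros((len(genotypes), 3))
    probs[np.arange(len(genotypes)), genotypes] = 1.0
    return probs


def origin_oracle(off, fa, mo):
    """Brute-force parental-origin oracle by enumerating concrete alleles.

    Enumerates every parental allele configuration consistent with the
    observed (possibly missing) genotypes and every transmission choice, and
    collects which origins of the B allele can produce a heterozygous
    offspring.  Fully independent of the production truth-table logic.
    """
    if off is None:
        return Origin.MISSING
    if off != 1:
        return Origin.NOT_HET

    def allele_pairs(gt):
        if gt is None:
            return [(0, 0), (0, 1), (1, 0), (1, 1)]
        return {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[gt]

    origins = set()
    for fa_pair, mo_pair in itertools.product(allele_pairs(fa), allele_pairs(mo)):
        for ti, tj in itertools.product((0, 1), repeat=2):
            pat_allele, mat_allele = fa_pair[ti], mo_pair[tj]
            if pat_allele + mat_allele == 1:  # heterozygous offspring
                origins.add("pat" if pat_allele == 1 else "mat")
    if origins == {"pat"}:
        return Origin.PATERNAL_B
    if origins == {"mat"}:
        return Origin.MATERNAL_B
    if origins == {"pat", "mat"}:
        return Origin.AMBIGUOUS
    return Origin.MENDEL_ERROR
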