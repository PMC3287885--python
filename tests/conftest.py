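"""Shared fixtures: small deterministic genotype datasets."""

import numpy as np
import pytest

from rvpath.io_formats import GeneMap, GenotypeMatrix


def make_genotypes(dosages, genes=None, prefix="V"):
    """GenotypeMatrix from a plain array (−1 = missing)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if genes is None:
        genes = ["GENEA"] * m
    return GenotypeMatrix.from_dosages(
        [f"I{i}" for i in range(n)],
        [f"{prefix}{j}" for j in range(m)],
        dosages,
        genes,
    )


@pytest.fixture
def small_genotypes():
    """8 individuals × 4 variants in 2 genes, mixed rare/common."""
    rng = np.random.default_rng(7)
    dosages = rng.binomial(2, [0.02, 0.05, 0.3, 0.02], size=(8, 4))
    dosages[0, 0] = 1  # make sure the rare variants are polymorphic
    dosages[1, 1] = 1
    dosages[2, 3] = 1
    return make_genotypes(dosages, ["GENEA", "GENEA", "GENEB", "GENEB"])


@pytest.fixture
def small_gene_map(small_genotypes):
    return GeneMap(
        dict(zip(small_genotypes.variant_ids, small_genotypes.variant_gene))
    )
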