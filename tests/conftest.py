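import numpy as np
import pandas as pd
import pytest

from gwasbench import GenotypeMatrix, compute_kinship, compute_pcs, simulate_genotypes, simulate_trait


@pytest.fixture(scope="session")
def structured_panel():
    """Two subpopulations (Fst 0.1) with full-sib families and block LD."""
    return simulate_genotypes(120, 600, n_chromosomes=4, seed=11)


@pytest.fixture(scope="session")
def plain_panel():
    """Unstructured panel: one pool, unrelated individuals, no LD blocks."""
    return simulate_genotypes(100, 300, n_chromosomes=3, n_subpops=1, fst=0.0,
                              family_size=1, block_len_bp=0, seed=5)


@pytest.fixture(scope="session")
def trait60(structured_panel):
    phen, arch = simulate_trait(structured_panel, 10, 0.6, seed=21)
    return phen, arch


@pytest.fixture(scope="session")
def structured_pcs(structured_panel):
    return compute_pcs(structured_panel, 3)


@pytest.fixture(scope="session")
def structured_kinship(structured_panel):
    return compute_kinship(structured_panel, "VanRaden")


def make_genotypes(dosages, chrom=None, pos=None, taxa=None):
    """Hand-built GenotypeMatrix for small worked examples."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    chrom = chrom if chrom is not None else ["Chr01"] * m
    pos = pos if pos is not None else np.arange(1, m + 1) * 1000
    taxa = taxa if taxa is not None else [f"ind{i:03d}" for i in range(n)]
    mm = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
         "id": [f"S{j + 1:03d}" for j in range(m)],
         "minor": ["A"] * m, "major": ["C"] * m}
    )
    return GenotypeMatrix(dosages, taxa, mm)
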