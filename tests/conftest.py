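import numpy as np
import pandas as pd
import pytest

from adgwas.model import SNP_COLUMNS, make_genotype_matrix
from adgwas import simul


def build_matrix(calls, chroms=None, positions=None, line_ids=None,
                 alleles=None):
    """Hand-build a GenotypeMatrix from a nested list of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    chroms = chroms or ["1"] * n_snps
    positions = positions or list(range(100, 100 + 100 * n_snps, 100))
    line_ids = line_ids or [f"L{i}" for i in range(n_lines)]
    alleles = alleles or [("A", "C")] * n_snps
    snps = pd.DataFrame(
        [(f"s{j}", chroms[j], positions[j], alleles[j][0], alleles[j][1])
         for j in range(n_snps)],
        columns=SNP_COLUMNS)
    return make_genotype_matrix(line_ids, snps, calls)


@pytest.fixture
def tiny_g():
    # 3 lines x 4 SNPs, includes a het and a missing call
    return build_matrix([[0, 1, 2, 0],
                         [0, 0, 2, -9],
                         [2, 0, 0, 1]])


@pytest.fixture(scope="session")
def structured_panel():
    """200-line, 2,000-SNP Balding-Nichols panel with 3 subpopulations."""
    return simul.simulate_structured_genotypes(200, 2000, 3, fst=0.1, seed=11)
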