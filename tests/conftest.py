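import numpy as np
import pytest

from dkpc.containers import GeneBlock, GenotypeMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(values, sample_prefix="s", snp_prefix="snp"):
    values = np.asarray(values)
    n, p = values.shape
    return GenotypeMatrix(
        [f"{sample_prefix}{i}" for i in range(n)],
        [f"{snp_prefix}{j}" for j in range(p)],
        values,
    )


def make_block(values, gene_id="geneA"):
    values = np.asarray(values)
    n, m = values.shape
    return GeneBlock(
        gene_id=gene_id,
        snp_ids=[f"{gene_id}_snp{j}" for j in range(m)],
        sample_ids=[f"s{i}" for i in range(n)],
        values=values,
    )


def make_phenotype(values, kind="corrected"):
    values = np.asarray(values, float)
    return PhenotypeVector([f"s{i}" for i in range(values.size)], values, kind=kind)


@pytest.fixture
def random_block(rng):
    return make_block(rng.integers(0, 3, size=(60, 5)))
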