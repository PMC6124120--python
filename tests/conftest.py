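import numpy as np
import pandas as pd
import pytest

from segscan.synthetic_cross import Chromosome, GenomeMap


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_genome():
    """Two chromosomes, five markers each, 1 Morgan / 1 Mb."""
    positions = np.array([100_000, 300_000, 500_000, 700_000, 900_000])
    return GenomeMap(
        chromosomes=(Chromosome("1", 1_000_000, 1.0), Chromosome("2", 1_000_000, 1.0)),
        markers={"1": positions.copy(), "2": positions.copy()},
    )


def planted_fpkm_fixture(n_genes=1000, n_planted=100, seed=7):
    """Expression matrix with a known >= fourfold DE gene set.

    Genes ``de0000 .. de0099`` have evolved/ancestor mean ratios >= 4 at
    time point 3h (half of them over-, half underexpressed); ``de0000`` sits
    exactly at the fourfold boundary.  All remaining genes have ratios well
    inside (1/4, 4).  Replicates are exact copies of the condition mean so
    the planted ratios are exact.
    """
    rng = np.random.default_rng(seed)
    genes = [f"de{i:04d}" for i in range(n_planted)] + \
            [f"bg{i:04d}" for i in range(n_genes - n_planted)]
    anc = np.empty(n_genes)
    evo = np.empty(n_genes)
    anc[0], evo[0] = 10.0, 40.0  # exact fourfold boundary gene
    for i in range(1, n_planted):
        base = rng.uniform(5, 50)
        fold = rng.uniform(4.5, 30)
        if i % 2:
            anc[i], evo[i] = base, base * fold
        else:
            anc[i], evo[i] = base * fold, base
    base = rng.uniform(5, 50, n_genes - n_planted)
    anc[n_planted:] = base
    evo[n_planted:] = base * rng.uniform(0.5, 2.0, n_genes - n_planted)
    cols = {}
    for r in (1, 2, 3):
        cols[f"ancestor_3h_r{r}"] = anc
        cols[f"evolved_3h_r{r}"] = evo
        # a second time point with no DE signal at all
        cols[f"ancestor_6h_r{r}"] = anc
        cols[f"evolved_6h_r{r}"] = anc
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    planted = set(genes[:n_planted])
    return matrix, planted


@pytest.fixture
def planted_fpkm():
    return planted_fpkm_fixture()
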