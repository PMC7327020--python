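import numpy as np
import pytest

from platymeth import SimulationConfig, generate_gene_models, generate_genome, simulate_methylome


@pytest.fixture(scope="session")
def small_config():
    """A compact but non-degenerate study: 400 kb, 30 genes, two families."""
    return SimulationConfig(
        seed=11,
        chrom_length_bp=400_000,
        n_genes=30,
        family_spec={"CYP716": 8, "bAS": 6},
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    genome = generate_genome(small_config)
    genes = generate_gene_models(genome, small_config)
    cx_by_sample, truth = simulate_methylome(genome, genes, small_config)
    return genome, genes, cx_by_sample, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
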