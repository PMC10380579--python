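import numpy as np
import pytest

from mitohairpin.datasets import p_pustulosus_gene_table
from mitohairpin.simulate import SimulationConfig, simulate_bundle, to_alignment_records


@pytest.fixture(scope="session")
def p_table():
    """The bundled 37-gene P. pustulosus annotation."""
    return p_pustulosus_gene_table()


@pytest.fixture(scope="session")
def sim_bundle():
    """One deterministic synthetic study at default settings.

    Returns (config, genome, table, dna_reads, rna_reads, truth).
    """
    cfg = SimulationConfig(seed=7)
    genome, table, dna, rna, truth = simulate_bundle(cfg)
    return cfg, genome, table, dna, rna, truth


@pytest.fixture(scope="session")
def sim_dna_records(sim_bundle):
    return to_alignment_records(sim_bundle[3])


@pytest.fixture(scope="session")
def sim_rna_records(sim_bundle):
    return to_alignment_records(sim_bundle[4])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
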