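import numpy as np
import pytest

from taxogenome import SimulationConfig, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """A 2-genera x 2-species x 2-strain clade with genes, shared by tests."""
    cfg = SimulationConfig(
        seed=42,
        ancestor_length=12_000,
        n_genera=2,
        species_per_genus=2,
        strains_per_species=2,
        n_genes=8,
        gene_length=450,
        gene_loss_prob_per_species=0.1,
    )
    return simulate_clade(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genome(rng, length, strain_id="g"):
    from taxogenome.genome_io import GenomeRecord

    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeRecord(strain_id, [seq])
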