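import warnings

import pytest

from pdxsplit.synthetic_data import make_toy_genomes, simulate_counts


@pytest.fixture(scope="session")
def toy_genomes():
    """Small two-species reference with 15%-diverged orthologs."""
    genomes, truth = make_toy_genomes(
        n_ortholog_genes=12, n_private_per_species=4, gene_length_bp=600,
        divergence=0.15, seed=101,
    )
    return genomes, truth


@pytest.fixture(scope="session")
def small_count_sim():
    """Structured count matrix at unit-test scale."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, metadata, truth = simulate_counts(
            n_samples=30, n_human_genes=80, n_mouse_genes=60, planted_k=3,
            cluster_strength=8.0, n_coupled_pairs=2, n_hub_partners=0,
            n_de_genes=12, gender_ratio=0.5, seed=202,
        )
    return matrix, metadata, truth
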