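import numpy as np
import pytest

from editome_kit import edcall, selfsim, simgen


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale bundle for unit/integration tests (smaller than the
    default study conditions, same structure)."""
    return simgen.SimConfig(
        seed=7, genome_length=120_000, n_chromosomes=2, n_genes=20,
        n_edit_sites=300, n_artifact_sites=80, n_snp_leak_sites=80,
        n_snps=800, n_edqtl=50, samples_per_tissue=(20, 20, 20),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simgen.simulate_all(small_config)


@pytest.fixture(scope="session")
def small_mask(small_bundle):
    return selfsim.build_similarity_mask(small_bundle.genome.sequences)


@pytest.fixture(scope="session")
def small_catalog(small_bundle, small_mask):
    b = small_bundle
    catalog, stages, cands = edcall.run_filter_cascade(
        b.pileups, b.genotypes.sample_tissue, b.genome.sequences,
        b.genome.genes, b.genome.repeats, small_mask,
        [b.genotypes.variants],
        min_samples=7, min_fraction=0.10,  # 20-sample tissues
    )
    return catalog, stages, cands


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
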