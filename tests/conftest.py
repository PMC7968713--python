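import pytest

from orthoexpress import dge, syndata

SMALL_PATHWAYS = (
    ("glycolysis_gluconeogenesis", 20, 0.36),
    ("tca_cycle", 20, -0.18),
    ("pentose_phosphate", 20, 0.77),
)


@pytest.fixture(scope="session")
def small_config():
    return syndata.SimulationConfig(
        seed=11, n_genes_per_species=300, pathway_specs=SMALL_PATHWAYS
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return syndata.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_dataset, tmp_path_factory):
    directory = tmp_path_factory.mktemp("bundle")
    syndata.write_fixture_bundle(small_dataset, directory)
    return directory


@pytest.fixture(scope="session")
def small_dge(small_dataset):
    """DGE tables for both species of the small dataset (computed once)."""
    out = {}
    for sp in (syndata.SPECIES_A, syndata.SPECIES_B):
        table, norm, summary = dge.run_dge(
            small_dataset.counts[sp], small_dataset.designs[sp]
        )
        out[sp] = (table, norm, summary)
    return out
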