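import numpy as np
import pytest
from hypothesis import settings

import barcode_audit as ba

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def toy_matrix(labels, dists):
    """DistanceMatrix from {(a, b): distance} with zero diagonal."""
    n = len(labels)
    values = np.zeros((n, n))
    idx = {l: k for k, l in enumerate(labels)}
    for (a, b), d in dists.items():
        values[idx[a], idx[b]] = d
        values[idx[b], idx[a]] = d
    return ba.DistanceMatrix(list(labels), values)


def toy_taxonomy(mapping):
    """Taxonomy frame from {specimen: (species, genus, family, order)}."""
    import pandas as pd

    rows = {}
    for sid, lineage in mapping.items():
        species, genus, family, order = lineage
        rows[sid] = {
            "species": species, "genus": genus, "family": family,
            "order": order, "class": "Actinopterygii",
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "specimen_id"
    return frame


@pytest.fixture(scope="session")
def sim_config():
    # small survey: ~30 species, ~120 specimens; quick to simulate and tree
    return ba.SimConfig(
        n_orders=3,
        n_families_per_order=2,
        n_genera_per_family=2,
        n_species_per_genus=(2, 3),
        specimens_mean=4.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    return ba.simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def sim_dm(sim_dataset):
    return ba.pairwise_matrix(sim_dataset.records)


@pytest.fixture(scope="session")
def sim_taxonomy(sim_dataset):
    return ba.taxonomy_frame(sim_dataset.records)


@pytest.fixture(scope="session")
def sim_tree(sim_dm):
    return ba.nj(sim_dm)
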