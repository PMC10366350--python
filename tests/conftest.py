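import numpy as np
import pandas as pd
import pytest

from spatprox import SimulationConfig, build_network, simulate_cohort
from spatprox.proximity import SpatialNetwork
from spatprox.synthdata import default_lr_catalog


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-type, 324-spot cohort with planted proximity and L-R effects."""
    cfg = SimulationConfig(
        grid_rows=20,
        grid_cols=20,
        n_types=4,
        domain_scale=2.0,
        n_genes=40,
        n_marker_genes=2,
        lr_catalog=default_lr_catalog(3),
        planted_proximity=[(0, 1, 0.8, "recurrent")],
        planted_lr=[(0, 1, "G0000", "G0001", 3.0, "recurrent")],
        seed=23,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sample_with_network(small_cohort):
    """First recurrent sample plus its Delaunay network and true labels."""
    sample = small_cohort.samples[3]
    coords = pd.DataFrame(
        {
            "spot_id": sample.spot_ids,
            "x": sample.coords[:, 0],
            "y": sample.coords[:, 1],
        }
    )
    network = build_network(coords)
    labels = small_cohort.truth.labels[sample.sample_id].to_numpy()
    return sample, network, labels


def path_network(labels_len: int = 3) -> SpatialNetwork:
    """A simple path graph 0-1-2-...-(n-1) with unit edge lengths."""
    edges = np.column_stack(
        [np.arange(labels_len - 1), np.arange(1, labels_len)]
    )
    return SpatialNetwork(
        [str(i) for i in range(labels_len)],
        edges,
        np.ones(labels_len - 1),
    )
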