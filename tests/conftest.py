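import numpy as np
import pytest

import menigrad as mg


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (5 naive / 6 EAE), fixed seed."""
    return mg.simulate_study(mg.SimConfig(), seed=11)


@pytest.fixture(scope="session")
def default_assignment(default_study):
    """Clustering of the default study at the standard settings."""
    return mg.cluster_study(default_study, n_pcs=10, k_neighbors=20, resolution=0.3, seed=0)


@pytest.fixture()
def toy_sample():
    """Tiny deterministic 4-gene x 5-spot sample."""
    counts = np.array(
        [
            [10, 0, 3, 7, 1],
            [0, 5, 2, 0, 4],
            [6, 1, 0, 2, 0],
            [3, 2, 8, 1, 5],
        ]
    )
    return mg.SpatialSample(
        sample_id="toy",
        group="naive",
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(4)], dtype=object),
        spot_ids=np.array([f"s{i}" for i in range(5)], dtype=object),
        spot_xy_um=np.column_stack([np.arange(5) * 100.0, np.zeros(5)]),
    )
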