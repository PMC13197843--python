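import numpy as np
import pandas as pd
import pytest

from ctctransit.synthetic import default_config, generate_cohort


def make_events(rows):
    """Build a minimal event table from (n_cells_in, fragment_sizes,
    fragment_branches, dissociated?) tuples; dissociated is derived."""
    records = []
    for i, (n_in, sizes, branches) in enumerate(rows):
        records.append(
            {
                "cluster_id": f"e{i}",
                "device_code": "ENA_7/7",
                "n_cells_in": n_in,
                "fragment_sizes": ";".join(map(str, sizes)),
                "fragment_branches": ";".join(map(str, branches)),
                "n_lysed": 0,
                "dissociated": len(sizes) > 1,
                "treated": False,
                "seed": 0,
            }
        )
    return pd.DataFrame(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort_20k():
    """One shared default-calibration cohort: 20,000 clusters, fixed seed."""
    cfg = default_config(n_clusters=20000, seed=11)
    clusters, events, viability = generate_cohort(cfg)
    return cfg, clusters, events, viability
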