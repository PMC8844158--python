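import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose _reference helpers

from hemigrad import synthetic
from hemigrad.atlas import ParcelAtlas


@pytest.fixture(scope="session")
def tiny_spec() -> synthetic.PlantedCohortSpec:
    """3 networks x {L,R}, 12 parcels, fast to generate."""
    return synthetic.make_cohort_spec(
        n_participants=4,
        n_timepoints=60,
        networks=("NetA", "NetB", "NetC"),
        parcels_per_network_per_hemisphere=2,
        asymmetry_mean=0.0,
        asymmetry_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_atlas() -> ParcelAtlas:
    rows = []
    for net, counts in [("alpha", (2, 2)), ("beta", (3, 2))]:
        for hemi, k in zip("LR", counts):
            for i in range(k):
                rows.append(
                    {"parcel_id": f"{net}_{hemi}_{i}", "hemisphere": hemi,
                     "network": net}
                )
    return ParcelAtlas(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_summary(values: np.ndarray, networks, participants=None) -> pd.DataFrame:
    """Build a tidy network-summary table from an (n, 2, m) array
    (participants x hemispheres[L,R] x networks)."""
    n, two, m = values.shape
    assert two == 2 and m == len(networks)
    if participants is None:
        participants = [f"sub-{i:03d}" for i in range(n)]
    rows = []
    for i, pid in enumerate(participants):
        for h, hemi in enumerate("LR"):
            for j, net in enumerate(networks):
                rows.append(
                    {
                        "participant_id": pid,
                        "network": net,
                        "hemisphere": hemi,
                        "mean_gradient": float(values[i, h, j]),
                        "gradient_index": 1,
                    }
                )
    return pd.DataFrame(rows)
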