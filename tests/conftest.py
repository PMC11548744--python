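import numpy as np
import pandas as pd
import pytest

from organet.design import toy_design
from organet.synthetic import generate_ground_truth_network, simulate_trajectories


@pytest.fixture
def design15():
    """3 organs x 5 genes: the 15-node recovery design."""
    return toy_design()


@pytest.fixture
def truth15(design15):
    return generate_ground_truth_network(design15, density=0.05,
                                         coeff_scale=0.2,
                                         stability_bound=-0.05, seed=7)


@pytest.fixture
def dense_grid():
    """Uniform 257-point age grid over 8..24 weeks."""
    return np.linspace(8.0, 24.0, 257)


@pytest.fixture
def small_ct():
    """4 genes x 6 samples, fully observed, values chosen for hand checks."""
    rng = np.random.default_rng(0)
    genes = ["Ren", "Agt", "Ace", "Th"]
    samples = [f"s{i}" for i in range(6)]
    return pd.DataFrame(rng.uniform(18, 28, size=(4, 6)),
                        index=genes, columns=samples)


@pytest.fixture
def organ_meta():
    """Metadata for six samples of one organ, two strains x three ages."""
    rows = []
    sids = []
    for i, (strain, age) in enumerate([("SHR", 8), ("SHR", 12), ("SHR", 16),
                                       ("WKY", 8), ("WKY", 12), ("WKY", 16)]):
        sid = f"s{i}"
        sids.append(sid)
        rows.append((strain, "F", "kidney", float(age), f"{strain}{i}", "chip1"))
    return pd.DataFrame(rows, index=sids,
                        columns=["strain", "sex", "organ", "age_weeks",
                                 "animal_id", "chip_id"])
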