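import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def sim_bundle():
    """One default-condition simulation, assembled and featurized, shared
    across the test modules that exercise the downstream pipeline."""
    from types import SimpleNamespace

    from casprop.pipeline import assemble_from_simulation, combined_records, feature_table
    from casprop.simulate import SimConfig, simulate_dataset

    sim = simulate_dataset(SimConfig())
    dataset = assemble_from_simulation(sim)
    records = combined_records(dataset)
    features = feature_table(records, sim.genome)
    return SimpleNamespace(sim=sim, dataset=dataset, records=records, features=features)
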