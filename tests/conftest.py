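import pandas as pd
import pytest

from baitnet.simulate import SimConfig, generate_experiment
from baitnet.types import APMS, BIOID, ControlRun, PurificationRun


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic experiment, shared across tests."""
    return generate_experiment(SimConfig(seed=11))


@pytest.fixture
def toy_runs():
    return [
        PurificationRun("TF1", BIOID, 1, 1, {"P1": 4, "P2": 6}),
        PurificationRun("TF1", BIOID, 1, 2, {"P1": 2}),
    ]


@pytest.fixture
def toy_controls():
    return [
        ControlRun("GFP_1", "GFP", BIOID, {"C1": 5}),
        ControlRun("GFP_2", "GFP-NLS", BIOID, {"C1": 8, "P2": 1}),
    ]


def make_table(pairs, method=BIOID, avg_spec=10.0, score=0.9):
    """Interaction-table DataFrame from (bait, prey) pairs."""
    return pd.DataFrame(
        [(b, p, method, avg_spec, score) for b, p in pairs],
        columns=["bait", "prey", "method", "avg_spec", "score"],
    )


@pytest.fixture
def make_interactions():
    return make_table
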