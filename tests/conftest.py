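from __future__ import annotations

import numpy as np
import pytest

from immunotree import bundled_fixture, classify_cohort
from immunotree.network import bundled_network, simulate_to_steady_state


@pytest.fixture(scope="session")
def table1():
    return bundled_fixture()


@pytest.fixture(scope="session")
def table1_traces(table1):
    traces, counts = classify_cohort(table1)
    return traces, counts


@pytest.fixture(scope="session")
def pdl1_network():
    return bundled_network()


@pytest.fixture(scope="session")
def pdl1_baseline(pdl1_network):
    return simulate_to_steady_state(pdl1_network)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_profile(rng: np.random.Generator) -> dict[str, float]:
    """A random feature profile spanning all decision-tree branches."""
    from immunotree import ISM_NAMES

    profile = {
        "PDL1": float(rng.uniform(-20.0, 120.0)),
        "DC_index": float(rng.uniform(-10.0, 100.0)),
    }
    for m in ISM_NAMES:
        profile[m] = float(rng.uniform(-40.0, 140.0))
    return profile
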