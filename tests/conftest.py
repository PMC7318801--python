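import numpy as np
import pandas as pd
import pytest

from moralpd.battery import standard_battery
from moralpd.cohort import CohortSpec, sample_cohort, simulate_trials


@pytest.fixture(scope="session")
def battery():
    return standard_battery("means", "personal")


@pytest.fixture(scope="session")
def exp1_cohort():
    """A small two-condition cohort with trials, shared across tests."""
    spec = CohortSpec.from_experiment(1, n_per_cell=15, seed=101)
    participants = sample_cohort(spec)
    trials = simulate_trials(participants, seed=102)
    return participants, trials


def make_trials(records):
    """Hand-built trial table from (participant, congruency, response) triples."""
    rows = []
    counters = {}
    for pid, cong, resp in records:
        k = counters.get((pid, cong), 0)
        counters[(pid, cong)] = k + 1
        rows.append(
            {
                "participant_id": pid,
                "item_id": f"{cong[:3]}-{k}",
                "congruency": cong,
                "instrumentality": "means",
                "personal_force": "personal",
                "position": len(rows),
                "response": resp,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
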