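import numpy as np
import pandas as pd
import pytest

from opsinchoice import synthetic
from opsinchoice.preference import CourtshipEvent, CourtshipTrial


@pytest.fixture(scope="session")
def plan():
    return synthetic.SimulationPlan(seed=7)


@pytest.fixture(scope="session")
def cohort(plan):
    return synthetic.make_cohort(plan)


def make_trial(events, trial_id="T1", female_id="F1", test_light="shallow",
               interaction=20.0, wall=55.0):
    return CourtshipTrial(trial_id, female_id, "OBS1", test_light,
                          {"blue": "BM1", "red": "RM1"}, events,
                          interaction, wall)


def make_events(red_ld=(6, 3), blue_ld=(6, 3), red_q=(3, 0), blue_q=(3, 0)):
    """Build an event list from (total, positive) counts per male x behaviour."""
    events = []
    t = 0.0
    for species, beh, (total, pos) in (("red", "LD", red_ld),
                                       ("blue", "LD", blue_ld),
                                       ("red", "Q", red_q),
                                       ("blue", "Q", blue_q)):
        for i in range(total):
            t += 0.1
            resp = "positive" if i < pos else "negative"
            events.append(CourtshipEvent(t, species, beh, resp))
    return events


@pytest.fixture
def random_profiles():
    """Random but reproducible profile table for filter tests."""
    def _make(seed, n=40, groups=(("blue", "shallow"), ("blue", "deep"),
                                  ("red", "shallow"))):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            sp, light = groups[rng.integers(len(groups))]
            p = rng.dirichlet([2, 8, 12, 10])
            rows.append({"sample": f"S{i:03d}", "complete": True,
                         "prop_SWS2b": p[0], "prop_SWS2a": p[1],
                         "prop_RH2A": p[2], "prop_LWS": p[3],
                         "species": sp, "rearing_light": light})
        return pd.DataFrame(rows)
    return _make
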