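import numpy as np
import pandas as pd
import pytest

import burstrti as b


@pytest.fixture(scope="session")
def default_design():
    return b.BurstDesign()


@pytest.fixture(scope="session")
def small_design():
    """40 persons, full 4-year burst layout, short sessions."""
    return b.BurstDesign(n_persons=40, trials_per_session=20)


@pytest.fixture(scope="session")
def tiny_design():
    return b.BurstDesign(n_persons=6, n_years=2, sessions_per_year=(3, 2),
                         trials_per_session=8)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """One seeded synthetic study shared by read-only tests."""
    return b.generate_dataset(small_design, seed=42)


@pytest.fixture(scope="session")
def small_screened(small_dataset):
    clean, report = b.screen_trials(small_dataset["trials"])
    return clean, report


def make_cell_trials(rts, task="CRT", person=1, year=1, session=1,
                     correct=None, missing=None):
    """One person-session cell from explicit latencies."""
    n = len(rts)
    return pd.DataFrame({
        "person_id": person, "task": task, "year": year, "session": session,
        "trial": np.arange(1, n + 1), "rt_ms": rts,
        "correct": correct if correct is not None else np.ones(n, int),
        "missing": missing if missing is not None else np.zeros(n, int),
    })
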