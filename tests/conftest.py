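import numpy as np
import pandas as pd
import pytest

import palmflow as pf
from palmflow import synthetic as syn
from palmflow import pipeline as pl


@pytest.fixture(scope="session")
def small_grid():
    return pf.make_duration_grid(10, 200.0, 8000.0)


@pytest.fixture(scope="session")
def small_schedule():
    """2 participants, full block structure."""
    return pf.build_schedule(2, seed=11)


@pytest.fixture(scope="session")
def cohort_records():
    """A 14-participant simulated study used by several pipeline tests."""
    sched = pf.build_schedule(14, seed=42)
    cohort = syn.sample_cohort(14, seed=1, durations_ms=sched.grid.values_ms)
    records = syn.simulate_responses(sched, cohort, seed=2)
    return records


@pytest.fixture(scope="session")
def cohort_summaries(cohort_records):
    records, _ = pl.apply_exclusions(cohort_records)
    return pl.participant_summaries(records)
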