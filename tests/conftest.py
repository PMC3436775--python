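import numpy as np
import pandas as pd
import pytest

from pbpah import gps_processing as gp
from pbpah import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(n_subjects=6, days_per_subject=(3, 5), seed=42)


@pytest.fixture(scope="session")
def cohort(small_config):
    """A small synthetic cohort shared across test modules."""
    return sd.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def linked_minutes(cohort):
    """Classified, minute-aggregated, exposure-linked records for the cohort."""
    profs = {p.subject_id: p for p in cohort["profiles"]}
    minutes = []
    for sid, grp in cohort["fixes"].groupby("subject_id"):
        p = profs[sid]
        anchors = [p.home_location] + ([p.work_location] if p.works else [])
        labels = gp.classify_fixes(grp, anchors)
        minutes.append(gp.aggregate_to_minutes(grp, labels))
    minutes = pd.concat(minutes, ignore_index=True)
    linked, _ = gp.link_exposure(minutes, cohort["pah"])
    return linked


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
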