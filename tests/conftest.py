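import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings

    settings.register_profile(
        "repro", derandomize=True, max_examples=60, deadline=None
    )
    settings.load_profile("repro")
except ImportError:  # pragma: no cover
    pass

from rodentcam.synthetic import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A 40-site, 8-night two-species study used across test modules."""
    return simulate_study(StudyConfig(n_sites=40, seed=11))


@pytest.fixture(scope="session")
def small_events(small_study):
    from rodentcam.events import assign_survey_nights, discretize_events

    rec = assign_survey_nights(small_study.triggers, small_study.deployments)
    return discretize_events(rec)


@pytest.fixture()
def toy_deployments():
    """Three sites with staggered deployment windows (16:00 starts)."""
    return pd.DataFrame(
        {
            "site_id": ["A", "B", "C"],
            "start": pd.to_datetime(
                ["2012-04-01 16:00", "2012-04-01 16:00", "2012-04-03 16:00"]
            ),
            "end": pd.to_datetime(
                ["2012-04-09 12:00", "2012-04-09 12:00", "2012-04-08 12:00"]
            ),
        }
    )


def triggers_frame(rows):
    """rows: (site_id, timestamp string, species)."""
    return pd.DataFrame(
        {
            "site_id": [r[0] for r in rows],
            "timestamp": pd.to_datetime([r[1] for r in rows]),
            "species": [r[2] for r in rows],
        }
    )
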