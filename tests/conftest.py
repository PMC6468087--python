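import numpy as np
import pandas as pd
import pytest

from fincr.simulate import scenario_presets, simulate


@pytest.fixture
def tiny_records():
    """Hand-written sighting records covering the parsing edge cases."""
    return pd.DataFrame(
        {
            "individual_id": ["A", "A", "A", "B", "B", "C"],
            "date": [
                "2010-06-01",
                "2012-07-10",
                "2014-06-20",
                "2010-06-05",
                "2011-08-01",
                "2013-06-15",
            ],
            "area": ["JCP"] * 6,
            "calf": [False] * 6,
            "sex": ["F", "F", "F", "M", "M", "U"],
        }
    )


@pytest.fixture(scope="session")
def null_sim():
    """One homogeneous-world realization shared across tests."""
    return simulate(scenario_presets("null_homogeneous"), seed=42)


@pytest.fixture(scope="session")
def two_cluster_sim():
    return simulate(scenario_presets("two_cluster_fidelity"), seed=11)
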