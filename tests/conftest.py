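import numpy as np
import pandas as pd
import pytest

from serumpanel import GroupSpec, MarkerSpec, generate_cohort, make_fixture


@pytest.fixture(scope="session")
def edrn_cohort():
    """Study-composition synthetic cohort (952 samples), fixed seed."""
    return make_fixture("edrn_like", seed=1)


@pytest.fixture(scope="session")
def two_marker_control_pool():
    """20,000 healthy controls with two independent null markers."""
    groups = [GroupSpec("healthy", {"mdacc": 10000, "fhcc": 10000})]
    markers = [
        MarkerSpec("A", {"healthy": 0.0}, {"healthy": 1.0}),
        MarkerSpec("B", {"healthy": 0.0}, {"healthy": 1.0}),
    ]
    return generate_cohort(groups, markers, seed=11)


def tiny_table(groups, values, marker="m"):
    """Hand-built cohort table from parallel group/value lists."""
    n = len(groups)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "group": groups,
            "site": ["mdacc"] * n,
            marker: np.asarray(values, dtype=float),
        }
    )
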