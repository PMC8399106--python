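import numpy as np
import pytest

from floatdoe.doe import DoEDesign, build_ccf_design
from floatdoe.synthetic import (
    NoiseSpec,
    curve_through_points,
    generate_doe_dataset,
    generate_profile_set,
    reference_curve,
)

#: Actual response equations (physical units) used as the generating truth
#: for the response-surface fixtures: release % at 60/240/480 min as a
#: function of cetyl alcohol mass A (mg) and HPMC proportion B (%).
ACTUAL_EQUATIONS = {
    "R1": {"intercept": 53.73, "A": -0.03, "B": -0.59},
    "R2": {"intercept": 94.48, "A": -0.06, "B": -0.83},
    "R3": {"intercept": 111.17, "A": -0.06, "B": -0.78},
}

RSM_RANGES = (150.0, 250.0, 15.0, 25.0)

COMPARISON_TIMES = (60.0, 240.0, 480.0)


@pytest.fixture(scope="session")
def actual_equations():
    return ACTUAL_EQUATIONS


@pytest.fixture(scope="session")
def rsm_ranges():
    return RSM_RANGES


@pytest.fixture(scope="session")
def ccf_design() -> DoEDesign:
    return build_ccf_design(RSM_RANGES, center_points=2, seed=42)


@pytest.fixture(scope="session")
def noiseless_responses(ccf_design):
    return generate_doe_dataset(ACTUAL_EQUATIONS, ccf_design, noise_sd=0.0)


@pytest.fixture(scope="session")
def ref_profile():
    """12-unit reference run: ~30/60/80 % released at 60/240/480 min."""
    return generate_profile_set(
        reference_curve(),
        times=COMPARISON_TIMES,
        n_units=12,
        noise=NoiseSpec(unit_sd=2.0, seed=101),
        product_id="REF",
    )


@pytest.fixture(scope="session")
def test_profile():
    """12-unit test run from a slightly slower-releasing formulation."""
    return generate_profile_set(
        curve_through_points((60.0, 36.0), (480.0, 86.0)),
        times=COMPARISON_TIMES,
        n_units=12,
        noise=NoiseSpec(unit_sd=2.0, seed=202),
        product_id="TEST",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2021)
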