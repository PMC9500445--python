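import numpy as np
import pytest

from margcea.model import TwoArmModel, build_synthetic_fits
from margcea.synthetic_data import calibrate_arms, generate_arm_ipd


@pytest.fixture(scope="session")
def calibrations():
    """Default four arm × endpoint calibrations plus implied hazard ratios."""
    cals, implied_hr = calibrate_arms()
    return {(c.arm_label, c.endpoint): c for c in cals}, implied_hr


@pytest.fixture(scope="session")
def round_trip():
    """Full published-figure round trip at n = 20,000 per arm.

    Generates calibrated event times, summarises them as digitized KM
    coordinates plus 3-month risk tables, reconstructs pseudo-IPD and
    refits each endpoint's adopted family. Shared across the suite since
    it is the most expensive fixture.
    """
    fits, ipds = build_synthetic_fits(n_patients=20_000, base_seed=42,
                                      reconstruct=True, return_ipd=True)
    return fits, ipds


@pytest.fixture(scope="session")
def us_model(round_trip):
    fits, _ = round_trip
    return TwoArmModel(country="US", fits=fits)


@pytest.fixture(scope="session")
def cn_model(round_trip):
    fits, _ = round_trip
    return TwoArmModel(country="CN", fits=fits)


@pytest.fixture(scope="session")
def small_pfs_ipd(calibrations):
    """A cheap (n=2,000) margetuximab PFS sample for unit-level tests."""
    cals, _ = calibrations
    cal = cals[("margetuximab", "PFS")]
    from dataclasses import replace
    return generate_arm_ipd(replace(cal, n_patients=2000))
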