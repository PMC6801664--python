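import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))  # for oracles.py

from uvdose import validation
from uvdose.solar_geometry import SolarGeometry, eccentricity_factor


@pytest.fixture(scope="session")
def case_inputs():
    """Worked-example input set (Pisa, 21 June, solar noon, clear sky)."""
    return validation.case_inputs()


@pytest.fixture(scope="session")
def case_geometry(case_inputs):
    """Solar geometry fixed by the worked example's printed angles."""
    zen = case_inputs["zenith_deg"]
    return SolarGeometry(
        declination=case_inputs["declination_deg"],
        hour_angle=0.0,
        zenith=zen,
        elevation=90.0 - zen,
        azimuth=0.0,
        eccentricity=eccentricity_factor(int(case_inputs["day_of_year"])),
    )


@pytest.fixture(scope="session")
def case_components(case_inputs, case_geometry):
    from uvdose.decomposition import decompose

    return decompose(
        case_inputs["ierh_w_m2"],
        case_geometry.eccentricity,
        case_geometry.zenith,
        case_inputs["toc_du"],
    )
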