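"""Shared fixtures: reference patient, coarse domains, canonical scenarios.

All domains here are deliberately coarse (2.5-3 mm voxels) so the suite
stays fast; resolution-sensitive checks build their own grids.
"""

import numpy as np
import pytest
from hypothesis import settings

from callusim.cohort import FractureConfig, NailConfig, PatientCase
from callusim.grid import GeometryParams, build_domain, initial_state

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def patient():
    return PatientCase(id="ref", age=30.4, height=173.4, weight=80.4,
                       sex="M", side="right")


@pytest.fixture(scope="session")
def geometry(patient):
    return GeometryParams.from_patient(patient)


@pytest.fixture(scope="session")
def favorable_domain(geometry):
    """Small-gap, adequately nailed scenario on a coarse grid."""
    return build_domain(geometry, FractureConfig(gap_size=2.0),
                        NailConfig(diameter=13.0), voxel_size=2.5)


@pytest.fixture(scope="session")
def compromised_domain(geometry):
    """Large-gap, undersized-nail scenario on a coarse grid."""
    return build_domain(geometry, FractureConfig(gap_size=8.0),
                        NailConfig(diameter=9.0), voxel_size=2.5)


@pytest.fixture()
def favorable_state(favorable_domain):
    return initial_state(favorable_domain)


def fully_lamellar(domain):
    """State with the entire healing region remodeled to lamellar bone."""
    state = initial_state(domain)
    heal = domain.healing_mask
    state.connective[heal] = 0.0
    state.lamellar[heal] = 1.0
    state.vascularity[heal] = 1.0
    return state


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# --- shared full-pipeline runs (expensive; computed once per session) ------

def favorable_scenario():
    from callusim.cohort import Scenario
    return Scenario(
        patient=PatientCase(id="fav", age=30.4, height=173.4, weight=80.4,
                            sex="M", side="right"),
        fracture=FractureConfig(gap_size=2.0),
        nail=NailConfig(diameter=13.0), compromised=False)


def compromised_scenario():
    from callusim.cohort import Scenario
    return Scenario(
        patient=PatientCase(id="comp", age=30.4, height=173.4, weight=80.4,
                            sex="M", side="right"),
        fracture=FractureConfig(gap_size=8.0),
        nail=NailConfig(diameter=9.0), compromised=True)


@pytest.fixture(scope="session")
def fast_config():
    from callusim.pipeline import SimulationConfig
    return SimulationConfig(voxel_size=3.0, mrust_every=70)


@pytest.fixture(scope="session")
def favorable_report_h3(fast_config):
    from callusim.pipeline import run_case
    return run_case(favorable_scenario(), fast_config)


@pytest.fixture(scope="session")
def compromised_report_h3(fast_config):
    from callusim.pipeline import run_case
    return run_case(compromised_scenario(), fast_config)
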