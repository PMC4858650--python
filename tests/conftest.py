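import copy

import numpy as np
import pytest
from hypothesis import settings

from hepaspect.cohort import AnimalRecord
from hepaspect.kinetics import KineticParams
from hepaspect.pipeline import reference_config, validate_config

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_raw():
    return reference_config()


@pytest.fixture(scope="session")
def reference_run_config(reference_raw):
    return validate_config(copy.deepcopy(reference_raw))


@pytest.fixture(scope="session")
def control_params(reference_raw) -> KineticParams:
    """Control-group kinetics at the group-mean receptor density."""
    cohort = reference_raw["cohort"]
    g = cohort["groups"]["control"]
    return KineticParams(
        k_up=g["k_up"], R=g["asgpr_rel"]["mean"], **cohort["kinetic_defaults"]
    )


@pytest.fixture
def noiseless_raw(reference_raw):
    """Reference config with all covariate SDs zeroed and Poisson off."""
    raw = copy.deepcopy(reference_raw)
    raw["acquisition"]["poisson"] = False
    for g in raw["cohort"]["groups"].values():
        for key, val in g.items():
            if isinstance(val, dict) and "sd" in val:
                val["sd"] = 0.0
    return raw


@pytest.fixture
def control_animal(control_params) -> AnimalRecord:
    return AnimalRecord(
        animal_id="control_001", group="control", ishak=0,
        hydroxyproline=150.0, sirius_red_pct=0.3, asgpr_rel=1.0, mmp9_rel=1.0,
        liver_volume_mL=1.0, injected_MBq=18.0, kinetics=control_params,
    )
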