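import numpy as np
import pytest

from fdopakin import (
    TimeActivityCurve,
    study_schedule,
)
from fdopakin.simulate import (
    TissueKinetics,
    default_plasma_input,
    default_reference_kinetics,
    default_tissue_kinetics,
    simulate_region,
)


@pytest.fixture(scope="session")
def sched():
    return study_schedule()


@pytest.fixture(scope="session")
def plasma():
    return default_plasma_input()


@pytest.fixture(scope="session")
def kin():
    return default_tissue_kinetics()


@pytest.fixture(scope="session")
def ref_kin():
    return default_reference_kinetics()


@pytest.fixture(scope="session")
def striatum_tac(kin, plasma, sched):
    return simulate_region(kin, plasma, sched, region_label="whole_striatum")


@pytest.fixture(scope="session")
def striatum_tac_irreversible(kin, plasma, sched):
    trapped = TissueKinetics(kin.K1, kin.k2, kin.k3, 0.0)
    return simulate_region(trapped, plasma, sched, region_label="whole_striatum")


@pytest.fixture(scope="session")
def cerebellum_tac(ref_kin, plasma, sched):
    return simulate_region(ref_kin, plasma, sched, region_label="cerebellum")


@pytest.fixture()
def flat_tac(sched):
    return TimeActivityCurve(sched, np.ones(sched.n_frames), region_label="flat")
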