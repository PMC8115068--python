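import numpy as np
import pytest

from fdopa.core import FrameSchedule, KineticGroundTruth
from fdopa.synthetic import CohortDesign, make_mask, make_reference_tac


@pytest.fixture(scope="session")
def schedule1():
    return FrameSchedule.dataset1()


@pytest.fixture(scope="session")
def schedule2():
    return FrameSchedule.dataset2()


@pytest.fixture(scope="session")
def ref_tac(schedule1):
    return make_reference_tac(schedule1)


@pytest.fixture(scope="session")
def mask():
    return make_mask()


@pytest.fixture(scope="session")
def small_mask():
    # tiny atlas for fast voxel-level tests (still all six labels)
    return make_mask(
        shape=(10, 10, 4),
        striatal_counts={"limbic": 40, "associative": 80, "sensorimotor": 40},
        n_cerebellum=60,
        n_extra_striatal=120,
    )


@pytest.fixture
def truth():
    return KineticGroundTruth(ki_true=0.01, v_prime=0.5)


@pytest.fixture
def small_design():
    return CohortDesign(n_per_group={"responder": 4, "non_responder": 4})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
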