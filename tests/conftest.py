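import numpy as np
import pytest

from ossasl.config import (AcquisitionConfig, FitConfig, PhantomSpec,
                           StudyConfig)
from ossasl.kinetic import KineticParams
from ossasl.phantom import make_phantom, simulate_masks


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def fitcfg():
    return FitConfig()


@pytest.fixture
def gm_params():
    """GM-like 7T kinetic parameters."""
    return KineticParams(f=50.7, delta_t=0.70, tau=0.7, t1_tissue=1.9,
                         m0_blood=110.0)


@pytest.fixture
def wm_params():
    """WM-like 7T kinetic parameters."""
    return KineticParams(f=16.3, delta_t=0.89, tau=0.7, t1_tissue=1.4,
                         m0_blood=110.0)


@pytest.fixture(scope="session")
def default_phantom(acq, fitcfg):
    return make_phantom(PhantomSpec(), acq, fitcfg)


@pytest.fixture(scope="session")
def default_masks(default_phantom):
    return simulate_masks(default_phantom)


@pytest.fixture(scope="session")
def noiseless_phantom(acq, fitcfg):
    return make_phantom(PhantomSpec(noise_sigma=0.0), acq, fitcfg)


def tiny_study_config(**overrides) -> StudyConfig:
    """A fast end-to-end configuration (small matrix, few blocks)."""
    cfg = StudyConfig()
    cfg.phantom.matrix = 16
    cfg.phantom.n_slices = 2
    cfg.acquisition.n_blocks = 2
    cfg.cohort.n_subjects = 1
    cfg.mask_variants = ("gm", "wm-gm")
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture
def tiny_config():
    return tiny_study_config()
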