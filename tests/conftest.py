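import numpy as np
import pytest

from bnctshift import (BeamConfig, WeightingConfig, build_cylinder_phantom,
                       calibrate_engine)
from bnctshift.study import StudyConfig, run_study


@pytest.fixture(scope="session")
def beam():
    return BeamConfig()


@pytest.fixture(scope="session")
def weighting():
    return WeightingConfig()


@pytest.fixture(scope="session")
def calibration(beam, weighting):
    return calibrate_engine(beam, weighting)


@pytest.fixture(scope="session")
def params(calibration):
    return calibration.params


@pytest.fixture(scope="session")
def study_report(params):
    """Full default battery at both depths on both phantom families."""
    return run_study(StudyConfig(), params=params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180501)


@pytest.fixture()
def tiny_phantom():
    """Small mixed air/tissue grid exercising interior-air depth handling."""
    from bnctshift.phantom import AIR, PMMA, VoxelPhantom

    gen = np.random.default_rng(7)
    labels = (gen.random((10, 10, 10)) < 0.7).astype(np.int16)
    labels[:, 0, :] = 0  # leading air layer creates per-ray gaps
    density = np.where(labels == 1, PMMA.density, AIR.density)
    table = {0: AIR, 1: PMMA}
    return VoxelPhantom(labels, density, (0.8, 0.8, 0.8), (-4.0, 0.0, -4.0),
                        table)
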