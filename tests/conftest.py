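import numpy as np
import pytest
from hypothesis import settings

import nfbsim as nfb

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def roi_design():
    return nfb.build_session_design("ROI", "tenderness")


@pytest.fixture(scope="session")
def svm_design():
    return nfb.build_session_design("SVM", "tenderness")


@pytest.fixture(scope="session")
def noiseless_roi_session(roi_design):
    """Noise- and drift-free phantom with 2% effects in both target ROIs."""
    cfg = nfb.roi_phantom_config(seed=11, noise_sd=0.0, drift_amplitude_per_run=0.0)
    return nfb.generate_session(roi_design, cfg)


@pytest.fixture(scope="session")
def noisy_roi_training_run(roi_design):
    """Training run at voxelwise CNR ~ 1 (2% effect on baseline 1000, sd 20)."""
    cfg = nfb.roi_phantom_config(seed=12, noise_sd=20.0)
    return cfg, nfb.generate_run(roi_design, cfg, 1)


@pytest.fixture(scope="session")
def svm_session_noisy(svm_design):
    cfg = nfb.svm_phantom_config(seed=13, noise_sd=20.0)
    return cfg, nfb.generate_session(svm_design, cfg)
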