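import numpy as np
import pytest
from hypothesis import settings

from scfs.detection import DetectionParams
from scfs.presets import preset_condition
from scfs.simulate import NoiseModel, simulate_retract_curve

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return DetectionParams()


@pytest.fixture(scope="session")
def nf_curve():
    """One default NF-NF-like noisy curve with ground truth."""
    cfg = preset_condition("NF-NF", seed=3)
    return simulate_retract_curve(cfg)


@pytest.fixture(scope="session")
def clean_curve():
    """Noise-free, drift-only curve with ground truth."""
    from dataclasses import replace

    cfg = preset_condition("NF-NF", seed=8)
    cfg = replace(cfg, noise=NoiseModel(deflection_sd=0.0, drift_slope=0.002))
    return simulate_retract_curve(cfg)
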