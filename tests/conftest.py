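import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecgvision as ev

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def two_class_record() -> ev.EcgRecord:
    """120 s record alternating narrow-normal and wide-ventricular beats."""
    cfg = ev.SynthesisConfig(duration=120.0, classes=("N", "V"), seed=3)
    return ev.generate_record(cfg)


@pytest.fixture(scope="session")
def normal_record() -> ev.EcgRecord:
    """30 s record of normal beats only."""
    cfg = ev.SynthesisConfig(duration=30.0, classes=("N",), seed=1)
    return ev.generate_record(cfg)


@pytest.fixture(scope="session")
def small_dataset(two_class_record):
    """Aligned 180x64 train/test image split from the two-class record."""
    return ev.build_dataset([two_class_record], 180, 64, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
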