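import numpy as np
import pytest
from hypothesis import settings

from hf183.model import StandardCurve, VolumeConfig
from hf183.pipeline import analyze_campaign
from hf183.simulate import default_study_like_scenario, simulate_campaign

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def volumes():
    return VolumeConfig()  # composite factor 78.9 at 100 mL filtered


@pytest.fixture(scope="session")
def curve():
    """Noise-free reference curve: Cq = 37 - 3.5 log10(copies)."""
    return StandardCurve(
        lab_id="L00",
        slope=-3.5,
        intercept=37.0,
        r_squared=1.0,
        efficiency=10 ** (1 / 3.5) - 1,
        n_points_used=18,
        lod_cq=37.0,
        lloq_cq=33.7,
    )


@pytest.fixture(scope="session")
def default_campaign():
    return simulate_campaign(default_study_like_scenario())


@pytest.fixture(scope="session")
def default_result(default_campaign):
    c = default_campaign
    return analyze_campaign(c.plates, c.metadata, c.rain)


def cq_for_copies(copies: float, curve: StandardCurve) -> float:
    return curve.intercept + curve.slope * np.log10(copies)
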