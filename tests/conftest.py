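import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_plant():
    """One default plant shared by read-only tests."""
    from mangoray.canopy3d import PlantConfig, build_plant

    return build_plant(PlantConfig())


@pytest.fixture(scope="session")
def vertical_beam():
    from mangoray.lightenv import BeamSource, SceneIllumination

    return SceneIllumination(
        beam=BeamSource(direction=np.array([0.0, 0.0, -1.0]),
                        ppfd_normal=1000.0))
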