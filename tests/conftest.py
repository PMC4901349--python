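import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fast",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")

import mechanoscale as ms


@pytest.fixture(scope="session")
def anchor_params():
    """The canonical 3D free-boundary parameter set (r0 = 50a, R = 20000a)."""
    return ms.ModelParams.with_source_scale(
        50.0,
        dimension=3,
        boundary="free",
        system_size=20000.0,
        interaction_mag=1.0,
    )


@pytest.fixture(scope="session")
def anchor_profile(anchor_params):
    """Fixed-lambda (1000a) shooting solution on the canonical set."""
    return ms.shoot(1000.0, anchor_params)


@pytest.fixture(scope="session")
def fig2_record():
    """Calibrated three-size self-consistent trio (the collapse experiment)."""
    return ms.run_fig2()


@pytest.fixture()
def uniform_profile():
    """Flat phi = 0.5 profile on [1, 100] in 3D (strain-formula fixture)."""
    params = ms.ModelParams(
        dimension=3,
        boundary="free",
        system_size=100.0,
        source_flux=0.1,
        interaction_mag=0.2,
    )
    grid = np.geomspace(1.0, 100.0, 4096)
    return ms.Profile(
        grid=grid, values=np.full_like(grid, 0.5), lambda_used=10.0, params=params
    )
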