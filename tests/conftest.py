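import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from beadquant import (
    ArrayLayout,
    DetectionParams,
    OpticsParams,
    SignalModel,
    random_occupancy,
    render_pair,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_layout():
    """The reference chip: 10 rows x 60 pillars = 590 traps."""
    return ArrayLayout()


@pytest.fixture(scope="session")
def small_layout():
    """A reduced array (4 rows x 12 pillars = 44 traps) for fast rendering."""
    return ArrayLayout(n_rows=4, pillars_per_row=12)


@pytest.fixture(scope="session")
def default_optics():
    return OpticsParams()


@pytest.fixture(scope="session")
def clean_optics():
    """Noiseless, gradient-free optics for exact-value checks."""
    return OpticsParams(noise_sd=0.0, background_gradient=0.0)


@pytest.fixture(scope="session")
def detection_params(default_optics):
    return DetectionParams(template_radius_px=default_optics.bead_radius_px)


@pytest.fixture(scope="session")
def small_pair(small_layout, default_optics):
    """A fully occupied small array at default noise, mixed signal."""
    occ = random_occupancy(small_layout, 1.0, seed=11)
    signal = SignalModel(positive_fraction=0.5)
    bf, fl, gt = render_pair(small_layout, occ, default_optics, signal, seed=12)
    return bf, fl, gt
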