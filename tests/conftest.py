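import numpy as np
import pytest

from acqa import GapProfile, PhantomSpec, make_phantom
from acqa.study import make_fixtures


@pytest.fixture(scope="session")
def tiny_bundle():
    """Deterministic miniature fixtures: noiseless phantom + series."""
    return make_fixtures("tiny")


@pytest.fixture(scope="session")
def small_bundle():
    """Noisy small fixtures for statistics-level checks."""
    return make_fixtures("small")


@pytest.fixture(scope="session")
def noiseless_spec():
    """Crisp-edged, noise-free tiny spec for exact-value checks."""
    return PhantomSpec(
        shape=(16, 56, 48),
        semi_axes_mm=(14.0, 12.0),
        target_radius_mm=6.0,
        tissue_noise_sd=0.0,
        bolus_noise_sd=0.0,
        air_noise_sd=0.0,
        edge_blur_mm=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_bolus_phantom(noiseless_spec):
    """Noiseless phantom with a 4 mm bolus and a uniform 1 mm air gap."""
    from dataclasses import replace

    spec = replace(
        noiseless_spec,
        surface_layer_thickness_cm=0.4,
        gap_profile=GapProfile(base_width_mm=1.0),
    )
    return make_phantom(spec)
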