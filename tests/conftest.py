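import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "derandomized",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")

from capscan.simulate import (  # noqa: E402
    ChannelSpec,
    NucleusSpec,
    cap_channel_pair,
    coloc_channel_pair,
    flat_density_field,
    simulate_nucleus_image,
)


@pytest.fixture
def circle_spec():
    """Circular nucleus with angularly flat NPC density (symmetric baseline)."""
    return NucleusSpec(semi_axes=(10.0, 10.0), npc_density_field=flat_density_field)


@pytest.fixture
def noiseless_channel():
    return ChannelSpec(noise="none")


@pytest.fixture
def make_cap_image():
    """Factory: simulated cap-enrichment image (GFP ring + cluster blob)."""

    def factory(enrichment=1.0, seed=0, displaced=0.0, noise="poisson", **spec_kwargs):
        spec = NucleusSpec(cap_enrichment=enrichment, **spec_kwargs)
        return simulate_nucleus_image(spec, cap_channel_pair(displaced, noise=noise), seed)

    return factory


@pytest.fixture
def make_coloc_image():
    """Factory: simulated colocalization image (two co-labeled rings)."""

    def factory(displaced=0.0, seed=0, noise="poisson", **spec_kwargs):
        spec = NucleusSpec(**spec_kwargs)
        return simulate_nucleus_image(spec, coloc_channel_pair(displaced, noise=noise), seed)

    return factory


def circle_radial_errors(contour, center, radius):
    """Distance of each traced point from a true circle of given radius."""
    d = np.linalg.norm(contour.points - np.asarray(center), axis=1)
    return np.abs(d - radius)
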