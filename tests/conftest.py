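import numpy as np
import pytest

from pseudodxa.cohort import GeometrySpec, build_fn_volume


@pytest.fixture(scope="session")
def circular_geom() -> GeometrySpec:
    """Circular tube: 20 mm outer diameter, 2 mm wall, 15 mm long."""
    return GeometrySpec(
        neck_length=15.0,
        si_outer_diameter=20.0,
        ap_si_ratio=1.0,
        cortical_thickness=2.0,
        trabecular_bvtv_target=0.0,
    )


@pytest.fixture(scope="session")
def realistic_geom() -> GeometrySpec:
    """Cohort-scale elliptical geometry with a trabecular interior."""
    return GeometrySpec(
        neck_length=15.0,
        si_outer_diameter=31.3,
        ap_si_ratio=0.84,
        cortical_thickness=1.2,
        trabecular_bvtv_target=0.14,
    )


@pytest.fixture(scope="session")
def realistic_volume(realistic_geom):
    return build_fn_volume(realistic_geom, 0.3, 42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
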