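import numpy as np
import pytest

from sicklestain import GeneratorParams, StainGeometry, generate_stain, to_intensity


@pytest.fixture
def quiet_params():
    """Default stain parameters with noise switched off."""
    return GeneratorParams(percent_hbs=40.0, noise_sd=0.0)


@pytest.fixture
def stain_factory():
    """Render a noiseless stain and return (intensity_map, truth, true_geometry)."""

    def make(**kwargs):
        kwargs.setdefault("noise_sd", 0.0)
        params = GeneratorParams(**kwargs)
        image, record = generate_stain(params)
        geom = StainGeometry(
            center_xy=record.center_xy,
            r_center=params.r_center_mm,
            r_outer=params.r_outer_eff_mm,
        )
        return to_intensity(image), record, geom

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
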