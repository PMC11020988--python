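import numpy as np
import pytest

from petimm import PhantomSpec, SUVVolume, VOIMask, generate_phantom


@pytest.fixture
def noiseless_sphere():
    """Sphere of SUV 10 (radius 18.75 mm) in a constant SUV-1 background."""

    def make(radius_mm=18.75, tumor_suv=10.0, spacing=(4.07, 4.07, 2.5), shape=(48, 48, 48)):
        spec = PhantomSpec(
            grid_shape=shape,
            voxel_spacing_mm=spacing,
            background_suv_mean=1.0,
            background_suv_sd=0.0,
            tumor_center_mm=tuple(0.5 * n * s for n, s in zip(shape, spacing)),
            tumor_radius_mm=radius_mm,
            tumor_suv_mean=tumor_suv,
            tumor_texture_sd=0.0,
            organ_specs=(),
            noise_sd=0.0,
            seed=0,
        )
        return spec, *generate_phantom(spec)

    return make


@pytest.fixture
def random_voi():
    """A small random volume + random non-empty mask, reproducible per seed."""

    def make(seed, shape=(8, 8, 6), spacing=(4.07, 4.07, 2.5)):
        rng = np.random.default_rng(seed)
        vol = SUVVolume(rng.uniform(0.5, 15.0, shape), spacing)
        mask = rng.random(shape) < rng.uniform(0.2, 0.8)
        if not mask.any():
            mask[tuple(rng.integers(0, s) for s in shape)] = True
        return vol, VOIMask(mask, spacing)

    return make
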