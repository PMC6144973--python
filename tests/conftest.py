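"""Shared fixtures: noiseless synthetic egg pairs and trait datasets."""

import numpy as np
import pytest

from ovoscope import eggsim, radiometry


@pytest.fixture(scope="session")
def noiseless_truth() -> eggsim.EggImageTruth:
    """A gamma-2.2, noise-free VIS/UV egg pair with a mild smooth warp."""
    return eggsim.make_egg_image(
        gamma=2.2, noise_sd=0.0, uv_noise_sd=0.0, n_spots=8, seed=3,
        warp_params={"style": "smooth_bumps", "magnitude_px": 4.0},
        n_control_points=20,
    )


@pytest.fixture(scope="session")
def refl_vis(noiseless_truth) -> radiometry.ReflectanceImage:
    raw = radiometry.RawImage(
        noiseless_truth.vis_raw, ("R", "G", "B"), noiseless_truth.bit_depth
    )
    return radiometry.to_reflectance(
        radiometry.linearize(raw, noiseless_truth.gamma),
        noiseless_truth.standard_patch,
        noiseless_truth.standard_value,
    )


@pytest.fixture(scope="session")
def refl_uv(noiseless_truth) -> radiometry.ReflectanceImage:
    raw = radiometry.RawImage(
        noiseless_truth.uv_raw, ("UV",), noiseless_truth.bit_depth
    )
    return radiometry.to_reflectance(
        radiometry.linearize(raw, noiseless_truth.gamma),
        noiseless_truth.standard_patch_uv,
        noiseless_truth.standard_value,
    )


@pytest.fixture(scope="session")
def trait_truth() -> eggsim.TraitTableTruth:
    return eggsim.make_trait_dataset(seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
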