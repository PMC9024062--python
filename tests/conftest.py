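"""Shared fixtures: a desk-scale instrument and small synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from octadc.sim import (
    DispersionSpec,
    Layer,
    LayeredSample,
    NoiseModel,
    make_source_spectrum,
    resample_to_k,
    simulate_volume,
)


@pytest.fixture(scope="session")
def source():
    return make_source_spectrum(840.0, 50.0, 256)


@pytest.fixture(scope="session")
def grid(source):
    return resample_to_k(source)


@pytest.fixture(scope="session")
def single_layer_frame_factory(source, grid):
    """Factory for noise-free frames with one dispersive layer at 200 um."""

    def make(a2: float = 0.0, delta_z_um: float = 200.0, reflectivity: float = 0.8, n_alines: int = 8):
        sample = LayeredSample(
            (Layer(delta_z_um, reflectivity, DispersionSpec(a2=a2)),),
            lateral_profile=np.linspace(0.0, 3.0, n_alines),  # break A-line degeneracy
        )
        return simulate_volume(
            sample,
            1,
            n_alines,
            repeats=1,
            noise_model=NoiseModel(),
            rng_seed=3,
            source=source,
            grid=grid,
        )[0]

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
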