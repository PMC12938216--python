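"""Shared fixtures: the protocol-default interleaf and a small noise-free
phantom acquisition reused across module tests (designs and simulations are
deterministic, so session scope is safe)."""

import dataclasses

import numpy as np
import pytest

from spiralpc.phantom import (PhantomConfig, beat_onsets, simulate_acquisition,
                              simulate_coils)
from spiralpc.trajectory import (SpiralDesignSpec, build_schedule,
                                 design_dual_density_spiral)


@pytest.fixture(scope="session")
def table1_spec():
    return SpiralDesignSpec()


@pytest.fixture(scope="session")
def table1_interleaf(table1_spec):
    return design_dual_density_spiral(table1_spec)


@pytest.fixture(scope="session")
def small_setup():
    """64x64, 12-frame, 4-coil, noise-free phantom acquisition."""
    spec = SpiralDesignSpec(fov=300.0, resolution=300.0 / 64)
    interleaf = design_dual_density_spiral(spec)
    schedule = build_schedule(12 * 0.044, 11.0)
    config = dataclasses.replace(
        PhantomConfig(), matrix=64, n_coils=4, noise_sigma=0.0, seed=99)
    onsets = beat_onsets(config, 12 * 44.0)
    maps = simulate_coils(config.n_coils, config.matrix, seed=config.seed)
    kspace = simulate_acquisition(schedule, config, maps, interleaf,
                                  onsets=onsets)
    return dict(spec=spec, interleaf=interleaf, schedule=schedule,
                config=config, onsets=onsets, maps=maps, kspace=kspace)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
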