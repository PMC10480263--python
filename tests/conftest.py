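"""Shared fixtures: desk-scale phantoms, simulator settings and a small
pre-trained translation model reused by the training-dependent tests."""

from __future__ import annotations

import numpy as np
import pytest

from cbctrepair.gan import Pix2PixGAN
from cbctrepair.phantom import PhantomSpec, make_cohort, make_thorax_phantom
from cbctrepair.simulate import SimParams, simulate_scbct_slice


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    return PhantomSpec(image_size=128)

@pytest.fixture(scope="session")
def desk_phantom(desk_spec) -> np.ndarray:
    return make_thorax_phantom(desk_spec, seed=1)

@pytest.fixture(scope="session")
def desk_sim_params() -> SimParams:
    return SimParams(fov_radius=32.0, n_angles=90, deform_grid_spacing=16, deform_max_disp=4.0)

@pytest.fixture(scope="session")
def tiny_sim_params() -> SimParams:
    return SimParams(fov_radius=16.0, n_angles=60, deform_grid_spacing=16, deform_max_disp=3.0)


@pytest.fixture(scope="session")
def training_pairs(tiny_sim_params) -> tuple[np.ndarray, np.ndarray]:
    """Eight simulated (sCBCT, full CT) pairs at 64 px."""
    vols = make_cohort(2, 4, PhantomSpec(image_size=64), seed=5)
    X, Y = [], []
    for v, vol in enumerate(vols):
        for i in range(len(vol)):
            p = simulate_scbct_slice(vol[i], tiny_sim_params, seed=50 * v + i)
            X.append(p.scbct)
            Y.append(p.full_gt)
    return np.stack(X), np.stack(Y)


@pytest.fixture(scope="session")
def trained_model(training_pairs) -> Pix2PixGAN:
    """A short but genuinely trained desk-scale model (reused, never mutated
    in place: transfer learning always returns a copy)."""
    X, Y = training_pairs
    est = Pix2PixGAN(input_size=64, base_filters=8, encoder_depth=6, epochs=12, seed=1)
    return est.fit(X, Y)
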