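"""Shared fixtures: desk-scale phantoms reused across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from tibrad.features import extract_all
from tibrad.phantom import PhantomParams, generate_tibia_phantom
from tibrad.voi import extract_vois

#: Coarse test-scale phantom: 1 mm isotropic, 10-voxel VOI tiers.
COARSE = dict(grid_shape=(40, 40, 56), spacing_mm=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def coarse_params() -> PhantomParams:
    return PhantomParams(**COARSE, seed=11)


@pytest.fixture(scope="session")
def control_phantom(coarse_params):
    return generate_tibia_phantom(coarse_params, oa_class=False)


@pytest.fixture(scope="session")
def oa_phantom(coarse_params):
    return generate_tibia_phantom(coarse_params, oa_class=True)


@pytest.fixture(scope="session")
def control_vois(control_phantom):
    vol, mask = control_phantom
    return extract_vois(mask, vol.spacing)


@pytest.fixture(scope="session")
def control_features(control_phantom, control_vois):
    vol, mask = control_phantom
    return extract_all(vol, mask, control_vois)


def make_phantom(seed: int, oa: bool = False, **overrides):
    params = PhantomParams(**{**COARSE, **overrides}, seed=seed)
    return generate_tibia_phantom(params, oa)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
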