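"""Shared fixtures: small phantoms sized for fast, deterministic tests."""

from __future__ import annotations

import numpy as np
import pytest

from tagflow3d.phantom import (PhantomConfig, DeformationModel,
                               default_tag_specs, make_tagged_sequence,
                               make_lv_phantom)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A compact LV phantom: 40x40x14 voxels, 4 phases."""
    return PhantomConfig(grid_shape=(40, 40, 14), n_phases=4,
                         phase_times=np.linspace(50, 350, 4),
                         endo_radius_mm=6.0, epi_radius_mm=11.0,
                         wall_extent_mm=16.0, texture_seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    """(sequence, truth, mask) for the compact deforming tagged phantom."""
    return make_tagged_sequence(small_config, default_tag_specs(),
                                DeformationModel())


@pytest.fixture(scope="session")
def small_base(small_config):
    """Untagged static base volume + myocardial mask."""
    return make_lv_phantom(small_config)


@pytest.fixture(scope="session")
def textured_volume(small_base):
    """A single textured 3D volume (phase 0 of the static base)."""
    seq, _ = small_base
    return seq.phase(0).copy()
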