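"""Shared fixtures: small hand-built scaffolds and concentration fields."""

from __future__ import annotations

import numpy as np
import pytest

from angioscaffold.abm_core import RuleParams
from angioscaffold.gf_transport import ConcentrationField
from angioscaffold.scaffold_gen import MATERIAL, PORE, VoxelScaffold


def make_open_scaffold(shape=(10, 40, 10), spacing_um=20.0) -> VoxelScaffold:
    """A fully porous box (no material) for rule-level tests."""
    grid = np.full(shape, PORE, dtype=np.uint8)
    return VoxelScaffold(grid, spacing_um)


def make_channel_scaffold(length=40, spacing_um=20.0) -> VoxelScaffold:
    """A single 1-voxel-wide vertical pore channel walled by material."""
    grid = np.full((3, length, 3), MATERIAL, dtype=np.uint8)
    grid[1, :, 1] = PORE
    return VoxelScaffold(grid, spacing_um)


def make_linear_field(height_mm: float, top_conc: float, t_end_h: float = 2000.0) -> ConcentrationField:
    """A static field rising linearly from 0 at the host face to the top."""
    y = np.linspace(0.0, height_mm, 41)
    t = np.array([0.0, t_end_h])
    prof = top_conc * y / height_mm
    return ConcentrationField(y, t, np.vstack([prof, prof]))


def make_uniform_field(height_mm: float, conc: float, t_end_h: float = 2000.0) -> ConcentrationField:
    y = np.linspace(0.0, height_mm, 11)
    t = np.array([0.0, t_end_h])
    prof = np.full_like(y, conc)
    return ConcentrationField(y, t, np.vstack([prof, prof]))


def make_zero_field(height_mm: float) -> ConcentrationField:
    return make_uniform_field(height_mm, 0.0)


@pytest.fixture
def open_scaffold():
    return make_open_scaffold()


@pytest.fixture
def channel_scaffold():
    return make_channel_scaffold()


@pytest.fixture
def quick_params():
    """Single-voxel steps, no exploration: fully predictable migration."""
    return RuleParams(
        migration_step_um_per_tick=20.0,
        explore_prob=0.0,
        source_density_per_mm2=25.0,
    )
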