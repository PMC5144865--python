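"""Preformed capillary networks seeded into the pore space before simulation.

A prevascularized scaffold starts with capillary chains already laid into
the pores (emulating in-vitro prevascularization) in one of three spatial
configurations: the whole scaffold, the top half (distal, away from the
host) or the bottom half (adjacent to the host).  Each chain starts at a
random pore voxel of the region and is extended by random adjacent-pore
steps; when no admissible pore location is found within ``max_retries``
draws the chain stops, which makes chain lengths vary with the local pore
structure.

Preformed chains are ordinary non-stable vessels: they regress if the
growth factor around them falls below threshold, and they become
anastomosed and stable — along with their whole connected component — the
moment a host-derived sprout fuses with any of their cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .abm_core import _NEIGH, _NEIGH_LEN, SimulationState, Vessel
from .scaffold_gen import PORE, VoxelScaffold

__all__ = ["PrevascSpec", "seed_network", "integrate", "REGIONS"]

REGIONS = ("NONE", "FULL", "TOP_HALF", "BOTTOM_HALF")


@dataclass
class PrevascSpec:
    """Configuration of the preformed network.

    ``n_seeds`` is the number of chain starting points; the resulting
    network density also depends on how far chains run before stopping,
    which the scaffold's pore structure controls.
    """

    region: str = "NONE"
    n_seeds: int = 90
    max_retries: int = 10
    max_chain_voxels: int = 100
    seed: int | None = None

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be non-negative")
        if self.max_retries < 1:
            raise ValueError("max_retries must be at least 1")


def _region_bounds(region: str, ny: int) -> tuple[int, int]:
    half = ny // 2
    if region == "FULL":
        return 0, ny
    if region == "TOP_HALF":
        return half, ny
    if region == "BOTTOM_HALF":
        return 0, half
    raise ValueError(region)


def seed_network(scaffold: VoxelScaffold, spec: PrevascSpec) -> list[Vessel]:
    """Grow preformed capillary chains confined to the requested region.

    Returns standalone :class:`Vessel` objects (origin ``PREFORMED``, no
    migrating tip, not stable); pass them to :func:`integrate` or to
    ``SimulationConfig.preformed`` to enter a simulation.
    """
    spec.validate()
    if spec.region == "NONE" or spec.n_seeds == 0:
        return []
    rng = np.random.default_rng(spec.seed)
    grid = scaffold.grid
    ny = grid.shape[1]
    y0, y1 = _region_bounds(spec.region, ny)
    sub = grid[:, y0:y1, :] == PORE
    mask = scaffold.domain_mask()
    if mask is not None:
        sub = sub & mask[:, y0:y1, :]
    pores = np.argwhere(sub)
    if len(pores) == 0:
        raise ValueError(f"region {spec.region} contains no pore voxels")
    pores[:, 1] += y0

    vessels: list[Vessel] = []
    starts = pores[rng.choice(len(pores), size=spec.n_seeds, replace=True)]
    for vid, start in enumerate(starts):
        v = Vessel(vid, "PREFORMED", tuple(int(c) for c in start), active=False)
        prev = None
        while len(v.path) < spec.max_chain_voxels:
            here = np.asarray(v.tip)
            extended = False
            for _ in range(spec.max_retries):
                k = int(rng.integers(len(_NEIGH)))
                cand = here + _NEIGH[k]
                if np.any(cand < 0) or np.any(cand >= grid.shape):
                    continue
                if not (y0 <= cand[1] < y1):
                    continue
                if grid[cand[0], cand[1], cand[2]] != PORE:
                    continue
                if mask is not None and not mask[cand[0], cand[1], cand[2]]:
                    continue
                tup = (int(cand[0]), int(cand[1]), int(cand[2]))
                if prev is not None and tup == prev:
                    continue
                prev = tuple(here)
                v.extend(tup, float(_NEIGH_LEN[k] * scaffold.spacing_um))
                extended = True
                break
            if not extended:
                break
        vessels.append(v)
    return vessels


def integrate(
    preformed: list[Vessel],
    state: SimulationState,
    link_distance_um: float | None = None,
) -> SimulationState:
    """Add preformed vessels to a simulation state.

    Chains enter as non-stable, non-migrating vessels.  Chains that touch
    (within one voxel of each other) are pre-linked into one connected
    component — they fused while the network formed in vitro — so a host
    contact stabilizes the whole touching component; pre-linking alone
    does not mark anything stable or anastomosed.
    """
    if not preformed:
        return state
    if link_distance_um is None:
        link_distance_um = 1.01 * state.scaffold.spacing_um
    new_ids = []
    for v in preformed:
        nv = state.network.add_vessel("PREFORMED", v.path[0], active=False)
        nv.path = list(v.path)
        nv.seg_lengths = list(v.seg_lengths)
        new_ids.append(nv.id)

    pts = []
    owners = []
    for vid in new_ids:
        v = state.network.vessels[vid]
        arr = np.asarray(v.path, dtype=float) * state.scaffold.spacing_um
        pts.append(arr)
        owners.append(np.full(len(arr), vid))
    all_pts = np.vstack(pts)
    all_own = np.concatenate(owners)
    tree = cKDTree(all_pts)
    for i, j in tree.query_pairs(link_distance_um):
        a, b = int(all_own[i]), int(all_own[j])
        if a != b:
            state.network.link(a, b)
    return state
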