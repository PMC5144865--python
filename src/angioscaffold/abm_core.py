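"""Endothelial-cell agent rules on a scaffold and concentration field.

The simulation is a lattice agent-based model on the scaffold voxel grid.
Source endothelial cells sit on the host face (y = 0).  When the local
growth-factor concentration reaches the activation threshold, a source
becomes a migrating tip cell and starts a sprout.  Tips climb the
concentration gradient through pore space (26-neighbour moves, material
voxels are impassable); trailing stalk cells elongate with the tip and
proliferate when they reach their maximum length.  Two sprouts from
different capillaries that come within the anastomosis distance fuse into a
stable vessel, which is assumed to carry blood flow and thereafter ignores
growth-factor levels.  Non-stable vessels whose distal cells fall below the
regression threshold retract from the distal end inward.

Each tick applies, in order: field time advance, activation, tip migration,
elongation/proliferation bookkeeping, anastomosis, regression.  All
randomness is drawn from one seeded generator, so a (seed, config) pair
reproduces a trajectory exactly.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .gf_transport import ConcentrationField
from .scaffold_gen import PORE, VoxelScaffold

__all__ = [
    "RuleParams",
    "ECAgent",
    "Vessel",
    "VesselNetwork",
    "SimulationState",
    "SimulationConfig",
    "initialize_state",
    "activate_sprouts",
    "migrate_tip",
    "check_anastomosis",
    "regress",
    "step",
    "run_simulation",
    "state_signature",
    "HOURS_PER_WEEK",
]

HOURS_PER_WEEK = 168.0

# 26-neighbourhood offsets, fixed order for determinism
_NEIGH = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=np.int64
)
_NEIGH_LEN = np.linalg.norm(_NEIGH, axis=1)


@dataclass
class RuleParams:
    """Behavioural parameters of the endothelial-cell agents.

    The activation and regression thresholds default to 1 ng/mL, the order
    of magnitude reported for endothelial activation by PDGF-BB.  Migration
    speed, stalk length, anastomosis distance and source density are not
    printed in the primary reference; the defaults below are this package's
    calibration and are deliberately exposed.
    """

    activation_threshold_ng_per_ml: float = 1.0
    regression_threshold_ng_per_ml: float = 1.0
    max_stalk_length_um: float = 50.0
    anastomosis_distance_um: float = 25.0
    migration_step_um_per_tick: float = 40.0
    tick_h: float = 6.0
    max_sim_weeks: float = 6.0
    explore_prob: float = 1.0
    activation_depth_um: float = 100.0
    source_density_per_mm2: float = 40.0
    max_regression_um_per_tick: float | None = 24.0

    def validate(self) -> None:
        positive = (
            self.activation_threshold_ng_per_ml,
            self.regression_threshold_ng_per_ml,
            self.max_stalk_length_um,
            self.anastomosis_distance_um,
            self.migration_step_um_per_tick,
            self.tick_h,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all rule thresholds, lengths and steps must be positive")
        if self.regression_threshold_ng_per_ml > self.activation_threshold_ng_per_ml:
            raise ValueError("regression threshold must not exceed activation threshold")
        if not 0.0 <= self.explore_prob <= 1.0:
            raise ValueError("explore_prob must lie in [0, 1]")

    @property
    def regression_budget_um(self) -> float:
        if self.max_regression_um_per_tick is None:
            return self.migration_step_um_per_tick
        return self.max_regression_um_per_tick


@dataclass
class ECAgent:
    """View of one endothelial cell (derived from vessel bookkeeping)."""

    id: int
    position: tuple[int, int, int]
    role: str  # "TIP" | "STALK"
    vessel_id: int
    length_um: float
    state: str  # "ACTIVE" | "QUIESCENT" | "APOPTOTIC"


class Vessel:
    """One capillary: an ordered voxel path with per-step lengths."""

    __slots__ = ("id", "origin", "path", "seg_lengths", "active", "alive", "anastomosed", "stable")

    def __init__(self, vid: int, origin: str, start: tuple[int, int, int], active: bool = True):
        self.id = vid
        self.origin = origin  # "HOST" | "PREFORMED"
        self.path: list[tuple[int, int, int]] = [start]
        self.seg_lengths: list[float] = []
        self.active = active  # has a migrating tip
        self.alive = True
        self.anastomosed = False
        self.stable = False

    @property
    def tip(self) -> tuple[int, int, int]:
        return self.path[-1]

    def total_length_um(self) -> float:
        return float(sum(self.seg_lengths))

    def extend(self, voxel: tuple[int, int, int], length_um: float) -> None:
        self.path.append(voxel)
        self.seg_lengths.append(length_um)

    def ec_lengths(self, max_stalk_um: float) -> list[float]:
        """Partition the vessel length into cells of at most ``max_stalk_um``."""
        total = self.total_length_um()
        if total <= 0:
            return [0.0]
        n_full = int(total // max_stalk_um)
        rem = total - n_full * max_stalk_um
        out = [max_stalk_um] * n_full
        if rem > 1e-9:
            out.append(rem)
        return out or [0.0]


class VesselNetwork:
    """All vessels plus the union-find over anastomosed components."""

    def __init__(self) -> None:
        self.vessels: list[Vessel] = []
        self._parent: list[int] = []

    # -- construction -------------------------------------------------------
    def add_vessel(self, origin: str, start: tuple[int, int, int], active: bool = True) -> Vessel:
        v = Vessel(len(self.vessels), origin, start, active=active)
        self.vessels.append(v)
        self._parent.append(v.id)
        return v

    # -- union-find ---------------------------------------------------------
    def find(self, vid: int) -> int:
        while self._parent[vid] != vid:
            self._parent[vid] = self._parent[self._parent[vid]]
            vid = self._parent[vid]
        return vid

    def link(self, a: int, b: int) -> None:
        """Join two vessels into one component without flagging stability."""
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra

    def component(self, vid: int) -> list[Vessel]:
        root = self.find(vid)
        return [v for v in self.vessels if self.find(v.id) == root]

    def anastomose(self, a: int, b: int) -> None:
        """Fuse two vessels into a flow-carrying loop.

        The two fusing vessels become anastomosed and stable.  Preformed
        chains in the merged component become stable as well — they are
        passive conduits that carry flow once connected to the host — but
        growing branch sprouts elsewhere in the component stay non-stable
        until they close a loop of their own.
        """
        self.link(a, b)
        for vid in (a, b):
            self.vessels[vid].anastomosed = True
            self.vessels[vid].stable = True
        root = self.find(a)
        for v in self.vessels:
            if v.origin == "PREFORMED" and v.alive and self.find(v.id) == root:
                v.anastomosed = True
                v.stable = True

    # -- queries ------------------------------------------------------------
    def living(self) -> list[Vessel]:
        return [v for v in self.vessels if v.alive and v.path]

    def total_length_um(self) -> float:
        return float(sum(v.total_length_um() for v in self.living()))

    def agents(self, max_stalk_um: float = 50.0) -> list[ECAgent]:
        """Materialize per-cell views (tip last, stalks along the path)."""
        out: list[ECAgent] = []
        counter = 0
        for v in self.living():
            lengths = v.ec_lengths(max_stalk_um)
            n = len(lengths)
            # place each cell at the path voxel closest to its distal end
            cum = np.concatenate([[0.0], np.cumsum(v.seg_lengths)]) if v.seg_lengths else np.array([0.0])
            for k, length in enumerate(lengths):
                distal = min((k + 1) * max_stalk_um, cum[-1])
                idx = int(np.searchsorted(cum, distal))
                idx = min(idx, len(v.path) - 1)
                role = "TIP" if (k == n - 1 and v.active) else "STALK"
                state = "ACTIVE" if v.active else "QUIESCENT"
                out.append(ECAgent(counter, v.path[idx], role, v.id, length, state))
                counter += 1
        return out


@dataclass
class SimulationState:
    scaffold: VoxelScaffold
    field: ConcentrationField | None
    params: RuleParams
    network: VesselNetwork
    rng: np.random.Generator
    sources: list[tuple[int, int, int]]
    source_vessel: list[int | None]
    tick: int = 0
    layer_conc: np.ndarray | None = None  # conc at each voxel-centre depth

    @property
    def t_h(self) -> float:
        return self.tick * self.params.tick_h


@dataclass
class SimulationConfig:
    scaffold: VoxelScaffold
    field: ConcentrationField | None = None
    params: RuleParams = dc_field(default_factory=RuleParams)
    weeks: float | None = None  # default: params.max_sim_weeks
    seed: int | None = None
    preformed: list | None = None  # vessels from the prevascular module


# ---------------------------------------------------------------------------
# state construction
# ---------------------------------------------------------------------------


def initialize_state(
    scaffold: VoxelScaffold,
    field: ConcentrationField | None,
    params: RuleParams,
    seed: int | None = None,
    preformed: list | None = None,
) -> SimulationState:
    """Seed host-face source cells and (optionally) a preformed network."""
    params.validate()
    rng = np.random.default_rng(seed)
    face = scaffold.host_face_pore_voxels()
    face_area_mm2 = (
        scaffold.grid.shape[0] * scaffold.grid.shape[2] * (scaffold.spacing_um / 1000.0) ** 2
    )
    n_sources = min(len(face), max(1, int(round(params.source_density_per_mm2 * face_area_mm2))))
    if len(face) == 0:
        n_sources = 0
        chosen = np.empty((0, 3), dtype=int)
    else:
        chosen = face[rng.choice(len(face), size=n_sources, replace=False)]
    state = SimulationState(
        scaffold=scaffold,
        field=field,
        params=params,
        network=VesselNetwork(),
        rng=rng,
        sources=[tuple(int(c) for c in row) for row in chosen],
        source_vessel=[None] * n_sources,
    )
    if preformed:
        from .prevascular import integrate

        integrate(preformed, state)
    _update_layer_conc(state)
    return state


def _update_layer_conc(state: SimulationState) -> None:
    ny = state.scaffold.grid.shape[1]
    y_mm = (np.arange(ny) + 0.5) * state.scaffold.spacing_um / 1000.0
    if state.field is None:
        state.layer_conc = np.zeros(ny)
        return
    t = min(state.t_h, float(state.field.times_h[-1]))
    prof = state.field.profile_at(t)
    state.layer_conc = np.interp(y_mm, state.field.y_mm, prof)


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


def activate_sprouts(state: SimulationState) -> SimulationState:
    """Quiescent source cells sprout where the local concentration suffices.

    The source samples the field at the activation depth (the scale over
    which a nascent sprout senses the gradient); a source whose previous
    sprout has fully regressed may sprout again.
    """
    p = state.params
    ny = state.scaffold.grid.shape[1]
    iy_act = min(ny - 1, int(round(p.activation_depth_um / state.scaffold.spacing_um)))
    conc = state.layer_conc[iy_act]
    if conc < p.activation_threshold_ng_per_ml:
        return state
    for i, src in enumerate(state.sources):
        vid = state.source_vessel[i]
        prev = state.network.vessels[vid] if vid is not None else None
        if prev is not None and prev.alive:
            # a source may sprout again only once its previous sprout has
            # fully regressed, or has fused into a stable (flow-carrying)
            # vessel and stopped elongating
            if not prev.stable or prev.active:
                continue
        if prev is not None and prev.alive and prev.stable:
            # the new sprout branches off the perfused network near its
            # distal end, where the growth-factor concentration is highest;
            # it shares that component (no self-anastomosis with it) but is
            # itself a growing sprout without flow until it fuses
            branch_point = max(
                (p for v2 in state.network.component(prev.id)
                 if v2.stable and v2.alive and v2.path for p in [max(v2.path, key=lambda q: q[1])]),
                key=lambda p: p[1],
            )
            v = state.network.add_vessel("HOST", branch_point, active=True)
            state.network.link(prev.id, v.id)
        else:
            v = state.network.add_vessel("HOST", src, active=True)
        state.source_vessel[i] = v.id
    return state


def _pore_neighbours(state: SimulationState, voxel: tuple[int, int, int]) -> np.ndarray:
    grid = state.scaffold.grid
    pos = np.asarray(voxel)
    cand = pos + _NEIGH
    ok = np.all(cand >= 0, axis=1) & np.all(cand < grid.shape, axis=1)
    idx = np.nonzero(ok)[0]
    cand = cand[idx]
    pore = grid[cand[:, 0], cand[:, 1], cand[:, 2]] == PORE
    return idx[pore]


def migrate_tip(vessel: Vessel, state: SimulationState) -> None:
    """Move a tip up the gradient through pore space, one voxel substep.

    The tip moves to the admissible pore neighbour with the strictly highest
    concentration (ties broken randomly).  If no pore neighbour improves on
    the current concentration — the way up is blocked by material or the
    field is flat — the tip explores a random pore neighbour with
    probability ``explore_prob`` (searching a new route through the
    gradient), otherwise it stalls.
    """
    p = state.params
    here = vessel.tip
    conc_here = state.layer_conc[here[1]]
    # the tip senses over a filopodia-scale distance ahead of itself; when
    # even the concentration there is below the activation threshold the
    # cell is growth-factor deficient and stops migrating
    ny = len(state.layer_conc)
    look = min(ny - 1, here[1] + max(1, int(round(p.activation_depth_um / state.scaffold.spacing_um))))
    if state.layer_conc[look] < p.activation_threshold_ng_per_ml:
        return
    nb = _pore_neighbours(state, here)
    if len(nb) == 0:
        return
    nb_y = here[1] + _NEIGH[nb, 1]
    nb_conc = state.layer_conc[nb_y]
    improving = nb_conc > conc_here * (1.0 + 1e-12) + 1e-15
    if np.any(improving):
        cand = nb[improving]
        best = nb_conc[improving]
        winners = cand[best >= best.max() - 1e-15]
        choice = int(winners[state.rng.integers(len(winners))])
    elif state.rng.random() < p.explore_prob:
        # route search along the scaffold wall: prefer not to retreat down
        # the gradient while looking for a way around the material
        level = nb[nb_conc >= conc_here * (1.0 - 1e-12) - 1e-15]
        pool = level if len(level) else nb
        choice = int(pool[state.rng.integers(len(pool))])
    else:
        return
    offset = _NEIGH[choice]
    new = (here[0] + int(offset[0]), here[1] + int(offset[1]), here[2] + int(offset[2]))
    vessel.extend(new, float(_NEIGH_LEN[choice] * state.scaffold.spacing_um))


def _open_path(grid: np.ndarray, a, b) -> bool:
    """True when the straight segment between two voxels stays in pore space."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = max(2, int(np.ceil(2.0 * np.linalg.norm(b - a))) + 1)
    for t in np.linspace(0.0, 1.0, n):
        p = np.round(a + t * (b - a)).astype(int)
        if grid[p[0], p[1], p[2]] != PORE:
            return False
    return True


def check_anastomosis(state: SimulationState) -> SimulationState:
    """Fuse sprouts that come within the anastomosis distance.

    Fusion happens between two elongating sprout tips of different
    capillaries, or between an elongating tip and any cell of a preformed
    capillary chain (a prevascular segment is fusion-competent along its
    length).  The merged connected component becomes anastomosed and
    stable, and the fusing tips stop elongating; cells of the same vessel
    or component never self-anastomose.
    """
    living = state.network.living()
    radius = state.params.anastomosis_distance_um
    spacing = state.scaffold.spacing_um
    tips = [v for v in living if v.active]
    if not tips:
        return state

    # tip-tip fusions: union over all proximity pairs first (chains of
    # converging sprouts merge into one component within a tick), then the
    # fused tips stop elongating
    if len(tips) >= 2:
        tip_pts = np.asarray([v.tip for v in tips], dtype=float) * spacing
        tree = cKDTree(tip_pts)
        fused: set[int] = set()
        for i, j in sorted(tree.query_pairs(radius)):
            a, b = tips[i], tips[j]
            # sprouts of one component may close a loop; a vessel never
            # anastomoses with itself, and two sprouts separated by scaffold
            # material cannot touch
            if a.id == b.id:
                continue
            if not _open_path(state.scaffold.grid, a.tip, b.tip):
                continue
            state.network.anastomose(a.id, b.id)
            fused.add(a.id)
            fused.add(b.id)
        for v in tips:
            if v.id in fused:
                v.active = False

    # tip-preformed fusions
    chains = [v for v in living if v.origin == "PREFORMED"]
    if chains:
        pts = []
        owners = []
        for v in chains:
            arr = np.asarray(v.path, dtype=float) * spacing
            pts.append(arr)
            owners.append(np.full(len(arr), v.id))
        all_pts = np.vstack(pts)
        tree = cKDTree(all_pts)
        all_own = np.concatenate(owners)
        for v in tips:
            if not v.active:
                continue
            hits = tree.query_ball_point(np.asarray(v.tip, dtype=float) * spacing, radius)
            for h in hits:
                other = int(all_own[h])
                if state.network.find(other) == state.network.find(v.id):
                    continue
                if not _open_path(state.scaffold.grid, v.tip, all_pts[h] / spacing - 0.0):
                    continue
                state.network.anastomose(v.id, other)
                v.active = False
                break
    return state


def regress(state: SimulationState) -> SimulationState:
    """Retract non-stable vessels whose distal cells lack growth factor.

    Pruning proceeds from the distal (free) end inward, at most the
    per-tick regression budget, and never touches stable vessels — once a
    capillary carries flow it no longer depends on the growth factor.  A
    fully pruned vessel dies and frees its source for later re-sprouting.
    """
    p = state.params
    for v in state.network.living():
        if v.stable:
            continue
        budget = p.regression_budget_um
        while v.path and budget > 0:
            tail = v.path[-1]
            if state.layer_conc[tail[1]] >= p.regression_threshold_ng_per_ml:
                break
            if len(v.path) == 1:
                v.path.pop()
                v.alive = False
                break
            v.path.pop()
            budget -= v.seg_lengths.pop()
        if v.path and v.origin == "PREFORMED":
            # a preformed chain has two free ends; the head dies back at the
            # same rate as the tail while unsupported
            budget = p.regression_budget_um
            while v.path and budget > 0:
                head = v.path[0]
                if state.layer_conc[head[1]] >= p.regression_threshold_ng_per_ml:
                    break
                if len(v.path) == 1:
                    v.path.pop()
                    v.alive = False
                    break
                v.path.pop(0)
                budget -= v.seg_lengths.pop(0)
        if not v.path:
            v.alive = False
    return state


def step(state: SimulationState) -> SimulationState:
    """Advance one tick: field -> activation -> migration -> anastomosis -> regression."""
    state.tick += 1
    _update_layer_conc(state)
    activate_sprouts(state)
    p = state.params
    substeps = max(1, int(round(p.migration_step_um_per_tick / state.scaffold.spacing_um)))
    for v in state.network.vessels:
        if not (v.alive and v.active and not v.stable):
            continue
        before = len(v.path)
        for _ in range(substeps):
            migrate_tip(v, state)
            if len(v.path) == before:  # stalled; further substeps would too
                break
            before = len(v.path)
    check_anastomosis(state)
    regress(state)
    return state


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


def run_simulation(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationState]:
    """Run a multi-week simulation and collect weekly invasion metrics."""
    from .metrics import weekly_metrics

    params = config.params
    params.validate()
    weeks = config.weeks if config.weeks is not None else params.max_sim_weeks
    state = initialize_state(
        config.scaffold, config.field, params, seed=config.seed, preformed=config.preformed
    )
    ticks_per_week = max(1, int(round(HOURS_PER_WEEK / params.tick_h)))
    total_ticks = int(round(weeks * ticks_per_week))
    rows = [dict(week=0.0, **weekly_metrics(state.network, state.scaffold))]
    for k in range(1, total_ticks + 1):
        step(state)
        if k % ticks_per_week == 0:
            rows.append(dict(week=k / ticks_per_week, **weekly_metrics(state.network, state.scaffold)))
    return pd.DataFrame(rows), state


def network_edge_table(network: VesselNetwork, scaffold: VoxelScaffold) -> pd.DataFrame:
    """Flatten the network into a CSV-ready edge list (one row per step)."""
    rows = []
    for v in network.living():
        arr = np.asarray(v.path)
        for k in range(len(v.seg_lengths)):
            rows.append(
                {
                    "vessel_id": v.id,
                    "origin": v.origin,
                    "x0": arr[k, 0], "y0": arr[k, 1], "z0": arr[k, 2],
                    "x1": arr[k + 1, 0], "y1": arr[k + 1, 1], "z1": arr[k + 1, 2],
                    "length_um": v.seg_lengths[k],
                    "anastomosed": v.anastomosed,
                    "stable": v.stable,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "vessel_id", "origin", "x0", "y0", "z0", "x1", "y1", "z1",
            "length_um", "anastomosed", "stable",
        ],
    )


def state_signature(state: SimulationState) -> str:
    """Deterministic digest of the vessel paths (for reproducibility tests)."""
    h = hashlib.sha256()
    for v in state.network.vessels:
        h.update(str((v.id, v.origin, v.alive, v.stable, v.anastomosed)).encode())
        h.update(np.asarray(v.path, dtype=np.int64).tobytes())
    h.update(str(state.tick).encode())
    return h.hexdigest()
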