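"""Voxelized model scaffolds with controlled pore architecture.

Two generators are provided, mirroring the two fabrication routes they
emulate:

* sphere-templated scaffolds (``generate_spherical_scaffold``), in which
  equal-diameter spherical pores are packed so that every pore overlaps its
  anchor pore with a circular throat of prescribed diameter.  The ratio of
  mean throat diameter to mean pore diameter is the normalized pore
  connectivity (NPC), the quantity the generator controls.
* salt-leached scaffolds (``generate_rectangular_scaffold``), in which
  randomly rotated rectangular pores (salt-crystal analogues, 300-500 um)
  are accreted with partial overlap until a target bulk porosity is reached.

The voxel grid is indexed ``grid[ix, iy, iz]``; the y axis is depth from the
host tissue, with the host face at ``iy == 0`` and the growth-factor source
(distal layer) adjacent to the opposite face.  Physical voxel centres sit at
``(index + 0.5) * spacing_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

MATERIAL = 0
PORE = 1
DISTAL_LAYER = 2
LABELS = {"MATERIAL": MATERIAL, "PORE": PORE, "DISTAL_LAYER": DISTAL_LAYER}

__all__ = [
    "MATERIAL",
    "PORE",
    "DISTAL_LAYER",
    "VoxelScaffold",
    "SphericalScaffoldSpec",
    "RectScaffoldSpec",
    "PoreMorphometrics",
    "ScaffoldError",
    "ScaffoldIOError",
    "generate_spherical_scaffold",
    "generate_rectangular_scaffold",
    "compute_morphometrics",
    "write_scaffold",
    "read_scaffold",
]


class ScaffoldError(ValueError):
    """Raised for infeasible scaffold specifications or degenerate inputs."""


class ScaffoldIOError(ValueError):
    """Raised when a scaffold file on disk is malformed."""


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class VoxelScaffold:
    """A 3D labelled voxel grid with physical spacing.

    Parameters
    ----------
    grid
        uint8 array of shape ``(nx, ny, nz)`` with values in
        ``{MATERIAL, PORE, DISTAL_LAYER}``.
    spacing_um
        Edge length of one cubic voxel in micrometres.
    pores
        Generation records (one dict per placed pore); empty for scaffolds
        read from disk or built by hand.
    cylindrical
        If True the usable domain is the inscribed cylinder in the x-z
        cross-section (the experimental scaffolds are 10 mm diameter disks);
        voxels outside the cylinder are ignored by porosity measures.
    """

    grid: np.ndarray
    spacing_um: float
    pores: list = dc_field(default_factory=list)
    cylindrical: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ScaffoldError("scaffold grid must be 3-dimensional")
        bad = set(np.unique(self.grid)) - set(LABELS.values())
        if bad:
            raise ScaffoldError(f"grid contains labels outside the allowed set: {sorted(bad)}")
        if self.spacing_um <= 0:
            raise ScaffoldError("spacing_um must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)

    @property
    def dims_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.spacing_um / 1000.0 for n in self.grid.shape)

    @property
    def height_um(self) -> float:
        """Physical extent along the invasion (y) axis."""
        return self.grid.shape[1] * self.spacing_um

    def domain_mask(self) -> np.ndarray | None:
        """Boolean mask of voxels inside the usable domain (None = all)."""
        if not self.cylindrical:
            return None
        nx, _, nz = self.grid.shape
        radius = min(nx, nz) / 2.0
        ix = np.arange(nx) + 0.5 - nx / 2.0
        iz = np.arange(nz) + 0.5 - nz / 2.0
        disk = ix[:, None] ** 2 + iz[None, :] ** 2 <= radius**2
        return np.broadcast_to(disk[:, None, :], self.grid.shape)

    def n_domain_voxels(self) -> int:
        mask = self.domain_mask()
        return int(self.grid.size if mask is None else mask.sum())

    def pore_mask(self) -> np.ndarray:
        return self.grid == PORE

    def porosity(self) -> float:
        """Pore-voxel fraction of the usable domain."""
        mask = self.domain_mask()
        pores = self.pore_mask() if mask is None else (self.pore_mask() & mask)
        return float(pores.sum()) / self.n_domain_voxels()

    def interface_porosity(self, depth_um: float | None = None) -> float:
        """Pore fraction of the host-face layer (default: one pore diameter)."""
        if depth_um is None:
            diam = [2 * p["radius_um"] for p in self.pores if p.get("kind") == "sphere"]
            depth_um = float(np.mean(diam)) if diam else 2 * self.spacing_um
        n_layers = max(1, int(round(depth_um / self.spacing_um)))
        sub = self.grid[:, :n_layers, :]
        mask = self.domain_mask()
        if mask is None:
            return float((sub == PORE).sum()) / sub.size
        sub_mask = mask[:, :n_layers, :]
        return float(((sub == PORE) & sub_mask).sum()) / sub_mask.sum()

    def host_face_pore_voxels(self) -> np.ndarray:
        """(k, 3) voxel indices of pore voxels on the host face (iy = 0)."""
        face = self.grid[:, 0, :] == PORE
        mask = self.domain_mask()
        if mask is not None:
            face &= mask[:, 0, :]
        ix, iz = np.nonzero(face)
        return np.column_stack([ix, np.zeros_like(ix), iz])


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class SphericalScaffoldSpec:
    """Parameters for the sphere-templated generator.

    ``target_npc`` fixes the centre distance between an anchored pore pair at
    ``d * sqrt(1 - NPC^2)`` (d = pore diameter), which makes the circular
    intersection of the two spheres exactly ``NPC * d`` wide.
    """

    pore_diameter_um: float = 115.0
    target_npc: float = 0.45
    dims_mm: tuple[float, float, float] = (1.0, 4.0, 1.0)
    spacing_um: float = 10.0
    seed: int | None = None
    cylindrical: bool = False
    max_consecutive_failures: int = 500

    def validate(self) -> None:
        if not 0.0 < self.target_npc < 1.0:
            raise ScaffoldError("target_npc must lie in (0, 1)")
        if self.pore_diameter_um < 2 * self.spacing_um:
            raise ScaffoldError("pore_diameter_um must be at least 2 voxels")
        if min(self.dims_mm) <= 0 or self.spacing_um <= 0:
            raise ScaffoldError("dims_mm and spacing_um must be positive")
        if self.pore_diameter_um > min(self.dims_mm) * 1000.0:
            raise ScaffoldError(
                "infeasible spec: pore diameter "
                f"{self.pore_diameter_um} um exceeds the smallest domain edge"
            )


@dataclass
class RectScaffoldSpec:
    """Parameters for the salt-leached (rectangular-pore) generator."""

    pore_size_range_um: tuple[float, float] = (300.0, 500.0)
    target_porosity: float = 0.644
    rotation_step_deg: float = 10.0
    dims_mm: tuple[float, float, float] = (2.0, 4.0, 2.0)
    spacing_um: float = 20.0
    seed: int | None = None
    cylindrical: bool = False
    max_overlap_fraction: float = 0.5
    max_attempts: int = 200_000

    def validate(self) -> None:
        lo, hi = self.pore_size_range_um
        if not 0 < lo <= hi:
            raise ScaffoldError("pore_size_range_um must satisfy 0 < min <= max")
        if not 0.0 <= self.target_porosity < 1.0:
            raise ScaffoldError("target_porosity must lie in [0, 1)")
        if self.rotation_step_deg <= 0 or 360.0 % self.rotation_step_deg != 0:
            raise ScaffoldError("rotation_step_deg must divide 360")
        if min(self.dims_mm) <= 0 or self.spacing_um <= 0:
            raise ScaffoldError("dims_mm and spacing_um must be positive")


@dataclass
class PoreMorphometrics:
    mean_pore_diameter_um: float
    mean_throat_diameter_um: float
    npc: float
    bulk_porosity: float
    interface_porosity: float
    n_pores: int = 0
    n_throats: int = 0


# ---------------------------------------------------------------------------
# voxelization helpers
# ---------------------------------------------------------------------------


def _carve_sphere(grid: np.ndarray, spacing: float, center_um: np.ndarray, r_um: float) -> None:
    lo = np.maximum(0, ((center_um - r_um) / spacing - 1).astype(int))
    hi = np.minimum(grid.shape, ((center_um + r_um) / spacing + 2).astype(int))
    ax = [(np.arange(lo[i], hi[i]) + 0.5) * spacing - center_um[i] for i in range(3)]
    d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    sub = grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[d2 <= r_um**2] = PORE


def _rect_inside(
    shape: tuple[int, int, int],
    spacing: float,
    center_um: np.ndarray,
    edges_um: np.ndarray,
    angles_deg: np.ndarray,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Boolean voxel mask (within a bounding box) of a rotated cuboid."""
    bound = float(np.linalg.norm(edges_um / 2.0))
    lo = np.maximum(0, ((center_um - bound) / spacing - 1).astype(int))
    hi = np.minimum(shape, ((center_um + bound) / spacing + 2).astype(int))
    if np.any(lo >= hi):
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        return sl, np.zeros(tuple(np.maximum(hi - lo, 0)), dtype=bool)
    ax = [(np.arange(lo[i], hi[i]) + 0.5) * spacing - center_um[i] for i in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    rot = Rotation.from_euler("xyz", angles_deg, degrees=True)
    local = pts.reshape(-1, 3) @ rot.as_matrix()  # inverse rotation of offsets
    half = edges_um / 2.0
    inside = np.all(np.abs(local) <= half, axis=1).reshape(xx.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return sl, inside


def _snap_to_pair(a: np.ndarray, b: np.ndarray, c: float, p: np.ndarray) -> np.ndarray | None:
    """Project ``p`` onto the circle of points at distance ``c`` from both
    ``a`` and ``b`` (None when the two constraint spheres do not meet)."""
    ab = b - a
    dab = float(np.linalg.norm(ab))
    if dab < 1e-9 or dab > 2.0 * c:
        return None
    axis = ab / dab
    mid = (a + b) / 2.0
    rho = np.sqrt(c**2 - (dab / 2.0) ** 2)
    v = p - mid
    v_perp = v - np.dot(v, axis) * axis
    norm = float(np.linalg.norm(v_perp))
    if norm < 1e-9:
        ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v_perp = np.cross(axis, ref)
        norm = float(np.linalg.norm(v_perp))
    return mid + rho * v_perp / norm


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - vanishing probability
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_spherical_scaffold(spec: SphericalScaffoldSpec) -> VoxelScaffold:
    """Pack equal spherical pores with throats of prescribed NPC.

    Placement starts from one random pore.  Each subsequent candidate is an
    existing pore centre displaced by ``c = d * sqrt(1 - NPC^2)`` in a random
    direction; it is accepted if it lies inside the domain and every other
    existing pore is at least one pore diameter away (so the only throat the
    new pore forms is the anchored one, at exactly the target NPC).
    Placement terminates after ``max_consecutive_failures`` rejected
    candidates in a row, i.e. when no admissible location can be found.
    """
    spec.validate()
    spacing = spec.spacing_um
    dims_um = np.asarray(spec.dims_mm, dtype=float) * 1000.0
    shape = np.maximum(1, np.round(dims_um / spacing).astype(int))
    rng = np.random.default_rng(spec.seed)
    r = spec.pore_diameter_um / 2.0
    d = spec.pore_diameter_um
    c_dist = d * np.sqrt(1.0 - spec.target_npc**2)

    # pores may cut through the host face (y = 0), opening the interface to
    # the host vasculature; the lateral walls and the distal face stay solid
    lo_b = np.array([r, 0.0, r])
    hi_b = dims_um - r
    if np.any(lo_b > hi_b):
        raise ScaffoldError("infeasible spec: domain cannot contain a single pore")

    if spec.cylindrical:
        cx = dims_um[0] / 2.0
        cz = dims_um[2] / 2.0
        rad = min(dims_um[0], dims_um[2]) / 2.0 - r

        def in_domain(p: np.ndarray) -> bool:
            return bool(
                np.all(p >= lo_b)
                and np.all(p <= hi_b)
                and (p[0] - cx) ** 2 + (p[2] - cz) ** 2 <= rad**2
            )

    else:

        def in_domain(p: np.ndarray) -> bool:
            return bool(np.all(p >= lo_b) and np.all(p <= hi_b))

    first = None
    for _ in range(1000):
        cand = rng.uniform(lo_b, hi_b)
        if in_domain(cand):
            first = cand
            break
    if first is None:
        raise ScaffoldError("could not place a single pore in the domain")

    sphere_vol = 4.0 / 3.0 * np.pi * r**3
    max_pores = int(2.0 * np.prod(dims_um) / sphere_vol) + 8
    centers = np.empty((max_pores, 3))
    centers[0] = first
    n = 1
    failures = 0
    tol = 1e-6

    def conflicts(cand: np.ndarray) -> np.ndarray:
        dist = np.linalg.norm(centers[:n] - cand, axis=1)
        return np.nonzero((dist < d - 1e-9) & (np.abs(dist - c_dist) > tol))[0]

    while failures < spec.max_consecutive_failures and n < max_pores:
        anchor = centers[rng.integers(n)]
        cand = anchor + c_dist * _random_unit(rng)
        bad = conflicts(cand)
        if len(bad) > 0:
            # the candidate overlaps another pore at an off-target distance;
            # snap it onto the locus at exactly c from both that pore and
            # the anchor, so every throat it forms has the target NPC
            other = centers[bad[0]]
            snapped = _snap_to_pair(anchor, other, c_dist, cand)
            if snapped is None:
                failures += 1
                continue
            cand = snapped
            if len(conflicts(cand)) > 0:
                failures += 1
                continue
        if not in_domain(cand):
            failures += 1
            continue
        centers[n] = cand
        n += 1
        failures = 0

    grid = np.full(tuple(shape), MATERIAL, dtype=np.uint8)
    records = []
    for k in range(n):
        _carve_sphere(grid, spacing, centers[k], r)
        records.append({"kind": "sphere", "center_um": centers[k].tolist(), "radius_um": r})
    return VoxelScaffold(grid, spacing, pores=records, cylindrical=spec.cylindrical)


def generate_rectangular_scaffold(spec: RectScaffoldSpec) -> VoxelScaffold:
    """Accrete randomly rotated rectangular pores until the target porosity.

    Each pore's three edge lengths are drawn uniformly from the pore-size
    range and its orientation from independent multiples of the rotation
    step on all three axes.  After the first pore, candidate centres are
    offsets of an existing pore; a candidate is accepted when its voxel
    overlap fraction with the existing pore phase lies in ``overlap_range``
    (neighbouring pores must touch but not be swallowed).  Placement stops
    at the first crossing of the target porosity.
    """
    spec.validate()
    spacing = spec.spacing_um
    dims_um = np.asarray(spec.dims_mm, dtype=float) * 1000.0
    shape = tuple(np.maximum(1, np.round(dims_um / spacing).astype(int)))
    grid = np.full(shape, MATERIAL, dtype=np.uint8)
    scaffold = VoxelScaffold(grid, spacing, pores=[], cylindrical=spec.cylindrical)
    if spec.target_porosity == 0.0:
        return scaffold

    rng = np.random.default_rng(spec.seed)
    mask = scaffold.domain_mask()
    n_domain = scaffold.n_domain_voxels()
    target_count = spec.target_porosity * n_domain

    pore_count = 0
    attempts = 0
    while pore_count < target_count:
        attempts += 1
        if attempts > spec.max_attempts:
            raise ScaffoldError(
                "target porosity unreachable: achieved "
                f"{pore_count / n_domain:.4f} of {spec.target_porosity:.4f} "
                f"after {spec.max_attempts} attempts"
            )
        center = rng.uniform(0, dims_um)
        edges = rng.uniform(*spec.pore_size_range_um, size=3)
        angles = (
            rng.integers(0, int(360 / spec.rotation_step_deg), size=3) * spec.rotation_step_deg
        ).astype(float)
        sl, inside = _rect_inside(shape, spacing, center, edges, angles)
        if mask is not None:
            inside = inside & mask[sl]
        n_inside = int(inside.sum())
        if n_inside == 0:
            continue
        sub = grid[sl]
        n_overlap = int((inside & (sub == PORE)).sum())
        # neighbouring pores may overlap freely below a redundancy cap;
        # pore-to-pore interconnectivity is not controlled here
        if scaffold.pores and n_overlap / n_inside > spec.max_overlap_fraction:
            continue
        sub[inside] = PORE
        pore_count += n_inside - n_overlap
        scaffold.pores.append(
            {
                "kind": "rect",
                "center_um": center.tolist(),
                "edges_um": edges.tolist(),
                "angles_deg": angles.tolist(),
            }
        )
    return scaffold


# ---------------------------------------------------------------------------
# morphometrics
# ---------------------------------------------------------------------------


def _adjacent_pairs(label_grid: np.ndarray) -> set[tuple[int, int]]:
    """Label pairs of pore regions that share 6-connected voxel faces."""
    pairs: set[tuple[int, int]] = set()
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a = label_grid[tuple(sl_a)]
        b = label_grid[tuple(sl_b)]
        touching = (a >= 0) & (b >= 0) & (a != b)
        if not touching.any():
            continue
        keys = np.sort(np.column_stack([a[touching], b[touching]]), axis=1)
        pairs.update((int(i), int(j)) for i, j in np.unique(keys, axis=0))
    return pairs


def _throat_min_area_diameter(
    grid: np.ndarray,
    spacing: float,
    c1: np.ndarray,
    c2: np.ndarray,
    r1: float,
    r2: float,
    subsample: int = 2,
) -> float:
    """Throat diameter of one adjacent pore pair, measured on the grid.

    Cross-section planes perpendicular to the centre axis are swept through
    the overlap region of the two (approximately spherical) pores; each
    plane is sampled at sub-voxel resolution, counting sample points whose
    containing voxel is pore and which lie inside either pore envelope
    (excluding unrelated pore space).  The throat is the equivalent-circle
    diameter of the minimal cross-section area.
    """
    d = float(np.linalg.norm(c2 - c1))
    if d == 0.0:
        return 0.0
    u = (c2 - c1) / d
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    step = spacing / subsample
    s_lo, s_hi = d - r2, r1  # axial extent of the overlap region from c1
    if s_hi < s_lo:
        return 0.0
    planes = np.arange(s_lo, s_hi + 1e-9, step / 2.0)
    if len(planes) == 0:
        planes = np.array([(s_lo + s_hi) / 2.0])
    best = np.inf
    margin = 0.0  # exact envelope: clips voxelization overhang at the rim
    for s in planes:
        chord1 = max(0.0, r1**2 - s**2)
        chord2 = max(0.0, r2**2 - (d - s) ** 2)
        rho_max = np.sqrt(max(chord1, chord2))
        if rho_max <= 0:
            continue
        ab = np.arange(-rho_max, rho_max + 1e-9, step)
        aa, bb = np.meshgrid(ab, ab, indexing="ij")
        keep = aa**2 + bb**2 <= rho_max**2
        aa = aa[keep]
        bb = bb[keep]
        pts = c1 + s * u + aa[:, None] * e1 + bb[:, None] * e2
        in_pair = (np.einsum("ij,ij->i", pts - c1, pts - c1) <= (r1 + margin) ** 2) | (
            np.einsum("ij,ij->i", pts - c2, pts - c2) <= (r2 + margin) ** 2
        )
        pts = pts[in_pair]
        idx = np.floor(pts / spacing).astype(int)
        ok = np.all(idx >= 0, axis=1) & np.all(idx < grid.shape, axis=1)
        idx = idx[ok]
        count = int((grid[idx[:, 0], idx[:, 1], idx[:, 2]] == PORE).sum())
        best = min(best, count * step * step)
    if not np.isfinite(best):
        return 0.0
    return float(2.0 * np.sqrt(best / np.pi))


def _throat_diameters(
    scaffold: VoxelScaffold,
    label_grid: np.ndarray,
    centers_um: np.ndarray,
    radii_um: np.ndarray,
) -> dict[tuple[int, int], float]:
    """Measured throat diameter for every face-adjacent pore pair."""
    out = {}
    for i, j in _adjacent_pairs(label_grid):
        dia = _throat_min_area_diameter(
            scaffold.grid,
            scaffold.spacing_um,
            np.asarray(centers_um[i], dtype=float),
            np.asarray(centers_um[j], dtype=float),
            float(radii_um[i]),
            float(radii_um[j]),
        )
        if dia > 0:
            out[(i, j)] = dia
    return out


def _labels_from_records(scaffold: VoxelScaffold) -> tuple[np.ndarray, np.ndarray]:
    """Assign each pore voxel to its nearest generation-record centre."""
    centers = np.asarray([p["center_um"] for p in scaffold.pores])
    idx = np.argwhere(scaffold.pore_mask())
    pts = (idx + 0.5) * scaffold.spacing_um
    tree = cKDTree(centers)
    _, lbl = tree.query(pts, workers=-1)
    label_grid = np.full(scaffold.grid.shape, -1, dtype=np.int32)
    label_grid[tuple(idx.T)] = lbl
    return label_grid, centers


def _labels_from_watershed(
    scaffold: VoxelScaffold, min_pore_separation_um: float
) -> np.ndarray:
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    pm = scaffold.pore_mask()
    dist = ndimage.distance_transform_edt(pm, sampling=scaffold.spacing_um)
    min_dist = max(1, int(round(min_pore_separation_um / scaffold.spacing_um)))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=pm, exclude_border=False)
    markers = np.zeros(pm.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    ws = watershed(-dist, markers, mask=pm)
    return ws.astype(np.int32) - 1  # background/material -> -1


def _measured_sphere_diameters(scaffold: VoxelScaffold) -> np.ndarray:
    """Equivalent-sphere diameter of each recorded pore from its voxel count.

    Pores clipped by a domain face (e.g. cut open at the host interface)
    would bias the mean diameter low and are excluded when any unclipped
    pore exists.
    """
    spacing = scaffold.spacing_um
    dims_um = np.asarray(scaffold.grid.shape) * spacing
    interior = []
    for rec in scaffold.pores:
        center = np.asarray(rec["center_um"])
        r = rec["radius_um"]
        interior.append(bool(np.all(center - r >= -1e-9) and np.all(center + r <= dims_um + 1e-9)))
    use = [rec for rec, ok in zip(scaffold.pores, interior) if ok] or scaffold.pores
    diams = []
    for rec in use:
        center = np.asarray(rec["center_um"])
        r = rec["radius_um"]
        lo = np.maximum(0, ((center - r) / spacing - 1).astype(int))
        hi = np.minimum(scaffold.grid.shape, ((center + r) / spacing + 2).astype(int))
        ax = [(np.arange(lo[i], hi[i]) + 0.5) * spacing - center[i] for i in range(3)]
        d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        count = int((d2 <= r**2).sum())
        vol = count * spacing**3
        diams.append(2.0 * (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))
    return np.asarray(diams)


def compute_morphometrics(
    scaffold: VoxelScaffold,
    interface_depth_um: float | None = None,
    min_pore_separation_um: float = 50.0,
) -> PoreMorphometrics:
    """Measure pore morphometrics of a voxel scaffold.

    Pores are identified from generation records when available (nearest
    recorded centre, which for equal overlapping spheres is the bisector
    plane through the throat), otherwise by watershed segmentation of the
    pore phase on the Euclidean distance transform.  Throats are measured on
    the voxel grid as the openings between adjacent pore regions; NPC is the
    mean throat diameter over the mean pore diameter.  For rectangular-pore
    scaffolds interconnectivity is not controlled and the throat/NPC fields
    are reported as NaN.
    """
    if not scaffold.pore_mask().any():
        raise ScaffoldError("scaffold contains no pores")
    bulk = scaffold.porosity()
    interface = scaffold.interface_porosity(interface_depth_um)

    kinds = {p.get("kind") for p in scaffold.pores}
    if kinds == {"sphere"}:
        label_grid, centers = _labels_from_records(scaffold)
        diams = _measured_sphere_diameters(scaffold)
        radii = np.asarray([p["radius_um"] for p in scaffold.pores], dtype=float)
        throats = _throat_diameters(scaffold, label_grid, centers, radii)
        mean_d = float(diams.mean())
        if throats:
            mean_t = float(np.mean(list(throats.values())))
            npc = mean_t / mean_d
        else:
            mean_t = float("nan")
            npc = float("nan")
        return PoreMorphometrics(mean_d, mean_t, npc, bulk, interface, len(diams), len(throats))
    if kinds == {"rect"}:
        vols = []
        for rec in scaffold.pores:
            e = np.asarray(rec["edges_um"])
            vols.append(float(np.prod(e)))
        diams_arr = 2.0 * (3.0 * np.asarray(vols) / (4.0 * np.pi)) ** (1.0 / 3.0)
        return PoreMorphometrics(
            float(diams_arr.mean()), float("nan"), float("nan"), bulk, interface,
            len(vols), 0,
        )

    # no records: segment the pore phase
    label_grid = _labels_from_watershed(scaffold, min_pore_separation_um)
    labels, counts = np.unique(label_grid[label_grid >= 0], return_counts=True)
    vols = counts * scaffold.spacing_um**3
    diams = 2.0 * (3.0 * vols / (4.0 * np.pi)) ** (1.0 / 3.0)
    centroids = np.asarray(
        ndimage.center_of_mass(label_grid >= 0, label_grid, labels)
    )
    centers = np.zeros((int(labels.max()) + 1, 3))
    centers[labels] = (centroids + 0.5) * scaffold.spacing_um
    radii = np.zeros(int(labels.max()) + 1)
    # equivalent-sphere radii undershoot the true envelope where pores
    # overlap heavily (the watershed splits shared volume); inflate slightly
    radii[labels] = 1.1 * diams / 2.0
    throats = _throat_diameters(scaffold, label_grid, centers, radii)
    mean_d = float(diams.mean())
    mean_t = float(np.mean(list(throats.values()))) if throats else float("nan")
    npc = mean_t / mean_d if throats else float("nan")
    return PoreMorphometrics(mean_d, mean_t, npc, bulk, interface, len(labels), len(throats))


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF image stack + JSON sidecar
# ---------------------------------------------------------------------------


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in {".tif", ".tiff", ".json"}:
        p = p.with_suffix("")
    return p.with_suffix(".tif"), p.with_suffix(".json")


def write_scaffold(scaffold: VoxelScaffold, path: str | Path) -> None:
    """Write the grid as a multi-page TIFF (pages along y) + JSON sidecar."""
    import tifffile

    tif, sidecar = _paths(path)
    tifffile.imwrite(tif, scaffold.grid.transpose(1, 0, 2).astype(np.uint8))
    meta = {
        "spacing_um": scaffold.spacing_um,
        "dims_mm": list(scaffold.dims_mm),
        "labels": LABELS,
        "cylindrical": scaffold.cylindrical,
        "pores": scaffold.pores,
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def read_scaffold(path: str | Path) -> VoxelScaffold:
    import tifffile

    tif, sidecar = _paths(path)
    if not tif.exists() or not sidecar.exists():
        raise ScaffoldIOError(f"missing scaffold file(s): {tif} / {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ScaffoldIOError(f"malformed sidecar {sidecar}: {exc}") from exc
    if "spacing_um" not in meta:
        raise ScaffoldIOError("sidecar is missing required field 'spacing_um'")
    pages = tifffile.imread(tif)
    if pages.ndim == 2:
        pages = pages[None]
    grid = np.asarray(pages).transpose(1, 0, 2)
    scaffold = VoxelScaffold(
        grid.astype(np.uint8),
        float(meta["spacing_um"]),
        pores=meta.get("pores", []),
        cylindrical=bool(meta.get("cylindrical", False)),
    )
    dims = meta.get("dims_mm")
    if dims is not None:
        if np.max(np.abs(np.asarray(dims) - np.asarray(scaffold.dims_mm))) > scaffold.spacing_um / 1000.0:
            raise ScaffoldIOError("sidecar field 'dims_mm' is inconsistent with the image stack")
    return scaffold
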