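"""Invasion morphometrics of a simulated vessel network.

Normalized vessel invasion is the deepest vessel penetration from the host
face divided by the scaffold height, averaged over three equal vertical
slabs of the scaffold (sliced along x, perpendicular to the invasion axis).
Normalized anastomosed invasion is the same quantity restricted to vessels
that are anastomosed and stable, i.e. assumed to carry blood flow.  Total
capillary length sums the length contribution of every living endothelial
cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abm_core import Vessel, VesselNetwork
from .scaffold_gen import VoxelScaffold

__all__ = [
    "normalized_invasion",
    "normalized_anastomosed_invasion",
    "total_length",
    "weekly_metrics",
    "summarize_replicates",
]


def _slab_depths(
    vessels: list[Vessel], scaffold: VoxelScaffold, n_slabs: int
) -> np.ndarray:
    """Deepest vessel y-extent (um, far voxel edge) per vertical slab."""
    nx = scaffold.grid.shape[0]
    edges = np.linspace(0, nx, n_slabs + 1)
    depths = np.zeros(n_slabs)
    for v in vessels:
        if not (v.alive and v.path):
            continue
        arr = np.asarray(v.path)
        slab = np.clip(np.searchsorted(edges, arr[:, 0], side="right") - 1, 0, n_slabs - 1)
        reach = (arr[:, 1] + 1) * scaffold.spacing_um
        np.maximum.at(depths, slab, reach)
    return depths


def normalized_invasion(
    network: VesselNetwork, scaffold: VoxelScaffold, n_slabs: int = 3
) -> float:
    """Mean over vertical slabs of deepest vessel reach / scaffold height."""
    depths = _slab_depths(network.living(), scaffold, n_slabs)
    return float(np.clip(depths / scaffold.height_um, 0.0, 1.0).mean())


def normalized_anastomosed_invasion(
    network: VesselNetwork, scaffold: VoxelScaffold, n_slabs: int = 3
) -> float:
    """As :func:`normalized_invasion`, but only anastomosed stable vessels."""
    stable = [v for v in network.living() if v.stable and v.anastomosed]
    depths = _slab_depths(stable, scaffold, n_slabs)
    return float(np.clip(depths / scaffold.height_um, 0.0, 1.0).mean())


def total_length(network: VesselNetwork) -> float:
    """Total capillary length (um) over all living cells."""
    return network.total_length_um()


def weekly_metrics(network: VesselNetwork, scaffold: VoxelScaffold) -> dict:
    inv = normalized_invasion(network, scaffold)
    ana = normalized_anastomosed_invasion(network, scaffold)
    assert ana <= inv + 1e-12, "anastomosed invasion exceeded total invasion"
    return {
        "normalized_invasion": inv,
        "normalized_anastomosed_invasion": ana,
        "total_length_um": total_length(network),
    }


def summarize_replicates(series: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and sample standard deviation (n-1) per week.

    ``series`` is the long-format metrics table with a ``replicate`` column.
    With a single replicate the SD is undefined; it is reported as 0 with
    ``sd_defined = False``.
    """
    if "replicate" not in series.columns:
        raise ValueError("series must carry a 'replicate' column")
    if series.empty:
        raise ValueError("no replicate rows to summarize")
    metric_cols = [
        c for c in ("normalized_invasion", "normalized_anastomosed_invasion", "total_length_um")
        if c in series.columns
    ]
    grouped = series.groupby("week")
    out = []
    for week, g in grouped:
        n = g["replicate"].nunique()
        row: dict = {"week": week, "n": n, "sd_defined": n > 1}
        for c in metric_cols:
            row[f"{c}_mean"] = float(g[c].mean())
            row[f"{c}_sd"] = float(g[c].std(ddof=1)) if n > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
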