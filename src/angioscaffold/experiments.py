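"""Predefined in-silico studies run end to end.

Four studies are packaged, each returning the long-format weekly metrics
table per replicate plus the replicate mean +- SD summary:

* ``run_interconnectivity`` — sphere-templated scaffolds at low (0.25) and
  high (0.45) normalized pore connectivity under a growth-factor gradient.
* ``run_gf_dose`` — salt-leached scaffolds (64.4% porosity, 300-500 um
  pores) at 2, 20 and 200 ng total dose.
* ``run_release_rate`` — the 200 ng dose released at the reference rate
  (Case A) and 20%-500% slower (Cases B-F), dose conserved.
* ``run_prevascularization`` — high-connectivity scaffolds with no, full,
  top-half or bottom-half preformed capillary networks under the same
  high-dose gradient as the interconnectivity study.

The default problem sizes are scaled-down versions of the experimental
implants: the salt-leached studies keep the full 4 mm height (the invasion
axis) with the x-z cross-section reduced to 1.4 mm; the sphere-templated
hydrogel studies use a 1.6 mm-tall, 1 mm-wide domain (those implants are
thin slabs, much shorter than the salt-leached constructs).  Invasion
metrics are normalized depths along y.  Replicates default to n = 5.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .abm_core import RuleParams, SimulationConfig, run_simulation
from .gf_transport import (
    ConcentrationField,
    DiffusionParams,
    ReleaseCase,
    rescale_release,
    solve_diffusion_1d,
    synth_release_curve,
)
from .metrics import summarize_replicates
from .prevascular import PrevascSpec, seed_network
from .scaffold_gen import (
    RectScaffoldSpec,
    SphericalScaffoldSpec,
    generate_rectangular_scaffold,
    generate_spherical_scaffold,
)

__all__ = [
    "ExperimentSpec",
    "build_release_field",
    "run_interconnectivity",
    "run_gf_dose",
    "run_release_rate",
    "run_prevascularization",
    "run_experiment",
    "EXPERIMENT_NAMES",
]

EXPERIMENT_NAMES = ("interconnectivity", "gf_dose", "release_rate", "prevascularization")

# default scaled-down study geometries
SPHERE_DIMS_MM = (1.0, 1.6, 1.0)
SPHERE_SPACING_UM = 12.5
RECT_DIMS_MM = (1.4, 4.0, 1.4)
RECT_SPACING_UM = 20.0


@dataclass
class ExperimentSpec:
    name: str
    replicates: int = 5
    seed: int = 0
    output_dir: str | Path | None = None
    weeks: float = 6.0
    params: RuleParams = dc_field(default_factory=RuleParams)

    def validate(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}; expected one of {EXPERIMENT_NAMES}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _child_seed(seed: int, *key: int) -> int:
    """Derive a deterministic 31-bit child seed for one replicate/stage."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_release_field(
    dose_ng: float = 200.0,
    case: str | ReleaseCase = "A",
    weeks: float = 6.0,
    height_mm: float = 4.0,
    diffusion: DiffusionParams | None = None,
    **release_kwargs,
) -> ConcentrationField:
    """Synthetic release curve -> (optionally slower) case -> 1D field.

    ``height_mm`` is the scaffold height; the distal release layer sits on
    its top face, so the diffusion domain must match the scaffold.
    """
    if isinstance(case, str):
        case = ReleaseCase.from_label(case)
    diffusion = diffusion or DiffusionParams(height_mm=height_mm)
    profile = synth_release_curve(dose_ng=dose_ng, height_mm=height_mm, **release_kwargs)
    profile = rescale_release(profile, case)
    t_end = weeks * 168.0
    return solve_diffusion_1d(profile, diffusion, t_end_h=t_end, output_dt_h=2.0)


def _run_batch(
    scaffolds: list,
    field: ConcentrationField | None,
    params: RuleParams,
    weeks: float,
    seed: int,
    stage: int,
    preformed_builder=None,
) -> pd.DataFrame:
    rows = []
    for rep, scaffold in enumerate(scaffolds):
        preformed = preformed_builder(rep, scaffold) if preformed_builder else None
        cfg = SimulationConfig(
            scaffold=scaffold,
            field=field,
            params=params,
            weeks=weeks,
            seed=_child_seed(seed, stage, rep, 2),
            preformed=preformed,
        )
        df, _ = run_simulation(cfg)
        df["replicate"] = rep
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _write_outputs(output_dir, name: str, tables: dict[str, pd.DataFrame], config: dict) -> None:
    if output_dir is None:
        return
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    config = dict(config, config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16])
    (out / f"{name}_config.json").write_text(json.dumps(config, indent=1, default=str))
    for key, df in tables.items():
        df.to_csv(out / f"{name}_{key}.csv", index=False)


def _spherical_batch(npc: float, replicates: int, seed: int, stage: int) -> list:
    scaffolds = []
    for rep in range(replicates):
        spec = SphericalScaffoldSpec(
            target_npc=npc,
            dims_mm=SPHERE_DIMS_MM,
            spacing_um=SPHERE_SPACING_UM,
            seed=_child_seed(seed, stage, rep, 1),
        )
        scaffolds.append(generate_spherical_scaffold(spec))
    return scaffolds


def run_interconnectivity(
    replicates: int = 5,
    seed: int = 0,
    output_dir=None,
    weeks: float = 6.0,
    params: RuleParams | None = None,
    npcs: tuple[float, ...] = (0.25, 0.45),
    dose_ng: float = 600.0,
) -> dict:
    """Low- vs high-connectivity sphere-templated scaffolds, 6-week runs."""
    params = params or RuleParams()
    field = build_release_field(dose_ng=dose_ng, case="A", weeks=weeks, height_mm=SPHERE_DIMS_MM[1])
    metrics = []
    for i, npc in enumerate(npcs):
        scaffolds = _spherical_batch(npc, replicates, seed, stage=i)
        df = _run_batch(scaffolds, field, params, weeks, seed, stage=i)
        df["npc"] = npc
        metrics.append(df)
    metrics_df = pd.concat(metrics, ignore_index=True)
    summary = pd.concat(
        [
            summarize_replicates(g).assign(npc=npc)
            for npc, g in metrics_df.groupby("npc")
        ],
        ignore_index=True,
    )
    config = {"experiment": "interconnectivity", "replicates": replicates, "seed": seed,
              "weeks": weeks, "npcs": list(npcs), "dose_ng": dose_ng, "params": asdict(params)}
    _write_outputs(output_dir, "interconnectivity", {"metrics": metrics_df, "summary": summary}, config)
    return {"metrics": metrics_df, "summary": summary}


def run_gf_dose(
    replicates: int = 5,
    seed: int = 0,
    output_dir=None,
    weeks: float = 6.0,
    params: RuleParams | None = None,
    doses_ng: tuple[float, ...] = (2.0, 20.0, 200.0),
) -> dict:
    """Salt-leached scaffolds under three total growth-factor doses."""
    params = params or RuleParams()
    metrics = []
    for i, dose in enumerate(doses_ng):
        field = build_release_field(dose_ng=dose, case="A", weeks=weeks) if dose > 0 else None
        scaffolds = []
        for rep in range(replicates):
            spec = RectScaffoldSpec(
                dims_mm=RECT_DIMS_MM,
                spacing_um=RECT_SPACING_UM,
                seed=_child_seed(seed, i, rep, 1),
            )
            scaffolds.append(generate_rectangular_scaffold(spec))
        df = _run_batch(scaffolds, field, params, weeks, seed, stage=i)
        df["dose_ng"] = dose
        metrics.append(df)
    metrics_df = pd.concat(metrics, ignore_index=True)
    summary = pd.concat(
        [summarize_replicates(g).assign(dose_ng=d) for d, g in metrics_df.groupby("dose_ng")],
        ignore_index=True,
    )
    config = {"experiment": "gf_dose", "replicates": replicates, "seed": seed,
              "weeks": weeks, "doses_ng": list(doses_ng), "params": asdict(params)}
    _write_outputs(output_dir, "gf_dose", {"metrics": metrics_df, "summary": summary}, config)
    return {"metrics": metrics_df, "summary": summary}


def run_release_rate(
    replicates: int = 5,
    seed: int = 0,
    output_dir=None,
    weeks: float = 6.0,
    params: RuleParams | None = None,
    cases: str = "ABCDEF",
    dose_ng: float = 200.0,
) -> dict:
    """Dose-conserving slower-release cases in salt-leached scaffolds."""
    params = params or RuleParams()
    scaffolds = []
    for rep in range(replicates):
        spec = RectScaffoldSpec(
            dims_mm=RECT_DIMS_MM,
            spacing_um=RECT_SPACING_UM,
            seed=_child_seed(seed, 0, rep, 1),
        )
        scaffolds.append(generate_rectangular_scaffold(spec))
    metrics = []
    for i, label in enumerate(cases):
        field = build_release_field(dose_ng=dose_ng, case=label, weeks=weeks)
        df = _run_batch(scaffolds, field, params, weeks, seed, stage=i)
        df["case"] = label
        metrics.append(df)
    metrics_df = pd.concat(metrics, ignore_index=True)
    summary = pd.concat(
        [summarize_replicates(g).assign(case=c) for c, g in metrics_df.groupby("case")],
        ignore_index=True,
    )
    config = {"experiment": "release_rate", "replicates": replicates, "seed": seed,
              "weeks": weeks, "cases": cases, "dose_ng": dose_ng, "params": asdict(params)}
    _write_outputs(output_dir, "release_rate", {"metrics": metrics_df, "summary": summary}, config)
    return {"metrics": metrics_df, "summary": summary}


PREVASC_CONFIGS = {"none": "NONE", "full": "FULL", "top": "TOP_HALF", "bottom": "BOTTOM_HALF"}


def run_prevascularization(
    replicates: int = 5,
    seed: int = 0,
    output_dir=None,
    weeks: float = 6.0,
    params: RuleParams | None = None,
    configs: tuple[str, ...] = ("none", "full", "top", "bottom"),
    npc: float = 0.45,
    dose_ng: float = 600.0,
    n_seeds: int = 90,
) -> dict:
    """Preformed capillary networks in high-connectivity scaffolds.

    The same replicate scaffold is reused across configurations so that the
    comparison between prevascularization modes is paired.
    """
    params = params or RuleParams()
    field = build_release_field(dose_ng=dose_ng, case="A", weeks=weeks, height_mm=SPHERE_DIMS_MM[1])
    scaffolds = _spherical_batch(npc, replicates, seed, stage=0)
    metrics = []
    for i, cfg_name in enumerate(configs):
        region = PREVASC_CONFIGS[cfg_name]

        def builder(rep, scaffold, _region=region, _i=i):
            if _region == "NONE":
                return None
            # the same chain density everywhere: half regions get half the seeds
            n = n_seeds if _region == "FULL" else n_seeds // 2
            spec = PrevascSpec(
                region=_region, n_seeds=n, seed=_child_seed(seed, _i, rep, 3)
            )
            return seed_network(scaffold, spec)

        df = _run_batch(
            scaffolds, field, params, weeks, seed, stage=i, preformed_builder=builder
        )
        df["config"] = cfg_name
        metrics.append(df)
    metrics_df = pd.concat(metrics, ignore_index=True)
    summary = pd.concat(
        [summarize_replicates(g).assign(config=c) for c, g in metrics_df.groupby("config")],
        ignore_index=True,
    )
    config = {"experiment": "prevascularization", "replicates": replicates, "seed": seed,
              "weeks": weeks, "configs": list(configs), "npc": npc, "dose_ng": dose_ng,
              "n_seeds": n_seeds, "params": asdict(params)}
    _write_outputs(output_dir, "prevascularization", {"metrics": metrics_df, "summary": summary}, config)
    return {"metrics": metrics_df, "summary": summary}


def run_experiment(spec: ExperimentSpec) -> dict:
    """Dispatch an :class:`ExperimentSpec` to its runner."""
    spec.validate()
    runner = {
        "interconnectivity": run_interconnectivity,
        "gf_dose": run_gf_dose,
        "release_rate": run_release_rate,
        "prevascularization": run_prevascularization,
    }[spec.name]
    return runner(
        replicates=spec.replicates,
        seed=spec.seed,
        output_dir=spec.output_dir,
        weeks=spec.weeks,
        params=spec.params,
    )
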