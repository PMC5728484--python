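"""Batch pipeline: profile -> township -> focal stack -> suitability -> cost.

This is the scripted analogue of the interactive simulator: a YAML run
configuration replaces the county drop-down and landcover sliders, and a
seeded run writes everything the app would display — landcover and
suitability rasters for both the baseline and the scenario landscape,
per-category pixel counts, a cost breakdown, and a log that records the
seed, a hash of the resolved configuration, and library versions so any
run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import LandcoverComposition
from .economics import (
    CostBreakdown,
    CrpChargeMode,
    DEFAULT_HORIZON_YEARS,
    ManagementScenario,
    UnitManagementCosts,
    total_cost,
)
from .focal import DEFAULT_SCALE_MAP, compute_stack
from .landscape import (
    DEFAULT_BUFFER_PX,
    DEFAULT_CORE_COLS,
    DEFAULT_CORE_ROWS,
    DEFAULT_PIXEL_SIZE,
    TownshipGrid,
    generate_township,
)
from .profiles import CountyProfile, load_profiles
from .raster_io import write_class_codes, write_raster, write_township
from .suitability import (
    CoefficientSet,
    SuitabilitySurface,
    categorize_surface,
    predict_surface,
)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one scenario run.

    Baseline landcover comes from a county profile (``county_id`` +
    ``profiles`` CSV) or an explicit composition with inline economics.
    The scenario is the baseline shifted by ``scenario_deltas`` (the
    residual ``other`` re-balances, slider-style) or an explicit
    ``scenario_composition``.
    """

    profile: CountyProfile
    baseline: LandcoverComposition
    scenario: LandcoverComposition
    coefficients: CoefficientSet
    scale_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SCALE_MAP))
    core_rows: int = DEFAULT_CORE_ROWS
    core_cols: int = DEFAULT_CORE_COLS
    buffer_px: int = DEFAULT_BUFFER_PX
    pixel_size: float = DEFAULT_PIXEL_SIZE
    horizon_years: float = DEFAULT_HORIZON_YEARS
    unit_costs: UnitManagementCosts = field(default_factory=UnitManagementCosts)
    crp_charge: CrpChargeMode = "new"
    n_categories: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        max_radius = max(self.scale_map.values())
        if max_radius > self.buffer_px:
            raise ValueError(
                f"largest window radius ({max_radius} px) exceeds the buffer "
                f"({self.buffer_px} px); widen the buffer or shrink the windows"
            )


def _profile_from_mapping(raw: Mapping[str, Any]) -> CountyProfile:
    econ = raw.get("economics", {})
    return CountyProfile(
        county_id=str(raw.get("county_id", "custom")),
        mean_composition=LandcoverComposition(dict(raw["composition"])),
        row_crop_yield=float(econ.get("row_crop_yield", 0.0)),
        row_crop_price=float(econ.get("row_crop_price", 0.0)),
        small_grain_yield=float(econ.get("small_grain_yield", 0.0)),
        small_grain_price=float(econ.get("small_grain_price", 0.0)),
        pasture_rental=float(econ.get("pasture_rental", 0.0)),
        crp_rental=float(econ.get("crp_rental", 0.0)),
    )


def load_run_config(
    path: str | Path, seed: int | None = None, **overrides: Any
) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    ``seed`` and keyword overrides (matching RunConfig field names) win
    over file values, so a CLI flag always beats the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    if "county_id" in raw and "profiles" in raw:
        profiles = {p.county_id: p for p in load_profiles(raw["profiles"])}
        county = str(raw["county_id"])
        if county not in profiles:
            raise ValueError(f"county {county!r} not found in {raw['profiles']}")
        profile = profiles[county]
    elif "composition" in raw:
        profile = _profile_from_mapping(raw)
    else:
        raise ValueError(
            "config must give either county_id + profiles, or an explicit composition"
        )
    baseline = profile.mean_composition

    if "scenario_composition" in raw:
        scenario = LandcoverComposition(dict(raw["scenario_composition"]))
    else:
        deltas = {k: float(v) for k, v in (raw.get("scenario_deltas") or {}).items()}
        scenario = baseline.replace(**deltas)

    if "coefficients" in raw:
        coefficients = CoefficientSet.from_yaml(raw["coefficients"])
    else:
        coefficients = CoefficientSet.placeholder_default()

    kwargs: dict[str, Any] = {
        "profile": profile,
        "baseline": baseline,
        "scenario": scenario,
        "coefficients": coefficients,
    }
    grid = raw.get("grid", {})
    for key, raw_key in [
        ("core_rows", "core_rows"),
        ("core_cols", "core_cols"),
        ("buffer_px", "buffer_px"),
        ("pixel_size", "pixel_size"),
    ]:
        if raw_key in grid:
            kwargs[key] = grid[raw_key]
    if "scale_map" in raw:
        kwargs["scale_map"] = {k: int(v) for k, v in raw["scale_map"].items()}
    for key in ("horizon_years", "crp_charge", "n_categories", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "unit_costs" in raw:
        kwargs["unit_costs"] = UnitManagementCosts(**raw["unit_costs"])
    if seed is not None:
        kwargs["seed"] = seed
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def summarize_surface(surface: SuitabilitySurface) -> dict[str, Any]:
    """Mean/min/max of the suitability values plus per-category pixel counts."""
    record: dict[str, Any] = {
        "mean": float(surface.values.mean()),
        "min": float(surface.values.min()),
        "max": float(surface.values.max()),
        "n_pixels": int(surface.values.size),
    }
    if surface.categories is not None:
        for cat, count in surface.category_counts().items():
            record[f"category_{cat}"] = count
    return record


def _config_hash(config: RunConfig) -> str:
    payload = {
        "baseline": config.baseline.as_dict(),
        "scenario": config.scenario.as_dict(),
        "county_id": config.profile.county_id,
        "coefficients": {
            name: getattr(config.coefficients, name)
            for name in vars(config.coefficients)
        },
        "scale_map": dict(config.scale_map),
        "grid": [config.core_rows, config.core_cols, config.buffer_px, config.pixel_size],
        "horizon_years": config.horizon_years,
        "crp_charge": config.crp_charge,
        "n_categories": config.n_categories,
        "seed": config.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass(frozen=True)
class RunResult:
    baseline_grid: TownshipGrid
    scenario_grid: TownshipGrid
    baseline_surface: SuitabilitySurface
    scenario_surface: SuitabilitySurface
    cost: CostBreakdown


def run_scenario(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline for baseline and scenario landscapes.

    Both landscapes are realised with the SAME seed, so an identity
    scenario (no landcover change) yields identical rasters and category
    counts, and any difference between the two outputs is attributable
    to the landcover change alone.
    """
    sides: dict[str, tuple[TownshipGrid, SuitabilitySurface]] = {}
    for name, composition in [("baseline", config.baseline), ("scenario", config.scenario)]:
        grid = generate_township(
            composition,
            core_rows=config.core_rows,
            core_cols=config.core_cols,
            buffer_px=config.buffer_px,
            pixel_size=config.pixel_size,
            seed=config.seed,
        )
        stack = compute_stack(grid, config.scale_map)
        surface = categorize_surface(
            predict_surface(stack, config.coefficients), k=config.n_categories
        )
        sides[name] = (grid, surface)

    scenario = ManagementScenario(
        baseline=config.baseline,
        scenario=config.scenario,
        profile=config.profile,
        township_area_ha=sides["baseline"][0].core_area_ha,
        horizon_years=config.horizon_years,
    )
    cost = total_cost(scenario, config.unit_costs, crp_charge=config.crp_charge)

    result = RunResult(
        baseline_grid=sides["baseline"][0],
        scenario_grid=sides["scenario"][0],
        baseline_surface=sides["baseline"][1],
        scenario_surface=sides["scenario"][1],
        cost=cost,
    )
    if out_dir is not None:
        _write_outputs(config, result, Path(out_dir))
    return result


def _write_outputs(config: RunConfig, result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_class_codes(out_dir / "class_codes.csv")
    for name in ("baseline", "scenario"):
        grid: TownshipGrid = getattr(result, f"{name}_grid")
        surface: SuitabilitySurface = getattr(result, f"{name}_surface")
        write_township(out_dir / f"{name}_landcover.tif", grid)
        write_raster(out_dir / f"{name}_suitability.tif", surface.values)
        write_raster(
            out_dir / f"{name}_suitability_categories.tif",
            surface.categories.astype(np.int32),
        )
        pd.DataFrame([summarize_surface(surface)]).to_csv(
            out_dir / f"{name}_surface_summary.csv", index=False
        )
    with open(out_dir / "cost.json", "w") as fh:
        json.dump(result.cost.as_dict(), fh, indent=2)
    (out_dir / "cost.txt").write_text(result.cost.summary() + "\n")
    log = "\n".join(
        [
            f"pheasim {__version__}",
            f"numpy {np.__version__}",
            f"pandas {pd.__version__}",
            f"seed {config.seed}",
            f"config_sha256 {_config_hash(config)}",
            f"county {config.profile.county_id}",
            f"grid {config.core_rows}x{config.core_cols} core, "
            f"{config.buffer_px} px buffer, {config.pixel_size:g} m pixels",
        ]
    )
    (out_dir / "run_log.txt").write_text(log + "\n")
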