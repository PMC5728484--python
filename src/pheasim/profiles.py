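"""County profiles: default township compositions plus farm economics.

Each county carries the mean landcover composition of its townships and
the NASS-style economic quantities the cost module needs: crop yields
(bu/acre) and prices ($/bu) for row crop and small grain, the pasture
rental rate, and the CRP rental rate (both $/acre/yr).  Real county data
is out of scope; :func:`generate_fixture_profiles` synthesises
schema-identical stand-ins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import CLASSES, MODEL_CLASSES, CompositionError, LandcoverComposition

_ECON_COLUMNS = (
    "row_crop_yield",
    "row_crop_price",
    "small_grain_yield",
    "small_grain_price",
    "pasture_rental",
    "crp_rental",
)
#: CSV schema: ``other`` is optional (recomputed as the residual when absent).
REQUIRED_COLUMNS = ("county_id",) + MODEL_CLASSES + _ECON_COLUMNS


class ProfileSchemaError(ValueError):
    """The profile table is missing a required column."""


class ProfileValidationError(ValueError):
    """A profile row carries an out-of-range value."""


@dataclass(frozen=True)
class CountyProfile:
    county_id: str
    mean_composition: LandcoverComposition
    row_crop_yield: float  # bu/acre
    row_crop_price: float  # $/bu
    small_grain_yield: float  # bu/acre
    small_grain_price: float  # $/bu
    pasture_rental: float  # $/acre/yr
    crp_rental: float  # $/acre/yr

    def __post_init__(self) -> None:
        for name in _ECON_COLUMNS:
            value = getattr(self, name)
            if value < 0:
                raise ProfileValidationError(
                    f"county {self.county_id!r}: {name} = {value!r} is negative"
                )


def load_profiles(path: str | Path) -> list[CountyProfile]:
    """Read a county-profile CSV, validating every row.

    The residual ``other`` column may be omitted, in which case it is
    recomputed as ``1 - sum(named classes)`` per row.
    """
    frame = pd.read_csv(path, dtype={"county_id": str}, float_precision="round_trip")
    missing = [col for col in REQUIRED_COLUMNS if col not in frame.columns]
    if missing:
        raise ProfileSchemaError(f"profile table {path} is missing columns: {missing}")
    profiles = []
    for _, row in frame.iterrows():
        county = str(row["county_id"])
        props = {name: float(row[name]) for name in MODEL_CLASSES}
        if "other" in frame.columns and not pd.isna(row.get("other")):
            props["other"] = float(row["other"])
        try:
            composition = LandcoverComposition(props)
        except CompositionError as exc:
            raise ProfileValidationError(f"county {county!r}: {exc}") from exc
        profiles.append(
            CountyProfile(
                county_id=county,
                mean_composition=composition,
                **{name: float(row[name]) for name in _ECON_COLUMNS},
            )
        )
    return profiles


def write_profiles(profiles: Sequence[CountyProfile], path: str | Path) -> None:
    """Write profiles to CSV with the documented column schema.

    Floats are written with ``repr`` so that load(write(x)) == x exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("county_id",) + CLASSES + _ECON_COLUMNS)
        for p in profiles:
            row = [p.county_id]
            row += [repr(p.mean_composition[name]) for name in CLASSES]
            row += [repr(getattr(p, name)) for name in _ECON_COLUMNS]
            writer.writerow(row)


def generate_fixture_profiles(
    n_counties: int,
    seed: int,
    path: str | Path | None = None,
) -> list[CountyProfile]:
    """Synthesise ``n_counties`` schema-faithful county profiles.

    Compositions are drawn from a symmetric Dirichlet(2) over the seven
    classes (covers the simplex without favouring any class), with the
    residual ``other`` then recomputed exactly from the six named draws.
    Economics are uniform over order-of-magnitude-plausible ranges:
    yields 20-200 bu/acre, prices $2-15/bu, rentals $10-250/acre/yr.
    The values are placeholders, not estimates of any real county.
    """
    if n_counties < 1:
        raise ValueError(f"n_counties must be >= 1, got {n_counties}")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_counties):
        draw = rng.dirichlet(np.full(len(CLASSES), 2.0))
        props = {name: float(draw[j]) for j, name in enumerate(MODEL_CLASSES)}
        composition = LandcoverComposition(props)  # 'other' recomputed as residual
        profiles.append(
            CountyProfile(
                county_id=f"county_{i + 1:03d}",
                mean_composition=composition,
                row_crop_yield=float(rng.uniform(20, 200)),
                row_crop_price=float(rng.uniform(2, 15)),
                small_grain_yield=float(rng.uniform(20, 200)),
                small_grain_price=float(rng.uniform(2, 15)),
                pasture_rental=float(rng.uniform(10, 250)),
                crp_rental=float(rng.uniform(10, 250)),
            )
        )
    if path is not None:
        write_profiles(profiles, path)
    return profiles
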