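"""Log-linear pheasant habitat suitability surface.

Relative habitat suitability at a pixel p is the exponentiated linear
predictor of a species-habitat regression evaluated on that pixel's
focal landcover proportions:

    suitability_p = exp( b0
                         + a_R  * R_p                                 (rangeland)
                         + a_C  * C_p                                 (CRP)
                         + a_RC * RC_p + a_RC2 * RC_p^2 + a_RC3 * RC_p^3   (row crop)
                         + a_G  * G_p  + a_G2  * G_p^2  + a_G3  * G_p^3    (small grain)
                         + a_T  * T_p                                 (trees)
                         + a_W  * W_p )                               (wetland)

with un-centred, un-standardised proportions in [0, 1].  Row crop and
small grain enter as cubics (abundance peaks at intermediate cover);
rangeland, CRP, trees and wetland enter linearly.  Detection probability
is assumed constant and elevation is excluded by construction, so the
surface is a relative abundance-scale index, comparable across pixels
but not an absolute count.

The intercept defaults to 3.07.  The slope values are NOT published with
the intercept; this package ships clearly-labelled placeholder slopes
(see data/default_coefficients.yaml) that users must replace with fitted
values for any substantive use.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .focal import FocalProportionStack

DEFAULT_INTERCEPT = 3.07

#: Stack-layer name -> the coefficient fields applied to its powers 1..3.
_POLY_TERMS: dict[str, tuple[str, ...]] = {
    "rangeland": ("rangeland",),
    "crp": ("crp",),
    "row_crop": ("row_crop", "row_crop_sq", "row_crop_cu"),
    "small_grain": ("small_grain", "small_grain_sq", "small_grain_cu"),
    "trees": ("trees",),
    "wetland": ("wetland",),
}


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept plus the ten slope coefficients, all on the log scale."""

    intercept: float = DEFAULT_INTERCEPT
    rangeland: float = 0.0
    crp: float = 0.0
    row_crop: float = 0.0
    row_crop_sq: float = 0.0
    row_crop_cu: float = 0.0
    small_grain: float = 0.0
    small_grain_sq: float = 0.0
    small_grain_cu: float = 0.0
    trees: float = 0.0
    wetland: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value):
                raise ValueError(f"coefficient {f.name} is not finite: {value!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CoefficientSet":
        """Load coefficients from a YAML file with keys ``intercept`` and ``slopes``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        slopes = raw.get("slopes", {})
        known = {f.name for f in fields(cls)} - {"intercept"}
        unknown = set(slopes) - known
        if unknown:
            raise ValueError(f"unknown slope coefficients in {path}: {sorted(unknown)}")
        return cls(intercept=float(raw.get("intercept", DEFAULT_INTERCEPT)),
                   **{k: float(v) for k, v in slopes.items()})

    @classmethod
    def placeholder_default(cls) -> "CoefficientSet":
        """The shipped placeholder configuration (bundled YAML)."""
        return cls.from_yaml(Path(__file__).parent / "data" / "default_coefficients.yaml")


def linear_predictor(
    focal_values: Mapping[str, float | np.ndarray], coefficients: CoefficientSet
) -> float | np.ndarray:
    """Evaluate the log-suitability at given covariate fractions.

    Polynomial terms are powers of the SAME focal value (one layer per
    covariate, not separate squared/cubed layers).  Accepts scalars or
    arrays per covariate; broadcasting applies.
    """
    missing = [name for name in _POLY_TERMS if name not in focal_values]
    if missing:
        raise KeyError(f"focal values missing covariates: {missing}")
    eta = coefficients.intercept
    for name, coef_names in _POLY_TERMS.items():
        x = focal_values[name]
        for power, coef_name in enumerate(coef_names, start=1):
            eta = eta + getattr(coefficients, coef_name) * x**power
    return eta


@dataclass(frozen=True)
class SuitabilitySurface:
    """Predicted relative-suitability values, optionally categorised."""

    values: np.ndarray
    categories: np.ndarray | None = None  # ordinal 1..k, set by categorize_surface
    n_categories: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def category_counts(self) -> dict[int, int]:
        """Pixel count per ordinal category (requires categorisation)."""
        if self.categories is None:
            raise ValueError("surface has not been categorised")
        counts = np.bincount(self.categories.ravel(), minlength=self.n_categories + 1)
        return {k: int(counts[k]) for k in range(1, self.n_categories + 1)}


def predict_surface(
    stack: FocalProportionStack, coefficients: CoefficientSet
) -> SuitabilitySurface:
    """exp(linear predictor) at every core pixel; strictly positive."""
    eta = linear_predictor(stack.layers, coefficients)
    with np.errstate(over="ignore"):  # overflow is reported explicitly below
        values = np.exp(eta)
    if not np.all(np.isfinite(values)):
        idx = np.unravel_index(int(np.argmax(~np.isfinite(values))), values.shape)
        idx = tuple(int(i) for i in idx)
        raise FloatingPointError(
            f"non-finite suitability at pixel {idx}: linear predictor {float(eta[idx]):g}"
        )
    return SuitabilitySurface(values=values)


def categorize_surface(
    surface: SuitabilitySurface,
    breaks: "np.ndarray | list[float] | None" = None,
    k: int | None = None,
) -> SuitabilitySurface:
    """Assign ordinal suitability categories 1..k to every pixel.

    Either pass explicit strictly-increasing ``breaks`` (k = len+1
    categories; category i+1 starts strictly above break i) or a quantile
    count ``k`` for equal-count categories of the current surface
    (default k=5).  Categories are monotone in value by construction, and
    equal values always share a category.
    """
    values = surface.values
    if breaks is not None and k is not None:
        raise ValueError("pass either explicit breaks or a quantile count k, not both")
    if breaks is not None:
        breaks = np.asarray(breaks, dtype=float)
        if breaks.ndim != 1 or len(breaks) < 1 or np.any(np.diff(breaks) <= 0):
            raise ValueError("breaks must be a strictly increasing 1-D sequence")
        n_cat = len(breaks) + 1
    else:
        k = 5 if k is None else k
        if k < 2:
            raise ValueError(f"quantile category count must be >= 2, got {k}")
        flat = np.sort(values.ravel())
        n = flat.size
        cut_idx = [round(i * n / k) for i in range(1, k)]
        breaks = flat[cut_idx]
        n_cat = k
    categories = (np.searchsorted(breaks, values.ravel(), side="right") + 1).reshape(
        values.shape
    )
    return SuitabilitySurface(
        values=values, categories=categories.astype(np.int64), n_categories=n_cat
    )
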