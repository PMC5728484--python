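"""Landcover composition: the area-proportion vector of a township landscape.

A landscape is described by the fraction of its area in each of seven
landcover classes.  Six of them (CRP grassland, row crop, small grain,
rangeland, trees, wetland) are covariates of the pheasant-habitat model;
the seventh, ``other``, is the residual class that absorbs whatever area
the named classes do not claim.  It appears on simulated rasters for
visualisation and bookkeeping but never enters the habitat model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

# Canonical class order.  This order is load-bearing: it is the tie-break
# order for largest-remainder quantization and the integer-code order for
# rasters, so it must never be reordered.
CLASSES: tuple[str, ...] = (
    "crp",
    "row_crop",
    "small_grain",
    "rangeland",
    "trees",
    "wetland",
    "other",
)

#: Classes that enter the habitat model (everything except the residual).
MODEL_CLASSES: tuple[str, ...] = CLASSES[:-1]

_SUM_TOL = 1e-9


class CompositionError(ValueError):
    """A proportion vector violates the composition invariants."""


@dataclass(frozen=True)
class LandcoverComposition:
    """Proportions of the seven landcover classes; must sum to 1.

    Parameters
    ----------
    proportions
        Mapping from class name to unitless fraction.  Every key must be
        one of :data:`CLASSES`; missing classes default to 0 except
        ``other``, which — if omitted — is computed as the residual
        ``1 - sum(named classes)``.
    """

    proportions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        props = dict(self.proportions)
        unknown = set(props) - set(CLASSES)
        if unknown:
            raise CompositionError(f"unknown landcover classes: {sorted(unknown)}")
        for name in MODEL_CLASSES:
            props.setdefault(name, 0.0)
        named_sum = sum(props[name] for name in MODEL_CLASSES)
        if "other" not in props:
            if named_sum > 1.0 + _SUM_TOL:
                raise CompositionError(
                    f"named classes sum to {named_sum:.12g} > 1; no residual left for 'other'"
                )
            props["other"] = max(0.0, 1.0 - named_sum)
        for name, value in props.items():
            if not (0.0 <= value <= 1.0):
                raise CompositionError(
                    f"proportion of {name!r} is {value!r}, outside [0, 1]"
                )
        total = sum(props[name] for name in CLASSES)
        if abs(total - 1.0) > _SUM_TOL:
            raise CompositionError(
                f"proportions sum to {total:.12g}, not 1 (tolerance {_SUM_TOL})"
            )
        object.__setattr__(self, "proportions", {name: float(props[name]) for name in CLASSES})

    def __getitem__(self, name: str) -> float:
        return self.proportions[name]

    def __iter__(self) -> Iterator[str]:
        return iter(CLASSES)

    def as_dict(self) -> dict[str, float]:
        """Return the proportions as a plain dict in canonical class order."""
        return dict(self.proportions)

    def replace(self, **deltas: float) -> "LandcoverComposition":
        """Return a new composition with named-class proportions shifted by ``deltas``.

        The residual class ``other`` is recomputed so the result still sums
        to 1, mirroring how a slider interface re-balances the landscape.
        ``other`` itself cannot be shifted directly.
        """
        if "other" in deltas:
            raise CompositionError("'other' is the residual class and cannot be set directly")
        unknown = set(deltas) - set(MODEL_CLASSES)
        if unknown:
            raise CompositionError(f"unknown landcover classes: {sorted(unknown)}")
        new = {
            name: self.proportions[name] + deltas.get(name, 0.0)
            for name in MODEL_CLASSES
        }
        return LandcoverComposition(new)
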