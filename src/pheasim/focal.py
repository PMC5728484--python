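"""Circular moving-window focal statistics.

For each core pixel, the proportion of a landcover class within a
circular window of fixed pixel radius is the model's covariate value at
that pixel.  Two radii are in play: 10 pixels (1 km at 100 m pixels) and
50 pixels (5 km).  Which covariate takes which radius is configuration
(see :data:`DEFAULT_SCALE_MAP`); the buffer built into the township grid
guarantees every window centred on a core pixel lies fully on data, so
no edge correction is ever needed or applied.

Window membership is centre-to-centre Euclidean distance <= radius with
the boundary included; a radius-10 window therefore covers exactly 317
cells.  Counts are accumulated in integer arithmetic and divided by the
window cell count once at the end, so results are exact up to a single
final division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .composition import MODEL_CLASSES
from .landscape import CLASS_CODES, TownshipGrid

#: Covariate -> window radius (pixels).  The two radii come from the
#: habitat model's spatial scales; which covariate takes which radius is
#: an ASSUMPTION shipped as an overridable default (landscape-matrix
#: crops and rangeland at the broad 5 km scale, the patchier CRP, tree
#: and wetland classes at 1 km), not an assertion about the source model.
DEFAULT_SCALE_MAP: dict[str, int] = {
    "row_crop": 50,
    "small_grain": 50,
    "rangeland": 50,
    "crp": 10,
    "trees": 10,
    "wetland": 10,
}

#: Radii considered valid in configuration.
ALLOWED_RADII = frozenset({10, 50})


class WindowError(ValueError):
    """A window cannot be evaluated on this grid (radius exceeds buffer)."""


@dataclass(frozen=True)
class CircularKernel:
    """Discrete circular window membership mask.

    ``mask[r + dy, r + dx]`` is True iff ``sqrt(dx^2 + dy^2) <= radius``.
    """

    radius_px: int
    mask: np.ndarray
    cell_count: int


def build_kernel(radius_px: int) -> CircularKernel:
    """Enumerate the lattice offsets within Euclidean distance ``radius_px``."""
    if radius_px < 0:
        raise ValueError(f"radius must be >= 0, got {radius_px}")
    offsets = np.arange(-radius_px, radius_px + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    mask = dy * dy + dx * dx <= radius_px * radius_px
    return CircularKernel(radius_px=radius_px, mask=mask, cell_count=int(mask.sum()))


def _row_half_widths(radius: int) -> np.ndarray:
    """Half-width of the circular window in each row offset dy = -r..r."""
    dy = np.arange(-radius, radius + 1)
    return np.floor(np.sqrt(radius * radius - dy * dy)).astype(np.int64)


def _window_counts(binary: np.ndarray, radius: int) -> np.ndarray:
    """Exact integer in-window counts at every pixel where the window fits.

    The circular window is decomposed into its horizontal runs: for each
    row offset dy the member cells form the contiguous span
    ``|dx| <= floor(sqrt(r^2 - dy^2))``, whose sum is a difference of two
    row cumulative sums.  All arithmetic is int64, so the result is the
    same integer a brute-force recount would produce.
    """
    rows, cols = binary.shape
    r = radius
    out_rows, out_cols = rows - 2 * r, cols - 2 * r
    cs = np.zeros((rows, cols + 1), dtype=np.int64)
    np.cumsum(binary, axis=1, dtype=np.int64, out=cs[:, 1:])
    counts = np.zeros((out_rows, out_cols), dtype=np.int64)
    for dy, w in zip(range(-r, r + 1), _row_half_widths(r)):
        row_block = cs[r + dy : r + dy + out_rows]
        counts += row_block[:, r + w + 1 : r + w + 1 + out_cols]
        counts -= row_block[:, r - w : r - w + out_cols]
    return counts


def focal_proportion(
    grid: TownshipGrid, class_name: str, kernel: CircularKernel
) -> np.ndarray:
    """Per-core-pixel proportion of ``class_name`` within the window.

    Requires ``kernel.radius_px <= grid.buffer_px`` so that every core
    pixel's window lies fully on the buffered grid.
    """
    r = kernel.radius_px
    if r > grid.buffer_px:
        raise WindowError(
            f"window radius {r} px exceeds grid buffer {grid.buffer_px} px; "
            "every core window must lie fully on the grid"
        )
    binary = (grid.labels == CLASS_CODES[class_name]).astype(np.int64)
    counts = _window_counts(binary, r)
    # _window_counts covers pixels at offset r..; the core starts at buffer_px.
    off_r = grid.buffer_px - r
    core = counts[off_r : off_r + grid.core_rows, off_r : off_r + grid.core_cols]
    return core / kernel.cell_count


@dataclass(frozen=True)
class FocalProportionStack:
    """Core-extent focal-proportion layer per model covariate.

    ``layers[name]`` is a ``core_rows x core_cols`` float array in [0, 1];
    ``radii[name]`` records the window radius used.  The residual class
    ``other`` never has a layer.
    """

    layers: Mapping[str, np.ndarray]
    radii: Mapping[str, int]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]


def compute_stack(
    grid: TownshipGrid,
    scale_map: Mapping[str, int] | None = None,
    allowed_radii: frozenset[int] = ALLOWED_RADII,
) -> FocalProportionStack:
    """Compute all six covariate layers at their configured radii.

    ``allowed_radii`` guards against typo radii; pass a different set to
    run the pipeline at non-standard scales (e.g. miniature test grids).
    """
    scale_map = dict(DEFAULT_SCALE_MAP if scale_map is None else scale_map)
    missing = [name for name in MODEL_CLASSES if name not in scale_map]
    if missing:
        raise ValueError(f"scale_map is missing covariates: {missing}")
    bad = {name: r for name, r in scale_map.items() if r not in allowed_radii}
    if bad:
        raise ValueError(
            f"scale_map radii must be in {sorted(allowed_radii)}, got {bad}"
        )
    kernels = {r: build_kernel(r) for r in set(scale_map.values())}
    layers = {
        name: focal_proportion(grid, name, kernels[scale_map[name]])
        for name in MODEL_CLASSES
    }
    return FocalProportionStack(layers=layers, radii={n: scale_map[n] for n in MODEL_CLASSES})
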