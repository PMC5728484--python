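"""Township raster simulation.

A landcover composition is realised as a categorical raster covering a
"township" core (the 6x6-mile public-land-survey block, 9324 ha) plus a
buffer margin wide enough that every downstream moving window centred on
a core pixel lies fully on data.  Pixels are assigned to classes in exact
proportion to the composition (largest-remainder quantization) and placed
by a uniform random permutation: the simulated landscape is spatially
neutral by design, standing for the average composition of a region
rather than any real place.

Defaults: 100 m pixels (1 ha), an 84 x 111 pixel core (exactly 9324 ha;
the township area has no integral square root in whole pixels), and a
50-pixel buffer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CLASSES, LandcoverComposition

#: Raster integer code for each class, in canonical class order.
CLASS_CODES: dict[str, int] = {name: code for code, name in enumerate(CLASSES)}
CODE_CLASSES: dict[int, str] = {code: name for name, code in CLASS_CODES.items()}

DEFAULT_CORE_ROWS = 84
DEFAULT_CORE_COLS = 111
DEFAULT_BUFFER_PX = 50
DEFAULT_PIXEL_SIZE = 100.0  # metres; one pixel = 1 ha


@dataclass(frozen=True)
class TownshipGrid:
    """Buffered categorical landcover raster.

    ``labels`` holds integer class codes (see :data:`CLASS_CODES`) over
    the full core-plus-buffer extent; the core occupies the central
    ``core_rows x core_cols`` block.
    """

    labels: np.ndarray
    core_rows: int
    core_cols: int
    buffer_px: int
    pixel_size: float = DEFAULT_PIXEL_SIZE

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def core_slice(self) -> tuple[slice, slice]:
        b = self.buffer_px
        return (slice(b, b + self.core_rows), slice(b, b + self.core_cols))

    @property
    def core_labels(self) -> np.ndarray:
        return self.labels[self.core_slice]

    @property
    def core_area_ha(self) -> float:
        """Core area in hectares (pixel_size is in metres)."""
        return self.core_rows * self.core_cols * self.pixel_size**2 / 1e4

    def class_counts(self) -> dict[str, int]:
        """Per-class pixel counts over the full (core + buffer) grid."""
        counts = np.bincount(self.labels.ravel(), minlength=len(CLASSES))
        return {name: int(counts[CLASS_CODES[name]]) for name in CLASSES}


def quantize_composition(
    composition: LandcoverComposition, n_pixels: int
) -> dict[str, int]:
    """Apportion ``n_pixels`` to classes by largest-remainder (Hamilton).

    Each class gets the floor of its exact quota ``proportion * n_pixels``;
    the leftover pixels go one each to the classes with the largest
    fractional remainders.  Remainder ties are broken by canonical class
    order, so the result is deterministic.  Every count is within one
    pixel of its exact quota and the counts sum to exactly ``n_pixels``.
    """
    if n_pixels < 1:
        raise ValueError(f"n_pixels must be >= 1, got {n_pixels}")
    quotas = np.array([composition[name] * n_pixels for name in CLASSES])
    counts = np.floor(quotas).astype(np.int64)
    remainders = quotas - counts
    leftover = n_pixels - int(counts.sum())
    # np.argsort is stable, so equal remainders keep canonical class order.
    order = np.argsort(-remainders, kind="stable")
    for idx in order[:leftover]:
        counts[idx] += 1
    return {name: int(counts[i]) for i, name in enumerate(CLASSES)}


def generate_township(
    composition: LandcoverComposition,
    core_rows: int = DEFAULT_CORE_ROWS,
    core_cols: int = DEFAULT_CORE_COLS,
    buffer_px: int = DEFAULT_BUFFER_PX,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int | None = 0,
) -> TownshipGrid:
    """Realise a composition as a spatially random buffered raster.

    The buffer is drawn from the same proportional assignment as the
    core — quantization and random placement operate on the full grid at
    once — so the margin has the same expected composition as the centre
    and windows reaching into it see no compositional bias.
    """
    if core_rows < 1 or core_cols < 1:
        raise ValueError("core dimensions must be >= 1")
    if buffer_px < 0:
        raise ValueError("buffer_px must be >= 0")
    rows = core_rows + 2 * buffer_px
    cols = core_cols + 2 * buffer_px
    n_pixels = rows * cols
    counts = quantize_composition(composition, n_pixels)
    pool = np.repeat(
        np.array([CLASS_CODES[name] for name in CLASSES], dtype=np.uint8),
        [counts[name] for name in CLASSES],
    )
    rng = np.random.default_rng(seed)
    labels = rng.permutation(pool).reshape(rows, cols)
    return TownshipGrid(
        labels=labels,
        core_rows=core_rows,
        core_cols=core_cols,
        buffer_px=buffer_px,
        pixel_size=pixel_size,
    )
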