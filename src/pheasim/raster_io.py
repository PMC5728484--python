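"""Raster input/output.

Rasters are written as plain single-band TIFFs (via tifffile).  The
simulated township is a local, non-georeferenced grid — it deliberately
represents no real place — so no coordinate reference system is attached.
Categorical rasters use the integer class codes of
:data:`pheasim.landscape.CLASS_CODES`; a code<->class sidecar CSV can be
written next to any categorical raster so the coding travels with the
file.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile

from .landscape import (
    CLASS_CODES,
    DEFAULT_PIXEL_SIZE,
    TownshipGrid,
)


def write_raster(path: str | Path, array: np.ndarray) -> None:
    """Write a 2-D array as a single-band TIFF."""
    tifffile.imwrite(str(path), np.asarray(array))


def read_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_class_codes(path: str | Path) -> None:
    """Write the integer-code <-> class-name table as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "class"])
        for name, code in CLASS_CODES.items():
            writer.writerow([code, name])


def write_stack(directory: str | Path, stack) -> list[Path]:
    """Export each focal-proportion layer as ``<covariate>_r<radius>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, layer in stack.layers.items():
        path = directory / f"{name}_r{stack.radii[name]}.tif"
        write_raster(path, layer)
        paths.append(path)
    return paths


def write_township(path: str | Path, grid: TownshipGrid, full_extent: bool = True) -> None:
    """Write a township's label raster (full buffered extent by default)."""
    labels = grid.labels if full_extent else grid.core_labels
    write_raster(path, labels)


def read_township(
    path: str | Path,
    core_rows: int,
    core_cols: int,
    buffer_px: int,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> TownshipGrid:
    """Rehydrate a township from a label raster plus its geometry."""
    labels = read_raster(path)
    expected = (core_rows + 2 * buffer_px, core_cols + 2 * buffer_px)
    if labels.shape != expected:
        raise ValueError(
            f"raster shape {labels.shape} does not match geometry {expected}"
        )
    return TownshipGrid(
        labels=labels,
        core_rows=core_rows,
        core_cols=core_cols,
        buffer_px=buffer_px,
        pixel_size=pixel_size,
    )
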