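"""Height-map container and file I/O.

A height map is a rectangular grid of surface elevations z(x, y) sampled at a
uniform lateral step (µm), as produced by white-light confocal profilometry.
Convention: ``heights[row, col]`` with x (medio-lateral axis) running along
columns and y (antero-posterior axis) along rows.

On disk a surface is a single-band 32-bit float TIFF *or* a headerless CSV
(one CSV row per grid row), accompanied by a JSON sidecar recording the
lateral step and the axis convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError

AXIS_CONVENTION = "x=medio-lateral (columns), y=antero-posterior (rows)"


@dataclass
class HeightMap:
    """Surface heights (µm) on a uniform grid with lateral step (µm)."""

    heights: np.ndarray
    step: float = 1.0
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValidationError("heights must be a 2D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValidationError("heights must be finite")
        if not (self.step > 0):
            raise ValidationError("step must be > 0")

    @property
    def n_rows(self) -> int:
        return self.heights.shape[0]

    @property
    def n_cols(self) -> int:
        return self.heights.shape[1]

    def mean(self) -> float:
        return float(self.heights.mean())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_heightmap(hm: HeightMap, path: str | Path) -> Path:
    """Write a surface as float32 TIFF (.tif/.tiff) or headerless CSV (.csv).

    A sidecar ``<name>.<ext>.json`` records step and axis convention.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, hm.heights.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, hm.heights, delimiter=",", fmt="%.6g")
    else:
        raise ValidationError(f"unsupported height-map extension: {path.suffix}")
    sidecar = {
        "step_um": hm.step,
        "axis_convention": hm.axis_convention,
        "n_rows": hm.n_rows,
        "n_cols": hm.n_cols,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_heightmap(path: str | Path) -> HeightMap:
    """Read a TIFF or CSV surface; step taken from the JSON sidecar (default 1 µm)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = np.asarray(tifffile.imread(path), dtype=float)
    elif path.suffix.lower() == ".csv":
        heights = np.atleast_2d(np.loadtxt(path, delimiter=","))
    else:
        raise ValidationError(f"unsupported height-map extension: {path.suffix}")
    step = 1.0
    convention = AXIS_CONVENTION
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        step = float(meta.get("step_um", 1.0))
        convention = meta.get("axis_convention", AXIS_CONVENTION)
    return HeightMap(heights, step=step, axis_convention=convention)
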