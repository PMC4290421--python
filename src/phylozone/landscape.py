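"""Raster data model and I/O for co-registered probability and mask grids.

Grids are row-major, 0-based, origin top-left; the flat cell index of
(row, col) is ``row * n_cols + col``. Cell geometry metadata (corner
coordinates, cell size) is carried through untouched and never
interpreted: the analysis treats cells as equal-area planning units.

NoData and probability zero are distinct: zero means "species absent,
cell still rankable", NoData means "cell outside the analysis". Within a
stack the valid mask is shared across layers (the union of per-layer
NoData is applied to all layers on assembly).

Supported formats: ESRI ASCII grid (``.asc``/``.txt``) and single-band
TIFF (``.tif``/``.tiff``, NoData encoded as NaN). Values outside [0, 1]
beyond a 1e-9 tolerance are an error, not clamped — they indicate an
upstream distribution-model scaling mistake that should surface loudly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RasterStack",
    "MaskGrid",
    "read_layer",
    "write_layer",
    "assemble_stack",
    "read_mask",
    "write_mask",
    "read_stack_manifest",
]

_RANGE_TOL = 1e-9
_DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Shape and (uninterpreted) geometry of one analysis grid."""

    n_rows: int
    n_cols: int
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def flat_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row={row}, col={col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, flat: int) -> tuple:
        if not (0 <= flat < self.n_cells):
            raise IndexError(f"flat index {flat} outside grid")
        return divmod(flat, self.n_cols)

    def same_shape(self, other: "GridSpec") -> bool:
        return self.n_rows == other.n_rows and self.n_cols == other.n_cols


@dataclass
class RasterStack:
    """Co-registered [0, 1] probability layers over one grid.

    ``values`` has shape (n_layers, n_cells); invalid cells hold NaN in
    every layer and False in ``valid_mask``.
    """

    grid: GridSpec
    layer_ids: list
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != (len(self.layer_ids), self.grid.n_cells):
            raise ValueError("values shape does not match layers × cells")
        if self.valid_mask.shape != (self.grid.n_cells,):
            raise ValueError("valid_mask shape does not match grid")
        if len(set(self.layer_ids)) != len(self.layer_ids):
            raise ValueError("duplicate layer ids")
        valid_vals = self.values[:, self.valid_mask]
        if np.isnan(valid_vals).any():
            raise ValueError("NaN value inside the valid mask")
        if ((valid_vals < -_RANGE_TOL) | (valid_vals > 1 + _RANGE_TOL)).any():
            bad = valid_vals[(valid_vals < -_RANGE_TOL) | (valid_vals > 1 + _RANGE_TOL)]
            raise ValueError(f"values outside [0, 1]: e.g. {bad.flat[0]}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def layer(self, layer_id) -> np.ndarray:
        """Flat values of one layer (NaN outside the valid mask)."""
        return self.values[self.layer_ids.index(layer_id)]

    def layer_grid(self, layer_id) -> np.ndarray:
        return self.layer(layer_id).reshape(self.grid.n_rows, self.grid.n_cols)


@dataclass
class MaskGrid:
    """Integer removal-hierarchy levels per cell (land-tenure categories).

    Level semantics follow the removal-order convention: lower levels are
    removed first, so the highest level is the most protected. Level 0
    conventionally marks territory outside the analysis (e.g. cleared
    land); whether level-0 cells are excluded entirely or merely removed
    first is the caller's choice via ``outside_levels``.
    """

    grid: GridSpec
    levels: np.ndarray
    declared_levels: tuple
    outside_levels: tuple = ()

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int).reshape(self.grid.n_cells)
        self.declared_levels = tuple(sorted(int(l) for l in self.declared_levels))
        self.outside_levels = tuple(sorted(int(l) for l in self.outside_levels))
        present = set(np.unique(self.levels).tolist())
        undeclared = present - set(self.declared_levels)
        if undeclared:
            raise ValueError(f"undeclared mask levels present: {sorted(undeclared)}")
        if not set(self.outside_levels) <= set(self.declared_levels):
            raise ValueError("outside_levels must be a subset of declared_levels")

    def cells_at(self, level: int) -> np.ndarray:
        return np.flatnonzero(self.levels == level)

    @property
    def analysis_mask(self) -> np.ndarray:
        """Boolean mask of cells not in an outside level."""
        return ~np.isin(self.levels, self.outside_levels)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def _read_ascii(path) -> tuple:
    header: dict = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            } and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: not an ESRI ASCII grid (missing ncols/nrows)")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    arr = np.array(" ".join(data_lines).split(), dtype=float)
    if arr.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: header says {n_rows}×{n_cols} but found {arr.size} values"
        )
    arr = arr.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value")
    grid = GridSpec(
        n_rows,
        n_cols,
        xllcorner=header.get("xllcorner", header.get("xllcenter", 0.0)),
        yllcorner=header.get("yllcorner", header.get("yllcenter", 0.0)),
        cellsize=header.get("cellsize", 1.0),
    )
    flat = arr.reshape(-1)
    if nodata is not None:
        flat = np.where(flat == nodata, np.nan, flat)
    return grid, flat


def _write_ascii(path, grid: GridSpec, flat: np.ndarray, fmt: str = "%.10g") -> None:
    out = np.where(np.isnan(flat), _DEFAULT_NODATA, flat).reshape(
        grid.n_rows, grid.n_cols
    )
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {_DEFAULT_NODATA:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)


def _read_tiff(path) -> tuple:
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    grid = GridSpec(arr.shape[0], arr.shape[1])
    return grid, arr.reshape(-1)


def _write_tiff(path, grid: GridSpec, flat: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, flat.reshape(grid.n_rows, grid.n_cols).astype(np.float64))


def _read_any(path) -> tuple:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".tif", ".tiff"}:
        return _read_tiff(path)
    return _read_ascii(path)


def _write_any(path, grid: GridSpec, flat: np.ndarray, fmt: str = "%.10g") -> None:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".tif", ".tiff"}:
        _write_tiff(path, grid, flat)
    else:
        _write_ascii(path, grid, flat, fmt=fmt)


# ---------------------------------------------------------------------------
# Public I/O operations


def read_layer(
    path, expected_grid: Optional[GridSpec] = None, layer_id=None
) -> RasterStack:
    """Read one probability layer into a single-layer stack.

    NoData cells become NaN/invalid. Values outside [0, 1] (beyond 1e-9)
    raise. If ``expected_grid`` is given, the file's shape must match.
    """
    grid, flat = _read_any(path)
    if expected_grid is not None:
        if not grid.same_shape(expected_grid):
            raise ValueError(
                f"{path}: grid {grid.n_rows}×{grid.n_cols} does not match "
                f"expected {expected_grid.n_rows}×{expected_grid.n_cols}"
            )
        grid = expected_grid
    if layer_id is None:
        layer_id = os.path.splitext(os.path.basename(str(path)))[0]
    valid = ~np.isnan(flat)
    vals = flat[valid]
    if ((vals < -_RANGE_TOL) | (vals > 1 + _RANGE_TOL)).any():
        bad = vals[(vals < -_RANGE_TOL) | (vals > 1 + _RANGE_TOL)][0]
        raise ValueError(f"{path}: probability value outside [0, 1]: {bad}")
    flat = np.clip(flat, 0.0, 1.0)  # shave float-format noise within tolerance
    flat[~valid] = np.nan
    return RasterStack(grid, [layer_id], flat[None, :], valid)


def write_layer(path, stack: RasterStack, layer_id=None) -> None:
    """Write one layer (default: the only layer) of a stack to disk."""
    if layer_id is None:
        if stack.n_layers != 1:
            raise ValueError("layer_id required for a multi-layer stack")
        layer_id = stack.layer_ids[0]
    _write_any(path, stack.grid, stack.layer(layer_id))


def assemble_stack(
    layers: Sequence[RasterStack], ids: Optional[Sequence] = None
) -> RasterStack:
    """Stack single-layer rasters; the union of NoData invalidates a cell."""
    if not layers:
        raise ValueError("no layers to assemble")
    if ids is None:
        ids = [l.layer_ids[0] for l in layers]
    ids = list(ids)
    if len(ids) != len(layers):
        raise ValueError("ids and layers have different lengths")
    grid = layers[0].grid
    for l in layers[1:]:
        if not l.grid.same_shape(grid):
            raise ValueError("grid mismatch between layers")
    valid = np.logical_and.reduce([l.valid_mask for l in layers])
    values = np.vstack([l.values[0] for l in layers])
    values[:, ~valid] = np.nan
    return RasterStack(grid, ids, values, valid)


def read_mask(
    path,
    grid: Optional[GridSpec],
    declared_levels: Sequence[int],
    outside_levels: Sequence[int] = (),
) -> MaskGrid:
    """Read an integer hierarchy raster and validate its level set."""
    file_grid, flat = _read_any(path)
    if grid is not None:
        if not file_grid.same_shape(grid):
            raise ValueError(
                f"{path}: mask grid {file_grid.n_rows}×{file_grid.n_cols} "
                f"does not match {grid.n_rows}×{grid.n_cols}"
            )
        file_grid = grid
    if np.isnan(flat).any():
        flat = np.where(np.isnan(flat), 0.0, flat)  # NoData folds into level 0
    if not np.allclose(flat, np.round(flat)):
        raise ValueError(f"{path}: mask raster is not integer-valued")
    return MaskGrid(
        file_grid,
        np.round(flat).astype(int),
        declared_levels=tuple(declared_levels),
        outside_levels=tuple(outside_levels),
    )


def write_mask(path, mask: MaskGrid) -> None:
    _write_any(path, mask.grid, mask.levels.astype(float), fmt="%d")


def read_stack_manifest(path, expected_grid: Optional[GridSpec] = None) -> RasterStack:
    """Read a CSV manifest with columns id,path and assemble the stack.

    Relative paths resolve against the manifest's directory.
    """
    df = pd.read_csv(path)
    if not {"id", "path"}.issubset(df.columns):
        raise ValueError("stack manifest needs columns id,path")
    base = os.path.dirname(os.path.abspath(str(path)))
    layers = []
    for _, row in df.iterrows():
        p = str(row["path"])
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        layers.append(read_layer(p, expected_grid, layer_id=str(row["id"])))
        expected_grid = expected_grid or layers[-1].grid
    return assemble_stack(layers)
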