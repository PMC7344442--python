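"""Grid containers and plain-text raster I/O.

Land-use maps are integer class-coded grids; driving factors are stacks of
float layers on the same grid.  Rasters are stored as ESRI ASCII grids
(``.asc``), a widely supported text format, with a small JSON sidecar
(``<name>.asc.json``) carrying the legend, cell area and provenance metadata.
The math downstream is CRS-agnostic, so no geographic transform beyond the
ASCII-grid origin/cellsize header is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: canonical legend, code -> class name (column order of the valuation table)
DEFAULT_LEGEND: dict[int, str] = {
    1: "paddy_field",
    2: "unirrigated_field",
    3: "forest_land",
    4: "grass_land",
    5: "water_area",
    6: "wet_land",
    7: "built_up_land",
    8: "unused_land",
}

NODATA_INT = -9999


class RasterIOError(ValueError):
    """Raised for malformed raster files or legend violations."""


@dataclass
class CategoricalRaster:
    """Integer class-coded grid with legend and per-cell area.

    Parameters
    ----------
    grid : 2-D int array of class codes (``NODATA_INT`` marks nodata)
    cell_area_ha : area of one cell in hectares
    legend : mapping from class code to class name
    """

    grid: np.ndarray
    cell_area_ha: float = 1.0
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise RasterIOError("categorical raster must be 2-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise RasterIOError(
                "categorical raster requires an integer grid; got "
                f"{self.grid.dtype} (read float bands as FactorStack instead)"
            )
        if self.cell_area_ha <= 0:
            raise RasterIOError("cell_area_ha must be positive")
        codes = set(np.unique(self.grid).tolist()) - {NODATA_INT}
        unknown = codes - set(self.legend)
        if unknown:
            raise RasterIOError(f"unknown class codes {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_cells(self) -> int:
        return int((self.grid != NODATA_INT).sum())

    def class_counts(self) -> dict[int, int]:
        """Cell count per legend code (zero for absent classes)."""
        return {c: int((self.grid == c).sum()) for c in sorted(self.legend)}

    def class_areas_ha(self) -> dict[int, float]:
        return {c: n * self.cell_area_ha for c, n in self.class_counts().items()}

    def copy(self) -> "CategoricalRaster":
        return CategoricalRaster(self.grid.copy(), self.cell_area_ha, dict(self.legend))


@dataclass
class FactorStack:
    """Stack of aligned float factor layers.

    ``layers`` has shape (k, rows, cols); ``kinds`` entries are
    ``"continuous"`` or ``"multi-class"``; nodata is NaN.
    """

    layers: np.ndarray
    names: list[str]
    kinds: list[str]

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=np.float64)
        if self.layers.ndim != 3:
            raise RasterIOError("factor stack must be 3-D (layer, row, col)")
        if len(self.names) != self.layers.shape[0] or len(self.kinds) != self.layers.shape[0]:
            raise RasterIOError("names/kinds length must match layer count")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]


def _write_asc(path: Path, data: np.ndarray, nodata, fmt: str) -> None:
    rows, cols = data.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize 1.0\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def _read_asc(path: Path) -> tuple[np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterIOError(f"{path}: grid does not match header dimensions")
    return data, header.get("nodata_value", NODATA_INT)


def write_raster(raster: CategoricalRaster, path: str | Path, *, seed: int | None = None,
                 config_hash: str | None = None) -> None:
    """Write a categorical raster as ASCII grid + JSON sidecar."""
    path = Path(path)
    _write_asc(path, raster.grid, NODATA_INT, "%d")
    meta = {
        "kind": "categorical",
        "cell_area_ha": raster.cell_area_ha,
        "legend": {str(k): v for k, v in raster.legend.items()},
        "seed": seed,
        "config_hash": config_hash,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_raster(path: str | Path) -> CategoricalRaster:
    """Read a categorical raster written by :func:`write_raster`."""
    path = Path(path)
    data, nodata = _read_asc(path)
    if not np.allclose(data, np.round(data)):
        raise RasterIOError(f"{path}: float band cannot be read as categorical")
    grid = data.astype(np.int64)
    grid[grid == int(nodata)] = NODATA_INT
    meta_path = Path(str(path) + ".json")
    cell_area, legend = 1.0, dict(DEFAULT_LEGEND)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cell_area = float(meta.get("cell_area_ha", 1.0))
        legend = {int(k): v for k, v in meta.get("legend", {}).items()} or legend
    return CategoricalRaster(grid, cell_area, legend)


def write_stack(stack: FactorStack, directory: str | Path, *, seed: int | None = None,
                config_hash: str | None = None) -> None:
    """Write each factor layer as ``<name>.asc`` plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, layer in zip(stack.names, stack.layers):
        out = np.where(np.isnan(layer), NODATA_INT, layer)
        _write_asc(directory / f"{name}.asc", out, NODATA_INT, "%.8g")
    manifest = {
        "kind": "factor_stack",
        "names": stack.names,
        "kinds": stack.kinds,
        "seed": seed,
        "config_hash": config_hash,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_stack(directory: str | Path) -> FactorStack:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    layers = []
    for name in manifest["names"]:
        data, nodata = _read_asc(directory / f"{name}.asc")
        data[data == nodata] = np.nan
        layers.append(data)
    return FactorStack(np.stack(layers), manifest["names"], manifest["kinds"])
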