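"""Gridded prediction of seed bank responses and raster text I/O.

A :class:`PredictorGrid` is a stack of aligned lat/lon layers, one per model
covariate, cell-center registered at a configurable resolution (5 arcmin is
the reference resolution for global products; tests use coarse small-extent
grids).  Predictions are made by flattening the stack to a table, running
the fitted forest, and reshaping — the raster output is bit-identical to
the tabular prediction.  Cells with any missing covariate are nodata.

Rasters are stored as ESRI ASCII grids (plain text, ``.asc``): a lossless,
dependency-free format with full float precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import ForestFit

__all__ = [
    "PredictorGrid",
    "PredictionRaster",
    "predict_grid",
    "log10_display",
    "zonal_mean",
    "read_grid",
    "write_grid",
    "read_raster",
    "write_raster",
]

NODATA = -9999.0


@dataclass
class PredictorGrid:
    """Aligned covariate stack on a geographic (lon/lat) grid.

    ``lat`` holds cell-center latitudes (descending, row 0 = north),
    ``lon`` cell-center longitudes (ascending).  NaN marks nodata.
    """

    layers: dict[str, np.ndarray]
    lat: np.ndarray
    lon: np.ndarray
    resolution_arcmin: float

    def __post_init__(self):
        shape = (len(self.lat), len(self.lon))
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid shape {shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lat), len(self.lon))

    @property
    def mask(self) -> np.ndarray:
        """True where any layer is nodata."""
        m = np.zeros(self.shape, dtype=bool)
        for arr in self.layers.values():
            m |= np.isnan(arr)
        return m

    def abs_latitude_layer(self) -> np.ndarray:
        return np.tile(np.abs(self.lat)[:, None], (1, len(self.lon)))


@dataclass
class PredictionRaster:
    """Model output surface; NaN = nodata."""

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    resolution_arcmin: float
    metadata: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)


def predict_grid(fit: ForestFit, grid: PredictorGrid) -> PredictionRaster:
    """Cellwise forest prediction over the covariate stack.

    Identical to flattening the grid to a table, predicting, and reshaping.
    Cells where any required covariate is nodata stay nodata.  Raises when a
    model covariate has no layer, naming it.
    """
    missing = [p for p in fit.predictor_names if p not in grid.layers]
    if missing:
        raise ValueError(f"grid is missing predictor layers: {missing}")
    nrow, ncol = grid.shape
    cols = np.column_stack(
        [grid.layers[p].ravel() for p in fit.predictor_names]
    )
    valid = ~np.isnan(cols).any(axis=1)
    out = np.full(nrow * ncol, np.nan)
    if valid.any():
        out[valid] = fit.model.predict(cols[valid])
    return PredictionRaster(
        values=out.reshape(nrow, ncol),
        lat=grid.lat.copy(),
        lon=grid.lon.copy(),
        resolution_arcmin=grid.resolution_arcmin,
        metadata={
            "response": fit.response_name,
            "n_trees": fit.n_trees,
            "seed": fit.seed,
            "log10": False,
        },
    )


def log10_display(raster: PredictionRaster) -> PredictionRaster:
    """log10-transform positive cells for display; cells <= 0 become nodata."""
    vals = raster.values
    out = np.where(np.isfinite(vals) & (vals > 0), np.log10(np.maximum(vals, 1e-300)), np.nan)
    meta = dict(raster.metadata)
    meta["log10"] = True
    return PredictionRaster(
        values=out, lat=raster.lat.copy(), lon=raster.lon.copy(),
        resolution_arcmin=raster.resolution_arcmin, metadata=meta,
    )


def zonal_mean(raster: PredictionRaster) -> tuple[np.ndarray, np.ndarray]:
    """(latitudes, mean value per latitude row), rows with data only."""
    with np.errstate(invalid="ignore"):
        means = np.nanmean(
            np.where(np.isnan(raster.values), np.nan, raster.values), axis=1
        )
    ok = ~np.isnan(means)
    return raster.lat[ok], means[ok]


# ---------------------------------------------------------------- text I/O

def _header(lat: np.ndarray, lon: np.ndarray, cellsize_deg: float) -> dict:
    return {
        "ncols": len(lon),
        "nrows": len(lat),
        "xllcorner": float(lon[0] - cellsize_deg / 2),
        "yllcorner": float(lat[-1] - cellsize_deg / 2),
        "cellsize": cellsize_deg,
        "NODATA_value": NODATA,
    }


def write_raster(raster: PredictionRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid with full float precision."""
    _write_asc(
        Path(path), raster.values, raster.lat, raster.lon,
        raster.resolution_arcmin,
    )


def _write_asc(
    path: Path, values: np.ndarray, lat: np.ndarray, lon: np.ndarray,
    resolution_arcmin: float,
) -> None:
    cellsize = resolution_arcmin / 60.0
    hdr = _header(lat, lon, cellsize)
    with open(path, "w") as fh:
        for key, val in hdr.items():
            fh.write(f"{key} {val!r}\n" if isinstance(val, float) else f"{key} {val}\n")
        out = np.where(np.isnan(values), NODATA, values)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_asc(path: Path) -> tuple[np.ndarray, dict]:
    hdr: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0][0].isalpha():
                hdr[parts[0]] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows"):
        hdr[key] = int(hdr[key])
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (hdr["nrows"], hdr["ncols"]):
        raise ValueError(f"{path}: data shape {arr.shape} does not match header")
    arr[arr == hdr.get("NODATA_value", NODATA)] = np.nan
    return arr, hdr


def _axes_from_header(hdr: dict) -> tuple[np.ndarray, np.ndarray, float]:
    cs = float(hdr["cellsize"])
    lon = hdr["xllcorner"] + cs / 2 + cs * np.arange(hdr["ncols"])
    top = hdr["yllcorner"] + cs * hdr["nrows"]
    lat = top - cs / 2 - cs * np.arange(hdr["nrows"])
    return lat, lon, cs * 60.0


def read_raster(path: str | Path) -> PredictionRaster:
    arr, hdr = _read_asc(Path(path))
    lat, lon, res = _axes_from_header(hdr)
    return PredictionRaster(
        values=arr, lat=lat, lon=lon, resolution_arcmin=res, metadata={}
    )


def write_grid(grid: PredictorGrid, directory: str | Path) -> list[Path]:
    """One ``<layer>.asc`` per covariate (``/`` in names replaced by ``_``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in grid.layers.items():
        p = directory / f"{name.replace('/', '_')}.asc"
        _write_asc(p, arr, grid.lat, grid.lon, grid.resolution_arcmin)
        paths.append(p)
    return paths


def read_grid(paths: Iterable[str | Path] | str | Path) -> PredictorGrid:
    """Read aligned ``.asc`` layers (an iterable of files or a directory).

    Layer names come from file stems.  Misaligned layers raise with a
    per-layer extent report.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.asc"))
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster layers to read")
    layers: dict[str, np.ndarray] = {}
    headers: dict[str, dict] = {}
    for p in paths:
        arr, hdr = _read_asc(p)
        layers[p.stem] = arr
        headers[p.stem] = hdr
    ref_name = paths[0].stem
    ref = headers[ref_name]
    bad = {
        name: hdr
        for name, hdr in headers.items()
        if any(
            not math.isclose(float(hdr[k]), float(ref[k]), rel_tol=0, abs_tol=1e-9)
            for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
        )
    }
    if bad:
        lines = [
            f"  {name}: ncols={h['ncols']} nrows={h['nrows']} "
            f"xll={h['xllcorner']} yll={h['yllcorner']} cellsize={h['cellsize']}"
            for name, h in {ref_name: ref, **bad}.items()
        ]
        raise ValueError("misaligned raster layers:\n" + "\n".join(lines))
    lat, lon, res = _axes_from_header(ref)
    return PredictorGrid(layers=layers, lat=lat, lon=lon, resolution_arcmin=res)
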