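"""Grid input/output: CF-style netCDF and ESRI ASCII raster dialects.

netCDF files are written through xarray's scipy backend (classic netCDF-3),
with cell-center ``lat``/``lon`` coordinates and CF attributes; edges are
reconstructed from the uniform center spacing on read. ESRI ASCII grids are
plain text with full float precision so round trips are bit-faithful.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from .geomap import Grid

__all__ = ["write_netcdf", "read_netcdf", "write_esri_ascii", "read_esri_ascii"]


def _edges_from_centers(centers: np.ndarray) -> np.ndarray:
    steps = np.diff(centers)
    if centers.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("grid centers must be uniform to reconstruct edges")
    half = steps[0] / 2.0
    return np.concatenate([centers - half, [centers[-1] + half]])


def write_netcdf(grid: Grid, path: str | Path, name: str = "value") -> None:
    """Write a grid as a CF-style netCDF file (classic format)."""
    ds = xr.Dataset(
        {name: (("lat", "lon"), grid.values, {"units": grid.units})},
        coords={
            "lat": ("lat", grid.lat_centers, {"units": "degrees_north", "standard_name": "latitude"}),
            "lon": ("lon", grid.lon_centers, {"units": "degrees_east", "standard_name": "longitude"}),
        },
        attrs={"Conventions": "CF-1.8", **{str(k): str(v) for k, v in grid.metadata.items()}},
    )
    ds.to_netcdf(Path(path), engine="scipy")


def read_netcdf(path: str | Path, name: str | None = None) -> Grid:
    """Read a grid written by :func:`write_netcdf`.

    Without an explicit ``name``, the file must contain exactly one data
    variable.
    """
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        if name is None:
            data_vars = list(ds.data_vars)
            if len(data_vars) != 1:
                raise ValueError(
                    f"expected one data variable, found {data_vars}; pass name="
                )
            name = data_vars[0]
        da = ds[name]
        values = da.values.copy()
        units = str(da.attrs.get("units", ""))
        lat_edges = _edges_from_centers(ds["lat"].values)
        lon_edges = _edges_from_centers(ds["lon"].values)
    return Grid(lat_edges=lat_edges, lon_edges=lon_edges, values=values, units=units)


def write_esri_ascii(grid: Grid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a grid as an ESRI ASCII raster (requires square cells)."""
    d_lat = np.diff(grid.lat_edges)
    d_lon = np.diff(grid.lon_edges)
    cell = d_lat[0]
    if not (np.allclose(d_lat, cell) and np.allclose(d_lon, cell)):
        raise ValueError("ESRI ASCII requires uniform square cells")
    nrows, ncols = grid.values.shape
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {float(grid.lon_edges[0])!r}",
        f"yllcorner {float(grid.lat_edges[0])!r}",
        f"cellsize {float(cell)!r}",
        f"NODATA_value {float(nodata)!r}",
    ]
    # ESRI rasters run north to south
    body = grid.values[::-1]
    for row in body:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_esri_ascii(path: str | Path, units: str = "") -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_esri_ascii`."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    values = np.array(
        [[float(v) for v in line.split()] for line in text[i : i + nrows]]
    )
    if values.shape != (nrows, ncols):
        raise ValueError("ESRI ASCII body does not match header dimensions")
    lat_edges = header["yllcorner"] + cell * np.arange(nrows + 1)
    lon_edges = header["xllcorner"] + cell * np.arange(ncols + 1)
    return Grid(
        lat_edges=lat_edges, lon_edges=lon_edges, values=values[::-1], units=units
    )
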