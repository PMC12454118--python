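"""Readers and writers for the pipeline's file formats.

Gridded layers travel as CF-style NetCDF (classic format) or ESRI ASCII
grid; both round-trip the grid spec exactly and carry an explicit nodata
value.  Tabular inputs (water contents, bilateral trade, zone coverage)
are plain CSV.  Country zones may alternatively be supplied as GeoJSON
polygons, from which fractional cell coverage is computed by exact
cell-polygon intersection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec, Layer
from .trade import TradeTable
from .zonal import CountryZones

NODATA = -9999.0


# ---------------------------------------------------------------- NetCDF

def write_netcdf(layer: Layer, path: str | Path, var: str = "value") -> None:
    """Write a single-band CF-style NetCDF (classic) file."""
    spec = layer.spec
    data = layer.filled(np.nan)
    ds = xr.Dataset(
        {var: (("lat", "lon"), data)},
        coords={"lat": spec.lat_centers(), "lon": spec.lon_centers()},
    )
    ds["lat"].attrs = {"units": "degrees_north", "standard_name": "latitude"}
    ds["lon"].attrs = {"units": "degrees_east", "standard_name": "longitude"}
    ds[var].attrs["units"] = layer.units
    ds.attrs["cell_size"] = spec.cell_size
    ds.to_netcdf(
        path,
        engine="scipy",
        encoding={var: {"_FillValue": NODATA}},
    )


def read_netcdf(path: str | Path, var: str = "value") -> Layer:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds[var].load()
        lat = da["lat"].values
        lon = da["lon"].values
        units = str(da.attrs.get("units", ""))
        values = np.asarray(da.values, dtype=float)
        cell_attr = ds.attrs.get("cell_size")
    if lat.size > 1 and lat[0] < lat[-1]:  # stored south-up; flip to row0-north
        lat = lat[::-1]
        values = values[::-1, :]
    cell = float(cell_attr if cell_attr is not None else abs(lat[1] - lat[0]))
    spec = GridSpec(
        n_rows=lat.size,
        n_cols=lon.size,
        cell_size=cell,
        origin_lon=float(lon[0] - cell / 2),
        origin_lat=float(lat[0] + cell / 2),
    )
    return Layer(spec, values, ~np.isfinite(values), units)


# ------------------------------------------------------------ ASCII grid

def write_ascii_grid(layer: Layer, path: str | Path) -> None:
    """Write an ESRI ASCII grid (text raster; unit tag not preserved)."""
    spec = layer.spec
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_lon!r}\n"
        f"yllcorner {spec.lat_min!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    data = layer.filled(NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, units: str = "") -> Layer:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            k, v = fh.readline().split()
            head[k.lower()] = float(v)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(head["nrows"]), int(head["ncols"])
    values = values.reshape(n_rows, n_cols)
    cell = head["cellsize"]
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=head["xllcorner"],
        origin_lat=head["yllcorner"] + n_rows * cell,
    )
    nodata = head["nodata_value"]
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    return Layer(spec, values, mask, units)


# ----------------------------------------------------------------- CSVs

def read_water_table(path: str | Path, required: list[str] | None = None) -> dict[str, float]:
    """Water-content table (crop_id, water_pct) as a dict.

    With ``required``, unknown crops raise a KeyError listing every missing
    id at once.
    """
    df = pd.read_csv(path)
    missing_cols = {"crop_id", "water_pct"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"water table missing columns: {sorted(missing_cols)}")
    table = dict(zip(df["crop_id"].astype(str), df["water_pct"].astype(float)))
    if required is not None:
        absent = sorted(set(required) - set(table))
        if absent:
            raise KeyError(f"water content missing for crops: {absent}")
    return table


def read_trade_csv(path: str | Path) -> TradeTable:
    return TradeTable(pd.read_csv(path))


# ----------------------------------------------------------------- Zones

def write_zone_labels(
    spec: GridSpec, labels: np.ndarray, path: str | Path
) -> None:
    """Write all-or-nothing zone labels as long-format CSV
    (country_id, row, col, coverage)."""
    rows = []
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            cid = labels[r, c]
            if cid:
                rows.append({"country_id": cid, "row": r, "col": c, "coverage": 1.0})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_zones_csv(path: str | Path, spec: GridSpec) -> CountryZones:
    """Zone coverage from long-format CSV (country_id, row, col, coverage)."""
    df = pd.read_csv(path)
    need = {"country_id", "row", "col", "coverage"}
    if not need <= set(df.columns):
        raise ValueError(f"zones CSV needs columns {sorted(need)}")
    cells = {}
    for cid, grp in df.groupby("country_id"):
        idx = (grp["row"].to_numpy(np.intp) * spec.n_cols
               + grp["col"].to_numpy(np.intp))
        cells[str(cid)] = (idx, grp["coverage"].to_numpy(float))
    return CountryZones(spec, cells)


def read_zones_geojson(
    path: str | Path, spec: GridSpec, id_property: str = "country_id"
) -> CountryZones:
    """Country zones from a GeoJSON FeatureCollection of polygons.

    Coverage fractions come from exact cell-polygon intersection areas.
    """
    from shapely.geometry import shape

    gj = json.loads(Path(path).read_text())
    geoms = {}
    for feat in gj["features"]:
        cid = str(feat["properties"][id_property])
        geoms[cid] = shape(feat["geometry"])
    return CountryZones.from_polygons(spec, geoms)
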