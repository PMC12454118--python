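"""Equal-angle raster grids: data model, cell-area geometry and resampling.

All surfaces in this package live on a corner-registered latitude-longitude
lattice with square angular cells, row 0 northmost.  Values are located at
cell centres for interpolation purposes.  Cell physical areas follow the
spherical-band formula on the authalic sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Authalic Earth radius in metres (sphere of equal surface area to the
#: WGS84 ellipsoid); sub-0.3 % area error versus the ellipsoid.
AUTHALIC_RADIUS_M = 6_371_007.2

_SQM_PER_HA = 1e4


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an equal-angle grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; row 0 is the northmost row.
    cell_size : float
        Angular cell size in degrees (square cells).
    origin_lon, origin_lat : float
        Longitude / latitude of the north-west *corner* of cell (0, 0).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float = -180.0
    origin_lat: float = 90.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows * self.cell_size > 180.0 + 1e-9:
            raise ValueError("grid spans more than 180 degrees of latitude")
        if self.n_cols * self.cell_size > 360.0 + 1e-9:
            raise ValueError("grid spans more than 360 degrees of longitude")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lat_edges(self) -> np.ndarray:
        """Latitudes of row edges, north to south, length n_rows + 1."""
        return self.origin_lat - self.cell_size * np.arange(self.n_rows + 1)

    def lon_edges(self) -> np.ndarray:
        return self.origin_lon + self.cell_size * np.arange(self.n_cols + 1)

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - self.cell_size * (np.arange(self.n_rows) + 0.5)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + self.cell_size * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_min(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @classmethod
    def global_5arcmin(cls) -> "GridSpec":
        """The 5-arcmin (0.0833333 degree) global analysis grid."""
        return cls(n_rows=2160, n_cols=4320, cell_size=1.0 / 12.0)


@dataclass
class Layer:
    """A 2-D gridded field: values, grid geometry, missing-data mask, units.

    ``mask`` is True where data are *missing*.  Unmasked values must be
    finite; every operation either preserves the unit tag or transforms it
    explicitly.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise ValueError("mask shape does not match grid shape")
            self.mask = self.mask | ~np.isfinite(self.values)

    def copy(self) -> "Layer":
        return Layer(self.spec, self.values.copy(), self.mask.copy(), self.units)

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Values with masked cells replaced by ``fill``."""
        out = self.values.copy()
        out[self.mask] = fill
        return out

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def unmasked_sum(self) -> float:
        return float(self.values[~self.mask].sum())


def cell_area(spec: GridSpec) -> Layer:
    """Physical area of every cell in hectares.

    Uses the spherical band formula A = R^2 * dlambda * (sin(lat_top) -
    sin(lat_bot)) on the authalic sphere.  Area is constant within a row and
    strictly decreases away from the equator.
    """
    edges = np.radians(spec.lat_edges())
    dlam = np.radians(spec.cell_size)
    band = AUTHALIC_RADIUS_M**2 * dlam * (np.sin(edges[:-1]) - np.sin(edges[1:]))
    area_ha = band / _SQM_PER_HA  # m^2 -> ha
    values = np.repeat(area_ha[:, None], spec.n_cols, axis=1)
    return Layer(spec, values, np.zeros(spec.shape, dtype=bool), units="ha")


def _fractional_index(target: GridSpec, source: GridSpec):
    """Fractional (row, col) coordinates of target cell centres in the
    source's centre-based index space."""
    src_lat0 = source.lat_centers()[0]
    src_lon0 = source.lon_centers()[0]
    fy = (src_lat0 - target.lat_centers()) / source.cell_size  # row axis points south
    fx = (target.lon_centers() - src_lon0) / source.cell_size
    return fy, fx


def _check_overlap(source: GridSpec, target: GridSpec) -> None:
    lat_overlap = (
        min(source.origin_lat, target.origin_lat)
        - max(source.lat_min, target.lat_min)
    )
    lon_overlap = (
        min(source.lon_max, target.lon_max)
        - max(source.origin_lon, target.origin_lon)
    )
    if lat_overlap <= 0 or lon_overlap <= 0:
        raise ValueError("source and target grids have disjoint extents")


def align_to_grid(layer: Layer, target: GridSpec, method: str = "bilinear") -> Layer:
    """Resample a layer onto ``target`` by interpolating at its cell centres.

    ``method`` is ``"bilinear"`` (for continuous surfaces) or ``"nearest"``.
    Bilinear stencils that are partially masked drop the masked neighbours
    and renormalise the remaining weights; a target cell is masked only when
    the whole stencil is masked.  Target centres outside the source-centre
    hull take the nearest edge value (constant extrapolation), so output
    never overshoots the stencil extrema.  The unit tag is unchanged.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method: {method!r}")
    source = layer.spec
    if target == source:
        return layer.copy()
    _check_overlap(source, target)

    fy, fx = _fractional_index(target, source)

    if method == "nearest":
        iy = np.clip(np.rint(fy).astype(int), 0, source.n_rows - 1)
        ix = np.clip(np.rint(fx).astype(int), 0, source.n_cols - 1)
        vals = layer.values[np.ix_(iy, ix)]
        mask = layer.mask[np.ix_(iy, ix)]
        return Layer(target, vals, mask, layer.units)

    # bilinear: clamp the base index so the stencil stays on-grid, then clamp
    # the interpolation weights into [0, 1] (constant extrapolation at edges)
    y0 = np.clip(np.floor(fy).astype(int), 0, max(source.n_rows - 2, 0))
    x0 = np.clip(np.floor(fx).astype(int), 0, max(source.n_cols - 2, 0))
    ty = np.clip(fy - y0, 0.0, 1.0)
    tx = np.clip(fx - x0, 0.0, 1.0)
    y1 = np.minimum(y0 + 1, source.n_rows - 1)
    x1 = np.minimum(x0 + 1, source.n_cols - 1)

    TY, TX = np.meshgrid(ty, tx, indexing="ij")
    vals = np.zeros(target.shape)
    wsum = np.zeros(target.shape)
    corners = (
        (y0, x0, (1 - TY) * (1 - TX)),
        (y0, x1, (1 - TY) * TX),
        (y1, x0, TY * (1 - TX)),
        (y1, x1, TY * TX),
    )
    for ys, xs, w in corners:
        v = layer.values[np.ix_(ys, xs)]
        m = layer.mask[np.ix_(ys, xs)]
        w_eff = np.where(m, 0.0, w)
        vals += w_eff * np.where(m, 0.0, v)
        wsum += w_eff
    out_mask = wsum <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(out_mask, np.nan, vals / np.where(out_mask, 1.0, wsum))
    return Layer(target, vals, out_mask, layer.units)


def totals_change(before: Layer, after: Layer) -> dict:
    """Pre/post resampling totals and their relative change.

    Bilinear resampling is not mass conserving; callers that care about
    conserved totals should log this record rather than renormalise.
    """
    pre = before.unmasked_sum()
    post = after.unmasked_sum()
    rel = (post - pre) / pre if pre != 0 else np.nan
    return {"total_before": pre, "total_after": post, "relative_change": rel}
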