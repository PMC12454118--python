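"""Country-level aggregation with fractional cell coverage.

Zonal statistics here follow the exact-extraction convention: each country
is a set of (cell, coverage fraction) pairs, and country totals weight each
cell's value by the fraction of the cell the country covers.  The country
mean BP is production-weighted, so the national figure assumes exports are
sourced proportionally to where production is largest:

    BP_ci = sum_l f_il * P_l * BP_l / sum_l f_il * P_l

and the national production pressure BP_prod = BP_ci * P_ci collapses, by
construction, to the country-summed ASR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import GridSpec, Layer
from .pressure import CropData, RichnessLayer, compute_asr, compute_bp_cell, compute_production


@dataclass
class CountryZones:
    """Mapping from country ids to grid cells with coverage fractions.

    ``cells`` maps each country id to ``(flat_indices, coverage)`` arrays;
    coverage fractions lie in (0, 1] and sum to at most 1 per cell across
    countries.
    """

    spec: GridSpec
    cells: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        total = np.zeros(self.spec.n_cells)
        for cid, (idx, cov) in self.cells.items():
            idx = np.asarray(idx, dtype=np.intp)
            cov = np.asarray(cov, dtype=float)
            if idx.size == 0:
                raise ValueError(f"country {cid!r} has no cells")
            if idx.min() < 0 or idx.max() >= self.spec.n_cells:
                raise ValueError(f"country {cid!r}: cell index out of grid")
            if np.any(cov <= 0) or np.any(cov > 1 + 1e-9):
                raise ValueError(f"country {cid!r}: coverage outside (0, 1]")
            self.cells[cid] = (idx, cov)
            np.add.at(total, idx, cov)
        if np.any(total > 1 + 1e-6):
            raise ValueError("summed coverage exceeds 1 in some cell")

    @property
    def country_ids(self) -> list[str]:
        return sorted(self.cells)

    @classmethod
    def from_labels(
        cls, spec: GridSpec, labels: np.ndarray, exclude: Iterable[str] = ()
    ) -> "CountryZones":
        """All-or-nothing zones from a labelled raster (one id per cell).

        Cells labelled with an empty string or an id in ``exclude`` belong
        to no country.
        """
        labels = np.asarray(labels)
        if labels.shape != spec.shape:
            raise ValueError("label raster shape does not match grid")
        flat = labels.ravel()
        skip = set(exclude) | {""}
        cells = {}
        for cid in np.unique(flat):
            scid = str(cid)
            if scid in skip:
                continue
            idx = np.flatnonzero(flat == cid)
            cells[scid] = (idx, np.ones(idx.size))
        return cls(spec, cells)

    @classmethod
    def from_polygons(
        cls,
        spec: GridSpec,
        geoms: Mapping[str, object],
        exclude: Iterable[str] = (),
    ) -> "CountryZones":
        """Exact cell-polygon intersection coverage from country polygons.

        ``geoms`` maps country ids to shapely geometries in lon/lat degrees.
        The coverage fraction is the intersected angular area over the cell's
        angular area, the convention used by exact-extraction zonal tools.
        """
        from shapely.geometry import box
        from shapely.prepared import prep

        lat_e = spec.lat_edges()
        lon_e = spec.lon_edges()
        cell_area_deg2 = spec.cell_size**2
        skip = set(exclude)
        cells = {}
        for cid, geom in geoms.items():
            if cid in skip:
                continue
            prepared = prep(geom)
            minx, miny, maxx, maxy = geom.bounds
            c0 = max(int(np.floor((minx - spec.origin_lon) / spec.cell_size)), 0)
            c1 = min(
                int(np.ceil((maxx - spec.origin_lon) / spec.cell_size)), spec.n_cols
            )
            r0 = max(int(np.floor((spec.origin_lat - maxy) / spec.cell_size)), 0)
            r1 = min(
                int(np.ceil((spec.origin_lat - miny) / spec.cell_size)), spec.n_rows
            )
            idx_list, cov_list = [], []
            for r in range(r0, r1):
                for c in range(c0, c1):
                    cell = box(lon_e[c], lat_e[r + 1], lon_e[c + 1], lat_e[r])
                    if not prepared.intersects(cell):
                        continue
                    if prepared.contains_properly(cell):
                        frac = 1.0
                    else:
                        frac = cell.intersection(geom).area / cell_area_deg2
                    if frac > 1e-12:
                        idx_list.append(r * spec.n_cols + c)
                        cov_list.append(min(frac, 1.0))
            if idx_list:
                cells[str(cid)] = (np.array(idx_list), np.array(cov_list))
        return cls(spec, cells)


def country_sum(layer: Layer, zones: CountryZones) -> pd.Series:
    """Coverage-weighted country totals of a layer; masked cells add 0."""
    if layer.spec != zones.spec:
        raise ValueError("layer and zones are on different grids")
    flat = layer.filled(0.0).ravel()
    out = {
        cid: float(np.dot(flat[idx], cov))
        for cid, (idx, cov) in zones.cells.items()
    }
    return pd.Series(out, dtype=float).sort_index()


def country_bp(bp: Layer, production: Layer, zones: CountryZones) -> pd.Series:
    """Production-weighted mean BP per country.

    Cells masked in the BP layer (zero production) carry zero weight and are
    excluded from both numerator and denominator.  A country whose weighted
    production is zero gets NaN, never 0: "no production" is not "no
    pressure".
    """
    if bp.spec != zones.spec or production.spec != zones.spec:
        raise ValueError("inputs and zones are on different grids")
    ok = ~bp.mask
    w_flat = np.where(ok, production.filled(0.0), 0.0).ravel()
    bp_flat = np.where(ok, bp.values, 0.0).ravel()
    out = {}
    for cid, (idx, cov) in zones.cells.items():
        w = w_flat[idx] * cov
        denom = w.sum()
        out[cid] = float(np.dot(w, bp_flat[idx]) / denom) if denom > 0 else np.nan
    return pd.Series(out, dtype=float).sort_index()


def bp_prod(bp_mean: float, production_total: float) -> float:
    """National production pressure BP_prod = BP_ci x P_ci (species*ha).

    Equals the country-summed ASR when the coverage weights match, since
    sum P * (ASR / P) = sum ASR.  Missing BP (no production) gives NaN.
    """
    if np.isnan(bp_mean):
        return np.nan
    return bp_mean * production_total


@dataclass
class CountryCropMetrics:
    """Per (country, crop) aggregates."""

    country_id: str
    crop_id: str
    production_total: float
    asr_total: float
    bp_mean: float
    bp_prod: float


def country_crop_metrics(
    crops: Iterable[CropData],
    rich: RichnessLayer,
    zones: CountryZones,
    dry: bool = True,
    zero_tol: float = 1e-9,
) -> pd.DataFrame:
    """Full per-(country, crop) metrics table.

    Columns: country_id, crop_id, production_total (t), asr_total
    (species*ha), bp_mean (species*ha/t), bp_prod (species*ha).
    """
    rows = []
    for crop in crops:
        production = compute_production(crop, dry=dry)
        asr = compute_asr(crop, rich)
        bp = compute_bp_cell(crop, rich, production, zero_tol=zero_tol)
        p_tot = country_sum(production, zones)
        asr_tot = country_sum(asr, zones)
        bp_mean = country_bp(bp, production, zones)
        for cid in zones.country_ids:
            rows.append(
                {
                    "country_id": cid,
                    "crop_id": crop.crop_id,
                    "production_total": p_tot[cid],
                    "asr_total": asr_tot[cid],
                    "bp_mean": bp_mean[cid],
                    "bp_prod": bp_prod(bp_mean[cid], p_tot[cid]),
                }
            )
    return pd.DataFrame(rows).sort_values(["country_id", "crop_id"]).reset_index(
        drop=True
    )


RANKABLE_METRICS = ("bp_mean", "production_total", "asr_total", "bp_prod")


def rank_entities(table: pd.DataFrame, by: str, entity: str = "crop_id") -> pd.DataFrame:
    """Dense descending ranks of entities by a metric (rank 1 = largest).

    Ties share a dense rank; rows are ordered by rank then entity id, so
    tied entities appear in lexicographic order.  NaN metrics are dropped.
    """
    if by not in table.columns:
        raise ValueError(f"unknown metric {by!r}; have {list(table.columns)}")
    out = table[[entity, by]].dropna(subset=[by]).copy()
    out["rank"] = out[by].rank(method="dense", ascending=False).astype(int)
    return out.sort_values(["rank", entity]).reset_index(drop=True)
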