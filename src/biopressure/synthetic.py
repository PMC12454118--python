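"""Seeded synthetic worlds with analytically known ground truth.

The generator emulates the statistical shape of the real inputs the
pipeline is built for: sparse non-negative harvested-area surfaces bounded
by cell area, smooth positive yield surfaces, a spatially autocorrelated
integer species-richness map, a contiguous partition of cells into
countries, per-crop water contents and sparse non-negative bilateral trade
flows whose origins actually grow the crop.  Everything is deterministic
for a fixed seed: the root seed fans out to named substreams so adding a
field never perturbs existing draws.

:func:`generate_known_bp_world` builds worlds whose true country-level BP
values are prescribed exactly (uniform yield, per-country uniform richness
= target x yield), for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, Layer, cell_area
from .pressure import CropData, RichnessLayer
from .trade import TradeTable
from .zonal import CountryZones

_SUBSTREAMS = ("richness", "crops", "countries", "trade", "water")


@dataclass
class WorldConfig:
    """Configuration of a synthetic world.

    Defaults give a coarse 24 x 48 global grid (7.5 degree cells), three
    contiguous countries, four crops with 30 % of cells cultivated, yields
    of 1-20 t/ha fresh weight and water contents of 70-95 % — the ranges
    typical of fruit and vegetable crops.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(24, 48, 7.5))
    n_countries: int = 3
    n_crops: int = 4
    richness_range: tuple[int, int] = (5, 400)
    crop_sparsity: float = 0.3
    yield_range: tuple[float, float] = (1.0, 20.0)
    water_range: tuple[float, float] = (70.0, 95.0)
    trade_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("richness_range", self.richness_range),
            ("yield_range", self.yield_range),
            ("water_range", self.water_range),
        ):
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be ordered and non-negative")
        if not 0 <= self.crop_sparsity <= 1:
            raise ValueError("crop_sparsity must be in [0, 1]")
        if not 0 <= self.trade_density <= 1:
            raise ValueError("trade_density must be in [0, 1]")
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")
        if self.n_crops < 1:
            raise ValueError("need at least 1 crop")
        if self.n_countries > self.grid.n_cells:
            raise ValueError("more countries than grid cells")


@dataclass
class World:
    """A complete synthetic study system."""

    config: WorldConfig
    crops: list[CropData]
    richness: RichnessLayer
    zones: CountryZones
    water_table: pd.DataFrame  # columns crop_id, water_pct
    trade: TradeTable


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _smooth_field(rng: np.random.Generator, shape, sigma: float = 2.0) -> np.ndarray:
    """Spatially autocorrelated field in [0, 1]: smoothed white noise,
    min-max rescaled.  Longitude wraps."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    lo, hi = sm.min(), sm.max()
    if hi == lo:
        return np.full(shape, 0.5)
    return (sm - lo) / (hi - lo)


def _country_ids(n: int) -> list[str]:
    """ISO alpha-3 style synthetic ids: AAA, AAB, AAC, ..."""
    ids = []
    for k in range(n):
        a, rem = divmod(k, 26 * 26)
        b, c = divmod(rem, 26)
        ids.append(chr(65 + a) + chr(65 + b) + chr(65 + c))
    return ids


def _grow_countries(
    rng: np.random.Generator, spec: GridSpec, n_countries: int
) -> np.ndarray:
    """Contiguous partition of the grid by frontier accretion from random
    seed cells; at each step the lowest-id country claims one unassigned
    cell adjacent (4-neighbour, longitude wrapping) to its territory."""
    n_rows, n_cols = spec.shape
    labels = np.full(spec.shape, -1, dtype=int)
    seeds = rng.choice(spec.n_cells, size=n_countries, replace=False)
    frontiers: list[list[tuple[int, int]]] = []
    for k, s in enumerate(seeds):
        r, c = divmod(int(s), n_cols)
        labels[r, c] = k
        frontiers.append([(r, c)])
    remaining = spec.n_cells - n_countries
    while remaining > 0:
        progressed = False
        for k in range(n_countries):
            claim = None
            new_frontier = []
            for r, c in frontiers[k]:
                nbrs = [
                    (r - 1, c),
                    (r + 1, c),
                    (r, (c - 1) % n_cols),
                    (r, (c + 1) % n_cols),
                ]
                open_nbrs = [
                    (rr, cc)
                    for rr, cc in nbrs
                    if 0 <= rr < n_rows and labels[rr, cc] == -1
                ]
                if open_nbrs:
                    new_frontier.append((r, c))
                    if claim is None:
                        # deterministic: first open neighbour in scan order
                        claim = open_nbrs[0]
            frontiers[k] = new_frontier
            if claim is not None:
                labels[claim] = k
                frontiers[k].append(claim)
                remaining -= 1
                progressed = True
                if remaining == 0:
                    break
        if not progressed:  # isolated pockets: assign to lowest country id
            for idx in np.flatnonzero(labels.ravel() == -1):
                labels.ravel()[idx] = 0
            remaining = 0
    return labels


def generate_world(config: WorldConfig) -> World:
    """Generate a complete, self-consistent world from a seeded config."""
    spec = config.grid
    rngs = _substreams(config.seed)

    # richness: smoothed noise mapped into richness_range, rounded
    lo, hi = config.richness_range
    sr = np.rint(lo + _smooth_field(rngs["richness"], spec.shape) * (hi - lo))
    richness = RichnessLayer(
        Layer(spec, sr, np.zeros(spec.shape, bool), units="species")
    )

    # countries: contiguous partition, full coverage
    labels_int = _grow_countries(rngs["countries"], spec, config.n_countries)
    ids = _country_ids(config.n_countries)
    labels = np.array(ids, dtype=object)[labels_int]
    zones = CountryZones.from_labels(spec, labels)

    # crops: sparse HA bounded by cell area; smooth positive yields
    area = cell_area(spec).values
    crop_rng = rngs["crops"]
    water_rng = rngs["water"]
    ylo, yhi = config.yield_range
    wlo, whi = config.water_range
    crops, water_rows = [], []
    for k in range(config.n_crops):
        crop_id = f"crop{k:02d}"
        grown = crop_rng.random(spec.shape) < config.crop_sparsity
        ha_frac = crop_rng.random(spec.shape) * grown
        ha = Layer(spec, ha_frac * area, np.zeros(spec.shape, bool), units="ha")
        yld_vals = ylo + _smooth_field(crop_rng, spec.shape) * (yhi - ylo)
        yld = Layer(spec, yld_vals, np.zeros(spec.shape, bool), units="t ha-1")
        water = float(water_rng.uniform(wlo, whi))
        crops.append(CropData(crop_id, ha, yld, water))
        water_rows.append({"crop_id": crop_id, "water_pct": water})
    water_table = pd.DataFrame(water_rows)

    trade = _generate_trade(rngs["trade"], config, crops, zones)
    return World(config, crops, richness, zones, water_table, trade)


def _generate_trade(
    rng: np.random.Generator,
    config: WorldConfig,
    crops: list[CropData],
    zones: CountryZones,
) -> TradeTable:
    """Sparse flows; origins restricted to producers, and total exports per
    (origin, crop) kept below fresh production so clamping never fires."""
    from .pressure import compute_production
    from .zonal import country_sum

    ids = zones.country_ids
    rows = []
    for crop in crops:
        prod = country_sum(compute_production(crop, dry=False), zones)
        producers = [c for c in ids if prod[c] > 0]
        for origin in producers:
            dests = [d for d in ids if d != origin]
            chosen = [d for d in dests if rng.random() < config.trade_density]
            if not chosen:
                continue
            # export at most 80 % of fresh production, split across partners
            exportable = prod[origin] * 0.8 * rng.random()
            shares = rng.random(len(chosen))
            shares /= shares.sum()
            for d, s in zip(chosen, shares):
                rows.append(
                    {
                        "origin": origin,
                        "destination": d,
                        "crop_id": crop.crop_id,
                        "tonnes": float(exportable * s),
                    }
                )
    flows = pd.DataFrame(rows, columns=["origin", "destination", "crop_id", "tonnes"])
    return TradeTable(flows)


def generate_known_bp_world(
    target_bp: dict[str, float],
    config: WorldConfig | None = None,
    uniform_yield: float = 2.0,
    integer_richness: bool = False,
) -> World:
    """World whose true country BP values equal ``target_bp`` exactly.

    Construction: uniform yield y everywhere, zero water content, and
    richness constant within each country at SR_i = target_i * y.  Then at
    every cultivated cell BP = SR / y = target_i, so the production-weighted
    country mean is the target regardless of the harvested-area pattern.

    With ``integer_richness=True`` a target whose implied richness is not an
    integer raises; by default real-valued richness is accepted (downstream
    never needs integrality).
    """
    if config is None:
        config = WorldConfig(n_countries=len(target_bp))
    if len(target_bp) != config.n_countries:
        raise ValueError("one BP target per country required")
    if any(v <= 0 for v in target_bp.values()):
        raise ValueError("BP targets must be positive")

    base = generate_world(config)
    id_map = dict(zip(base.zones.country_ids, sorted(target_bp)))
    spec = config.grid

    sr = np.zeros(spec.shape)
    for cid, (idx, _) in base.zones.cells.items():
        target = target_bp[id_map[cid]]
        implied = target * uniform_yield
        if integer_richness and abs(implied - round(implied)) > 1e-12:
            raise ValueError(
                f"target {target} implies non-integer richness {implied}"
            )
        sr.ravel()[idx] = implied
    richness = RichnessLayer(
        Layer(spec, sr, np.zeros(spec.shape, bool), units="species")
    )

    crops = []
    water_rows = []
    for crop in base.crops:
        yld = Layer(
            spec, np.full(spec.shape, uniform_yield), np.zeros(spec.shape, bool),
            units="t ha-1",
        )
        crops.append(CropData(crop.crop_id, crop.harvested_area, yld, 0.0))
        water_rows.append({"crop_id": crop.crop_id, "water_pct": 0.0})

    # relabel zones with the target's country ids
    cells = {id_map[cid]: arrs for cid, arrs in base.zones.cells.items()}
    zones = CountryZones(spec, cells)
    flows = base.trade.flows.copy()
    flows["origin"] = flows["origin"].map(id_map)
    flows["destination"] = flows["destination"].map(id_map)
    return World(
        config, crops, richness, zones, pd.DataFrame(water_rows), TradeTable(flows)
    )


def write_fixture(world: World, outdir: str | Path, fmt: str = "netcdf") -> Path:
    """Write a complete fixture directory: per-crop layers, richness, zone
    labels, water CSV, trade CSV and a manifest recording config + seed."""
    from . import io as bio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"netcdf": ".nc", "ascii": ".asc"}[fmt]
    write = bio.write_netcdf if fmt == "netcdf" else bio.write_ascii_grid

    for crop in world.crops:
        write(crop.harvested_area, outdir / f"{crop.crop_id}_harvested_area{ext}")
        write(crop.yield_, outdir / f"{crop.crop_id}_yield{ext}")
    write(world.richness.richness, outdir / f"richness{ext}")

    labels = np.full(world.config.grid.shape, "", dtype=object)
    for cid, (idx, _) in world.zones.cells.items():
        labels.ravel()[idx] = cid
    bio.write_zone_labels(
        world.config.grid, labels, outdir / "zones.csv"
    )
    world.water_table.to_csv(outdir / "water_content.csv", index=False)
    world.trade.flows.to_csv(outdir / "trade.csv", index=False)

    cfg = world.config
    manifest = {
        "seed": cfg.seed,
        "grid": {
            "n_rows": cfg.grid.n_rows,
            "n_cols": cfg.grid.n_cols,
            "cell_size": cfg.grid.cell_size,
            "origin_lon": cfg.grid.origin_lon,
            "origin_lat": cfg.grid.origin_lat,
        },
        "n_countries": cfg.n_countries,
        "n_crops": cfg.n_crops,
        "richness_range": list(cfg.richness_range),
        "crop_sparsity": cfg.crop_sparsity,
        "yield_range": list(cfg.yield_range),
        "water_range": list(cfg.water_range),
        "trade_density": cfg.trade_density,
        "format": fmt,
        "crop_ids": [c.crop_id for c in world.crops],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
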