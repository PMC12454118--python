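"""Trade attribution of biodiversity pressure.

National supply follows the standard accounting identity (production +
imports - exports).  The consumption-side pressure of a focal country is
the pressure embedded in what it eats:

    BP_cons = C_dom * BP_focal + sum_i T_i * BP_i

where C_dom is domestic supply (production - exports, clamped at zero),
T_i the import tonnage from origin i, and BP_i the origin's
production-weighted mean per-tonne pressure.  Using the country-level BP of
each origin encodes the assumption that exports are sourced proportionally
to where production is largest within the exporter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRADE_COLUMNS = ["origin", "destination", "crop_id", "tonnes"]


@dataclass
class TradeTable:
    """Bilateral trade flows: origin, destination, crop_id, tonnes per year."""

    flows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRADE_COLUMNS if c not in self.flows.columns]
        if missing:
            raise ValueError(f"trade table missing columns: {missing}")
        f = self.flows
        if (f["tonnes"] < 0).any():
            raise ValueError("trade tonnes must be non-negative")
        if (f["origin"] == f["destination"]).any():
            raise ValueError("trade flows must have origin != destination")
        key = ["origin", "destination", "crop_id"]
        if f.duplicated(subset=key).any():
            raise ValueError("duplicate (origin, destination, crop) records")
        self.flows = f.reset_index(drop=True)

    def imports_of(self, focal: str, crop_id: str) -> pd.Series:
        """Import tonnes into ``focal`` for one crop, indexed by origin."""
        f = self.flows
        sel = f[(f["destination"] == focal) & (f["crop_id"] == crop_id)]
        return sel.set_index("origin")["tonnes"].sort_index()

    def exports_of(self, focal: str, crop_id: str) -> float:
        f = self.flows
        sel = f[(f["origin"] == focal) & (f["crop_id"] == crop_id)]
        return float(sel["tonnes"].sum())

    def to_dry_weight(self, water_pct: dict[str, float]) -> "TradeTable":
        """Convert fresh tonnes to dry weight per crop: t * (1 - w/100)."""
        missing = sorted(set(self.flows["crop_id"]) - set(water_pct))
        if missing:
            raise KeyError(f"water content missing for crops: {missing}")
        f = self.flows.copy()
        dry = f["crop_id"].map(lambda c: 1.0 - water_pct[c] / 100.0)
        f["tonnes"] = f["tonnes"] * dry
        return TradeTable(f)


def _check_nonneg(**named: float) -> None:
    for name, v in named.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def domestic_supply(production: float, exports: float) -> float:
    """Domestic supply = production - exports, clamped at zero.

    An export excess (re-exports or inconsistent data) is logged as a
    warning and the supply floored at 0.
    """
    _check_nonneg(production=production, exports=exports)
    if exports > production:
        logger.warning(
            "exports (%.6g t) exceed production (%.6g t); "
            "likely re-exports, clamping domestic supply to 0",
            exports,
            production,
        )
        return 0.0
    return production - exports


def consumption(production: float, imports: float, exports: float) -> float:
    """National supply: production + imports - exports, clamped at zero."""
    _check_nonneg(production=production, imports=imports, exports=exports)
    c = production + imports - exports
    if c < 0:
        logger.warning("negative consumption (%.6g t) clamped to 0", c)
        return 0.0
    return c


def split_supply(
    focal: str, crop_id: str, production: float, trade: TradeTable
) -> tuple[float, float]:
    """Split a focal country's supply into (domestic, imported) tonnes."""
    dom = domestic_supply(production, trade.exports_of(focal, crop_id))
    imp = float(trade.imports_of(focal, crop_id).sum())
    return dom, imp


@dataclass
class ConsumptionPressure:
    """Decomposition of a focal country's consumption pressure for a crop.

    ``bp_cons`` (species*ha) = ``domestic_term`` + sum of ``import_terms``.
    Imports from origins without a defined BP are counted in
    ``unattributed_import_tonnes`` and contribute nothing.
    """

    focal_country: str
    crop_id: str
    domestic_supply: float
    domestic_term: float
    import_terms: dict[str, float] = field(default_factory=dict)
    unattributed_import_tonnes: float = 0.0

    @property
    def bp_cons(self) -> float:
        return self.domestic_term + sum(self.import_terms.values())

    @property
    def imported_term(self) -> float:
        return sum(self.import_terms.values())


def bp_cons(
    focal: str,
    crop_id: str,
    supply: float,
    bp_table: pd.DataFrame,
    trade: TradeTable,
) -> ConsumptionPressure:
    """Consumption-side pressure BP_cons for one (focal country, crop).

    Parameters
    ----------
    supply : float
        Domestic supply in tonnes (production - exports), on the same
        weight basis as the BPs and the trade tonnes.
    bp_table : DataFrame
        Country-crop metrics with columns country_id, crop_id, bp_mean.
    trade : TradeTable
        Bilateral flows, already on the matching weight basis.

    Raises
    ------
    ValueError
        If the focal country has positive domestic supply but no defined
        BP (the domestic term cannot be formed).
    """
    _check_nonneg(supply=supply)
    sel = bp_table[bp_table["crop_id"] == crop_id]
    bp_by_country = sel.set_index("country_id")["bp_mean"].dropna().to_dict()

    focal_bp = bp_by_country.get(focal, np.nan)
    if supply > 0 and np.isnan(focal_bp):
        raise ValueError(
            f"{focal}/{crop_id}: positive domestic supply but no domestic BP"
        )
    domestic_term = supply * focal_bp if supply > 0 else 0.0

    import_terms: dict[str, float] = {}
    unattributed = 0.0
    for origin, tonnes in trade.imports_of(focal, crop_id).items():
        origin_bp = bp_by_country.get(origin, np.nan)
        if np.isnan(origin_bp):
            if tonnes > 0:
                unattributed += tonnes
                logger.warning(
                    "%s/%s: %.6g t imported from %s has no origin BP; "
                    "left unattributed",
                    focal,
                    crop_id,
                    tonnes,
                    origin,
                )
        else:
            import_terms[str(origin)] = float(tonnes * origin_bp)
    return ConsumptionPressure(
        focal_country=focal,
        crop_id=crop_id,
        domestic_supply=supply,
        domestic_term=float(domestic_term),
        import_terms=import_terms,
        unattributed_import_tonnes=float(unattributed),
    )
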