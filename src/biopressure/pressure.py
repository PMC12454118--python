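"""Per-cell pressure surfaces: production, affected species range, BP.

ASR (affected species range, species*ha) is the per-cell product of a
crop's harvested area and the vertebrate species richness of the cell; it
measures the extent of species range overlapped by cultivation.  BP
(biodiversity pressure, species*ha per tonne) divides ASR by the cell's
production tonnage, giving a per-unit-food pressure intensity that is
comparable across crops and places.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Layer, cell_area

#: Production below this many tonnes is treated as zero when forming BP,
#: so resampling float noise cannot create astronomically large cells.
ZERO_PRODUCTION_TOLERANCE = 1e-9


@dataclass
class CropData:
    """A crop with its harvested-area and yield surfaces and water content.

    ``harvested_area`` is in hectares per cell (0 <= HA <= cell area),
    ``yield_`` in fresh-weight tonnes per hectare, ``water_pct`` the water
    content percentage in [0, 100) used for dry-weight conversion.
    """

    crop_id: str
    harvested_area: Layer
    yield_: Layer
    water_pct: float

    def __post_init__(self) -> None:
        if self.harvested_area.spec != self.yield_.spec:
            raise ValueError(
                f"crop {self.crop_id}: harvested area and yield grids differ"
            )
        if not 0 <= self.water_pct < 100:
            raise ValueError(
                f"crop {self.crop_id}: water_pct {self.water_pct} outside [0, 100)"
            )
        ha = self.harvested_area
        if np.any(ha.values[~ha.mask] < 0):
            raise ValueError(f"crop {self.crop_id}: negative harvested area")
        yl = self.yield_
        if np.any(yl.values[~yl.mask] < 0):
            raise ValueError(f"crop {self.crop_id}: negative yield")

    def validate_area_bound(self, rtol: float = 1e-9) -> None:
        """Check HA <= physical cell area everywhere unmasked."""
        area = cell_area(self.harvested_area.spec).values
        ok = ~self.harvested_area.mask
        if np.any(self.harvested_area.values[ok] > area[ok] * (1 + rtol)):
            raise ValueError(
                f"crop {self.crop_id}: harvested area exceeds cell area"
            )

    @property
    def dry_fraction(self) -> float:
        return 1.0 - self.water_pct / 100.0


@dataclass
class RichnessLayer:
    """Vertebrate species richness per cell (count of overlapping ranges).

    Source richness maps are integer counts; after bilinear resampling the
    surface may be real-valued, which is accepted (nothing downstream needs
    integrality).
    """

    richness: Layer

    def __post_init__(self) -> None:
        r = self.richness
        if np.any(r.values[~r.mask] < 0):
            raise ValueError("species richness must be non-negative")


def _require_same_grid(a: Layer, b: Layer, what: str) -> None:
    if a.spec != b.spec:
        raise ValueError(f"{what}: layers are on different grids; align first")


def compute_production(crop: CropData, dry: bool = True) -> Layer:
    """Per-cell production in tonnes: yield (t/ha) x harvested area (ha).

    With ``dry=True`` the fresh tonnage is multiplied by
    (1 - water_pct / 100), the dry-matter fraction.
    """
    ha, yl = crop.harvested_area, crop.yield_
    _require_same_grid(ha, yl, f"crop {crop.crop_id} production")
    factor = crop.dry_fraction if dry else 1.0
    values = ha.filled(0.0) * yl.filled(0.0) * factor
    mask = ha.mask | yl.mask
    values[mask] = np.nan
    return Layer(ha.spec, values, mask, units="t")


def compute_asr(crop: CropData, rich: RichnessLayer) -> Layer:
    """Affected species range per cell: ASR = HA * SR, in species*ha."""
    ha = crop.harvested_area
    sr = rich.richness
    _require_same_grid(ha, sr, f"crop {crop.crop_id} ASR")
    values = ha.filled(0.0) * sr.filled(0.0)
    mask = ha.mask | sr.mask
    values[mask] = np.nan
    return Layer(ha.spec, values, mask, units="species·ha")


def compute_bp_cell(
    crop: CropData,
    rich: RichnessLayer,
    production: Layer,
    zero_tol: float = ZERO_PRODUCTION_TOLERANCE,
) -> Layer:
    """Per-cell biodiversity pressure: BP = (HA * SR) / P, species*ha / t.

    ``production`` must come from :func:`compute_production` on the weight
    basis configured for the whole pipeline.  Cells with production at or
    below ``zero_tol`` tonnes are masked rather than infinite.
    """
    asr = compute_asr(crop, rich)
    _require_same_grid(asr, production, f"crop {crop.crop_id} BP")
    p = production.filled(0.0)
    mask = asr.mask | production.mask | (p <= zero_tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(mask, np.nan, asr.filled(0.0) / np.where(mask, 1.0, p))
    return Layer(asr.spec, values, mask, units="species·ha t-1")
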