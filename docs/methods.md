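# Methods

## Model

The framework treats cultivation as a pressure on vertebrate biodiversity
through spatial overlap: wherever a crop is harvested inside a species'
range, that species is assumed exposed. No population response, habitat
suitability or intensity gradient is modelled — the affected species range
(ASR = harvested area × richness, species·ha) is a pure overlap measure,
and every downstream quantity is an exact algebraic function of it.

The per-tonne intensity BP = ASR / P relativises pressure to food output.
Substituting P = yield × HA shows BP = SR / yield at the cell level: the
metric rewards high yields and penalises cultivation in species-rich
cells, and is independent of how much area is planted. At the country
level the mean BP is production-weighted, which carries a behavioural
assumption into the trade step: a tonne exported from country *i* is taken
to originate across *i*'s cells in proportion to production, so one
country-level BP value prices every exported tonne. BP_prod = BP × total
production then collapses to the country-summed ASR (Σ P·(ASR/P) = Σ ASR),
which the test suite uses as a standing cross-check, and BP_cons prices a
focal country's supply: domestic supply (production − exports) at the
domestic BP plus each import flow at its origin's BP.

## Weight basis

Whether tonnages are fresh or dry matters only as a uniform per-crop
rescaling (dry = fresh × (1 − water %/100)), but mixing bases across the
BP_cons sum would be incoherent. The pipeline therefore has a single
`weight_basis` switch (default `dry`) applied consistently to production,
to the BP denominator and to trade tonnes, and recorded in the run log.
Country BP scales by 1/(1 − w/100) between bases; rankings within a crop
are unaffected.

## Grid geometry and resampling

Grids are equal-angle, corner-registered, row 0 north, values at cell
centres. Cell areas use the spherical band formula
A = R²·Δλ·(sin φ_top − sin φ_bot) on the authalic sphere
(R = 6 371 007.2 m), which keeps the global sum exactly 4πR² and is within
0.3 % of ellipsoidal areas — adequate for 5-arcmin accounting. A 5-arcmin
equatorial cell is ≈ 8.59 × 10³ ha by this formula.

Crop layers are aligned to the richness grid (or an explicit target grid)
by bilinear interpolation, appropriate for continuous surfaces; `nearest`
is available for categorical data. Three numerical choices:

- **Masked stencils.** A target cell is masked only when all four stencil
  cells are masked; otherwise masked neighbours are dropped and the
  remaining weights renormalised. This avoids eroding the coastlines of
  sparse crop maps at every resampling step.
- **Edge handling.** Target centres outside the source-centre hull take
  the nearest edge value (weights clamped to [0, 1]), so output is always
  a convex combination of source values and can never overshoot the
  stencil extrema.
- **No renormalisation.** Bilinear resampling is not mass-conserving;
  totals of HA and P change slightly on regridding. The pipeline logs the
  pre/post totals and their relative change rather than rescaling, keeping
  the stored surfaces faithful to the interpolant.

## Zonal statistics

Countries are (cell, coverage-fraction) sets. Coverage comes either from
exact cell–polygon intersection (shapely, angular areas) when polygons are
supplied, or all-or-nothing from labelled rasters — the synthetic worlds
use the latter. Cells with production below the zero-production tolerance
(default 10⁻⁹ t, guarding against resampling float noise producing
astronomical BP values) are masked in BP and carry zero weight in the
country mean, but still count toward ASR totals: ASR is
production-independent. A country with no production of a crop gets a
missing BP, written as an empty CSV field, never 0.

## Trade attribution

Domestic supply is clamped at zero when exports exceed production (a
re-export signature in real data); the shortfall is logged. Imports from
an origin lacking a BP value (it grows none of the crop in the data)
contribute nothing and are reported as `unattributed_import_tonnes` with
their share of total imports — never silently dropped. Trade tonnes are
converted to the pipeline's weight basis with the same water-content table
before entering BP_cons.

## Synthetic worlds

The generator emulates the statistical structure of the real inputs, not
their geography:

- **Richness**: Gaussian white noise smoothed with a wrap-around Gaussian
  filter (σ = 2 cells), min–max mapped into `richness_range` (default
  5–400 species, the span of observed vertebrate richness) and rounded —
  a spatially autocorrelated integer surface.
- **Crops** (default 4): each cell cultivated with probability
  `crop_sparsity` (default 0.3); harvested area a uniform fraction of the
  physical cell area, so HA ≤ cell area holds by construction; yields a
  smooth positive surface in `yield_range` (default 1–20 t ha⁻¹ fresh);
  water contents uniform in 70–95 %, the typical fruit/vegetable range.
- **Countries** (default 3): contiguous territories grown by frontier
  accretion from random seed cells, ties to the lowest id; every cell
  assigned, coverage 1, so partition completeness is exact.
- **Trade**: each (producer origin, destination, crop) triple trades with
  probability `trade_density`; per-origin exports are capped at 80 % of
  production so domestic-supply clamping never fires in closed-world
  conservation checks.
- **Determinism**: one root seed fans out to named substreams (richness,
  crops, countries, trade, water) via `SeedSequence.spawn`, so adding a
  field never perturbs existing draws.

The default study system is a 24×48-cell global grid (7.5° cells) — large
enough for non-trivial zonal structure, small enough that the brute-force
reference loops run in seconds.

`generate_known_bp_world` inverts the algebra for parameter recovery:
uniform yield y, zero water content, per-country uniform richness
SR_i = target_i × y makes every cultivated cell's BP equal the target, so
the production-weighted mean recovers it exactly whatever the HA pattern.
Richness integrality is relaxed here by default (resampled richness is
real-valued anyway); a strict mode raises on non-integer implied richness.

What passing on these worlds does *not* show: behaviour under real
coastline masks, strongly skewed harvested-area distributions,
multi-resolution regridding artefacts at real 5-arcmin/10-km scales, or
trade tables with re-exports and unbalanced totals. Those enter only
through the clamping and unattributed-import pathways, which are tested
directly but on synthetic cases.

## Outputs and reproducibility

CSVs use fixed column order and 9-significant-digit scientific notation,
making re-runs byte-identical — regression tests can diff files. Log10
transforms used for visualisation in this literature are never applied to
stored values. The run log records weight basis, grid, tolerances,
masked-cell counts per crop and unattributed-import shares.

## Known limitations

- Richness is treated as static and uniform within its grid cell;
  elevational or habitat clipping of ranges is assumed already applied to
  the input raster.
- One BP value per (country, crop) prices all exports; sub-national
  sourcing heterogeneity is invisible to BP_cons.
- Conversion of processed commodities to primary equivalents is out of
  scope; trade inputs must already be primary-equivalent.
- Equal-angle cells shrink toward the poles; harvested-area fractions are
  interpreted against the physical (band-formula) cell area, not a
  constant nominal area.
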