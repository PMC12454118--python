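# biopressure

Spatial biodiversity-pressure accounting for crop production, trade and
consumption.

Agricultural land use is a leading pressure on terrestrial vertebrates, and
that pressure travels: a country's food supply embeds cultivation happening
inside the ranges of species on the other side of the world. `biopressure`
implements a gridded accounting framework that quantifies this overlap and
follows it through bilateral trade, for analysts working with harvested-area
and yield rasters, stacked species-range richness maps and bilateral trade
tables.

## The metrics

All surfaces live on an equal-angle latitude–longitude grid. For crop *c*
at grid cell *l*, with harvested area HA (ha), vertebrate species richness
SR (count of overlapping ranges) and production *P* (tonnes, the product of
yield and harvested area, optionally converted to dry weight by
1 − water %/100):

- **ASR** (affected species range, species·ha): ASR = HA<sub>c,l</sub> × SR<sub>l</sub> —
  the extent of species range overlapped by cultivation in a cell.
- **BP** (biodiversity pressure, species·ha t⁻¹): BP<sub>c,l</sub> = ASR / P<sub>c,l</sub> —
  the per-tonne pressure intensity; a crop that feeds many people from the
  same pressured area scores lower.
- **Country BP** — the production-weighted mean over a country's cells,
  BP<sub>c,i</sub> = Σ f<sub>il</sub> P<sub>l</sub> BP<sub>l</sub> / Σ f<sub>il</sub> P<sub>l</sub>, where f is the fraction
  of each cell the country covers. Production weighting assumes exports are
  sourced proportionally to where production is largest.
- **BP<sub>prod</sub>** (species·ha): BP<sub>c,i</sub> × P<sub>c,i</sub>, the pressure of national
  production; algebraically equal to the country-summed ASR.
- **BP<sub>cons</sub>** (species·ha): the pressure embedded in national consumption,
  C<sup>dom</sup> × BP<sub>fc,c</sub> + Σ<sub>i</sub> T<sub>i,fc,c</sub> × BP<sub>c,i</sub>, where
  C<sup>dom</sup> is domestic supply (production − exports) and T the import
  tonnage from each origin.

Because real global inputs (circa-2000 crop grids, registered-access range
stacks, balanced trade matrices) are large external datasets, the package
ships a seeded synthetic-world generator that reproduces their statistical
structure — sparse non-negative harvested areas bounded by cell area,
smooth yields, spatially autocorrelated integer richness, contiguous
country partitions and sparse trade flows — with analytically known ground
truth, so the entire pipeline is testable offline.

## Worked example

Generate a seeded world (24×48 global grid, 3 countries, 4 crops) and run
the accounting:

```sh
biopressure simulate --seed 7 demo/fx
biopressure aggregate demo/fx demo/out
```

```
country_id crop_id  production_total    asr_total    bp_mean      bp_prod
       AAA  crop00      1.935889e+09 6.034451e+11 311.714807 6.034451e+11
       AAA  crop01      5.104393e+09 5.390005e+11 105.595420 5.390005e+11
       AAA  crop02      4.241480e+09 4.490185e+11 105.863632 4.490185e+11
       ...
```

Country AAA produces 1.9 Gt (dry weight) of crop00 across cells that
overlap 6.0 × 10¹¹ species·ha of vertebrate range, so each tonne carries a
pressure of ~312 species·ha — almost three times the intensity of crop01,
whose production sits in less species-rich cells. `bp_prod` equals
`asr_total` row by row, the built-in algebraic cross-check.

Consumption accounting for focal country AAA:

```sh
biopressure consume demo/fx demo/out2 --focal AAA
```

```
focal_country crop_id  domestic_supply  imported_tonnes  domestic_term  imported_term      bp_cons
          AAA  crop00     1.917744e+09     1.164549e+09   5.977892e+11   3.003540e+11 8.981432e+11
          AAA  crop01     5.026617e+09     1.246456e+09   5.307878e+11   1.195301e+11 6.503179e+11
          ...
```

A third of AAA's crop00 consumption pressure (3.0 of 9.0 × 10¹¹ species·ha)
is imported — pressure exerted inside its trade partners' borders.

The `rank` and `summarize` subcommands produce the global crop rankings by
BP / production / ASR and the domestic-versus-imported summary tables;
`run` executes everything from a YAML config.

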