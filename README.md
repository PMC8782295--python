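# atollcarbon

Terrestrial carbon accounting for a whole coral atoll undergoing forest
transformation: the managed replacement of a coconut-palm (*Cocos nucifera*)
dominated canopy by native mixed-species forest (*Pisonia grandis*,
*Heliotropium foertherianum*). The package answers the management question
"what happens to the atoll's carbon stocks when the palms go?" by combining

- **soil organic carbon (SOC) stocks** over a 20 cm hardpan-limited depth,
  estimated two ways — a random forest predicting a %C bin (low < 10%,
  medium 10–20%, high > 20%) per 1-m raster cell from vegetation community
  and tree species, and a community × species averages method with an
  explicit fallback ladder — both feeding one stock formula,

      Mg C = (%C / 100) · ρ_bulk · depth · area_ha · 100 ,

  with ρ_bulk in g cm⁻³ (≡ Mg m⁻³) and depth in cm;
- **aboveground carbon** per tree crown via the tropical allometry

      AGB (kg) = 0.0673 · (ρ D² H)^0.976 ,   C = 0.47 · AGB ,

  with ρ the species' corrected basic wood density (g cm⁻³), D the species
  quadratic-mean stem diameter (cm), and H the crown height from a LIDAR-like
  elevation surface minus a 2 m sea-level offset;
- a **stochastic transformation scenario** (remove palms inside the
  transformation polygons, replant natives 2:1 with 46% seedling survival ⇒
  ≈50:50 mature mix) and pre/post accounting with percent changes;
- **chronosequence soil-accumulation rates** (stock density / islet age on
  man-made islets of known completion date) projected 15 years under both
  scenarios;
- a **nearshore dissolved organic carbon (DOC) comparison** of intertidal
  sites adjacent to palm vs. native canopy, via a site-level permutation
  test (site mean DOC as the exchangeable unit) with a random-intercept
  mixed model as cross-check.

Because the study's 1-m rasters and full field tables are not distributed,
everything runs on a **synthetic atoll generator** with known ground truth
(islet polygons, community/species rasters, crowns, elevation, soil and DOC
samples), parameterized by the published community composition, bin
statistics, wood densities, and DOC group means. Published accounting tables
are also replicated cell-by-cell from their printed components.

## Worked example

```sh
$ atollcarbon run --seed 1 --out runs/demo
canopy area: 43.0 ha
 aboveground:      825.5 ->      376.2 Mg C  (-54.4%)
        soil:     3603.0 ->     4578.7 Mg C  (+27.1%)
       total:     4428.4 ->     4954.9 Mg C  (+11.9%)
DOC canopy effect: 110.9 vs 85.6 uM C, p = 0.0087
```

On this synthetic atoll (8 islets, ~43 ha of canopy, ~6,500 crowns, 99
stratified soil sites) the transformation removes dense-wooded palms, so
aboveground carbon falls; the expanding *Pisonia*-bearing communities carry
much richer soils, so SOC rises enough to lift the total stock (+11.9%).
Nearshore DOC is ~25 μM C higher next to palm canopy than native canopy
(site-level permutation p ≈ 0.009) — the same qualitative pattern as the
field study. The random-forest soil total lands within ~9% of the
generator's true stock, and the aboveground total within 0.1% of truth.

The same stages are available programmatically:

```python
from atollcarbon import RunConfig, run_pipeline
report = run_pipeline(RunConfig(seed=1))
print(report.scenario.pct_change)        # {'aboveground': -54.4, 'soil': 27.1, 'total': 11.9}
print(report.truth_recovery)             # estimates vs generator truth
```

`atollcarbon verify-tables` recomputes every derived cell of the published
scenario-summary and 15-year-accumulation tables from their printed
components and confirms agreement at the printed rounding.

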