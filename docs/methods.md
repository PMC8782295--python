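# Methods

## Spatial model

All layers live on one regular planar grid in local metres: origin at the
upper-left corner, row-major indexing, cells half-open `[x, x+s) × (y−s, y]`.
Categorical rasters share a sentinel block (blank, water, unknown, runway,
bare ground, grassland) distinct from vegetation classes; blank, water,
unknown and runway zero out soil stocks, and unknown/runway/bare/grassland
are additionally excluded from the canopy area that normalizes carbon
densities. Majority rasterization pools coverage by label and resolves
exact ties to the lowest legend code (legends are built in sorted label
order), so rasterization is deterministic and seed-free. Since neither
rasterio nor geopandas is a dependency, rasters are plain numpy arrays
serialized as ESRI ASCII grids with CSV legends, and vector layers are
shapely geometries serialized as GeoJSON — all text formats.

## Soil organic carbon

Samples carry organic %C (imputed for the later campaign by OLS of organic
on total %C, fitted on within-dataset pairs and clamped to `[0, total]` —
organic carbon cannot exceed total carbon), dry bulk density, and
community/species labels read from the rasters at the site.

Binning is low < 10%, medium 10–20% inclusive, high > 20%. The published
bin ranges never touch the boundaries, so placing 10% and 20% in the medium
bin is a free choice made once and used everywhere.

The **random-forest estimator** (500 trees, one-hot-encoded community and
species predictors, seeded) predicts a bin per distinct label pair; cells
get the bin's mean %C and mean bulk density through the stock formula.
Out-of-bag accuracy is retained as a diagnostic. The **averages estimator**
works on the community × species overlay with the fallback ladder:
combination mean when the combination has n ≥ 2 samples, else community
mean, else species mean, else the global mean; zero where either label is
blank/unknown/water/runway. On rasters the overlay reduces without loss to
a cross-tabulation of label pairs, which is how the pipeline computes it;
the polygon-overlay route exists for vector inputs. The accounting depth is
fixed at 20 cm (mean hardpan depth) even where a site's measured hardpan is
shallower; per-site depths stay in the record for sensitivity work.

The published bin table carries an internal inconsistency (the medium bin's
bulk-density mean falls outside its printed range); it is stored exactly as
printed with a flag, and no corrected value is invented.

## Aboveground carbon

Heights prefer the elevation surface (elevation at the crown centroid minus
the 2 m sea-level offset, applied uniformly); crowns in elevation-data gaps,
or whose subtraction yields a non-positive height, fall back to the
study-wide species mean with a recorded source flag. Diameters are species
quadratic means from transect lists; only the eight dominant species carry
biomass, other crowns contribute zero and are counted. Densities divide by
canopy-bearing area, not total land.

Basic wood density is anhydrous mass over green volume: the saturated-disc
cylinder volume when measured, else dry volume inflated by `1/(1−S)` with
`S` the volumetric shrinkage. The shrinkage/fiber-saturation coefficient
defaults (0.28/0.12 tropical mean; 0.40/0.10 for *Pisonia*) are
representative literature-scale estimates, editable per species; final
densities are insensitive within plausible coefficient ranges because `S`
enters only through `1/(1−S)`. A secondary routine converts 12%-moisture
literature densities to the basic-density basis via linear volume shrinkage
below the fiber saturation point.

## Transformation scenario

Community cells of the palm classes inside the transformation polygons move
to the mixed native class per an explicit mapping (the treatment of mixed
palm communities is interpretive and sits in config). Palm crowns inside
the polygons are independently reassigned to the two natives with survivor
proportions ∝ planting ratio × survival (2:1 and 0.46/1.0 ⇒ 0.479/0.521);
an exact-split mode exists for sensitivity. *P. grandis* survival is
assumed 1.0 since only *H. foertherianum* survival is reported. Replanted
trees jump directly to species mean height/diameter/density — maturity-at-
15-years accounting with no growth curve. Reclassification conserves cell
counts, reassignment conserves crown counts, and non-target cells and crowns
are returned unchanged.

## Accumulation projections

Chronosequence rates divide current stock density by islet age (77 / 76
years for the man-made islets, baseline 2019) — a linear-accumulation
assumption, hence minimum rates. The palm community uses the literature
pair 27 Mg C ha⁻¹ / 20 yr = 1.35 Mg C ha⁻¹ yr⁻¹, carried at full precision:
the published table's cells are reproducible only from unrounded rates, so
display rounding never contaminates computation. Projections are
area × rate × 15 yr per community under each scenario; the scenario
difference is flagged "marginal" below 5% of either total.

## Nearshore DOC

After pooling the two palm-adjacent intertidal habitats (with a preliminary
two-group comparison reported first) and excluding recently-controlled
sites (kept in a side table — their depressed DOC is itself informative),
the canopy comparison is a site-level permutation test: site mean DOC is
the exchangeable unit, which absorbs the two-samples-per-site repeated
measures; all distinct label assignments are enumerated when feasible
(C(12,6) = 924 at the study's 12 sites), otherwise 10,000 seeded draws.
This is exact under site-level exchangeability and avoids distributional
assumptions at two samples per site. A random-intercept linear mixed model
is fitted as a cross-check; the package reports both p-values without
asserting equivalence. Comparison habitats (offshore, forereef, open
lagoon) are summarized descriptively only. Relative lux is the ratio of a
site's daily-mean lux to an unshaded reference.

## Synthetic generator

One global integer seed fans out to fixed named substreams (islets,
community, species, landcover, crowns, elevation, soil, DOC, transects), so
every stage is independently reproducible. Islets are random convex blobs
affinely scaled to exact target areas — shape is irrelevant to the
accounting, area is not. Community classes are drawn i.i.d. per land cell
from the published vegetated-area composition (the printed column sums to
100.1% and is renormalized); species are drawn from per-community
compositions; a runway strip, scattered bare/unknown cells and the grass
community populate the excluded land-cover classes. Crowns occupy
tree-bearing canopy cells at a fixed rate; elevation is a 2 m base plus the
crown's true canopy height plus Gaussian noise (SD 0.2 m), with one islet
optionally masked nodata to emulate the elevation-data gap. Transformation
polygons are the islets shrunk about their centroids to cover 95% of
emergent land.

Soil truth assigns each community a mean %C and bulk density, with rich,
low-density soils under *Pisonia*-bearing canopies (the seabird-subsidy
pattern); samples are stratified over islet × community proportionally to
stratum area, %C is lognormal around the stratum mean (positive,
right-skewed, σ = 0.35), and the later campaign's samples carry total
carbon only, exercising the imputation path. DOC truth uses the published
group means (110.0 / 81.5 μM C); the between-site (12) and within-site (5)
standard deviations are this package's choices — the study prints none —
sized so that site-to-site variation dominates replicate noise.

What the generator does **not** emulate: spatial autocorrelation of
communities (cells are i.i.d., so class shares converge faster than patchy
real maps would), tides and shoreline clipping, guano nutrient fields,
temporal forest growth, and within-species wood-density variation by site.
Passing recovery tests therefore shows the estimators are unbiased under
correct labels and calibrated noise, not that they are robust to spatially
structured misclassification.

## Problem sizes and numerical choices

The default scene uses 8 islets (0.25–12 ha, log-uniform), 2 m cells
(~10⁵ grid cells, ~35,000 land cells), ~6,500 crowns and 99 soil sites —
the study's sampling effort on a desk-scale atoll. Statistical calibration
runs use a 4-islet scene with 12 DOC sites per replicate. Majority-
rasterization ties break to the lowest legend code; %C values are clipped
to [0.05, 95]; heights are floored at 1 m; degenerate geometry (zero-area
crowns) raises rather than silently contributing zero. The permutation
p-value with random draws uses the add-one estimator `(hits+1)/(N+1)`;
enumerated p-values are exact fractions.

## Known limitations

Belowground biomass, litter, and coconut mass are out of scope, as are
nonlinear (saturating) soil-accumulation curves and decomposition-driven
decay. The organic~total imputation fits only within-dataset pairs. The
averages and random-forest estimators share the same training samples, so
their comparison measures methodological, not sampling, disagreement.
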