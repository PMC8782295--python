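"""Published Palmyra Atoll study constants used as pipeline inputs.

These are the printed field and accounting tables from the Palmyra Atoll
forest-transformation carbon study: per-islet soil-sample bookkeeping,
vegetation-community composition, the soil organic-carbon bin summary,
corrected basic wood density by species, and the headline carbon accounting
(baseline vs. post-transformation totals and the 15-year soil-accumulation
comparison).  They parameterize the synthetic-scene generator and drive the
table-replication checks; none of them is a computed output of this package.
"""

# Soil samples by islet with islet area (ha).
SOIL_SAMPLES_BY_ISLET = {
    "Aviation": (3, 4.28),
    "Cooper": (18, 91.81),
    "Dudley": (7, 0.89),
    "Eastern": (7, 11.43),
    "Engineer": (7, 6.52),
    "Fern": (2, 0.25),
    "Holei": (4, 11.42),
    "Kaula": (5, 14.18),
    "Lesley": (6, 0.61),
    "N. Fighter": (5, 6.13),
    "Pelican": (3, 6.07),
    "Paradise": (5, 6.21),
    "Portsmouth": (1, 0.26),
    "S. Fighter": (5, 8.12),
    "Sand": (11, 6.92),
    "Strawn": (5, 7.04),
    "Whippoorwill": (5, 1.18),
}

# Vegetation community -> (number of soil samples, % of vegetated area).
SOIL_SAMPLES_BY_COMMUNITY = {
    "C. nucifera": (20, 29.8),
    "C. nucifera/H. foertherianum": (16, 11.5),
    "H. foertherianum/S. sericea": (3, 4.0),
    "H. tiliaceus": (2, 2.6),
    "Lepturus repens/Fimbristylis cymosa": (2, 6.5),
    "P. tectorius": (12, 13.0),
    "P. grandis": (29, 13.2),
    "P. grandis/H. foertherianum": (14, 1.4),
    "S. sericea/H. foertherianum": (1, 11.8),
    "Other": (0, 6.3),
}

# Soil organic-carbon bin summary: count, %C range/mean/SE, bulk density
# range/mean/SE (g cm^-3).  The medium bin's printed bulk-density mean (0.43)
# lies outside its printed range (1.17-3.84) — an inconsistency in the
# published table, stored here exactly as printed and flagged.
SOIL_BIN_SUMMARY = {
    "low": {
        "n": 83, "c_pct_range": (0.48, 9.93), "c_pct_mean": 3.64, "c_pct_se": 0.25,
        "bd_range": (0.15, 2.09), "bd_mean": 1.0, "bd_se": 0.05,
    },
    "medium": {
        "n": 9, "c_pct_range": (10.16, 15.95), "c_pct_mean": 12.88, "c_pct_se": 0.69,
        "bd_range": (1.17, 3.84), "bd_mean": 0.43, "bd_se": 0.11,
        "inconsistent": "printed bulk-density mean lies outside printed range",
    },
    "high": {
        "n": 7, "c_pct_range": (21.80, 38.46), "c_pct_mean": 30.43, "c_pct_se": 2.7,
        "bd_range": (0.10, 0.54), "bd_mean": 0.27, "bd_se": 0.06,
    },
}

# Corrected basic wood density by species:
# (min, max, mean g cm^-3, SE, pooled n).
BWD_TABLE = {
    "Cocos nucifera": (0.31, 0.70, 0.50, 0.08, 5),
    "Cordia subcordata": (0.18, 0.89, 0.42, 0.01, 135),
    "Heliotropium foertherianum": (0.23, 0.44, 0.31, 0.01, 31),
    "Hibiscus tiliaceus": (0.26, 0.66, 0.38, 0.02, 28),
    "Pandanus tectorius": (0.06, 0.32, 0.16, 0.01, 43),
    "Pisonia grandis": (0.12, 0.46, 0.23, 0.01, 51),
    "Scaevola sericea": (0.23, 0.57, 0.40, 0.06, 6),
    "Terminalia catappa": (0.22, 0.83, 0.47, 0.01, 330),
}

BWD_MEANS = {sp: row[2] for sp, row in BWD_TABLE.items()}

#: the eight biomass-bearing species of the aboveground accounting
BIOMASS_SPECIES = tuple(BWD_TABLE)

# Headline carbon accounting: component totals (Mg C) and densities
# (Mg C ha^-1) for the baseline and post-transformation scenarios.
CARBON_SUMMARY_COMPONENTS = {
    "aboveground": {
        "baseline_total": 692.6, "baseline_density": 4.3,
        "future_total": 433.3, "future_density": 2.7,
    },
    "soil": {
        "baseline_total": 11872.3, "baseline_density": 73.4,
        "future_total": 13590.8, "future_density": 84.0,
    },
}

# Printed derived cells of the same table (checked, never used as inputs).
CARBON_SUMMARY_DERIVED = {
    "baseline_total": 12564.9,
    "future_total": 14024.1,
    "pct_change": {"aboveground": -37.4, "soil": 14.5, "total": 11.6},
}

# Soil-method comparison totals (Mg C): averages method vs. random forest.
SOIL_METHOD_TOTALS = {
    "averages": {"baseline": 11856.2, "future": 15378.2},
    "random_forest": {"baseline": 11872.2, "future": 13590.8},
}

# 15-year soil accumulation: community ->
# (current ha, printed rate Mg C ha^-1 yr^-1, accumulation no-transform Mg C,
#  projected ha, accumulation with transform Mg C).
ACCUMULATION_TABLE = {
    "C. nucifera": (57.3, 1.3, 1160.5, 14.5, 292.7),
    "H. foertherianum/P. grandis": (2.7, 1.3, 51.1, 54.0, 1020.3),
    "H. foertherianum/C. nucifera": (22.6, 1.0, 325.3, 14.2, 204.3),
}
ACCUMULATION_TOTALS = {"no_transform": 1536.9, "transform": 1517.3}
ACCUMULATION_HORIZON_YEARS = 15

# Chronosequence inputs: man-made islet completion years (baseline 2019) and
# the literature coconut stand used for the C. nucifera rate.
CHRONOSEQUENCE = {
    "baseline_year": 2019,
    "islet_ages": {"Dudley/Lesley": 77, "N. Fighter": 76},
    "c_nucifera_literature": {"stock_per_ha": 27.0, "age": 20},
}

# Nearshore dissolved organic carbon (uM C): group means from the canopy
# comparison and the descriptive comparison habitats.
DOC_GROUP_MEANS = {"c_nucifera": 110.0, "native": 81.5}
DOC_COMPARISON_MEANS = {
    "offshore": 71.9, "forereef": 78.9, "lagoon_open": 73.8,
    "intertidal_lagoon_flat_cn": 117.0, "intertidal_reef_flat_cn": 112.7,
    "recently_controlled_site": 69.1,
}
DOC_N_SITES = 12
DOC_SAMPLES_PER_SITE = 2

TOTAL_SOIL_SITES = 99
SOIL_SITES_2016 = 72
SOIL_SITES_2019 = 27
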