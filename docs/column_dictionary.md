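# Column dictionary

All tables are UTF-8 CSV. Empty cells are missing values (NA), meaning
"not surveyed", never "absent".

## `simulate/correlates.csv` — one row per survey location

| column | unit | meaning |
|---|---|---|
| location_id | — | unique location label (`L0000`…) |
| lon, lat | degrees | planar coordinates (equal-area-faithful units) |
| dist_to_land | km | shortest distance to the nearest major landmass |
| dist_to_shelf_edge | km | distance to the 200 m shelf edge |
| dist_to_margin | km | distance to the nearest species-range margin |
| rel_margin_dist | 0–1 | relative distance to range margin (0 = margin, 1 = range centre) |
| rel_lon, rel_lat | −1–1 | relative position within range |
| dist_to_IAA | km | distance to the Coral Triangle reference point |
| reef_area | km² | area of the sampled reef |
| reef_perimeter | km | perimeter of the sampled reef |
| reef_area_10km, reef_area_50km | km² | total reef area within 10 / 50 km kernels |
| shelf_area_50km | km² | shelf area within 50 km (historical habitat proxy) |
| sst_mean, sst_winter, sst_summer | °C | climatological sea-surface temperature means |
| sst_sdev | °C | SST seasonality (s.d. of monthly means) |
| chla_mean, chla_sdev | mg m⁻³ | chlorophyll-a mean and seasonality |
| present_threat, integrated_threat | ordinal 1–4 | local / integrated reef threat class |
| human_impact | index | cumulative human impact score |
| ocean_health | 0–100 | overall ocean-health index |
| ohi_* | 0–100 | ocean-health sub-component scores (fisheries, artisanal, livelihoods, sense of place, biodiversity, coastal protection) |

## `simulate/traits.csv` — one row per species

| column | unit | meaning |
|---|---|---|
| species_id | — | unique species label (`SP000`…) |
| family, genus | — | taxonomy; genera nest within families |
| body_size | cm | maximum adult total length |
| range_size | 10⁶ km² | extent of occurrence (convex-hull area minus land) |
| trophic_group | code | FC, HD, HM, IM, IS, OM, PK |
| home_range | code | Sed, Mob, VMob |
| mobility | code | low, high |
| diel_activity | code | diurnal, nocturnal |
| schooling | code | Sol, Pair, SmallG, MedG, LargeG |
| water_level | code | bottom, low, high |

## `simulate/survey.csv` — one row per (location, replicate, species)

| column | meaning |
|---|---|
| location_id, replicate_id | sampling unit and replicate transect |
| transect_area | m², set by the data source |
| data_source | RLS, GASPAR, WCS or PROCFish |
| species_id | species looked for on this replicate |
| detected | 1 recorded, 0 not recorded, empty = not surveyed (restricted list) |
| distance_band | `within-5m` or `beyond-5m` (only-beyond = false absence within 5 m); empty when not detected |
| fishing_intensity | ordinal 1 (none/weak) – 5 (intense) |

## `simulate/matrix.csv` — locations × species pooled presence

Value 1 iff any replicate detection, 0 if surveyed and never detected,
empty if every record for the pair is NA.

## Derived outputs

* `brt/results.csv`: species_id, converged, is_null, n_trees, n_locations,
  n_presences, cv_deviance_explained (%), reason, and one `contrib_<correlate>`
  column per correlate (percent, summing to 100 per converged species).
* `brt/curves.csv` (long): species_id, correlate, x (correlate units),
  logit, prob — partial-dependence curves.
* `traits/hyp_contributions.csv`: species_id, total_deviance_explained,
  four hypothesis shares (%), and `abs_<hypothesis>` (share × total / 100).
* `traits/aicc_<response>.csv`: formula, k, loglik, AICc, dAICc, wAICc,
  R2_marginal, R2_conditional.
* `traits/surfaces.csv` (long): body_size, range_size, response, predicted.
* `thresholds/thresholds.csv`: group (size class), small_ranging,
  hypothesis, correlate, unit, n_species, davies_p, threshold ±
  threshold_se (correlate units), rate_before / rate_after (slopes on
  [0, 1]-rescaled x), converged.
* `thresholds/mean_curves.csv` (long): group, small_ranging, correlate,
  x, mean, ci_lower, ci_upper, n_species.
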