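# Canonical table column dictionaries

All tables are UTF-8, comma-separated, with a header row.  Identifiers
are free-form strings; reals use `.` decimals.  `load_*` functions
validate every invariant below and name offending rows.

## assemblage.csv

| column | type | meaning |
|---|---|---|
| source_id | identifier | data source (publication) the study came from |
| study_id | identifier | study (one sampling method within a source) |
| block_id | identifier, optional | spatial block, nested within study; empty if none |
| site_id | identifier | site the measurement was taken at |
| taxon_id | identifier | taxon measured |
| status | `native` / `alien` / `unknown` | origin status of the taxon at this island |
| measurement | real ≥ 0 | abundance in study-specific units, or 0/1 occurrence |
| metric_kind | `abundance` / `occurrence` | constant within a study |
| sampling_effort | real > 0 | study-specific effort units; divides abundance when effort varies within a study |

One row per (study, site, taxon); duplicates are rejected.

## sites.csv

| column | type | meaning |
|---|---|---|
| site_id | identifier | unique site key |
| study_id | identifier | owning study |
| block_id | identifier, optional | spatial block |
| island_id | identifier | island the site sits on |
| longitude, latitude | WGS84 decimal degrees | site coordinates |
| land_use | one of `PriMin`, `Primary`, `Secondary`, `Plantation`, `Cropland`, `Pasture`, `Urban` | collapsed land-use/use-intensity class; `PriMin` = minimally-used primary vegetation |
| hpd_raw | persons / km² ≥ 0 | human population density |
| dist_road_raw | metres ≥ 0 | distance to the nearest road |
| altitude | metres | site altitude |
| tmax, tmin | °C | max / min temperature (bioclimatic) |
| precip_wet, precip_dry | mm | precipitation of wettest / driest month |
| max_linear_extent | metres > 0, optional | greatest distance between sampling points within the site |

## islands.csv

| column | type | meaning |
|---|---|---|
| island_id | identifier | unique island key |
| area_km2 | real > 0 | island area |
| surrounding_landmass | real in [0, 3] | sum of landmass proportions within 100 / 1,000 / 10,000 km buffers (isolation proxy; smaller = more isolated) |
| gdp_per_capita | real > 0 | per-capita GDP, current USD |

## status table (for `attach_status`)

| column | type | meaning |
|---|---|---|
| taxon_id | identifier | taxon to classify |
| scope | e.g. `island`, `country` | resolution of the classification; matched in precedence order (island before country) |
| scope_id | identifier, optional | island id for island scope; empty = matches anywhere |
| status | `native` / `alien` / `unknown` | classification |

Conflicting statuses for one (taxon, scope, scope_id) are an error.
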