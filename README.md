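# isleco

Land-use change and related human pressures reshape island assemblages
unevenly: native species decline in working landscapes while alien
species thrive there, and the composition of disturbed sites drifts
away from — and homogenises relative to — minimally-disturbed
vegetation.  `isleco` is a tested, reusable implementation of the full
analysis chain behind that kind of study, for hierarchical site-level
survey data (source → study → block → site, each taxon labelled
alien/native/unknown):

* **site-level diversity models** — weighted gaussian linear mixed
  models of square-root rescaled total abundance and Poisson log-link
  mixed models of species richness (with an observation-level random
  effect for overdispersion), with land use × status interactions,
  quadratic orthogonal-polynomial pressure covariates, AIC selection
  among random-effect structures, backward LRT simplification, GVIF
  collinearity screening and post-hoc slope tests;
* **island-trait models** — land use × island characteristic (area,
  surrounding landmass, per-capita GDP) interactions for alien
  diversity;
* **compositional similarity** — the directional (asymmetric) Jaccard
  indices for every ordered within-study site pair,

      J_R = S_ij / S_j        J_A = A_ij / A_j

  (the share of site *j*'s species, or summed abundance, also present
  at site *i*), modelled on the logit scale against the 49-level
  land-use contrast, ln geographic distance (haversine, scaled by the
  median maximum linear extent) and cube-root Gower environmental
  distance, with significance from within-study permutation tests —
  `p = (1 + #{null ≥ observed}) / (1 + n_perm)`, so 199 permutations
  give the conventional 0.005 floor;
* **a synthetic metacommunity generator** with known truth (land-use
  effects on abundance and richness by status, random-effect
  hierarchy, gamma-Poisson counts, distance decay of composition,
  alien–isolation effect, unclassifiable species), so every stage is
  testable without any data download.

The mixed-model engine is written here (profiled ML/REML for weighted
gaussian models with crossed variance components; penalised IRLS with
a Laplace approximation for Poisson models) and is cross-checked in
the test suite against lme4 to six decimals.  See `docs/methods.md`
for the full model description, the generator's design and its
limitations.

## Worked example

Run the whole pipeline on a synthetic dataset (10 studies × 12 sites
on 4 islands, seed 11, 199 permutations):

```python
from isleco import PipelineConfig, SimulationConfig, run_pipeline
cfg = PipelineConfig(simulation=SimulationConfig(
    n_studies=10, sites_per_study=12, n_islands=4, seed=11), n_perm=199)
run_pipeline(cfg, "run/")
```

or from the shell, putting the simulation block in a YAML file:

```bash
printf 'simulation: {n_studies: 10, sites_per_study: 12, n_islands: 4}\n' > cfg.yaml
isleco run --config cfg.yaml --seed 11 --n-perm 199 --out run/
```

`run/alien_share.csv` then contains (percent of classified species and
individuals that are alien, per land use):

```
  land_use  share_richness_pct  share_abundance_pct
    PriMin                17.1                 17.2
  Cropland                41.2                 43.6
   Pasture                50.7                 44.3
```

— about 17% of species even at minimally-disturbed (PriMin) sites are
alien, matching the generator's calibration.  `run/effects_richness.csv`
reports percent change versus PriMin with asymmetric back-transformed
CIs; for natives:

```
 land_use    percent_change   ci_low  ci_high
 Plantation           -32.7    -42.1    -21.8
 Cropland             -51.9    -59.3    -43.1
 Pasture              -59.5    -66.4    -51.3
```

recovering the generating effects (−30, −50, −65).  The permutation
trail (`run/permutation_results.json`) for the richness-based
similarity model shows the status × land-use-contrast interaction
retained at the 0.005 floor while the status × distance interactions
are dropped:

```
 step                    term      lr  df     p  action
    1 status:landuse_contrast  680.19  48 0.005  tested
    1       status:geo_dist_t    0.53   1 0.465  dropped
    ...
    4              geo_dist_t   28.11   1 0.005  tested
    4 status:landuse_contrast  681.64  48 0.005  tested
```

and `run/similarity_contrasts.csv` quantifies the compositional
asymmetry: alien assemblages in pasture pairs are far more similar to
each other (J_R 0.81) than alien assemblages of PriMin pairs (0.35) —
homogenisation — while native within-pasture similarity (0.36) falls
below its PriMin baseline (0.75).

Each stage is also exposed separately (`isleco simulate`, `metrics`,
`pairs`) and as library functions (`site_diversity`,
`build_pair_table`, `fit_mixed`, `permutation_lr_test`, …).

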