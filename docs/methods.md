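# Methods

This note records the statistical model behind `isleco`, the estimation
machinery, the design of the synthetic-data generator, and the numerical
conventions, in enough detail to reproduce or audit any number the
package emits.

## Scientific setting

Surveys of island assemblages compare local biodiversity across sites in
different land uses.  Records are organised hierarchically — data source
(publication) → study (one sampling method) → optional spatial block →
site — and each taxon at a site carries an alien/native/unknown status.
The analyses ask three questions:

1. how land use and two continuous pressures (human population density,
   distance to the nearest road) affect site-level total abundance and
   species richness of aliens versus natives;
2. whether island traits (area, surrounding landmass as an isolation
   proxy, per-capita GDP) moderate alien diversity across land uses;
3. how land-use change reshapes *composition*: the directional
   similarity of each site pair within a study, modelled against the
   pair's land-use contrast, geographic distance and environmental
   distance, separately for aliens and natives.

## Site-level responses

For status *s* ∈ {native, alien} at site *j*:

* total abundance `T_sj` = Σ measurements of taxa with status *s*;
  divided by the site's sampling effort only in studies whose effort
  varies among sites.  Occurrence-only studies have missing abundance.
* species richness `S_sj` = number of distinct taxa of status *s* with
  measurement > 0.
* Studies that sampled the whole assemblage but whose classified taxa
  are all one status contribute zeros for the other status; studies
  that deliberately targeted one status contribute missing values for
  the other.
* site weight `w_j` = (classified taxa at *j*) / (recorded taxa at
  *j*): sites dominated by unclassifiable taxa carry little weight, and
  a fully unclassified site (weight 0) is effectively excluded.

Abundance is rescaled to [0, 1] within each study by the study maximum
(one shared scale across both statuses — the spec leaves the split
ambiguous and a shared scale keeps native and alien rows comparable
within a study), then square-root transformed; the model response is
`sqrt(T_sj / max_study T)`.  Richness is modelled as counts.

HPD and DistRd are ln-transformed (ln(x+1) for HPD always, and for
DistRd whenever a zero distance occurs, which raster-derived road
distances avoid but synthetic data may not), min-max rescaled to [0, 1]
over the modelling dataset (constants stored with the transform so
predictions are reproducible), and expanded into orthonormal quadratic
polynomial bases (QR of the centred powers, signs fixed positive
against the raw powers — the contract of orthogonal polynomials in
standard statistical software).

## Pairwise compositional similarity

For an ordered within-study pair (*i*, *j*) and one status:

* `J_R = S_ij / S_j` — the share of *j*'s species also present at *i*;
* `J_A = A_ij / A_j` — the share of *j*'s summed abundance contributed
  by species shared with *i*.

Both lie in [0, 1], equal 1 when *j* is nested in *i*, and are
undefined when site *j* has no organisms of that status (the undefined
direction is dropped; the reverse direction, with a non-empty *j*, is
kept).  Study-level exclusions applied before pairing, so the J_R and
J_A models use identical data: occurrence-only studies, studies with
varying effort, and single-species studies.  Pair-level exclusions:
zero geographic distance (coordinate imprecision) and undefined
environmental distance.

Distances and transforms:

* geographic: haversine on a sphere of radius 6,378,137 m; transformed
  as `ln(d / median MLE)` where the median maximum linear extent is
  taken over the sites entering the pair dataset, so zero means
  adjacent sites;
* environmental: Gower distance over altitude and four bioclimatic
  variables, ranges computed once over the modelling dataset (a single
  dissimilarity definition, not per study); cube-root transformed;
* similarity: logit after the range compression `y → 0.01 + 0.98 y`,
  which keeps 0 and 1 finite and the transform strictly monotone.

Each pair row is weighted by the proportion of classified species at
site *j* (the site whose assemblage is being "explained").

## Mixed models

All three families run through one variance-components engine:

* **Abundance** (gaussian): response `sqrt` rescaled abundance, weights
  as per-observation precision multipliers.
* **Richness** (Poisson, log link): weights multiply log-likelihood
  contributions; an observation-level random effect (OLRE) absorbs
  extra-Poisson variance.
* **Similarity** (gaussian): response logit J, study random intercept,
  pair weights.

Random-effect structures are variance components over grouping factors:
study, block nested in study (keyed by the study × block combination),
island, and land use within study for random slopes.  Random slopes are
implemented as independent per-(study, land-use) deviations with a
single shared variance — the diagonal analogue of a full 7 × 7 slope
covariance, which is not identifiable at the synthetic sample sizes and
matches the generator's scalar slope deviation.  Candidate structures
follow the study design: (i) slopes + study + block + island,
(ii) slopes + study + block, (iii) study + block + island,
(iv) study + block; island-trait models compare study vs study +
island.  Structures are compared by AIC (REML for gaussian, Laplace ML
for Poisson); non-converging candidates are dropped and the fallback is
recorded.

**Gaussian estimation.**  With V₀ = W⁻¹ + Σ_k γ_k Z_k Z_kᵀ (W the
weight matrix, γ_k variance ratios), β and σ² are profiled out
analytically and the profiled deviance is minimised over log γ by
Nelder-Mead (two starts, tolerance 1e-10 on the objective; bounds
−20 ≤ log γ ≤ 12, a ratio at the lower bound flags a singular fit and
reproduces weighted least squares to ≈ 1e-8).  All linear algebra runs
through the Woodbury identity on the (small) random-effect dimension,
and the response-dependent cross-products are isolated so the same
design refits a permuted response in microseconds.  REML adds the usual
ln |XᵀV₀⁻¹X| term and uses n − p degrees of freedom.  The implementation
agrees with lme4's `lmer` to six decimals on weighted ML fits (checked
in the test suite via Rscript).

**Poisson estimation.**  For fixed variance parameters, (β, u) maximise
the penalised log-likelihood by damped Newton iterations (PIRLS); the
Laplace approximation ℓ = f(β̂, û) − ½ ln|G| − ½ ln|ZᵀMZ + G⁻¹| is then
maximised over log variances by Nelder-Mead.  Profiling β inside PIRLS
makes this the same estimator as `glmer(..., nAGQ = 0)`, with which it
agrees to six decimals (also checked against R).  β's covariance comes
from the Schur complement of the joint Hessian.

**Simplification and diagnostics.**  Fixed effects are simplified
backwards under ML: at each step every droppable term (marginality
respected — a main effect never leaves while an interaction contains
it) is tested by LRT; the least significant term with p ≥ α (α = 0.05)
is dropped.  Because two independently optimised fits can carry
opposite-signed optimiser noise, the nested pair is "polished": if the
reduced model found a better variance-ratio point, the full model is
re-optimised from there, guaranteeing a non-negative LR (asserted).
A significance level of exactly zero is a sentinel meaning "never
drop".  Collinearity is screened by generalised variance inflation
factors, det(R₁₁)det(R₂₂)/det(R) over the fixed-effects correlation
matrix per term group.  Post-hoc slope tests build the per-level slope
as a design-row contrast (level at covariate 1 minus covariate 0) with
Wald chi-square on 1 df.

## Permutation inference

The similarity models' pairwise rows are massively pseudo-replicated,
so term significance uses permutation: the response column is shuffled
among rows within each study (explanatory variables, weights and
grouping fixed) and the LR (or coefficient) is recomputed.  p =
(1 + #{null as or more extreme}) / (1 + n_perm), so 199 permutations
give a floor of 0.005.  Coefficient tests are two-tailed by absolute
value.  Randomness flows through a seed tree (`numpy` `SeedSequence`):
one stream per permutation index and one branch per term test during
stepwise simplification (the permuted datasets are regenerated per
test rather than reused — the source procedure leaves this open, and
regeneration keeps tests independent of execution order).  If more
than 5% of permutation fits fail to converge the test errors rather
than report a biased null.

## Reporting scale

Effects are reported as percent change versus the PriMin baseline
(PriMin–PriMin for similarity):

* abundance: with s₀, s₁ the fixed-effects predictions on the
  square-root scale (covariates at their reference of zero),
  `%Δ = (s₁²/s₀² − 1)·100`.  The interval is a delta-method Wald
  interval on ln(s₁²/s₀²) carrying var(s₀), var(s₁) and their
  covariance — a calibration simulation showed the simpler
  fixed-baseline interval undercovers because it ignores the
  baseline's uncertainty.
* richness: `%Δ = (exp δ − 1)·100` with the Wald interval of the
  contrast δ exponentiated.
* similarity: the focal contrast minus PriMin–PriMin on the logit
  scale, also back-transformed through the inverse compressed logit;
  contrasts informed by fewer than 3 studies are flagged unreliable
  (generalising the suppression of 1–2-study contrasts).

Critical values use Student t with (number of studies − 1) degrees of
freedom rather than 1.96: the reported contrasts are identified between
studies, and with ~15 study clusters normal quantiles are
anticonservative (with the ~150 studies of a full compiled dataset the
two coincide).  ML is used wherever likelihoods are compared; final
gaussian models are refitted by REML for reported estimates and
intervals.  The baseline group's interval has zero width by
construction.

## Synthetic-data generator

The generator emulates the statistical structure the models assume —
it is the test bed, not a biogeographic simulation.

Mechanics per island: a native and an alien species pool; each species
has a lognormal relative abundance λ (meanlog 1.2, sdlog 0.8), a home
point in the island's 1° box, and a range radius drawn log-uniformly
with width 1/decay_rate_geo around a 60 km scale, which makes the
probability that two sites share a species fall linearly in ln
distance — the distance-decay the similarity models estimate.  A
species is present at a site if the site lies in its range **and** an
independent Bernoulli fires with probability

    base occupancy × richness effect(land use, status)
      × exp(study + block + island + slope random effects)
      × exp(isolation effect × centred surrounding landmass)   [aliens]

so expected richness scales exactly with the configured richness
effects (probabilities are clipped at 1; the generator warns when
clipping exceeds 5% and reports the clip fraction in the truth record).
Given presence, the count is `1 + NB(μ − 1)` with
μ = λ × (abundance effect / richness effect) × random effects, negative
binomial size = 1/overdispersion (0 = Poisson).  The +1 floor keeps
presence and abundance decoupled so both configured effect vectors are
generating truths; its cost is a small (<1%) inflation of means for
species with μ < 1, documented rather than hidden.

Defaults are the reference study conditions: 15 studies × 12 sites on
5 islands; native land-use abundance effects
(1, 1, 0.88, 0.70, 0.79, 0.68, 1) — i.e. −12/−30/−21/−32% in
secondary/plantation/cropland/pasture — and richness effects down to
0.35 (−65%) in pasture and 0.50 (−50%) in cropland; alien effects
increase in disturbed classes; overdispersion 0.5; random-effect SDs
0.30 (study), 0.15 (block), 0.10 (island), 0.10 (slopes); 15% of
species unclassified; isolation effect −0.3 on log alien richness per
unit surrounding landmass.  Pool sizes and base occupancies
(150 natives × 0.5, 60 aliens × 0.25) satisfy two design requirements
at once: the alien share of classified species at a PriMin site is
15/90 ≈ 17%, and sites are species-rich enough that the site-level
coefficient of variation of total abundance is nearly homogeneous
across land uses.  The second requirement matters because the
square-root-scale analysis estimates E[√T] ratios: when species-poor
classes have much higher CV, Jensen's inequality drags their estimand
below the configured multiplier, and no estimator of the prescribed
form can recover the configured truth.  In the default regime the
estimand sits within two percentage points of the configured value for
every land use.

What the generator does **not** emulate: species–area curves,
phylogenetic or trait structure, occupancy–abundance correlations,
metric_kind heterogeneity (all studies report abundance; the
occurrence-only code path is exercised by hand-built fixtures), and
real spatial covariance of the environmental variables (smooth
gradients plus noise only).  Passing tests therefore demonstrate that
the pipeline recovers known effects under the models' own assumptions,
not that those assumptions hold in any real dataset.

## Problem sizes and calibration results

The test suite's simulation sizes are chosen to make each statistical
property measurable in minutes on one core: parameter recovery uses 100
replicates of the default scenario (abundance) and of a lean
12-study × 10-site, no-block scenario (richness with study + OLRE
random effects); null calibration of the permutation LR test uses 200
datasets of 20 studies × 10 sites with 99 permutations each (the 0.005
floor itself is demonstrated with the conventional 199); the Wilks
check uses 500 replicates.  Observed calibration at these sizes:
abundance coverage 90–100 per 100 across the four native effects,
richness 96–98, permutation rejection rate inside the binomial 95%
band around 0.05.

## Known limitations

* The Poisson engine is the nAGQ = 0 Laplace estimator; for very small
  counts with large random effects it shares that estimator's known
  bias relative to adaptive quadrature.
* Random slopes are diagonal (no slope–intercept correlation).
* Permutation of the response within studies tests exchangeability of
  whole rows; restricted schemes (e.g. permuting sites rather than
  pair rows) are out of scope.
* The `%Δ` interval for abundance treats the variance parameters as
  known (standard Wald practice); profile or bootstrap intervals are
  not provided.
* GVIF requires every term to have non-degenerate variation; perfectly
  aliased designs error out upstream at the rank check.
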