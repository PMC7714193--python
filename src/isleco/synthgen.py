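"""Forward simulation of island assemblage surveys with known truth.

The generator emulates the statistical structure the downstream models
assume, so that every stage of the pipeline (site metrics, pairwise
similarity, mixed models, permutation inference, reporting) can be
exercised against a known generating process:

* a source -> study -> block -> site hierarchy, each study on one island;
* separate native and alien species pools per island;
* land-use effects on expected total abundance and expected species
  richness that differ between natives and aliens (multiplicative, with
  minimally-used primary vegetation ``PriMin`` as baseline 1);
* lognormal random effects of study, block, island and of land use
  within study (random slopes) on the expected-count scale;
* gamma-Poisson (negative binomial) counts with configurable
  overdispersion;
* compositional distance decay: each species occupies a disc of
  log-uniform radius around a random home point, so the probability
  that two sites share a species falls linearly in log distance;
* an isolation effect on alien richness (fewer aliens on islands with
  more surrounding landmass); and
* a configurable fraction of species whose status is hidden
  (relabelled ``unknown``).

Species occupancy and species abundance are generated by separate
mechanisms so the configured richness effects and abundance effects are
each the generating truth: a species is present at a site with
probability ``base occupancy x richness effect x random effects``
(independent of its abundance), and, given presence, its count is
``1 + NB(mu - 1)`` with ``mu`` proportional to the ratio of abundance
to richness effect — making expected total abundance scale exactly
with the configured abundance effect.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import LAND_USES
from .pairs import geographic_distance

__all__ = ["SimulationConfig", "simulate_dataset", "truth_report", "draw_counts"]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: Default land-use composition of sites (PriMin, Primary, Secondary,
#: Plantation, Cropland, Pasture, Urban).
_DEFAULT_LU_PROBS = (0.25, 0.10, 0.20, 0.10, 0.15, 0.15, 0.05)

# Multiplicative land-use effects on expected total abundance, baseline
# PriMin = 1.  Natives decline in working landscapes (pasture -32%,
# plantation -30%, cropland -21%, secondary -12%); aliens increase in
# all disturbed classes.
_DEFAULT_AB_NATIVE = (1.0, 1.0, 0.88, 0.70, 0.79, 0.68, 1.0)
_DEFAULT_AB_ALIEN = (1.0, 1.5, 1.8, 2.5, 2.8, 3.2, 3.5)

# Multiplicative land-use effects on expected species richness
# (native cropland -50%, pasture -65%).
_DEFAULT_RICH_NATIVE = (1.0, 1.0, 0.90, 0.70, 0.50, 0.35, 0.85)
_DEFAULT_RICH_ALIEN = (1.0, 1.3, 1.5, 2.2, 1.6, 2.2, 1.9)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic dataset.

    Defaults describe the reference scenario used throughout the test
    suite: 15 studies of 12 sites on 5 islands, native abundance
    effects matching -32/-30/-21/-12% in pasture/plantation/cropland/
    secondary vegetation, native richness effects of -65%/-50% in
    pasture/cropland, and base occupancies calibrated so that roughly
    17% of the classified species at a PriMin site are aliens.
    """

    n_studies: int = 15
    sites_per_study: int = 12
    n_islands: int = 5
    land_use_probs: tuple = _DEFAULT_LU_PROBS
    native_pool_size: int = 150
    alien_pool_size: int = 60
    effect_landuse_native: tuple = _DEFAULT_AB_NATIVE
    effect_landuse_alien: tuple = _DEFAULT_AB_ALIEN
    richness_effects_native: tuple = _DEFAULT_RICH_NATIVE
    richness_effects_alien: tuple = _DEFAULT_RICH_ALIEN
    #: Quadratic overdispersion of counts: Var = mu (1 + overdispersion * mu).
    #: 0 recovers Poisson; the negative-binomial size is its reciprocal.
    overdispersion: float = 0.5
    study_sd: float = 0.30
    block_sd: float = 0.15
    island_sd: float = 0.10
    slope_sd: float = 0.10
    #: Slope of the decline of species-sharing probability per unit of
    #: ln geographic distance.
    decay_rate_geo: float = 0.15
    unclassified_fraction: float = 0.15
    #: Effect of surrounding landmass (centred) on log expected alien
    #: richness; negative means more aliens on isolated islands.
    island_isolation_effect_alien: float = -0.3
    seed: int = 0
    # Base per-species site-occupancy probabilities (before land-use and
    # random effects).  Together with the pool sizes these set the PriMin
    # alien share of species at ~17% and keep sites species-rich enough
    # that the site-level coefficient of variation of total abundance is
    # nearly homogeneous across land uses — the regime in which the
    # square-root-scale analysis estimates the configured multipliers.
    base_occupancy_native: float = 0.5
    base_occupancy_alien: float = 0.25
    #: Fraction of the alien pool made specialists of one land use
    #: (novel species absent elsewhere); 0 disables.
    alien_specialist_fraction: float = 0.0
    alien_specialist_landuse: str = "Cropland"

    def validate(self) -> "SimulationConfig":
        probs = np.asarray(self.land_use_probs, dtype=float)
        if probs.shape != (7,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("land_use_probs must be 7 non-negative values summing to 1")
        for name in ("native_pool_size", "alien_pool_size", "n_studies",
                     "sites_per_study", "n_islands"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("effect_landuse_native", "effect_landuse_alien",
                     "richness_effects_native", "richness_effects_alien"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (7,) or (v <= 0).any():
                raise ValueError(f"{name} must be 7 positive multipliers")
        if not 0.0 <= self.unclassified_fraction <= 1.0:
            raise ValueError("unclassified_fraction must lie in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if probs.max() == 1.0 and self.sites_per_study < 2:
            warnings.warn("degenerate config: a single land use and <2 sites per study",
                          stacklevel=2)
        return self


def draw_counts(mean, overdispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson counts with Var = mu (1 + overdispersion * mu).

    ``overdispersion`` is the reciprocal negative-binomial size; 0 gives
    exact Poisson draws.
    """
    mean = np.asarray(mean, dtype=float)
    if overdispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / overdispersion
    lam = rng.gamma(shape, overdispersion * mean)
    return rng.poisson(lam)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig):
    """Generate one dataset in the canonical table format plus its truth.

    Returns ``(assemblage, sites, islands, truth)`` where the first
    three are DataFrames matching the io_model column dictionaries and
    ``truth`` is a JSON-serialisable dict of every generating parameter
    and derived per-land-use truths.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    lu_probs = np.asarray(cfg.land_use_probs, dtype=float)

    # ---- islands ---------------------------------------------------------
    islands = pd.DataFrame({
        "island_id": [f"isl{i:02d}" for i in range(cfg.n_islands)],
        "area_km2": np.round(np.exp(rng.normal(7.0, 1.5, cfg.n_islands)), 2),
        "surrounding_landmass": np.round(rng.uniform(0.5, 2.5, cfg.n_islands), 4),
        "gdp_per_capita": np.round(np.exp(rng.normal(9.5, 0.8, cfg.n_islands)), 2),
    })
    isl_center_lon = rng.uniform(-150, 150, cfg.n_islands)
    isl_center_lat = rng.uniform(-35, 35, cfg.n_islands)
    landmass_c = islands["surrounding_landmass"].to_numpy() - 1.5

    # ---- species pools per island ---------------------------------------
    # Each species has a home point inside the island's 1-degree box and a
    # range radius; log-uniform radii make the probability of two sites
    # sharing a species fall linearly in ln distance with slope
    # -decay_rate_geo.
    log_width = 1.0 / cfg.decay_rate_geo
    rho_center = np.log(60_000.0)  # metres; typical within-island scale

    pools = []  # per island: dict of arrays
    n_spec_alien = int(round(cfg.alien_specialist_fraction * cfg.alien_pool_size))
    for i in range(cfg.n_islands):
        n_nat, n_al = cfg.native_pool_size, cfg.alien_pool_size
        n_tot = n_nat + n_al
        status = np.array(["native"] * n_nat + ["alien"] * n_al)
        specialist = np.zeros(n_tot, dtype=bool)
        if n_spec_alien:
            specialist[n_nat:n_nat + n_spec_alien] = True
        pool = {
            "taxon_id": np.array([f"isl{i:02d}_sp{k:03d}" for k in range(n_tot)]),
            "status": status,
            "specialist": specialist,
            "lam": np.exp(rng.normal(1.2, 0.8, n_tot)),
            "home_lon": isl_center_lon[i] + rng.uniform(-0.5, 0.5, n_tot),
            "home_lat": isl_center_lat[i] + rng.uniform(-0.5, 0.5, n_tot),
            "radius": np.exp(rho_center + rng.uniform(-0.5, 0.5, n_tot) * log_width),
        }
        n_unknown = int(round(cfg.unclassified_fraction * n_tot))
        hidden = np.zeros(n_tot, dtype=bool)
        if n_unknown:
            hidden[rng.choice(n_tot, size=n_unknown, replace=False)] = True
        pool["hidden"] = hidden
        pools.append(pool)

    # ---- studies, blocks, sites -----------------------------------------
    study_island = np.arange(cfg.n_studies) % cfg.n_islands
    u_study = rng.normal(0.0, cfg.study_sd, cfg.n_studies)
    u_island = rng.normal(0.0, cfg.island_sd, cfg.n_islands)
    u_slope = rng.normal(0.0, cfg.slope_sd, (cfg.n_studies, 7))
    n_blocks = 2 if cfg.block_sd > 0 else 0
    u_block = rng.normal(0.0, cfg.block_sd, (cfg.n_studies, max(n_blocks, 1)))

    eff_ab = {"native": np.asarray(cfg.effect_landuse_native, float),
              "alien": np.asarray(cfg.effect_landuse_alien, float)}
    eff_rich = {"native": np.asarray(cfg.richness_effects_native, float),
                "alien": np.asarray(cfg.richness_effects_alien, float)}
    base_occ = {"native": cfg.base_occupancy_native, "alien": cfg.base_occupancy_alien}

    site_rows, occ_rows = [], []
    n_clipped = 0
    n_occ_prob = 0
    spec_lu = cfg.alien_specialist_landuse
    for s in range(cfg.n_studies):
        isl = study_island[s]
        pool = pools[isl]
        study_id = f"st{s:02d}"
        source_id = f"src{s // 2:02d}"
        mle = float(rng.choice([50.0, 100.0, 200.0]))
        lus = rng.choice(7, size=cfg.sites_per_study, p=lu_probs)
        lon = isl_center_lon[isl] + rng.uniform(-0.5, 0.5, cfg.sites_per_study)
        lat = isl_center_lat[isl] + rng.uniform(-0.5, 0.5, cfg.sites_per_study)
        block_of = rng.integers(0, max(n_blocks, 1), cfg.sites_per_study)

        # smooth environmental fields plus local noise
        altitude = 400 + 900 * (lat - isl_center_lat[isl]) + rng.normal(0, 60, cfg.sites_per_study)
        tmax = 29 - 0.006 * altitude + rng.normal(0, 0.8, cfg.sites_per_study)
        tmin = tmax - 10 + rng.normal(0, 0.8, cfg.sites_per_study)
        precip_wet = 320 + 120 * (lon - isl_center_lon[isl]) + rng.normal(0, 25, cfg.sites_per_study)
        precip_dry = np.maximum(5.0, 60 + 12 * (lon - isl_center_lon[isl])
                                + rng.normal(0, 8, cfg.sites_per_study))
        hpd_mult = {0: 1, 1: 2, 2: 3, 3: 4, 4: 8, 5: 6, 6: 60}
        road_mult = {0: 4, 1: 3, 2: 2, 3: 1.5, 4: 1, 5: 1, 6: 0.1}

        for t in range(cfg.sites_per_study):
            lu = int(lus[t])
            site_id = f"{study_id}_site{t:02d}"
            block_id = f"{study_id}_b{block_of[t]}" if n_blocks else None
            g = (u_study[s] + u_island[isl]
                 + (u_block[s, block_of[t]] if n_blocks else 0.0)
                 + u_slope[s, lu])
            site_rows.append({
                "site_id": site_id, "study_id": study_id, "block_id": block_id,
                "island_id": f"isl{isl:02d}",
                "longitude": lon[t], "latitude": lat[t],
                "land_use": LAND_USES[lu],
                "hpd_raw": float(np.exp(rng.normal(2.0, 1.0)) * hpd_mult[lu]),
                "dist_road_raw": float(np.exp(rng.normal(5.5, 0.8)) * road_mult[lu]),
                "altitude": altitude[t], "tmax": tmax[t], "tmin": tmin[t],
                "precip_wet": precip_wet[t], "precip_dry": precip_dry[t],
                "max_linear_extent": mle,
            })

            # species occupancy: inside range AND an independent Bernoulli
            d = geographic_distance(pool["home_lon"], pool["home_lat"], lon[t], lat[t])
            in_range = d <= pool["radius"]
            stat = pool["status"]
            occ_base = np.where(stat == "native", base_occ["native"], base_occ["alien"])
            rich_mult = np.where(stat == "native",
                                 eff_rich["native"][lu], eff_rich["alien"][lu])
            iso = np.where(stat == "alien",
                           np.exp(cfg.island_isolation_effect_alien * landmass_c[isl]), 1.0)
            p_occ = occ_base * rich_mult * iso * np.exp(g)
            if pool["specialist"].any():
                p_occ = np.where(pool["specialist"],
                                 np.where(LAND_USES[lu] == spec_lu, 0.9, 0.02), p_occ)
            n_clipped += int((p_occ > 1).sum())
            n_occ_prob += p_occ.size
            p_occ = np.minimum(p_occ, 1.0)
            present = in_range & (rng.random(p_occ.size) < p_occ)
            idx = np.flatnonzero(present)
            if idx.size == 0:
                continue
            ab_mult = np.where(stat[idx] == "native",
                               eff_ab["native"][lu] / eff_rich["native"][lu],
                               eff_ab["alien"][lu] / eff_rich["alien"][lu])
            mu = pool["lam"][idx] * ab_mult * np.exp(g)
            counts = 1 + draw_counts(np.maximum(mu - 1.0, 0.0), cfg.overdispersion, rng)
            for k, c in zip(idx, counts):
                occ_rows.append({
                    "source_id": source_id, "study_id": study_id,
                    "block_id": block_id, "site_id": site_id,
                    "taxon_id": pool["taxon_id"][k],
                    "status": "unknown" if pool["hidden"][k] else stat[k],
                    "measurement": float(c),
                    "metric_kind": "abundance",
                    "sampling_effort": 1.0,
                })

    if n_clipped / max(n_occ_prob, 1) > 0.05:
        warnings.warn(
            f"occupancy probability clipped at 1 for {n_clipped / n_occ_prob:.1%} of "
            "species-site combinations; realised richness effects will be attenuated",
            stacklevel=2)

    sites = pd.DataFrame(site_rows)
    assemblage = pd.DataFrame(occ_rows)
    sites["block_id"] = sites["block_id"].astype("string")
    assemblage["block_id"] = assemblage["block_id"].astype("string")

    truth = {
        "config": dataclasses.asdict(cfg),
        "land_uses": list(LAND_USES),
        "effects": {
            "abundance": {"native": list(eff_ab["native"]), "alien": list(eff_ab["alien"])},
            "richness": {"native": list(eff_rich["native"]), "alien": list(eff_rich["alien"])},
        },
        "random_effects": {
            "study": u_study.tolist(),
            "island": u_island.tolist(),
            "slope": u_slope.tolist(),
            "block": u_block.tolist() if n_blocks else [],
        },
        "hidden_taxa": sorted(
            t for pool in pools for t in pool["taxon_id"][pool["hidden"]]),
        "true_status": {t: s for pool in pools
                        for t, s in zip(pool["taxon_id"], pool["status"])},
        "occupancy_clip_fraction": n_clipped / max(n_occ_prob, 1),
    }
    return assemblage, sites, islands, truth


def truth_report(truth: dict) -> pd.DataFrame:
    """Tabulate generating land-use effects on the reporting scale.

    One row per (response, status, land use): the multiplicative effect
    and its expression as percent change versus the PriMin baseline,
    directly comparable with the report module's back-transformed
    estimates.
    """
    rows = []
    for response, by_status in truth["effects"].items():
        for status, effects in by_status.items():
            for lu, f in zip(truth["land_uses"], effects):
                rows.append({
                    "response": response,
                    "status": status,
                    "land_use": lu,
                    "multiplier": f,
                    "percent_change": (f - 1.0) * 100.0,
                })
    return pd.DataFrame(rows)


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2), encoding="utf-8")
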