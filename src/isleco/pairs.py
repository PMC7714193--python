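"""Ordered pairwise site comparisons: asymmetric Jaccard similarity,
geographic and environmental distance, land-use contrasts and the
transforms used by the compositional-similarity models.

The similarity indices are directional.  For an ordered pair (i, j),

* ``J_R = S_ij / S_j`` — the share of site j's species also found at
  site i;
* ``J_A = A_ij / A_j`` — the share of site j's total abundance
  contributed by species also found at site i.

Both are 1 when j's assemblage is nested in i's, 0 when the sites share
nothing, and undefined (NaN, later dropped) when site j has no
organisms of the focal status.  Because the indices are asymmetric,
every unordered pair yields two rows (forward and reverse).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_model import ENV_VARIABLES

__all__ = [
    "jaccard_richness_asym",
    "jaccard_abundance_asym",
    "geographic_distance",
    "transform_geo",
    "environmental_distance",
    "env_ranges",
    "logit_adjusted",
    "inverse_logit_adjusted",
    "build_pair_table",
]

#: Sphere radius (m) used for great-circle distance, matching the
#: default of the haversine implementation standard in this field.
EARTH_RADIUS_M = 6_378_137.0


# --------------------------------------------------------------------------
# Similarity indices
# --------------------------------------------------------------------------


def jaccard_richness_asym(taxa_i: Iterable, taxa_j: Iterable) -> float:
    """Richness-based asymmetric Jaccard ``|i ∩ j| / |j|``.

    NaN (undefined) when site j has no taxa; such pairs are dropped
    downstream.
    """
    set_j = set(taxa_j)
    if not set_j:
        return float("nan")
    return len(set(taxa_i) & set_j) / len(set_j)


def jaccard_abundance_asym(abund_i: Mapping, abund_j: Mapping) -> float:
    """Abundance-based asymmetric Jaccard: the summed abundance at j of
    species shared with i, divided by j's total abundance.

    NaN when site j's total abundance is zero.
    """
    total_j = float(sum(abund_j.values()))
    if total_j <= 0:
        return float("nan")
    shared = set(abund_i) & set(abund_j)
    if len(shared) == len(abund_j):
        return 1.0  # j nested in i: exactly one regardless of summation order
    return sum(float(abund_j[t]) for t in shared) / total_j


# --------------------------------------------------------------------------
# Distances and transforms
# --------------------------------------------------------------------------


def geographic_distance(lon1, lat1, lon2, lat2):
    """Great-circle haversine distance in metres (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def transform_geo(geo_dist_m: float, median_mle_m: float) -> float:
    """ln(distance / median maximum linear extent).

    Zero on this scale means two adjacent sites (distance equal to the
    median site extent).  Zero distances must have been excluded
    upstream.
    """
    if median_mle_m <= 0:
        raise ValueError("median maximum linear extent must be positive")
    d = np.asarray(geo_dist_m, dtype=float)
    if (d <= 0).any():
        raise ValueError("geographic distance must be positive (zero-distance "
                         "pairs are excluded before transformation)")
    out = np.log(d / median_mle_m)
    return out if out.ndim else float(out)


def env_ranges(sites: pd.DataFrame) -> dict:
    """Per-variable ranges of the five environmental variables over the
    modelling dataset (used to scale Gower distance)."""
    return {v: float(sites[v].max() - sites[v].min()) for v in ENV_VARIABLES}


def environmental_distance(site_a, site_b, ranges: Mapping[str, float]) -> float:
    """Gower distance over altitude and the four bioclimatic variables.

    The mean over variables of |difference| / range.  Variables with
    zero range are dropped from the mean; a missing value in either
    site makes the distance undefined (NaN) and the pair is excluded.
    """
    terms = []
    for v in ENV_VARIABLES:
        r = ranges.get(v, 0.0)
        if r == 0.0:
            continue
        a, b = float(site_a[v]), float(site_b[v])
        if math.isnan(a) or math.isnan(b):
            return float("nan")
        terms.append(abs(a - b) / r)
    if not terms:
        return 0.0
    return float(np.mean(terms))


def logit_adjusted(y) -> float:
    """Logit with range compression ``y -> 0.01 + 0.98 y`` so 0 and 1
    stay finite; strictly monotone on [0, 1]."""
    arr = np.asarray(y, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("logit_adjusted requires values in [0, 1]")
    z = 0.01 + 0.98 * arr
    out = np.log(z / (1.0 - z))
    return out if out.ndim else float(out)


def inverse_logit_adjusted(v):
    """Inverse of :func:`logit_adjusted` (clipped back to [0, 1])."""
    z = 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))
    y = (z - 0.01) / 0.98
    out = np.clip(y, 0.0, 1.0)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Pair table assembly
# --------------------------------------------------------------------------


def _study_eligibility(occurrences: pd.DataFrame) -> tuple[set, dict]:
    """Apply the study-level exclusion rules shared by the J_R and J_A
    models: abundance data present, constant sampling effort, and more
    than one sampled species."""
    excl = {"no_abundance_data": 0, "varying_effort": 0, "single_species": 0}
    eligible = set()
    for study, grp in occurrences.groupby("study_id"):
        if (grp["metric_kind"] != "abundance").any():
            excl["no_abundance_data"] += 1
            continue
        if grp["sampling_effort"].nunique() > 1:
            excl["varying_effort"] += 1
            continue
        if grp["taxon_id"].nunique() <= 1:
            excl["single_species"] += 1
            continue
        eligible.add(study)
    return eligible, excl


def build_pair_table(
    occurrences: pd.DataFrame,
    sites: pd.DataFrame,
    statuses: tuple = ("native", "alien"),
) -> tuple[pd.DataFrame, dict]:
    """All ordered within-study site pairs with similarity, distances,
    contrasts, transforms and weights.

    Study-level exclusions (so the richness- and abundance-based models
    share one dataset): occurrence-only studies, studies whose sampling
    effort varies among sites, and studies that sampled a single
    species.  Pair-level exclusions: undefined similarity (site j empty
    for the focal status), zero geographic distance (coordinate
    imprecision) and undefined environmental distance (missing data).

    Weights are the proportion of classified species at site j.
    Returns the pair table and a log of exclusion counts.
    """
    from .sitemetrics import site_weight  # local import to avoid a cycle

    eligible, exclusions = _study_eligibility(occurrences)
    occ = occurrences[occurrences["study_id"].isin(eligible)]
    use_sites = sites[sites["study_id"].isin(eligible)].set_index("site_id")

    median_mle = float(use_sites["max_linear_extent"].median()) if len(use_sites) else float("nan")
    ranges = env_ranges(use_sites.reset_index()) if len(use_sites) else {}
    weights = site_weight(occ)

    present = occ[occ["measurement"] > 0]
    comp: dict[tuple, dict] = {}
    for (site, status), grp in present.groupby(["site_id", "status"]):
        comp[(site, status)] = dict(zip(grp["taxon_id"], grp["measurement"].astype(float)))

    exclusions.update({"empty_site_j": 0, "zero_geo_distance": 0, "missing_env": 0})
    rows = []
    for study, sgrp in use_sites.groupby("study_id"):
        ids = list(sgrp.index)
        lon = sgrp["longitude"].to_numpy()
        lat = sgrp["latitude"].to_numpy()
        lu = sgrp["land_use"].to_numpy()
        n = len(ids)
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                gd = geographic_distance(lon[a], lat[a], lon[b], lat[b])
                if gd <= 0:
                    exclusions["zero_geo_distance"] += 1
                    continue
                ed = environmental_distance(sgrp.iloc[a], sgrp.iloc[b], ranges)
                if math.isnan(ed):
                    exclusions["missing_env"] += 1
                    continue
                for status in statuses:
                    ab_i = comp.get((ids[a], status), {})
                    ab_j = comp.get((ids[b], status), {})
                    jr = jaccard_richness_asym(ab_i, ab_j)
                    ja = jaccard_abundance_asym(ab_i, ab_j)
                    if math.isnan(jr) or math.isnan(ja):
                        exclusions["empty_site_j"] += 1
                        continue
                    rows.append({
                        "study_id": study,
                        "site_i": ids[a], "site_j": ids[b],
                        "status": status,
                        "J_R": jr, "J_A": ja,
                        "landuse_contrast": f"{lu[a]}-{lu[b]}",
                        "geo_dist_m": gd,
                        "geo_dist_t": transform_geo(gd, median_mle),
                        "env_dist": ed,
                        "env_dist_t": ed ** (1.0 / 3.0),
                        "weight": float(weights.get(ids[b], 1.0)),
                        "logit_J_R": logit_adjusted(jr),
                        "logit_J_A": logit_adjusted(ja),
                    })
    table = pd.DataFrame(rows)
    exclusions["median_mle_m"] = median_mle
    exclusions["n_pairs"] = len(table)
    return table, exclusions
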