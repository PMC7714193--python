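"""Per-site, per-status diversity responses and model covariates.

For aliens and natives separately, each site gets a total abundance
(sum of the measurements of taxa of that status, divided by sampling
effort when effort varies within the study) and a species richness
(number of distinct taxa of that status recorded with measurement > 0).
Sites are weighted by the proportion of their recorded species that
could be classified as alien or native, so sites with mostly
unclassifiable species contribute little to the fits.

Abundances are rescaled to [0, 1] within each study (one shared study
maximum across both statuses) and square-root transformed before
gaussian modelling.  Human population density and distance to the
nearest road are log-transformed, min-max rescaled over the modelling
dataset and expanded into orthonormal quadratic polynomial bases.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "site_diversity",
    "apply_status_scope_rule",
    "site_weight",
    "rescale_abundance",
    "transform_pressures",
    "orthonormal_poly",
]

SCOPE_LEVELS = ("whole_assemblage", "natives_only", "aliens_only")


def site_diversity(occurrences: pd.DataFrame, status: str) -> pd.DataFrame:
    """Total abundance and species richness of one status per site.

    Abundance is effort-corrected (divided by the site's sampling
    effort) only in studies where effort varies among sites, keeping
    data comparable within each study while leaving constant-effort
    studies on their original scale.  Occurrence-only studies yield
    missing abundance.  Every site recorded in the study appears in the
    output; sites without taxa of the focal status get zeros (scope
    rules may later turn these into missing values).
    """
    if status not in ("native", "alien"):
        raise ValueError("status must be 'native' or 'alien'")
    base = (occurrences.groupby(["study_id", "site_id"])
            .agg(effort=("sampling_effort", "first"),
                 metric_kind=("metric_kind", "first"))
            .reset_index())
    effort_varies = occurrences.groupby("study_id")["sampling_effort"].nunique() > 1

    sub = occurrences[occurrences["status"] == status]
    ab = sub.groupby("site_id")["measurement"].sum()
    rich = sub[sub["measurement"] > 0].groupby("site_id")["taxon_id"].nunique()

    out = base.rename(columns={})
    out["status"] = status
    out["total_abundance"] = out["site_id"].map(ab).fillna(0.0)
    out["species_richness"] = out["site_id"].map(rich).fillna(0).astype(int)
    varying = out["study_id"].map(effort_varies).fillna(False)
    out.loc[varying, "total_abundance"] = (
        out.loc[varying, "total_abundance"] / out.loc[varying, "effort"])
    out.loc[out["metric_kind"] == "occurrence", "total_abundance"] = np.nan
    return out[["site_id", "study_id", "status", "total_abundance", "species_richness"]]


def apply_status_scope_rule(diversity: pd.DataFrame,
                            study_targets: Mapping[str, str]) -> pd.DataFrame:
    """Convert zeros to missing values for statuses a study never sampled.

    Studies that targeted the whole assemblage but whose classified
    records are all one status keep zeros for the absent status; studies
    that deliberately targeted only natives (or only aliens) get missing
    values for the other status, since it was never sampled.
    """
    out = diversity.copy()
    missing = sorted(set(out["study_id"]) - set(study_targets))
    if missing:
        raise KeyError(f"no target scope declared for studies {missing}")
    bad = [s for s, t in study_targets.items() if t not in SCOPE_LEVELS]
    if bad:
        raise ValueError(f"invalid target scope for studies {bad}")
    target = out["study_id"].map(dict(study_targets))
    mask = ((target == "natives_only") & (out["status"] == "alien")) | (
        (target == "aliens_only") & (out["status"] == "native"))
    out.loc[mask, ["total_abundance"]] = np.nan
    out.loc[mask, "species_richness"] = pd.NA
    out["species_richness"] = out["species_richness"].astype("Int64")
    return out


def site_weight(occurrences: pd.DataFrame, all_sites=None) -> pd.Series:
    """Per-site weight: distinct classified taxa / distinct recorded taxa.

    Sites with no recorded taxa weigh 1 (there is nothing unclassified
    to penalise); sites whose taxa are all unclassified weigh 0 and are
    thereby effectively excluded.
    """
    total = occurrences.groupby("site_id")["taxon_id"].nunique()
    classified = (occurrences[occurrences["status"] != "unknown"]
                  .groupby("site_id")["taxon_id"].nunique())
    w = (classified.reindex(total.index).fillna(0) / total).astype(float)
    if all_sites is not None:
        w = w.reindex(pd.Index(all_sites, name="site_id")).fillna(1.0)
    w.name = "weight"
    return w


def rescale_abundance(diversity: pd.DataFrame) -> pd.DataFrame:
    """Within-study zero-to-one rescaling and square-root transform.

    The study maximum is shared across native and alien rows (a single
    abundance scale per study).  Studies whose sites all have zero
    abundance keep zeros; occurrence-only studies stay missing.
    """
    out = diversity.copy()
    study_max = out.groupby("study_id")["total_abundance"].transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        rescaled = out["total_abundance"] / study_max
    rescaled[(study_max == 0) & out["total_abundance"].notna()] = 0.0
    out["rescaled_abundance"] = rescaled
    out["sqrt_rescaled_abundance"] = np.sqrt(rescaled)
    return out


def orthonormal_poly(x, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis of the centred powers of ``x``.

    Columns come from a QR factorisation of ``[x - mean, (x - mean)^2,
    ...]`` with unit norms, pairwise orthogonal, and signs fixed so each
    column correlates positively with its raw power — the contract of
    orthogonal-polynomial bases in standard statistical software.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size <= degree:
        raise ValueError(f"need more than {degree} distinct values for a "
                         f"degree-{degree} orthogonal polynomial basis")
    xc = x - x.mean()
    raw = np.column_stack([np.ones_like(xc)] +
                          [xc ** k for k in range(1, degree + 1)])
    # include the intercept in the QR so every basis column is exactly
    # orthogonal to it; near-duplicate inputs surface as a tiny pivot
    q, r = np.linalg.qr(raw)
    pivots = np.abs(np.diag(r))
    if (pivots < 1e-9 * max(pivots.max(), 1.0)).any():
        raise ValueError(f"need more than {degree} numerically distinct values "
                         f"for a degree-{degree} orthogonal polynomial basis")
    q = q[:, 1:]
    q /= np.linalg.norm(q, axis=0)
    for k in range(degree):
        if q[:, k] @ raw[:, k + 1] < 0:
            q[:, k] = -q[:, k]
    return q


def transform_pressures(sites: pd.DataFrame) -> pd.DataFrame:
    """Model covariates for the two continuous pressures.

    ``hpd_t`` is ln(HPD + 1) min-max rescaled to [0, 1] over the
    modelling dataset; ``dist_t`` is ln(DistRd) likewise (ln(x + 1)
    when any zero distance occurs, to keep the transform finite).
    Each is expanded into two orthonormal quadratic polynomial columns
    (``hpd_1``, ``hpd_2``, ``dist_1``, ``dist_2``).  The rescaling
    constants are stored in ``out.attrs['pressure_transforms']`` so
    predictions are reproducible.
    """
    out = sites.copy()
    constants = {}
    specs = {
        "hpd": (out["hpd_raw"], True),
        "dist": (out["dist_road_raw"], bool((out["dist_road_raw"] == 0).any())),
    }
    for name, (raw, plus_one) in specs.items():
        ln = np.log(raw + 1.0) if plus_one else np.log(raw)
        lo, hi = float(ln.min()), float(ln.max())
        if hi == lo:
            raise ValueError(f"covariate {name!r} is constant; min-max rescaling undefined")
        t = (ln - lo) / (hi - lo)
        out[f"{name}_t"] = t
        basis = orthonormal_poly(t.to_numpy(), 2)
        out[f"{name}_1"] = basis[:, 0]
        out[f"{name}_2"] = basis[:, 1]
        constants[name] = {"plus_one": plus_one, "ln_min": lo, "ln_max": hi}
    out.attrs["pressure_transforms"] = constants
    return out
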