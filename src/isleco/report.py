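"""Back-transformation of fitted models into headline quantities and
end-to-end orchestration.

The models work on transformed scales (square-root rescaled abundance,
log richness, logit compositional similarity); this module expresses
their fixed effects as percent changes versus the minimally-disturbed
baseline (PriMin sites, or the PriMin-PriMin land-use contrast), with
Wald confidence intervals back-transformed the same way — hence
asymmetric around the point estimate.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io_model, pairs, permtest, sitemetrics, synthgen
from .io_model import LAND_USES
from .modelfit import ModelSpec, backward_simplify, fit_mixed, posthoc_slopes, select_random_structure

__all__ = [
    "EffectEstimate",
    "percent_change_sqrt",
    "percent_change_log",
    "similarity_contrast_table",
    "percent_alien_share",
    "PipelineConfig",
    "run_pipeline",
]

Z95 = 1.959963984540054


def _crit(fit) -> float:
    """95% critical value for report intervals: Student t with
    (study clusters - 1) degrees of freedom, since the reported
    contrasts are identified between studies; reduces to the normal
    quantile for large cluster counts."""
    df = getattr(fit, "n_groups", 0) - 1
    if 0 < df < 200:
        return float(stats.t.ppf(0.975, df))
    return Z95

#: The 13 focal land-use contrasts: change from PriMin to each land use
#: (site i in PriMin) and within-land-use similarity for each non-baseline
#: class; PriMin-PriMin is the baseline.
FOCAL_CONTRASTS: tuple[str, ...] = tuple(
    [f"PriMin-{lu}" for lu in LAND_USES] + [f"{lu}-{lu}" for lu in LAND_USES[1:]])


@dataclass
class EffectEstimate:
    """A back-transformed effect versus the PriMin baseline."""

    group: tuple
    percent_change: float
    ci_low: float
    ci_high: float
    baseline: str
    scale: str

    def __post_init__(self):
        assert self.ci_low <= self.percent_change <= self.ci_high


def percent_change_sqrt(fit, group: tuple, at: dict | None = None) -> EffectEstimate:
    """Percent change in total abundance for one (status, land use).

    With ``s0`` the fixed-effects prediction for PriMin and ``s1`` for
    the focal land use on the square-root scale, the change is
    ``(s1^2 / s0^2 - 1) x 100``.  The interval is a delta-method Wald
    interval on ``ln(s1^2/s0^2)`` carrying the variances of both
    predictions and their covariance, with a Student t critical value
    on (study clusters - 1) degrees of freedom; back-transformation
    makes it asymmetric around the point estimate.
    """
    status, land_use = group
    base = dict(at or {})
    beta = fit.coefficients.to_numpy()
    V = fit.vcov.to_numpy()
    x1 = fit.predict_row({**base, "status": status, "land_use": land_use})
    x0 = fit.predict_row({**base, "status": status, "land_use": "PriMin"})
    s0 = float(x0 @ beta)
    if s0 <= 0:
        raise ValueError("degenerate baseline: PriMin prediction is not positive "
                         "on the square-root scale")
    s1 = float(x1 @ beta)
    delta = s1 - s0
    pc = (s1 ** 2 / s0 ** 2 - 1.0) * 100.0
    if s1 > 0:
        # delta-method interval for the squared ratio on the log scale,
        # carrying the baseline's uncertainty and its covariance with
        # the focal prediction
        v1 = float(x1 @ V @ x1)
        v0 = float(x0 @ V @ x0)
        c10 = float(x1 @ V @ x0)
        se_log = np.sqrt(max(v1 / s1 ** 2 + v0 / s0 ** 2
                             - 2.0 * c10 / (s1 * s0), 0.0))
        crit = _crit(fit)
        ratio2 = s1 ** 2 / s0 ** 2
        lo = (ratio2 * np.exp(-2.0 * crit * se_log) - 1.0) * 100.0
        hi = (ratio2 * np.exp(2.0 * crit * se_log) - 1.0) * 100.0
    else:
        # non-positive focal prediction: back-transform the contrast's
        # Wald endpoints with the baseline held fixed
        crit = _crit(fit)
        se = float(np.sqrt((x1 - x0) @ V @ (x1 - x0)))
        ends = ((s0 + delta - crit * se) ** 2 / s0 ** 2 - 1.0) * 100.0, \
               ((s0 + delta + crit * se) ** 2 / s0 ** 2 - 1.0) * 100.0
        lo, hi = min(*ends, pc), max(*ends, pc)
    return EffectEstimate(group=group, percent_change=pc,
                          ci_low=min(lo, pc), ci_high=max(hi, pc),
                          baseline="PriMin", scale="sqrt_abundance")


def percent_change_log(fit, group: tuple, at: dict | None = None) -> EffectEstimate:
    """Percent change in species richness for one (status, land use):
    ``(exp(beta) - 1) x 100`` with the Wald interval exponentiated."""
    status, land_use = group
    base = dict(at or {})
    beta = fit.coefficients.to_numpy()
    V = fit.vcov.to_numpy()
    x1 = fit.predict_row({**base, "status": status, "land_use": land_use})
    x0 = fit.predict_row({**base, "status": status, "land_use": "PriMin"})
    delta = float((x1 - x0) @ beta)
    se = float(np.sqrt((x1 - x0) @ V @ (x1 - x0)))
    crit = _crit(fit)
    pc = lambda d: (np.exp(d) - 1.0) * 100.0
    return EffectEstimate(group=group, percent_change=pc(delta),
                          ci_low=pc(delta - crit * se), ci_high=pc(delta + crit * se),
                          baseline="PriMin", scale="log_richness")


def similarity_contrast_table(fit, pair_data: pd.DataFrame,
                              min_studies: int = 3) -> pd.DataFrame:
    """Focal land-use-contrast effects from a similarity model.

    Per status, each of the 13 focal contrasts is expressed relative to
    PriMin-PriMin on the logit scale (distance terms at their reference
    of zero) and back-transformed to the similarity scale.  Contrasts
    informed by fewer than ``min_studies`` studies are flagged
    unreliable; contrasts absent from the data are marked missing.
    """
    beta = fit.coefficients.to_numpy()
    V = fit.vcov.to_numpy()
    counts = (pair_data.groupby(["status", "landuse_contrast"], observed=True)
              ["study_id"].nunique())
    rows = []
    for status in ("native", "alien"):
        x_base = fit.predict_row({"status": status,
                                  "landuse_contrast": "PriMin-PriMin"})
        base_logit = float(x_base @ beta)
        for contrast in FOCAL_CONTRASTS:
            n_stud = int(counts.get((status, contrast), 0))
            if n_stud == 0 and contrast != "PriMin-PriMin":
                rows.append({"status": status, "landuse_contrast": contrast,
                             "logit_diff": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "similarity": np.nan,
                             "baseline_similarity": pairs.inverse_logit_adjusted(base_logit),
                             "n_studies": 0, "reliable": False,
                             "missing": True})
                continue
            x1 = fit.predict_row({"status": status, "landuse_contrast": contrast})
            c = x1 - x_base
            d = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            crit = _crit(fit)
            rows.append({
                "status": status, "landuse_contrast": contrast,
                "logit_diff": d,
                "ci_low": d - crit * se, "ci_high": d + crit * se,
                "similarity": pairs.inverse_logit_adjusted(base_logit + d),
                "baseline_similarity": pairs.inverse_logit_adjusted(base_logit),
                "n_studies": n_stud,
                "reliable": n_stud >= min_studies,
                "missing": False,
            })
    return pd.DataFrame(rows)


def percent_alien_share(diversity: pd.DataFrame, land_use: str,
                        sites: pd.DataFrame) -> tuple[float, float]:
    """Mean alien share of species and of individuals in one land use.

    Per site, alien richness / total classified richness and alien
    abundance / total classified abundance; averaged over the land
    use's sites and expressed in percent.  Sites with no classified
    records (or no abundance data) drop from the respective mean.
    """
    lu_of = dict(zip(sites["site_id"], sites["land_use"]))
    d = diversity[diversity["site_id"].map(lu_of) == land_use]
    if d.empty:
        return (float("nan"), float("nan"))
    wide_r = d.pivot_table(index="site_id", columns="status",
                           values="species_richness", aggfunc="first")
    wide_a = d.pivot_table(index="site_id", columns="status",
                           values="total_abundance", aggfunc="first")
    for w in (wide_r, wide_a):
        for c in ("native", "alien"):
            if c not in w.columns:
                w[c] = 0.0
    tot_r = wide_r["native"].astype(float) + wide_r["alien"].astype(float)
    tot_a = wide_a["native"] + wide_a["alien"]
    share_r = (wide_r["alien"].astype(float) / tot_r)[tot_r > 0]
    share_a = (wide_a["alien"] / tot_a)[tot_a > 0]
    return (float(share_r.mean() * 100.0) if len(share_r) else float("nan"),
            float(share_a.mean() * 100.0) if len(share_a) else float("nan"))


# --------------------------------------------------------------------------
# Pipeline orchestration
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    ``simulation`` defines the synthetic dataset (ignored when
    ``input_dir`` points at canonical CSVs).  Permutation inference for
    the similarity models uses ``n_perm`` shuffles (199 gives the
    conventional 0.005 p-value floor).
    """

    simulation: synthgen.SimulationConfig = dataclasses.field(
        default_factory=synthgen.SimulationConfig)
    input_dir: str | None = None
    n_perm: int = 199
    permutations: bool = True
    simplify: bool = True
    island_models: bool = True
    structure_selection: bool = False
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = synthgen.SimulationConfig(**sim)
        return cls(simulation=sim, **d)


def _observed_categorical(series: pd.Series, baseline: str) -> pd.Categorical:
    levels = [baseline] + sorted(set(series) - {baseline})
    return pd.Categorical(series, categories=levels)


def build_model_table(assemblage: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Site-level modelling table: per-site, per-status diversity with
    rescaled responses, classification weights, land use, pressure
    covariates and the grouping columns the mixed models need."""
    div = pd.concat([sitemetrics.site_diversity(assemblage, s)
                     for s in ("native", "alien")], ignore_index=True)
    div = sitemetrics.rescale_abundance(div)
    w = sitemetrics.site_weight(assemblage)
    div["weight"] = div["site_id"].map(w).fillna(1.0)
    st = sitemetrics.transform_pressures(sites)
    tbl = div.merge(
        st[["site_id", "land_use", "island_id", "hpd_1", "hpd_2",
            "dist_1", "dist_2"]], on="site_id", how="left")
    tbl = tbl.merge(sites[["site_id", "block_id"]], on="site_id", how="left")
    tbl["land_use"] = pd.Categorical(tbl["land_use"], categories=[
        lu for lu in LAND_USES if lu in set(tbl["land_use"])])
    tbl["status"] = pd.Categorical(tbl["status"], categories=["native", "alien"])
    return tbl


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return inner
    return wrap


def _fit_to_dict(fit) -> dict:
    return {
        "terms": list(fit.spec.fixed_terms),
        "random_structure": str(fit.spec.random_structure),
        "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
        "vcov": fit.vcov.to_numpy().tolist(),
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "singular": fit.singular,
        "estimation": fit.estimation,
        "varcomps": fit.varcomps,
        "aic": fit.aic,
    }


def run_pipeline(config: PipelineConfig | dict, out_dir) -> Path:
    """Simulate (or load) -> site metrics -> pair table -> mixed models
    -> permutation inference -> report tables; everything written under
    ``out_dir`` with a manifest sufficient to reproduce the run."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.simulation.seed,
        "n_perm": config.n_perm,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    # ---- data ------------------------------------------------------------
    @_stage("data")
    def get_data():
        if config.input_dir:
            base = Path(config.input_dir)
            return (io_model.load_assemblage(base / "assemblage.csv"),
                    io_model.load_sites(base / "sites.csv"),
                    io_model.load_islands(base / "islands.csv"),
                    None)
        return synthgen.simulate_dataset(config.simulation)

    assemblage, sites, islands, truth = get_data()
    io_model.write_table(assemblage, out / "assemblage.csv")
    io_model.write_table(sites, out / "sites.csv")
    io_model.write_table(islands, out / "islands.csv")
    if truth is not None:
        synthgen.write_truth(truth, out / "truth.json")
    manifest["hierarchy_report"] = io_model.validate_hierarchy(assemblage, sites)

    # ---- site metrics ------------------------------------------------------
    @_stage("metrics")
    def metrics():
        div = pd.concat([sitemetrics.site_diversity(assemblage, s)
                         for s in ("native", "alien")], ignore_index=True)
        div = sitemetrics.rescale_abundance(div)
        w = sitemetrics.site_weight(assemblage)
        div["weight"] = div["site_id"].map(w).fillna(1.0)
        return div

    diversity = metrics()
    io_model.write_table(diversity, out / "site_diversity.csv")

    @_stage("covariates")
    def covariates():
        st = sitemetrics.transform_pressures(sites)
        manifest["pressure_transforms"] = st.attrs["pressure_transforms"]
        return build_model_table(assemblage, sites)

    model_data = covariates()

    # ---- site-level models -------------------------------------------------
    fits: dict[str, object] = {}
    trails: dict[str, list] = {}

    @_stage("site-models")
    def site_models():
        full_terms = (
            "land_use", "status", "hpd_1", "hpd_2", "dist_1", "dist_2",
            "land_use:status",
            "land_use:hpd_1", "land_use:hpd_2", "status:hpd_1", "status:hpd_2",
            "land_use:dist_1", "land_use:dist_2", "status:dist_1", "status:dist_2",
            "land_use:status:hpd_1", "land_use:status:hpd_2",
            "land_use:status:dist_1", "land_use:status:dist_2",
        )
        # land-use x pressure interactions are estimable only when every
        # land-use class has enough sites; thin datasets fall back to the
        # additive pressure structure
        min_class = int(sites.groupby("land_use").size().min())
        if min_class < 4:
            full_terms = ("land_use", "status", "hpd_1", "hpd_2",
                          "dist_1", "dist_2", "land_use:status")
        manifest["site_model_terms"] = list(full_terms)
        structure = "slopes+study+block"
        ab_spec = ModelSpec(response="sqrt_rescaled_abundance",
                            fixed_terms=full_terms,
                            random_structure=structure,
                            family="gaussian", weights="weight")
        ri_spec = ModelSpec(response="species_richness",
                            fixed_terms=full_terms,
                            random_structure=structure,
                            family="poisson_log", olre=True, weights="weight")
        if config.structure_selection:
            cands = ["slopes+study+block+island", "slopes+study+block",
                     "study+block+island", "study+block"]
            ab_best, ab_trail = select_random_structure(
                [dataclasses.replace(ab_spec, random_structure=c) for c in cands],
                model_data)
            manifest["abundance_structure_trail"] = ab_trail.to_dict("records")
            ab_spec = ab_best
        ri_data = model_data.dropna(subset=["species_richness"]).copy()
        ri_data["species_richness"] = ri_data["species_richness"].astype(float)
        if config.simplify:
            ab_fit, ab_trail = backward_simplify(ab_spec, model_data, config.alpha)
            ri_fit, ri_trail = backward_simplify(ri_spec, ri_data, config.alpha)
            trails["abundance"] = ab_trail.to_dict("records")
            trails["richness"] = ri_trail.to_dict("records")
        else:
            ab_fit = fit_mixed(ab_spec, model_data, reml=False)
            ri_fit = fit_mixed(ri_spec, ri_data, reml=False)
        # simplification compares models by ML; reported estimates and
        # intervals come from a REML refit of the final gaussian model
        fits["abundance"] = fit_mixed(ab_fit.spec, model_data, reml=True)
        fits["richness"] = ri_fit

    site_models()

    # ---- island-trait models ----------------------------------------------
    @_stage("island-models")
    def island_models():
        if not config.island_models:
            return
        traits = islands.assign(
            ln_area=np.log(islands["area_km2"]),
            landmass=islands["surrounding_landmass"],
            ln_gdp=np.log(islands["gdp_per_capita"]),
        )[["island_id", "ln_area", "landmass", "ln_gdp"]]
        alien = model_data[model_data["status"] == "alien"].merge(
            traits, on="island_id", how="left")
        # drop studies whose alien metrics are zero everywhere (these
        # zeros were assigned, not observed)
        nonzero = alien.groupby("study_id")["species_richness"].transform(
            lambda s: (s.fillna(0) > 0).any())
        alien = alien[nonzero]
        # the land use x trait interaction needs several sites per class
        class_counts = alien.groupby("land_use", observed=True).size()
        if len(alien) < 40 or (class_counts < 3).any():
            manifest["island_models"] = "skipped: too few alien observations per land use"
            return
        slopes = {}
        for trait in ("ln_area", "landmass", "ln_gdp"):
            spec = ModelSpec(response="species_richness",
                             fixed_terms=("land_use", trait, f"land_use:{trait}"),
                             random_structure="study+island",
                             family="poisson_log", weights="weight")
            data = alien.dropna(subset=["species_richness", trait]).copy()
            data["species_richness"] = data["species_richness"].astype(float)
            best, trail = select_random_structure(
                [dataclasses.replace(spec, random_structure="study"),
                 dataclasses.replace(spec, random_structure="study+island")], data)
            fit = fit_mixed(best, data)
            fits[f"island_richness_{trait}"] = fit
            slopes[trait] = posthoc_slopes(fit, focal=trait).to_dict("records")
        manifest["island_slope_tests"] = slopes
        pd.concat([
            posthoc_slopes(fits[f"island_richness_{t}"], focal=t).assign(trait=t)
            for t in ("ln_area", "landmass", "ln_gdp")
        ]).to_csv(out / "island_slopes.csv", index=False)

    island_models()

    # ---- pairwise similarity ----------------------------------------------
    @_stage("pairs")
    def pair_stage():
        table, excl = pairs.build_pair_table(assemblage, sites)
        manifest["pair_exclusions"] = excl
        # interactions with status need both statuses per contrast level
        ok = table.groupby("landuse_contrast")["status"].transform("nunique") == 2
        manifest["pair_exclusions"]["unbalanced_contrast_rows"] = int((~ok).sum())
        table = table[ok].copy()
        table["landuse_contrast"] = _observed_categorical(
            table["landuse_contrast"], "PriMin-PriMin")
        table["status"] = pd.Categorical(table["status"],
                                         categories=["native", "alien"])
        return table

    pair_table = pair_stage()
    io_model.write_table(pair_table, out / "pair_table.csv")

    @_stage("similarity-models")
    def similarity_models():
        terms = ("landuse_contrast", "geo_dist_t", "env_dist_t", "status",
                 "status:landuse_contrast", "status:geo_dist_t",
                 "status:env_dist_t")
        perm_results = {}
        for resp, label in (("logit_J_R", "J_R"), ("logit_J_A", "J_A")):
            spec = ModelSpec(response=resp, fixed_terms=terms,
                             random_structure="study", family="gaussian",
                             weights="weight")
            if config.permutations:
                fit, trail = permtest.stepwise_with_permutation(
                    spec, pair_table, alpha=config.alpha,
                    n_perm=config.n_perm, seed=config.simulation.seed + 7)
                trails[f"similarity_{label}"] = trail.to_dict("records")
            else:
                fit = fit_mixed(spec, pair_table, reml=False)
            fits[f"similarity_{label}"] = fit
            perm_results[label] = trails.get(f"similarity_{label}", [])
        if config.permutations:
            (out / "permutation_results.json").write_text(
                json.dumps(perm_results, indent=2, default=float), encoding="utf-8")

    similarity_models()

    # ---- report ------------------------------------------------------------
    @_stage("report")
    def report_stage():
        rows = []
        for status in ("native", "alien"):
            for lu in LAND_USES:
                try:
                    est = percent_change_sqrt(fits["abundance"], (status, lu))
                    rows.append({"status": status, "land_use": lu,
                                 "percent_change": est.percent_change,
                                 "ci_low": est.ci_low, "ci_high": est.ci_high})
                except Exception:
                    continue
        pd.DataFrame(rows).to_csv(out / "effects_abundance.csv", index=False)

        rows = []
        for status in ("native", "alien"):
            for lu in LAND_USES:
                try:
                    est = percent_change_log(fits["richness"], (status, lu))
                    rows.append({"status": status, "land_use": lu,
                                 "percent_change": est.percent_change,
                                 "ci_low": est.ci_low, "ci_high": est.ci_high})
                except Exception:
                    continue
        pd.DataFrame(rows).to_csv(out / "effects_richness.csv", index=False)

        sim_tables = []
        for label in ("J_R", "J_A"):
            t = similarity_contrast_table(fits[f"similarity_{label}"], pair_table)
            sim_tables.append(t.assign(index_kind=label))
        pd.concat(sim_tables).to_csv(out / "similarity_contrasts.csv", index=False)

        share_rows = []
        for lu in LAND_USES:
            sr, sa = percent_alien_share(diversity, lu, sites)
            share_rows.append({"land_use": lu, "share_richness_pct": sr,
                               "share_abundance_pct": sa})
        pd.DataFrame(share_rows).to_csv(out / "alien_share.csv", index=False)

    report_stage()

    (out / "fit.json").write_text(
        json.dumps({k: _fit_to_dict(f) for k, f in fits.items()},
                   indent=2, default=float), encoding="utf-8")
    if trails:
        trail_frames = []
        for k, t in trails.items():
            trail_frames.append(pd.DataFrame(t).assign(model=k))
        pd.concat(trail_frames).to_csv(out / "anova_trail.csv", index=False)
    manifest["outputs"] = sorted(p.name for p in out.iterdir())
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return out
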