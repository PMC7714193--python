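import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from isleco.io_model import LAND_USES
from isleco.modelfit import (
    ModelSpec,
    backward_simplify,
    droppable_terms,
    fit_mixed,
    gvif,
    posthoc_slopes,
    select_random_structure,
)


def _lmm_data(rng, n_groups=10, n_per=15, study_sd=0.6, beta=(1.0, 0.5),
              noise_sd=1.0, weights=False):
    n = n_groups * n_per
    g = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(size=n)
    u = rng.normal(0, study_sd, n_groups)
    y = beta[0] + beta[1] * x + u[g] + rng.normal(0, noise_sd, n)
    df = pd.DataFrame({"y": y, "x": x,
                       "study_id": [f"g{i:02d}" for i in g]})
    if weights:
        df["w"] = rng.uniform(0.3, 1.0, n)
    return df


class TestGaussianEngine:
    def test_zero_variance_data_matches_ols(self):
        """With no group-level variance the mixed fit collapses to
        ordinary least squares within 1e-6."""
        rng = np.random.default_rng(1)
        df = _lmm_data(rng, study_sd=0.0)
        fit = fit_mixed(ModelSpec("y", ("x",), "study"), df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = np.linalg.solve(X.T @ X, X.T @ df["y"])
        assert np.allclose(fit.coefficients.to_numpy(), ols, atol=1e-6)
        assert fit.singular  # variance pinned at the boundary

    def test_zero_variance_weighted_matches_wls(self):
        rng = np.random.default_rng(2)
        df = _lmm_data(rng, study_sd=0.0, weights=True)
        fit = fit_mixed(ModelSpec("y", ("x",), "study", weights="w"), df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        W = np.diag(df["w"])
        wls = np.linalg.solve(X.T @ W @ X, X.T @ W @ df["y"])
        assert np.allclose(fit.coefficients.to_numpy(), wls, atol=1e-6)

    def test_recovers_group_variance(self):
        rng = np.random.default_rng(3)
        df = _lmm_data(rng, n_groups=40, n_per=20, study_sd=0.8)
        fit = fit_mixed(ModelSpec("y", ("x",), "study"), df)
        assert fit.converged and not fit.singular
        assert fit.varcomps["study_id"] == pytest.approx(0.64, rel=0.5)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.2)

    def test_rank_deficient_design_names_aliased_columns(self):
        rng = np.random.default_rng(4)
        df = _lmm_data(rng)
        df["x2"] = df["x"]
        with pytest.raises(np.linalg.LinAlgError, match="x2"):
            fit_mixed(ModelSpec("y", ("x", "x2"), "study"), df)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestLme4Oracle:
    """Independent cross-checks against lme4 on tiny fixtures."""

    def test_weighted_gaussian_ml_matches_lmer(self, tmp_path):
        rng = np.random.default_rng(42)
        df = _lmm_data(rng, n_groups=8, n_per=12, study_sd=0.7, weights=True)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        fit = fit_mixed(ModelSpec("y", ("x",), "study", weights="w"), df)
        script = tmp_path / "m.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv('{csv}')
m <- lmer(y ~ x + (1|study_id), data=d, weights=w, REML=FALSE)
cat(sprintf('%.8f %.8f %.8f\\n', as.numeric(logLik(m)), fixef(m)[1], fixef(m)[2]))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        r_ll, r_b0, r_b1 = map(float, out)
        assert fit.loglik == pytest.approx(r_ll, abs=1e-4)
        assert fit.coefficients["Intercept"] == pytest.approx(r_b0, abs=1e-5)
        assert fit.coefficients["x"] == pytest.approx(r_b1, abs=1e-5)

    def test_poisson_olre_matches_glmer_nagq0(self, tmp_path):
        rng = np.random.default_rng(7)
        n_g, n_per = 10, 20
        g = np.repeat(np.arange(n_g), n_per)
        x = rng.normal(size=n_g * n_per)
        u = rng.normal(0, 0.5, n_g)
        eps = rng.normal(0, 0.4, n_g * n_per)
        y = rng.poisson(np.exp(1.5 + 0.3 * x + u[g] + eps)).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "study_id": [f"g{i}" for i in g]})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        fit = fit_mixed(ModelSpec("y", ("x",), "study", family="poisson_log",
                                  olre=True), df)
        script = tmp_path / "m.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv('{csv}')
d$obs <- seq_len(nrow(d))
m <- glmer(y ~ x + (1|study_id) + (1|obs), data=d, family=poisson, nAGQ=0)
cat(sprintf('%.6f %.6f %.6f\\n', as.numeric(logLik(m)), fixef(m)[1], fixef(m)[2]))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        r_ll, r_b0, r_b1 = map(float, out)
        assert fit.loglik == pytest.approx(r_ll, abs=1e-2)
        assert fit.coefficients["Intercept"] == pytest.approx(r_b0, abs=1e-3)
        assert fit.coefficients["x"] == pytest.approx(r_b1, abs=1e-3)


class TestPoissonEngine:
    def test_intercept_recovers_log_mean(self):
        rng = np.random.default_rng(11)
        n = 2000
        y = rng.poisson(5.0, n).astype(float)
        df = pd.DataFrame({"y": y, "study_id": "g0"})
        fit = fit_mixed(ModelSpec("y", (), "study", family="poisson_log"), df)
        se = 1.0 / np.sqrt(5.0 * n)
        assert fit.coefficients["Intercept"] == pytest.approx(np.log(5.0),
                                                              abs=4 * se)

    def test_olre_absorbs_overdispersion(self):
        """On gamma-Poisson counts at quadratic overdispersion 2 the
        OLRE variance comes out positive in nearly all replicates."""
        from isleco.synthgen import draw_counts
        positive = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            n_g, n_per = 8, 15
            g = np.repeat(np.arange(n_g), n_per)
            mu = np.exp(1.5 + rng.normal(0, 0.3, n_g)[g])
            y = draw_counts(mu, 2.0, rng).astype(float)
            df = pd.DataFrame({"y": y, "study_id": [f"g{i}" for i in g]})
            fit = fit_mixed(ModelSpec("y", (), "study", family="poisson_log",
                                      olre=True), df)
            if fit.varcomps["olre"] > 1e-4:
                positive += 1
        assert positive >= int(0.95 * n_rep)


class TestStructureSelection:
    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(21)
        df = _lmm_data(rng)
        spec = ModelSpec("y", ("x",), "study")
        best, trail = select_random_structure([spec], df)
        assert best == spec
        assert len(trail) == 1

    def test_strong_slope_variance_selects_slopes_structure(self):
        rng = np.random.default_rng(22)
        n_g, n_per = 12, 21
        g = np.repeat(np.arange(n_g), n_per)
        lu = np.tile(np.repeat(np.arange(7), 3), n_g)
        slope = rng.normal(0, 1.5, (n_g, 7))
        y = 1.0 + slope[g, lu] + rng.normal(0, 0.5, n_g * n_per)
        df = pd.DataFrame({
            "y": y, "study_id": [f"g{i}" for i in g],
            "land_use": pd.Categorical([LAND_USES[j] for j in lu],
                                       categories=LAND_USES),
            "block_id": pd.array([None] * (n_g * n_per), dtype="string"),
            "island_id": "i0"})
        cands = [ModelSpec("y", ("land_use",), s)
                 for s in ("slopes+study+block", "study+block")]
        best, _ = select_random_structure(cands, df)
        assert best.random_structure == "slopes+study+block"

    def test_zero_island_variance_prefers_island_free_structure(self):
        wins = 0
        for rep in range(5):
            rng = np.random.default_rng(30 + rep)
            df = _lmm_data(rng, n_groups=12, n_per=12, study_sd=0.6)
            df["island_id"] = [f"isl{int(s[1:]) % 4}" for s in df["study_id"]]
            cands = [ModelSpec("y", ("x",), s)
                     for s in ("study+island", "study")]
            best, _ = select_random_structure(cands, df)
            wins += best.random_structure == "study"
        assert wins >= 3


class TestBackwardSimplify:
    def _interaction_data(self, rng, effect=0.0, n_g=10, n_per=20):
        g = np.repeat(np.arange(n_g), n_per)
        x = rng.normal(size=n_g * n_per)
        z = rng.normal(size=n_g * n_per)
        u = rng.normal(0, 0.5, n_g)
        y = 1.0 + 0.5 * x + 0.3 * z + effect * x * z + u[g] \
            + rng.normal(0, 1.0, n_g * n_per)
        return pd.DataFrame({"y": y, "x": x, "z": z,
                             "study_id": [f"g{i}" for i in g]})

    def test_marginality_protects_main_effects(self):
        terms = ("x", "z", "x:z")
        assert droppable_terms(terms) == ["x:z"]

    def test_null_interaction_dropped_strong_retained(self):
        rng = np.random.default_rng(55)
        spec = ModelSpec("y", ("x", "z", "x:z"), "study")
        fit0, trail0 = backward_simplify(spec, self._interaction_data(rng, 0.0))
        assert "x:z" not in fit0.spec.fixed_terms
        assert "x" in fit0.spec.fixed_terms and "z" in fit0.spec.fixed_terms
        fit1, trail1 = backward_simplify(spec, self._interaction_data(rng, 1.0))
        assert "x:z" in fit1.spec.fixed_terms

    def test_trail_records_every_comparison(self):
        rng = np.random.default_rng(56)
        spec = ModelSpec("y", ("x", "z", "x:z"), "study")
        _, trail = backward_simplify(spec, self._interaction_data(rng, 0.0))
        assert {"step", "term", "lr", "df", "p", "action"} <= set(trail.columns)
        assert (trail["lr"] >= 0).all()
        assert (trail["action"] == "dropped").any()

    def test_null_lrt_statistic_is_chi_square(self):
        """Dropping a true-zero coefficient yields an ML deviance change
        distributed as chi-square(1) (Wilks), checked by KS at 200
        replicates."""
        from scipy import stats

        from isleco.modelfit import loglik_nested_pair
        lrs = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            n_g, n_per = 8, 10
            g = np.repeat(np.arange(n_g), n_per)
            x = rng.normal(size=n_g * n_per)
            z = rng.normal(size=n_g * n_per)  # true coefficient zero
            u = rng.normal(0, 0.5, n_g)
            y = 1.0 + 0.5 * x + u[g] + rng.normal(0, 1.0, n_g * n_per)
            df = pd.DataFrame({"y": y, "x": x, "z": z,
                               "study_id": [f"g{i}" for i in g]})
            full = fit_mixed(ModelSpec("y", ("x", "z"), "study"), df)
            red = fit_mixed(ModelSpec("y", ("x",), "study"), df)
            lf, lr_ = loglik_nested_pair(full, red)
            lrs.append(max(2 * (lf - lr_), 0.0))
        _, p = stats.kstest(lrs, stats.chi2(1).cdf)
        assert p > 0.01


class TestGVIF:
    def _fit(self, df, terms):
        return fit_mixed(ModelSpec("y", terms, "study"), df)

    def test_orthogonal_predictors_have_unit_gvif(self):
        rng = np.random.default_rng(61)
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x -= x.mean()
        z -= z.mean()
        z -= (z @ x) / (x @ x) * x  # exactly uncorrelated
        df = pd.DataFrame({"y": rng.normal(size=n), "x": x, "z": z,
                           "study_id": "g"})
        out = gvif(self._fit(df, ("x", "z")))
        assert out["x"][0] == pytest.approx(1.0, abs=1e-8)
        assert out["z"][0] == pytest.approx(1.0, abs=1e-8)

    def test_correlated_pair_matches_closed_form(self):
        """Two predictors with sample correlation r have
        VIF = 1 / (1 - r^2); at r = 0.8 that is 2.778."""
        rng = np.random.default_rng(62)
        n = 5000
        x = rng.normal(size=n)
        z = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        df = pd.DataFrame({"y": rng.normal(size=n), "x": x, "z": z,
                           "study_id": "g"})
        out = gvif(self._fit(df, ("x", "z")))
        r = np.corrcoef(x, z)[0, 1]
        expected = 1.0 / (1.0 - r ** 2)
        assert out["x"][0] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(2.778, abs=0.15)

    def test_duplicated_predictor_is_singular(self):
        rng = np.random.default_rng(63)
        n = 50
        x = rng.normal(size=n)
        df = pd.DataFrame({"y": rng.normal(size=n), "x": x, "x2": x.copy(),
                           "study_id": "g"})
        with pytest.raises(np.linalg.LinAlgError):
            gvif(self._fit(df, ("x", "x2")))


class TestPosthocSlopes:
    def _island_fit(self, rng, slopes):
        n_g, n_per = 10, 21
        g = np.repeat(np.arange(n_g), n_per)
        lu = np.tile(np.repeat(np.arange(7), 3), n_g)
        trait = rng.uniform(0, 1, n_g)[g]
        y = 1.0 + 0.2 * lu + np.array(slopes)[lu] * trait \
            + rng.normal(0, 0.4, n_g * n_per)
        df = pd.DataFrame({
            "y": y, "trait": trait, "study_id": [f"g{i}" for i in g],
            "land_use": pd.Categorical([LAND_USES[j] for j in lu],
                                       categories=LAND_USES)})
        spec = ModelSpec("y", ("land_use", "trait", "land_use:trait"), "study")
        return fit_mixed(spec, df)

    def test_reference_level_slope_equals_main_effect(self):
        rng = np.random.default_rng(71)
        fit = self._island_fit(rng, [0.5] * 7)
        out = posthoc_slopes(fit, focal="trait").set_index("land_use")
        assert out.loc["PriMin", "estimate"] == pytest.approx(
            fit.coefficients["trait"], abs=1e-10)

    def test_strong_negative_slope_detected(self):
        """A generating PriMin slope of -2.9 (the isolation effect size
        reported for alien richness) is significant at 0.001."""
        rng = np.random.default_rng(72)
        slopes = [-2.9, 0, 0, 0, 0, 0, 0]
        fit = self._island_fit(rng, slopes)
        out = posthoc_slopes(fit, focal="trait").set_index("land_use")
        assert out.loc["PriMin", "estimate"] == pytest.approx(-2.9, abs=0.5)
        assert out.loc["PriMin", "p"] < 0.001

    def test_missing_interaction_errors(self):
        rng = np.random.default_rng(73)
        df = pd.DataFrame({
            "y": rng.normal(size=21), "trait": rng.uniform(size=21),
            "study_id": "g",
            "land_use": pd.Categorical(
                [LAND_USES[i % 7] for i in range(21)], categories=LAND_USES)})
        fit = fit_mixed(ModelSpec("y", ("land_use", "trait"), "study"), df)
        with pytest.raises(ValueError, match="interaction"):
            posthoc_slopes(fit, focal="trait")


class TestModelSpecContracts:
    def test_olre_requires_poisson(self):
        with pytest.raises(ValueError, match="poisson"):
            ModelSpec("y", (), "study", family="gaussian", olre=True)

    def test_unknown_structure_rejected(self):
        with pytest.raises(KeyError):
            ModelSpec("y", (), "nonsense").resolve_random()

    def test_arbitrary_slope_terms_rejected(self):
        with pytest.raises(ValueError, match="slopes"):
            ModelSpec("y", (), (("island_id", "land_use"),))
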