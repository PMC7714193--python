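import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest

from isleco import SimulationConfig
from isleco.io_model import LAND_USES
from isleco.modelfit import ModelSpec, fit_mixed
from isleco.report import (
    FOCAL_CONTRASTS,
    PipelineConfig,
    percent_alien_share,
    percent_change_log,
    percent_change_sqrt,
    run_pipeline,
    similarity_contrast_table,
)


@pytest.fixture(scope="module")
def abundance_fit():
    """A deterministic gaussian fit on the square-root scale with known
    land-use contrasts (no noise, so predictions are exact)."""
    rng = np.random.default_rng(0)
    mult = {"PriMin": 1.0, "Pasture": 0.68, "Urban": 2.0}
    rows = []
    for rep in range(30):
        for lu, m in mult.items():
            rows.append({"y": math.sqrt(0.5 * m) + rng.normal(0, 1e-6),
                         "land_use": lu, "study_id": f"g{rep % 3}"})
    df = pd.DataFrame(rows)
    df["land_use"] = pd.Categorical(df["land_use"],
                                    categories=["PriMin", "Pasture", "Urban"])
    df["status"] = pd.Categorical(["native"] * len(df),
                                  categories=["native", "alien"])
    return fit_mixed(ModelSpec("y", ("land_use",), "study"), df)


class TestPercentChangeSqrt:
    def test_baseline_is_exactly_zero_with_zero_width_ci(self, abundance_fit):
        est = percent_change_sqrt(abundance_fit, ("native", "PriMin"))
        assert est.percent_change == 0.0
        assert est.ci_low == est.ci_high == 0.0

    def test_sqrt_ratio_back_transform(self, abundance_fit):
        """A land use at sqrt(0.68) x baseline on the square-root scale
        back-transforms to -32% total abundance."""
        est = percent_change_sqrt(abundance_fit, ("native", "Pasture"))
        assert est.percent_change == pytest.approx(-32.0, abs=0.1)
        est2 = percent_change_sqrt(abundance_fit, ("native", "Urban"))
        assert est2.percent_change == pytest.approx(100.0, abs=0.2)

    def test_ci_ordering_invariant(self, abundance_fit):
        est = percent_change_sqrt(abundance_fit, ("native", "Pasture"))
        assert est.ci_low <= est.percent_change <= est.ci_high


class TestPercentChangeLog:
    @pytest.fixture(scope="class")
    def richness_fit(self):
        rng = np.random.default_rng(1)
        mult = {"PriMin": 1.0, "Pasture": 0.35, "Urban": 2.0}
        rows = []
        for rep in range(60):
            for lu, m in mult.items():
                rows.append({"y": float(rng.poisson(40 * m)),
                             "land_use": lu, "study_id": f"g{rep % 3}"})
        df = pd.DataFrame(rows)
        df["land_use"] = pd.Categorical(df["land_use"],
                                        categories=["PriMin", "Pasture", "Urban"])
        df["status"] = pd.Categorical(["native"] * len(df),
                                      categories=["native", "alien"])
        return fit_mixed(ModelSpec("y", ("land_use",), "study",
                                   family="poisson_log"), df)

    def test_log_back_transform_round_trip(self, richness_fit):
        """exp / log back-transforms are exact inverses: a coefficient
        of ln(1 + p/100) reports p."""
        for p in (-65.0, -12.0, 40.0, 100.0):
            beta = math.log(1 + p / 100)
            assert (math.exp(beta) - 1) * 100 == pytest.approx(p)

    def test_recovery_of_minus_65_percent(self, richness_fit):
        est = percent_change_log(richness_fit, ("native", "Pasture"))
        assert est.percent_change == pytest.approx(-65.0, abs=3.0)
        assert est.ci_low <= est.percent_change <= est.ci_high
        base = percent_change_log(richness_fit, ("native", "PriMin"))
        assert base.percent_change == 0.0 and base.ci_low == base.ci_high == 0.0


class TestAlienShare:
    def _frames(self, rich_pairs):
        div_rows, site_rows = [], []
        for i, (nat, ali) in enumerate(rich_pairs):
            sid = f"s{i}"
            div_rows += [
                {"site_id": sid, "study_id": "st", "status": "native",
                 "total_abundance": float(nat), "species_richness": nat},
                {"site_id": sid, "study_id": "st", "status": "alien",
                 "total_abundance": float(ali), "species_richness": ali},
            ]
            site_rows.append({"site_id": sid, "land_use": "PriMin"})
        return pd.DataFrame(div_rows), pd.DataFrame(site_rows)

    def test_all_native_sites_share_zero(self):
        div, sites = self._frames([(5, 0), (3, 0)])
        sr, sa = percent_alien_share(div, "PriMin", sites)
        assert sr == 0.0 and sa == 0.0

    def test_one_in_five_gives_twenty_percent(self):
        div, sites = self._frames([(4, 1), (4, 1), (4, 1)])
        sr, sa = percent_alien_share(div, "PriMin", sites)
        assert sr == pytest.approx(20.0)
        assert sa == pytest.approx(20.0)

    def test_missing_land_use_is_nan(self):
        div, sites = self._frames([(4, 1)])
        sr, sa = percent_alien_share(div, "Urban", sites)
        assert math.isnan(sr) and math.isnan(sa)

    def test_generating_share_recovered_in_primin(self, sim_small, model_data):
        """The generator is calibrated for ~17% alien species share at
        PriMin sites; the raw-data summary agrees within sampling error."""
        assemblage, sites, _, _ = sim_small
        sr, sa = percent_alien_share(model_data, "PriMin", sites)
        n = (sites["land_use"] == "PriMin").sum()
        se = 100 * math.sqrt(0.17 * 0.83 / (20 * n))  # ~binomial, 20 spp/site
        assert abs(sr - 17.0) < max(3 * se, 5.0)


class TestSimilarityContrasts:
    def test_focal_contrast_set(self):
        assert len(FOCAL_CONTRASTS) == 13
        assert "PriMin-PriMin" in FOCAL_CONTRASTS
        assert "Urban-Urban" in FOCAL_CONTRASTS

    @pytest.fixture(scope="class")
    def sim_fit(self):
        rng = np.random.default_rng(3)
        contrasts = ["PriMin-PriMin", "PriMin-Cropland", "Cropland-Cropland"]
        shift = {"PriMin-PriMin": 0.0, "PriMin-Cropland": -1.0,
                 "Cropland-Cropland": 0.5}
        rows = []
        for i in range(400):
            c = contrasts[i % 3]
            st = ["native", "alien"][i % 2]
            extra = -0.8 if (st == "alien" and c == "PriMin-Cropland") else 0.0
            rows.append({
                "logit_J_R": shift[c] + extra + rng.normal(0, 0.3),
                "landuse_contrast": c, "status": st,
                "study_id": f"g{i % 5}", "weight": 1.0,
                "geo_dist_t": 0.0, "env_dist_t": 0.0})
        df = pd.DataFrame(rows)
        df["landuse_contrast"] = pd.Categorical(df["landuse_contrast"],
                                                categories=contrasts)
        df["status"] = pd.Categorical(df["status"],
                                      categories=["native", "alien"])
        spec = ModelSpec("logit_J_R",
                         ("landuse_contrast", "status",
                          "status:landuse_contrast"),
                         "study", weights="weight")
        return fit_mixed(spec, df), df

    def test_baseline_contrast_exactly_zero(self, sim_fit):
        fit, df = sim_fit
        table = similarity_contrast_table(fit, df)
        base = table[table["landuse_contrast"] == "PriMin-PriMin"]
        assert (base["logit_diff"] == 0.0).all()
        assert np.allclose(base["similarity"], base["baseline_similarity"])

    def test_alien_novelty_in_cropland_detected(self, sim_fit):
        """Alien similarity to PriMin drops in the PriMin-Cropland
        contrast when alien novel species concentrate in cropland."""
        fit, df = sim_fit
        table = similarity_contrast_table(fit, df).set_index(
            ["status", "landuse_contrast"])
        alien = table.loc[("alien", "PriMin-Cropland")]
        native = table.loc[("native", "PriMin-Cropland")]
        assert alien["logit_diff"] < native["logit_diff"] < 0
        assert alien["similarity"] < alien["baseline_similarity"]

    def test_absent_contrast_marked_missing_not_error(self, sim_fit):
        fit, df = sim_fit
        table = similarity_contrast_table(fit, df)
        missing = table[table["landuse_contrast"] == "Pasture-Pasture"]
        assert missing["missing"].all()

    def test_sparse_contrast_flagged_unreliable(self, sim_fit):
        fit, df = sim_fit
        few = df.copy()
        few.loc[few["landuse_contrast"] == "Cropland-Cropland", "study_id"] = "g0"
        table = similarity_contrast_table(fit, few).set_index(
            ["status", "landuse_contrast"])
        assert not table.loc[("alien", "Cropland-Cropland"), "reliable"]


class TestPipeline:
    @pytest.fixture(scope="class")
    def run_dir(self, tmp_path_factory):
        cfg = PipelineConfig(
            simulation=SimulationConfig(n_studies=6, sites_per_study=8,
                                        n_islands=3, seed=17),
            n_perm=19, permutations=True, simplify=False, island_models=False)
        out = tmp_path_factory.mktemp("run") / "out"
        return run_pipeline(cfg, out), cfg

    def test_all_outputs_present(self, run_dir):
        out, _ = run_dir
        expected = {"assemblage.csv", "sites.csv", "islands.csv", "truth.json",
                    "site_diversity.csv", "pair_table.csv", "fit.json",
                    "effects_abundance.csv", "effects_richness.csv",
                    "similarity_contrasts.csv", "alien_share.csv",
                    "manifest.json", "permutation_results.json"}
        assert expected <= {p.name for p in out.iterdir()}
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 17
        assert "pair_exclusions" in manifest

    def test_rerun_same_seed_is_bit_identical(self, run_dir, tmp_path):
        out, cfg = run_dir
        out2 = run_pipeline(cfg, tmp_path / "out2")
        for name in ("effects_abundance.csv", "effects_richness.csv",
                     "similarity_contrasts.csv", "alien_share.csv",
                     "pair_table.csv"):
            assert (out / name).read_text() == (out2 / name).read_text()

    def test_permutations_disabled_keeps_fits(self, run_dir, tmp_path):
        out, cfg = run_dir
        cfg2 = dataclasses.replace(cfg, permutations=False)
        out2 = run_pipeline(cfg2, tmp_path / "out3")
        assert not (out2 / "permutation_results.json").exists()
        fits1 = json.loads((out / "fit.json").read_text())
        fits2 = json.loads((out2 / "fit.json").read_text())
        assert fits1["abundance"]["coefficients"] == fits2["abundance"]["coefficients"]

    def test_cli_simulate_and_run(self, tmp_path):
        from click.testing import CliRunner

        from isleco.cli import main
        runner = CliRunner()
        res = runner.invoke(main, ["simulate", "--out", str(tmp_path / "d"),
                                   "--seed", "4"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "d" / "assemblage.csv").exists()
        res = runner.invoke(main, ["metrics", "--data", str(tmp_path / "d"),
                                   "--out", str(tmp_path / "m.csv")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "m.csv").exists()
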