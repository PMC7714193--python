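import numpy as np
import pandas as pd
import pytest

from isleco import SimulationConfig, build_model_table, simulate_dataset


@pytest.fixture(scope="session")
def sim_small():
    """One moderate synthetic dataset shared across test modules."""
    cfg = SimulationConfig(n_studies=10, sites_per_study=12, n_islands=4, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def model_data(sim_small):
    assemblage, sites, _, _ = sim_small
    return build_model_table(assemblage, sites)


@pytest.fixture()
def toy_assemblage():
    """Two studies, hand-sized: one abundance study with mixed statuses
    and varying content, one occurrence study."""
    rows = [
        # st1: abundance study, effort constant
        ("s1", "st1", "b1", "site1", "tx1", "native", 2.0, "abundance", 1.0),
        ("s1", "st1", "b1", "site1", "tx2", "native", 3.0, "abundance", 1.0),
        ("s1", "st1", "b1", "site1", "tx3", "alien", 5.0, "abundance", 1.0),
        ("s1", "st1", "b1", "site2", "tx1", "native", 4.0, "abundance", 1.0),
        ("s1", "st1", "b1", "site2", "tx4", "unknown", 1.0, "abundance", 1.0),
        # st2: occurrence study
        ("s1", "st2", None, "site3", "tx5", "native", 1.0, "occurrence", 1.0),
        ("s1", "st2", None, "site3", "tx6", "native", 1.0, "occurrence", 1.0),
        ("s1", "st2", None, "site4", "tx5", "alien", 1.0, "occurrence", 1.0),
    ]
    df = pd.DataFrame(rows, columns=[
        "source_id", "study_id", "block_id", "site_id", "taxon_id",
        "status", "measurement", "metric_kind", "sampling_effort"])
    df["block_id"] = df["block_id"].astype("string")
    return df


@pytest.fixture()
def toy_sites():
    rows = [
        ("site1", "st1", "b1", "islA", 0.00, 0.00, "PriMin", 10.0, 500.0,
         100.0, 25.0, 15.0, 300.0, 50.0, 100.0),
        ("site2", "st1", "b1", "islA", 0.10, 0.05, "Pasture", 40.0, 200.0,
         150.0, 26.0, 16.0, 280.0, 40.0, 100.0),
        ("site3", "st2", None, "islA", 0.20, 0.10, "PriMin", 5.0, 900.0,
         200.0, 24.0, 14.0, 320.0, 60.0, 50.0),
        ("site4", "st2", None, "islB", 0.30, 0.20, "Cropland", 80.0, 100.0,
         120.0, 27.0, 17.0, 260.0, 30.0, 50.0),
    ]
    df = pd.DataFrame(rows, columns=[
        "site_id", "study_id", "block_id", "island_id", "longitude",
        "latitude", "land_use", "hpd_raw", "dist_road_raw", "altitude",
        "tmax", "tmin", "precip_wet", "precip_dry", "max_linear_extent"])
    df["block_id"] = df["block_id"].astype("string")
    return df
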