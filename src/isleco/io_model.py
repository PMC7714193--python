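"""Canonical data model and I/O for island assemblage analyses.

Three tables drive every analysis in this package:

``assemblage``
    Long-format biodiversity records: one row is one measurement (an
    abundance, or a 0/1 occurrence) of one taxon at one site within a
    study.  Studies are nested in data sources and may contain spatial
    blocks; each taxon carries an alien/native/unknown status.
``sites``
    Site metadata: coordinates (WGS84 decimal degrees), one of seven
    land-use/use-intensity classes, human population density, distance
    to the nearest road, altitude, four bioclimatic variables, the
    maximum linear extent of the sampling layout, and the island the
    site sits on.
``islands``
    Island traits: area, surrounding landmass (an isolation proxy: the
    sum of proportions of landmass within 100/1,000/10,000 km buffers,
    hence bounded by 3) and per-capita GDP.

All tables are interchanged as UTF-8 comma-separated files with a
header row; loading validates types and invariants and reports
violations with row indices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Constants and schema definitions
# --------------------------------------------------------------------------

#: The seven collapsed land-use/use-intensity classes. ``PriMin``
#: (minimally-used primary vegetation) is the baseline everywhere.
LAND_USES: tuple[str, ...] = (
    "PriMin",
    "Primary",
    "Secondary",
    "Plantation",
    "Cropland",
    "Pasture",
    "Urban",
)

STATUS_LEVELS: tuple[str, ...] = ("native", "alien", "unknown")
METRIC_KINDS: tuple[str, ...] = ("abundance", "occurrence")

ASSEMBLAGE_COLUMNS: tuple[str, ...] = (
    "source_id",
    "study_id",
    "block_id",
    "site_id",
    "taxon_id",
    "status",
    "measurement",
    "metric_kind",
    "sampling_effort",
)

SITE_COLUMNS: tuple[str, ...] = (
    "site_id",
    "study_id",
    "block_id",
    "island_id",
    "longitude",
    "latitude",
    "land_use",
    "hpd_raw",
    "dist_road_raw",
    "altitude",
    "tmax",
    "tmin",
    "precip_wet",
    "precip_dry",
    "max_linear_extent",
)

#: The five environmental variables entering Gower distance.
ENV_VARIABLES: tuple[str, ...] = ("altitude", "tmax", "tmin", "precip_wet", "precip_dry")

ISLAND_COLUMNS: tuple[str, ...] = (
    "island_id",
    "area_km2",
    "surrounding_landmass",
    "gdp_per_capita",
)

_OPTIONAL_COLUMNS = {"block_id", "max_linear_extent"}


class SchemaError(ValueError):
    """A required column is missing or a column map is inconsistent."""


class ValidationError(ValueError):
    """Row-level contents violate a table invariant."""


# --------------------------------------------------------------------------
# Loading and validation
# --------------------------------------------------------------------------


def _read(path, schema: Mapping[str, str] | None, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in required if c not in df.columns and c not in _OPTIONAL_COLUMNS]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for c in _OPTIONAL_COLUMNS:
        if c in required and c not in df.columns:
            df[c] = np.nan
    return df.loc[:, list(required)]


def _fail_rows(df: pd.DataFrame, bad: pd.Series, message: str) -> None:
    if bad.any():
        rows = df.index[bad].tolist()[:20]
        raise ValidationError(f"{message} (rows {rows})")


def load_assemblage(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate an assemblage table.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from file column names to canonical names, for
        files using different headers.

    Returns
    -------
    DataFrame with the canonical assemblage columns, validated.
    """
    df = _read(path, schema, ASSEMBLAGE_COLUMNS)
    for c in ("source_id", "study_id", "site_id", "taxon_id"):
        df[c] = df[c].astype(str)
    df["block_id"] = df["block_id"].astype("string")
    df["status"] = df["status"].fillna("unknown").astype(str)
    df["metric_kind"] = df["metric_kind"].astype(str)
    df["measurement"] = pd.to_numeric(df["measurement"], errors="coerce")
    df["sampling_effort"] = pd.to_numeric(df["sampling_effort"], errors="coerce")
    return validate_assemblage(df)


def validate_assemblage(df: pd.DataFrame) -> pd.DataFrame:
    _fail_rows(df, ~df["status"].isin(STATUS_LEVELS), "invalid status value")
    _fail_rows(df, ~df["metric_kind"].isin(METRIC_KINDS), "invalid metric_kind value")
    _fail_rows(df, df["measurement"].isna() | (df["measurement"] < 0), "measurement must be >= 0")
    _fail_rows(df, df["sampling_effort"].isna() | (df["sampling_effort"] <= 0), "sampling_effort must be > 0")
    dup = df.duplicated(subset=["study_id", "site_id", "taxon_id"], keep=False)
    _fail_rows(df, dup, "duplicate (study_id, site_id, taxon_id)")
    mixed = df.groupby("study_id")["metric_kind"].nunique()
    bad_studies = mixed.index[mixed > 1].tolist()
    if bad_studies:
        raise ValidationError(f"metric_kind varies within studies {bad_studies}")
    return df.reset_index(drop=True)


def load_sites(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a site metadata table."""
    df = _read(path, schema, SITE_COLUMNS)
    for c in ("site_id", "study_id", "island_id"):
        df[c] = df[c].astype(str)
    df["block_id"] = df["block_id"].astype("string")
    df["land_use"] = df["land_use"].astype(str)
    num_cols = [c for c in SITE_COLUMNS if c not in
                ("site_id", "study_id", "block_id", "island_id", "land_use")]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return validate_sites(df)


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    _fail_rows(df, ~df["land_use"].isin(LAND_USES),
               f"land_use must be one of {LAND_USES}")
    _fail_rows(df, (df["latitude"] < -90) | (df["latitude"] > 90), "latitude outside [-90, 90]")
    _fail_rows(df, (df["longitude"] < -180) | (df["longitude"] > 180), "longitude outside [-180, 180]")
    _fail_rows(df, df["hpd_raw"] < 0, "hpd_raw must be >= 0")
    _fail_rows(df, df["dist_road_raw"] < 0, "dist_road_raw must be >= 0")
    _fail_rows(df, df["max_linear_extent"] <= 0, "max_linear_extent must be > 0")
    dup = df.duplicated(subset=["site_id"], keep=False)
    _fail_rows(df, dup, "duplicate site_id")
    return df.reset_index(drop=True)


def load_islands(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate an island-trait table."""
    df = _read(path, schema, ISLAND_COLUMNS)
    df["island_id"] = df["island_id"].astype(str)
    for c in ("area_km2", "surrounding_landmass", "gdp_per_capita"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    _fail_rows(df, df["area_km2"] <= 0, "area_km2 must be > 0")
    _fail_rows(df, (df["surrounding_landmass"] < 0) | (df["surrounding_landmass"] > 3),
               "surrounding_landmass outside [0, 3]")
    dup = df.duplicated(subset=["island_id"], keep=False)
    _fail_rows(df, dup, "duplicate island_id")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a canonical table as UTF-8 CSV (round-trips through load_*)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


# --------------------------------------------------------------------------
# Status attachment
# --------------------------------------------------------------------------


def attach_status(
    occurrences: pd.DataFrame,
    status_table: pd.DataFrame,
    sites: pd.DataFrame | None = None,
    precedence: Sequence[str] = ("island", "country"),
) -> pd.DataFrame:
    """Attach alien/native status to occurrence records from a lookup table.

    ``status_table`` has columns ``taxon_id``, ``scope`` (e.g. ``island``
    or ``country``), ``scope_id`` and ``status``.  Island-scope rows are
    matched on (taxon_id, island id of the occurrence's site); scopes
    whose ``scope_id`` is empty match on taxon alone.  Scopes are tried
    in ``precedence`` order — island-specific classifications take
    priority over country-level ones — and the first match wins.
    Unmatched occurrences are labelled ``unknown``.

    Duplicate keys with conflicting statuses inside one scope raise
    :class:`ValidationError` (never a silent pick).  The operation is
    idempotent and independent of row order.
    """
    out = occurrences.copy()
    out["status"] = "unknown"
    if status_table is None or len(status_table) == 0:
        return out

    st = status_table.copy()
    for c in ("taxon_id", "scope", "status"):
        if c not in st.columns:
            raise SchemaError(f"status_table missing column {c!r}")
        st[c] = st[c].astype(str)
    if "scope_id" not in st.columns:
        st["scope_id"] = ""
    st["scope_id"] = st["scope_id"].fillna("").astype(str)
    bad = ~st["status"].isin(STATUS_LEVELS)
    if bad.any():
        raise ValidationError(f"status_table has invalid status values (rows {st.index[bad].tolist()})")

    site_island: Mapping[str, str] = {}
    if sites is not None:
        site_island = dict(zip(sites["site_id"].astype(str), sites["island_id"].astype(str)))

    def occ_key(scope: str) -> pd.Series:
        if scope == "island":
            return out["site_id"].astype(str).map(site_island).fillna("")
        if "country_id" in out.columns:
            if scope == "country":
                return out["country_id"].astype(str)
        return pd.Series("", index=out.index)

    unresolved = pd.Series(True, index=out.index)
    for scope in precedence:
        sub = st[st["scope"] == scope]
        if sub.empty:
            continue
        conflicts = (
            sub.groupby(["taxon_id", "scope_id"])["status"].nunique()
        )
        clash = conflicts.index[conflicts > 1].tolist()
        if clash:
            raise ValidationError(
                f"conflicting statuses within scope {scope!r} for keys {clash}"
            )
        sub = sub.drop_duplicates(subset=["taxon_id", "scope_id"])
        keyed = sub.set_index(["taxon_id", "scope_id"])["status"]
        loc = occ_key(scope)
        idx = pd.MultiIndex.from_arrays([out["taxon_id"].astype(str), loc])
        matched = pd.Series(keyed.reindex(idx).to_numpy(), index=out.index)
        take = unresolved & matched.notna()
        out.loc[take, "status"] = matched[take]
        unresolved &= ~take
    return out


# --------------------------------------------------------------------------
# Hierarchy validation
# --------------------------------------------------------------------------


def validate_hierarchy(occurrences: pd.DataFrame, sites: pd.DataFrame) -> dict:
    """Report structural problems without raising.

    Checks that every occurrence's site exists in the site table, that
    sites are not orphaned from the assemblage, that a block never spans
    two studies, and that no study mixes abundance with occurrence rows.
    """
    occ_sites = set(occurrences["site_id"])
    known_sites = set(sites["site_id"])
    orphan_occurrences = sorted(occ_sites - known_sites)
    orphan_sites = sorted(known_sites - occ_sites)

    block_nesting: list[str] = []
    for table in (occurrences, sites):
        sub = table.dropna(subset=["block_id"])
        if len(sub):
            span = sub.groupby("block_id")["study_id"].nunique()
            block_nesting.extend(str(b) for b in span.index[span > 1])
    block_nesting = sorted(set(block_nesting))

    mixed = occurrences.groupby("study_id")["metric_kind"].nunique()
    metric_mixing = sorted(str(s) for s in mixed.index[mixed > 1])

    report = {
        "orphan_occurrence_sites": orphan_occurrences,
        "orphan_sites": orphan_sites,
        "block_nesting_violations": block_nesting,
        "metric_kind_mixing_studies": metric_mixing,
    }
    report["ok"] = not any(report[k] for k in report)
    return report


def report_to_json(report: dict, path=None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
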