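"""Read enrollment and claims tables and reduce raw claims to de-duplicated
pregnancy-related records.

A *record* is a distinct (person, service date, code, system) combination
among the outcome and direct gestational-age codes of the code set, with the
service date acting as proxy for the end of pregnancy and the last menstrual
period (LMP) computed as ``service_date − 7 × ga_weeks`` whenever the code
carries a gestational age.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .codesets import (
    CODE_TYPE_BY_SYSTEM,
    CODE_VERSION_BY_SYSTEM,
    CodeSet,
    SYSTEMS,
)
from .config import RunConfig

log = logging.getLogger(__name__)

ENROLLMENT_COLUMNS = [
    "person_id", "family_id", "sex", "birth_year",
    "month_start", "month_end", "plan_type", "region",
]
CLAIM_COLUMNS = ["person_id", "claim_id", "service_date", "setting", "code", "code_system"]

SETTINGS = frozenset({"inpatient", "outpatient", "facility_header"})
PLAN_TYPES = frozenset({"large_employer", "small_plan"})
REGIONS = frozenset({"Northeast", "Midwest", "South", "West", "Unknown"})

RECORD_COLUMNS = [
    "person_id", "service_date", "code", "system", "code_type", "code_version",
    "category", "outcome_class", "ga_weeks", "ga_is_temporary", "lmp",
]


class SchemaError(ValueError):
    """An input table does not match its declared schema."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def read_enrollment(path: str | Path) -> pd.DataFrame:
    """Read the enrollment table (one row per continuous monthly span)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ENROLLMENT_COLUMNS, "enrollment")
    df = df[ENROLLMENT_COLUMNS].copy()
    df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce").astype("Int64")
    df["month_start"] = pd.PeriodIndex(df["month_start"], freq="M")
    df["month_end"] = pd.PeriodIndex(df["month_end"], freq="M")
    bad_sex = ~df["sex"].isin({"F", "M"})
    if bad_sex.any():
        raise SchemaError(f"enrollment sex must be F or M; {int(bad_sex.sum())} bad rows")
    if (df["month_end"] < df["month_start"]).any():
        raise SchemaError("enrollment span with month_end before month_start")
    bad_plan = ~df["plan_type"].isin(PLAN_TYPES)
    if bad_plan.any():
        raise SchemaError(f"unknown plan_type value(s): {sorted(df.loc[bad_plan, 'plan_type'].unique())}")
    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        raise SchemaError(f"unknown region value(s): {sorted(df.loc[bad_region, 'region'].unique())}")
    return df


def read_claims(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read the claims table (one code per row).

    Returns the parsed table and the count of rows rejected for an
    unparseable service date (counted in the audit log rather than raised).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CLAIM_COLUMNS, "claims")
    df = df[CLAIM_COLUMNS].copy()
    dates = pd.to_datetime(df["service_date"], format="%Y-%m-%d", errors="coerce")
    n_bad = int(dates.isna().sum())
    if n_bad:
        log.warning("rejected %d claim rows with unparseable service dates", n_bad)
    df["service_date"] = dates
    df = df[dates.notna()].copy()
    bad_sys = ~df["code_system"].isin(SYSTEMS)
    if bad_sys.any():
        raise SchemaError(
            f"unknown code_system value(s): {sorted(df.loc[bad_sys, 'code_system'].unique())}"
        )
    bad_setting = ~df["setting"].isin(SETTINGS)
    if bad_setting.any():
        raise SchemaError(
            f"unknown setting value(s): {sorted(df.loc[bad_setting, 'setting'].unique())}"
        )
    return df, n_bad


def covered_months(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Explode enrollment spans into one row per (person_id, covered month)."""
    if enrollment.empty:
        return pd.DataFrame({"person_id": pd.Series(dtype=str),
                             "month": pd.PeriodIndex([], freq="M")})
    n = (enrollment["month_end"] - enrollment["month_start"]).map(lambda d: d.n) + 1
    persons = np.repeat(enrollment["person_id"].to_numpy(), n)
    months = np.concatenate([
        pd.period_range(s, e, freq="M").to_numpy()
        for s, e in zip(enrollment["month_start"], enrollment["month_end"])
    ])
    return pd.DataFrame({"person_id": persons, "month": pd.PeriodIndex(months, freq="M")}) \
        .drop_duplicates(ignore_index=True)


def last_enrolled_month(enrollment: pd.DataFrame) -> pd.Series:
    """Last covered month per person (Period index by person_id)."""
    return enrollment.groupby("person_id")["month_end"].max()


def select_women(enrollment: pd.DataFrame, config: RunConfig) -> set[str]:
    """Women of reproductive age: sex F with enrollment-year age within the
    configured band (15–49 by default) for at least one enrolled year inside
    the study window."""
    df = enrollment[enrollment["sex"] == "F"]
    no_birth_year = df["birth_year"].isna()
    if no_birth_year.any():
        for pid in df.loc[no_birth_year, "person_id"].unique():
            log.warning("person %s excluded: missing birth year", pid)
        df = df[~no_birth_year]
    if df.empty:
        return set()
    y0, y1 = config.study_start.year, config.study_end.year
    start_year = df["month_start"].map(lambda p: p.year).clip(lower=y0)
    end_year = df["month_end"].map(lambda p: p.year).clip(upper=y1)
    birth = df["birth_year"].astype(int)
    # a span contributes if any year y in [start_year, end_year] has
    # age_min <= y - birth <= age_max
    lo = np.maximum(start_year, birth + config.age_min)
    hi = np.minimum(end_year, birth + config.age_max)
    ok = (lo <= hi) & (start_year <= end_year)
    return set(df.loc[ok, "person_id"])


def select_infants(enrollment: pd.DataFrame, config: RunConfig) -> set[str]:
    """Infants: enrollees whose birth year equals their first enrolled year
    within the study window."""
    df = enrollment[enrollment["birth_year"].notna()]
    if df.empty:
        return set()
    first = df.groupby("person_id")["month_start"].min().map(lambda p: p.year)
    birth = df.groupby("person_id")["birth_year"].first().astype(int)
    ok = (first == birth) & (birth >= config.study_start.year) & (birth <= config.study_end.year)
    return set(ok.index[ok])


def _code_lookup_frame(code_set: CodeSet, categories: Iterable[str]) -> pd.DataFrame:
    cats = set(categories)
    rows = [
        {
            "code": e.code,
            "code_system": e.system,
            "category": e.category,
            "outcome_class": e.outcome_class,
            "ga_weeks": e.ga_weeks,
        }
        for e in code_set.entries
        if e.category in cats
    ]
    return pd.DataFrame(
        rows, columns=["code", "code_system", "category", "outcome_class", "ga_weeks"]
    )


def extract_records(
    claims: pd.DataFrame, code_set: CodeSet, persons: set[str], config: RunConfig
) -> pd.DataFrame:
    """Reduce claims to de-duplicated pregnancy-related records.

    Keeps claims of selected persons dated within
    ``[study_start − lookback_days, data_end]`` whose codes carry an
    ``outcome`` or ``direct_gestational_age`` role, de-duplicates on
    (person, service date, code, system), and annotates each record with its
    outcome class, gestational age, and LMP.  A code playing both roles
    yields a single record carrying both the outcome class and the directly
    coded gestational age.
    """
    lo = pd.Timestamp(config.study_start) - pd.Timedelta(days=config.lookback_days)
    hi = pd.Timestamp(config.data_end)
    df = claims[
        claims["person_id"].isin(persons)
        & claims["service_date"].between(lo, hi)
    ].copy()
    df["code"] = df["code"].str.strip().str.upper()

    lookup = _code_lookup_frame(code_set, {"outcome", "direct_gestational_age"})
    merged = df.merge(lookup, on=["code", "code_system"], how="inner")
    if merged.empty:
        out = pd.DataFrame(columns=RECORD_COLUMNS)
        out["service_date"] = pd.to_datetime(out["service_date"])
        out["lmp"] = pd.to_datetime(out["lmp"])
        out["ga_weeks"] = out["ga_weeks"].astype("Int64")
        out["ga_is_temporary"] = out["ga_is_temporary"].astype(bool)
        return out

    merged["is_direct"] = merged["category"] == "direct_gestational_age"
    grouped = (
        merged.sort_values(["is_direct"], ascending=False, kind="stable")
        .groupby(["person_id", "service_date", "code", "code_system"], as_index=False)
        .agg(
            outcome_class=("outcome_class", lambda s: next((v for v in s if v is not None), None)),
            ga_weeks=("ga_weeks", lambda s: next((v for v in s if v is not None), None)),
            is_direct=("is_direct", "any"),
        )
    )
    grouped = grouped.rename(columns={"code_system": "system"})
    grouped["category"] = np.where(
        grouped["is_direct"], "direct_gestational_age", "outcome"
    )
    grouped["code_type"] = grouped["system"].map(CODE_TYPE_BY_SYSTEM)
    grouped["code_version"] = grouped["system"].map(CODE_VERSION_BY_SYSTEM)
    grouped["ga_weeks"] = grouped["ga_weeks"].astype("Int64")
    grouped["ga_is_temporary"] = False
    grouped["lmp"] = grouped["service_date"] - pd.to_timedelta(
        grouped["ga_weeks"].astype("float") * 7, unit="D"
    )
    out = grouped[RECORD_COLUMNS].sort_values(
        ["person_id", "service_date", "code", "system"], kind="stable", ignore_index=True
    )
    return out


def extract_evidence(
    claims: pd.DataFrame, code_set: CodeSet, persons: set[str], config: RunConfig
) -> pd.DataFrame:
    """Auxiliary dated evidence used by verification and sensitivity steps.

    Returns one row per distinct (person, date, kind) with kinds
    ``ectopic_procedure``, ``methotrexate``, ``fertility_procedure``, and
    ``preterm_prolonged``; for the latter, ``subtype`` distinguishes preterm
    from prolonged (an assigned gestational age of 42+ weeks on the code
    entry marks it prolonged).
    """
    lo = pd.Timestamp(config.study_start) - pd.Timedelta(days=config.lookback_days)
    hi = pd.Timestamp(config.data_end)
    df = claims[
        claims["person_id"].isin(persons)
        & claims["service_date"].between(lo, hi)
    ].copy()
    df["code"] = df["code"].str.strip().str.upper()
    lookup = _code_lookup_frame(
        code_set,
        {"ectopic_verification", "methotrexate", "fertility_procedure", "preterm_prolonged"},
    )
    merged = df.merge(lookup, on=["code", "code_system"], how="inner")
    kind_map = {
        "ectopic_verification": "ectopic_procedure",
        "methotrexate": "methotrexate",
        "fertility_procedure": "fertility_procedure",
        "preterm_prolonged": "preterm_prolonged",
    }
    merged["kind"] = merged["category"].map(kind_map)
    merged["subtype"] = np.where(
        (merged["kind"] == "preterm_prolonged")
        & (merged["ga_weeks"].astype("float") >= 42),
        "prolonged",
        np.where(merged["kind"] == "preterm_prolonged", "preterm", ""),
    )
    out = (
        merged[["person_id", "service_date", "kind", "subtype"]]
        .rename(columns={"service_date": "date"})
        .drop_duplicates(ignore_index=True)
        .sort_values(["person_id", "date", "kind", "subtype"], kind="stable", ignore_index=True)
    )
    return out
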