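"""Shared fixtures and record-building helpers."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from pregclaims.claims_io import RECORD_COLUMNS
from pregclaims.codesets import CODE_TYPE_BY_SYSTEM, CODE_VERSION_BY_SYSTEM, default_codeset
from pregclaims.config import RunConfig

BASE = pd.Timestamp("2016-01-01")


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def codeset():
    return default_codeset()


def rec(
    person: str,
    day: int,
    outcome: str | None = None,
    ga: int | None = None,
    code: str = "",
    system: str = "ICD10-DX",
    direct: bool = False,
    base: pd.Timestamp = BASE,
) -> dict:
    """One pregnancy record at ``base + day`` days; LMP is derived from
    ``ga`` when given, otherwise left missing (temporary imputation fills
    it)."""
    service = base + pd.Timedelta(days=day)
    if not code:
        code = f"C{day}_{outcome or 'GA'}"
    return {
        "person_id": person,
        "service_date": service,
        "code": code,
        "system": system,
        "code_type": CODE_TYPE_BY_SYSTEM[system],
        "code_version": CODE_VERSION_BY_SYSTEM[system],
        "category": "direct_gestational_age" if direct else "outcome",
        "outcome_class": outcome,
        "ga_weeks": ga,
        "ga_is_temporary": False,
        "lmp": service - pd.Timedelta(days=7 * ga) if ga is not None else pd.NaT,
    }


def records_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df["service_date"] = pd.to_datetime(df["service_date"])
    df["lmp"] = pd.to_datetime(df["lmp"])
    df["ga_weeks"] = df["ga_weeks"].astype("Int64")
    df["ga_is_temporary"] = df["ga_is_temporary"].astype(bool)
    return df


def enrollment_frame(rows: list[tuple]) -> pd.DataFrame:
    """Build an enrollment table from (person, family, sex, birth_year,
    month_start, month_end, plan, region) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["person_id", "family_id", "sex", "birth_year", "month_start",
                 "month_end", "plan_type", "region"],
    )
    df["birth_year"] = df["birth_year"].astype("Int64")
    df["month_start"] = pd.PeriodIndex(df["month_start"], freq="M")
    df["month_end"] = pd.PeriodIndex(df["month_end"], freq="M")
    return df


def claims_frame(rows: list[tuple]) -> pd.DataFrame:
    """Build a claims table from (person, claim_id, date, setting, code,
    system) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["person_id", "claim_id", "service_date", "setting", "code",
                 "code_system"],
    )
    df["service_date"] = pd.to_datetime(df["service_date"])
    return df


def day(offset: int, base: pd.Timestamp = BASE) -> dt.date:
    return (base + pd.Timedelta(days=offset)).date()
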