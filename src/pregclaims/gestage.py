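"""Finalize gestational age and LMP and emit the final pregnancy cohort.

Gestational age is finalized from, in order of preference: the last direct
gestational-age code of the episode (ICD-10-CM ``Z3A.NN`` / ICD-9-CM
``765.2X``), a gestational age assigned to the anchor outcome code itself,
preterm/prolonged-gestation flags on the maternal or linked infant record,
and finally an outcome-specific default.  The final LMP and end date then
satisfy ``ga = floor((end − lmp) / 7)`` completed weeks.

Pregnancies with a missing outcome are assumed to be live births at 39
weeks, with a delivery date imputed as the episode's maximum LMP + 273
days; imputed deliveries after the end of data are right-censored, and
those falling after the woman's last enrolled month are unobservable.
Both are excluded from the final cohort, as are deliveries outside the
study years or maternal age range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig

PREGNANCY_COLUMNS = [
    "person_id", "series_index", "final_outcome", "end_date", "final_lmp",
    "ga_weeks_final", "ga_source", "linked_infant_ids", "censored",
    "excluded_reason", "era", "continuous_enrollment", "n_records",
]

GA_BIN_LABELS = [
    "8-10", "11-19", "20-23", "24-28", "29-33", "34-36", "37-38",
    "39-41", ">=42", "unknown",
]


def ga_bin(ga_weeks) -> str:
    """Gestational-age bin used for reporting and the sensitivity cross-tab."""
    if ga_weeks is None or (isinstance(ga_weeks, float) and np.isnan(ga_weeks)) or pd.isna(ga_weeks):
        return "unknown"
    ga = int(ga_weeks)
    if ga < 8:
        return "unknown"
    for lo, hi, label in [
        (8, 10, "8-10"), (11, 19, "11-19"), (20, 23, "20-23"), (24, 28, "24-28"),
        (29, 33, "29-33"), (34, 36, "34-36"), (37, 38, "37-38"), (39, 41, "39-41"),
    ]:
        if lo <= ga <= hi:
            return label
    return ">=42"


def _select_direct_ga(
    sub: pd.DataFrame, end: pd.Timestamp, config: RunConfig
) -> pd.Series | None:
    """Last direct gestational-age record usable for the episode.

    Records dated more than the configured tolerance after the end date are
    ignored (likely a subsequent pregnancy's claim mis-grouped), as are
    degenerate records whose implied LMP postdates the end date.  Same-day
    ties resolve to the larger gestational age.
    """
    direct = sub[sub["category"] == "direct_gestational_age"]
    if direct.empty:
        return None
    limit = end + pd.Timedelta(days=config.direct_ga_after_end_tolerance_days)
    usable = direct[(direct["service_date"] <= limit) & (direct["lmp"] <= end)]
    if usable.empty:
        return None
    return usable.sort_values(
        ["service_date", "ga_weeks"], ascending=[True, True], kind="stable"
    ).iloc[-1]


def finalize_ga(
    assignments: pd.DataFrame,
    episodes: pd.DataFrame,
    grouped_records: pd.DataFrame,
    linkage: pd.DataFrame,
    infants: pd.DataFrame,
    evidence: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Final gestational age, LMP, and linked infants per pregnancy.

    Missing-outcome pregnancies pass through with empty estimates; they are
    resolved by :func:`impute_missing_and_censor`.
    """
    epi_idx = episodes.set_index(["person_id", "series_index"])
    rec_groups = dict(iter(grouped_records.groupby(["person_id", "series_index"])))

    if linkage.empty:
        infants_by_episode: dict[tuple, list[str]] = {}
    else:
        merged = linkage.merge(
            infants[["infant_id", "has_preterm", "has_prolonged"]],
            on="infant_id", how="left",
        )
        infants_by_episode = {
            k: sorted(v["infant_id"]) for k, v in merged.groupby(["person_id", "series_index"])
        }
        infant_flags = {
            k: (bool(v["has_preterm"].any()), bool(v["has_prolonged"].any()))
            for k, v in merged.groupby(["person_id", "series_index"])
        }
    if linkage.empty:
        infant_flags = {}

    if evidence.empty:
        pp_by_person: dict[str, pd.DataFrame] = {}
    else:
        pp = evidence[evidence["kind"] == "preterm_prolonged"]
        pp_by_person = {pid: sub for pid, sub in pp.groupby("person_id")}

    rows = []
    for a in assignments.itertuples(index=False):
        key = (a.person_id, a.series_index)
        ep = epi_idx.loc[key]
        sub = rec_groups.get(key)
        linked_ids = infants_by_episode.get(key, [])
        outcome = a.final_outcome
        end = a.final_end_date
        if outcome == "MISSING":
            rows.append(
                {
                    "person_id": a.person_id,
                    "series_index": a.series_index,
                    "final_outcome": "MISSING",
                    "end_date": pd.NaT,
                    "final_lmp": pd.NaT,
                    "ga_weeks_final": pd.NA,
                    "ga_source": pd.NA,
                    "linked_infant_ids": linked_ids,
                    "max_episode_lmp": ep["max_lmp"],
                    "n_records": int(ep["n_records"]),
                    "refinement_trail": a.refinement_trail,
                }
            )
            continue

        direct = _select_direct_ga(sub, end, config) if sub is not None else None
        if direct is not None:
            lmp = direct["lmp"]
            ga = int((end - lmp).days // 7)
            source = "direct_code"
        elif pd.notna(a.final_anchor_ga):
            ga = int(a.final_anchor_ga)
            lmp = end - pd.Timedelta(days=7 * ga)
            source = "outcome_code"
        else:
            # preterm/prolonged flags on the maternal or linked infant record
            inf_pre, inf_pro = infant_flags.get(key, (False, False))
            mat = pp_by_person.get(a.person_id)
            mat_pre = mat_pro = False
            if mat is not None:
                lo = ep["min_lmp"]
                hi = ep["max_service_date"] + pd.Timedelta(
                    days=config.infant_window_after_days
                )
                in_window = mat[(mat["date"] >= lo) & (mat["date"] <= hi)]
                mat_pre = bool((in_window["subtype"] == "preterm").any())
                mat_pro = bool((in_window["subtype"] == "prolonged").any())
            if inf_pre or inf_pro or mat_pre or mat_pro:
                ga = (
                    config.ga_preterm_weeks
                    if (inf_pre or mat_pre)
                    else config.ga_prolonged_weeks
                )
                source = "preterm_adjusted"
            else:
                ga = config.ga_defaults[outcome]
                source = "default"
            lmp = end - pd.Timedelta(days=7 * ga)

        rows.append(
            {
                "person_id": a.person_id,
                "series_index": a.series_index,
                "final_outcome": outcome,
                "end_date": end,
                "final_lmp": lmp,
                "ga_weeks_final": ga,
                "ga_source": source,
                "linked_infant_ids": linked_ids,
                "max_episode_lmp": ep["max_lmp"],
                "n_records": int(ep["n_records"]),
                "refinement_trail": a.refinement_trail,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["person_id", "series_index", "final_outcome", "end_date",
                 "final_lmp", "ga_weeks_final", "ga_source", "linked_infant_ids",
                 "max_episode_lmp", "n_records", "refinement_trail"],
    )
    out["ga_weeks_final"] = out["ga_weeks_final"].astype("Int64")
    for col in ("end_date", "final_lmp", "max_episode_lmp"):
        out[col] = pd.to_datetime(out[col])
    return out


def impute_missing_and_censor(
    pregnancies: pd.DataFrame,
    enrollment: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Resolve missing outcomes and apply censoring/disenrollment exclusions.

    Missing-outcome pregnancies become live births at the configured imputed
    gestational age (39 weeks), delivered at the episode's maximum LMP +
    273 days.  Any pregnancy ending after the end of data is right-censored;
    one ending after the woman's last enrolled month is unobservable.  Both
    receive an ``excluded_reason``.
    """
    out = pregnancies.copy()
    if out.empty:
        out["censored"] = pd.Series(dtype=bool)
        out["excluded_reason"] = pd.Series(dtype=object)
        return out
    missing = out["final_outcome"] == "MISSING"
    imputed_days = 7 * config.imputed_ga_weeks
    out.loc[missing, "final_lmp"] = out.loc[missing, "max_episode_lmp"]
    out.loc[missing, "end_date"] = out.loc[missing, "max_episode_lmp"] + pd.Timedelta(
        days=imputed_days
    )
    out.loc[missing, "final_outcome"] = "LB"
    out.loc[missing, "ga_weeks_final"] = config.imputed_ga_weeks
    out.loc[missing, "ga_source"] = "imputed_39"
    out["ga_weeks_final"] = out["ga_weeks_final"].astype("Int64")

    data_end = pd.Timestamp(config.data_end)
    last_month = enrollment.groupby("person_id")["month_end"].max()
    end_month = out["end_date"].dt.to_period("M")
    person_last = out["person_id"].map(last_month)

    out["censored"] = out["end_date"] > data_end
    out["excluded_reason"] = None
    out.loc[out["censored"], "excluded_reason"] = "censored_after_data_end"
    disenrolled = (
        ~out["censored"] & person_last.notna() & (end_month > person_last)
    )
    out.loc[disenrolled, "excluded_reason"] = "disenrolled_before_end"
    return out


def _continuous_enrollment_flags(
    pregnancies: pd.DataFrame,
    enrollment: pd.DataFrame,
    config: RunConfig,
) -> pd.Series:
    """Coverage of every month from the LMP month through the end month,
    tolerating uncovered gaps of at most ``max_enrollment_gap_months``
    consecutive months."""
    covered: dict[str, set] = {}
    for row in enrollment.itertuples(index=False):
        covered.setdefault(row.person_id, set()).update(
            pd.period_range(row.month_start, row.month_end, freq="M")
        )
    flags = []
    for row in pregnancies.itertuples(index=False):
        months = pd.period_range(
            row.final_lmp.to_period("M"), row.end_date.to_period("M"), freq="M"
        )
        have = covered.get(row.person_id, set())
        run = worst = 0
        for m in months:
            if m in have:
                run = 0
            else:
                run += 1
                worst = max(worst, run)
        flags.append(worst <= config.max_enrollment_gap_months)
    return pd.Series(flags, index=pregnancies.index, dtype=bool)


def apply_cohort_filters(
    pregnancies: pd.DataFrame,
    enrollment: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split pregnancies into the final cohort and the excluded audit table.

    Adds delivery-year and maternal-age exclusions (age at delivery uses
    year arithmetic, as only birth year is available), then tags the
    retained cohort with coding era and continuous-enrollment status.
    """
    out = pregnancies.copy()
    birth_year = enrollment.groupby("person_id")["birth_year"].first()
    by = out["person_id"].map(birth_year)
    age = out["end_date"].dt.year - by.astype("float")

    open_slot = out["excluded_reason"].isna()
    year_bad = open_slot & (
        (out["end_date"] < pd.Timestamp(config.study_start))
        | (out["end_date"] > pd.Timestamp(config.study_end))
    )
    out.loc[year_bad, "excluded_reason"] = "year_out_of_range"
    open_slot = out["excluded_reason"].isna()
    age_bad = open_slot & ((age < config.age_min) | (age > config.age_max))
    out.loc[age_bad, "excluded_reason"] = "age_out_of_range"

    excluded = out[out["excluded_reason"].notna()].copy()
    cohort = out[out["excluded_reason"].isna()].copy()
    if not cohort.empty:
        cohort["era"] = np.where(
            cohort["end_date"] >= pd.Timestamp(config.era_boundary),
            "ICD10_era",
            "ICD9_era",
        )
        cohort["continuous_enrollment"] = _continuous_enrollment_flags(
            cohort, enrollment, config
        )
    else:
        cohort["era"] = pd.Series(dtype=object)
        cohort["continuous_enrollment"] = pd.Series(dtype=bool)
    return cohort.reset_index(drop=True), excluded.reset_index(drop=True)
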