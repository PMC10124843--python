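"""Link infants to candidate maternal pregnancy episodes.

Infants (enrollees whose birth year equals their first enrolled year) are
matched to pregnancy episodes of women sharing their family identifier.  An
infant with a birth-hospitalization or preterm/prolonged-gestation claim in
its birth year links through the *date window*: its earliest such claim must
fall between 7 days before the episode's minimum and 30 days after the
episode's maximum pregnancy end date.  Infants without such claims fall back
to matching their birth year against the episode's delivery year.  Either
way the linked episode must carry a live-birth code, and an infant links to
at most one episode (the earliest qualifying one); one episode may link
several infants (multiple gestation).
"""

from __future__ import annotations

import pandas as pd

from .codesets import CodeSet
from .config import LIVE_BIRTH_CLASSES, RunConfig

INFANT_COLUMNS = [
    "infant_id", "family_id", "birth_year", "first_relevant_claim_date",
    "has_birth_hosp_or_preterm_code", "has_preterm", "has_prolonged",
]
LINKAGE_COLUMNS = ["infant_id", "person_id", "series_index", "method"]


def build_infant_records(
    claims: pd.DataFrame,
    code_set: CodeSet,
    enrollment: pd.DataFrame,
    infant_ids: set[str],
    config: RunConfig,
) -> pd.DataFrame:
    """One row per infant with its birth-year claim evidence.

    ``first_relevant_claim_date`` is the earliest birth-year claim carrying
    an infant birth-hospitalization or preterm/prolonged code; the preterm
    and prolonged flags record which subtypes appeared.
    """
    enr = enrollment[enrollment["person_id"].isin(infant_ids)]
    base = (
        enr.groupby("person_id")
        .agg(family_id=("family_id", "first"), birth_year=("birth_year", "first"))
        .reset_index()
        .rename(columns={"person_id": "infant_id"})
    )
    base["birth_year"] = base["birth_year"].astype(int)

    sub = claims[claims["person_id"].isin(infant_ids)].copy()
    sub["code"] = sub["code"].str.strip().str.upper()
    lookup_rows = [
        {"code": e.code, "code_system": e.system, "category": e.category,
         "ga_weeks": e.ga_weeks}
        for e in code_set.entries
        if e.category in {"infant_birth_hospitalization", "preterm_prolonged"}
    ]
    lookup = pd.DataFrame(lookup_rows, columns=["code", "code_system", "category", "ga_weeks"])
    hits = sub.merge(lookup, on=["code", "code_system"], how="inner")
    hits = hits.merge(base, left_on="person_id", right_on="infant_id", how="inner")
    hits = hits[hits["service_date"].dt.year == hits["birth_year"]]

    if hits.empty:
        agg = pd.DataFrame(columns=["infant_id", "first_relevant_claim_date",
                                    "has_preterm", "has_prolonged"])
    else:
        hits["is_preterm"] = (hits["category"] == "preterm_prolonged") & (
            hits["ga_weeks"].astype("float").fillna(0) < 42
        )
        hits["is_prolonged"] = (hits["category"] == "preterm_prolonged") & (
            hits["ga_weeks"].astype("float") >= 42
        )
        agg = (
            hits.groupby("infant_id")
            .agg(
                first_relevant_claim_date=("service_date", "min"),
                has_preterm=("is_preterm", "any"),
                has_prolonged=("is_prolonged", "any"),
            )
            .reset_index()
        )

    out = base.merge(agg, on="infant_id", how="left")
    out["has_birth_hosp_or_preterm_code"] = out["first_relevant_claim_date"].notna()
    out["has_preterm"] = out["has_preterm"].eq(True)
    out["has_prolonged"] = out["has_prolonged"].eq(True)
    return out[INFANT_COLUMNS].sort_values("infant_id", ignore_index=True)


def _carries_live_birth(indicators: frozenset) -> bool:
    return any(oc in LIVE_BIRTH_CLASSES for oc, _ in indicators)


def link_infants(
    episodes: pd.DataFrame,
    infants: pd.DataFrame,
    enrollment: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Resolve each infant to at most one live-birth-coded episode.

    Selection when several episodes qualify: candidates are restricted to
    episodes carrying a live-birth code; if candidates span more than one
    woman in the family, the woman whose episode end lies closest to the
    infant's first relevant claim wins (ties: lower person id); within a
    woman the earliest episode wins.  Infants whose candidates all lack
    live-birth codes remain unlinked.
    """
    if episodes.empty or infants.empty:
        return pd.DataFrame(columns=LINKAGE_COLUMNS)

    fam = (
        enrollment.groupby("person_id")["family_id"].first().rename("family_id")
    )
    epi = episodes.merge(fam, left_on="person_id", right_index=True, how="left")
    epi = epi[[
        "person_id", "family_id", "series_index", "min_service_date",
        "max_service_date", "indicators",
    ]].copy()
    epi["has_lb"] = epi["indicators"].map(_carries_live_birth)
    epi["delivery_year"] = epi["max_service_date"].dt.year
    by_family = {k: v for k, v in epi.groupby("family_id")}

    before = pd.Timedelta(days=config.infant_window_before_days)
    after = pd.Timedelta(days=config.infant_window_after_days)

    links = []
    for row in infants.itertuples(index=False):
        cand = by_family.get(row.family_id)
        if cand is None:
            continue
        cand = cand[cand["person_id"] != row.infant_id]
        if cand.empty:
            continue
        if row.has_birth_hosp_or_preterm_code:
            d = row.first_relevant_claim_date
            ok = cand[
                (d >= cand["min_service_date"] - before)
                & (d <= cand["max_service_date"] + after)
                & cand["has_lb"]
            ]
            method = "date_window"
            if ok.empty:
                continue
            if ok["person_id"].nunique() > 1:
                dist = (ok["max_service_date"] - d).abs()
                best_person = (
                    ok.assign(_dist=dist)
                    .sort_values(["_dist", "person_id"], kind="stable")
                    .iloc[0]["person_id"]
                )
                ok = ok[ok["person_id"] == best_person]
        else:
            ok = cand[(cand["delivery_year"] == row.birth_year) & cand["has_lb"]]
            method = "year_fallback"
            if ok.empty:
                continue
            if ok["person_id"].nunique() > 1:
                best_person = ok.sort_values(
                    ["min_service_date", "person_id"], kind="stable"
                ).iloc[0]["person_id"]
                ok = ok[ok["person_id"] == best_person]
        chosen = ok.sort_values(["min_service_date", "series_index"], kind="stable").iloc[0]
        links.append(
            {
                "infant_id": row.infant_id,
                "person_id": chosen["person_id"],
                "series_index": int(chosen["series_index"]),
                "method": method,
            }
        )
    return pd.DataFrame(links, columns=LINKAGE_COLUMNS).sort_values(
        "infant_id", ignore_index=True
    )
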