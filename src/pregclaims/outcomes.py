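"""Assign each pregnancy episode an outcome.

The *initial* outcome comes from a 16-level hierarchy over the episode's
(outcome class × code type) indicators plus infant linkage: diagnosis codes
are the strongest evidence, a linked infant record implies a live birth,
spontaneous abortion beats induced abortion when both are coded, DRG codes
beat procedure codes for abortion-type outcomes, and DRG live-birth codes
count only when they are the sole pregnancy-related code present.

*Refinement* rules then adjust a small fraction of outcomes:

R1
    an induced abortion whose episode also carries an ectopic code, with a
    proximate ectopic procedure or methotrexate claim, is recoded ectopic;
R2
    an ectopic outcome is retained only with an ectopic procedure or
    methotrexate claim within the verification window of the end date —
    otherwise the episode is demoted to the next applicable hierarchy
    outcome (skipping ectopic rows), or missing if none applies;
R3
    a stillbirth with an estimated gestational age under 20 weeks and a
    co-occurring spontaneous-abortion code becomes a spontaneous abortion;
    a stillbirth with co-occurring live-birth records and a linked infant
    becomes a live birth.

Refinement is a pure function of the initial assignment, the episode's
indicators/records, and the evidence table, so applying it twice equals
applying it once.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .config import RunConfig

#: Table of (level, code_type, outcome); code_type "LINK" marks the
#: infant-linkage level.
HIERARCHY: tuple[tuple[int, str, str], ...] = (
    (1, "DX", "LB_SB"),
    (2, "LINK", "LB"),
    (3, "DX", "SB"),
    (4, "DX", "LB"),
    (5, "DX", "SAB"),
    (6, "DX", "IAB"),
    (7, "DX", "ECT"),
    (8, "DRG", "SAB"),
    (9, "DRG", "IAB"),
    (10, "DRG", "ECT"),
    (11, "PX", "SB"),
    (12, "PX", "SAB"),
    (13, "PX", "IAB"),
    (14, "PX", "ECT"),
    (15, "PX", "LB"),
    (16, "DRG", "LB"),
)

ASSIGNMENT_COLUMNS = [
    "person_id", "series_index", "initial_outcome", "hierarchy_level",
    "anchor_date", "initial_end_date", "initial_ga_weeks", "initial_lmp",
    "final_outcome", "final_end_date", "final_anchor_ga", "refinement_trail",
    "linked",
]

RULE_IDS = ("R1", "R2", "R3")


def first_applicable_level(
    indicators: frozenset,
    linked: bool,
    sole_code_is_drg_lb: bool,
    skip_ect: bool = False,
) -> tuple[Optional[int], Optional[str]]:
    """Walk the hierarchy top-down and return (level, outcome) of the first
    applicable row, or (None, None) when no row applies."""
    for level, code_type, outcome in HIERARCHY:
        if skip_ect and outcome == "ECT":
            continue
        if code_type == "LINK":
            if linked:
                return level, outcome
        elif level == 16:
            if sole_code_is_drg_lb and (outcome, code_type) in indicators:
                return level, outcome
        elif (outcome, code_type) in indicators:
            return level, outcome
    return None, None


def _anchor(sub: pd.DataFrame, outcome: str, level: int) -> pd.Series:
    """Earliest record of the assigned outcome type.

    For the linkage level the earliest live-birth-coded record is used when
    one exists, otherwise the episode's earliest record.
    """
    if level == 2:
        lb = sub[sub["outcome_class"].isin(["LB", "LB_SB"])]
        basis = lb if not lb.empty else sub
    else:
        basis = sub[sub["outcome_class"] == outcome]
        if basis.empty:  # defensive; indicators guarantee a match
            basis = sub
    return basis.sort_values(["service_date", "code"], kind="stable").iloc[0]


def assign_initial_outcomes(
    episodes: pd.DataFrame,
    grouped_records: pd.DataFrame,
    linkage: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Initial outcome, hierarchy level, and anchor per episode.

    Episodes matching no hierarchy row get outcome ``MISSING`` with no
    anchor-derived estimates.  The result depends only on the episode's
    indicator set, linkage flag, and record dates, never on input order.
    """
    linked_keys = (
        set(zip(linkage["person_id"], linkage["series_index"]))
        if not linkage.empty
        else set()
    )
    rec_groups = dict(iter(grouped_records.groupby(["person_id", "series_index"])))
    rows = []
    for ep in episodes.itertuples(index=False):
        key = (ep.person_id, ep.series_index)
        linked = key in linked_keys
        level, outcome = first_applicable_level(
            ep.indicators, linked, ep.sole_code_is_drg_lb
        )
        if level is None:
            rows.append(
                {
                    "person_id": ep.person_id,
                    "series_index": ep.series_index,
                    "initial_outcome": "MISSING",
                    "hierarchy_level": pd.NA,
                    "anchor_date": pd.NaT,
                    "initial_end_date": pd.NaT,
                    "initial_ga_weeks": pd.NA,
                    "initial_lmp": pd.NaT,
                    "linked": linked,
                }
            )
            continue
        sub = rec_groups[key]
        anchor = _anchor(sub, outcome, level)
        temporary = bool(anchor["ga_is_temporary"])
        rows.append(
            {
                "person_id": ep.person_id,
                "series_index": ep.series_index,
                "initial_outcome": outcome,
                "hierarchy_level": level,
                "anchor_date": anchor["service_date"],
                "initial_end_date": anchor["service_date"],
                "initial_ga_weeks": pd.NA if temporary else anchor["ga_weeks"],
                "initial_lmp": pd.NaT if temporary else anchor["lmp"],
                "linked": linked,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["person_id", "series_index", "initial_outcome", "hierarchy_level",
                 "anchor_date", "initial_end_date", "initial_ga_weeks",
                 "initial_lmp", "linked"],
    )
    out["initial_ga_weeks"] = out["initial_ga_weeks"].astype("Int64")
    out["hierarchy_level"] = out["hierarchy_level"].astype("Int64")
    return out


def _evidence_dates_by_person(evidence: pd.DataFrame) -> dict[str, pd.Series]:
    if evidence.empty:
        return {}
    ect = evidence[evidence["kind"].isin(["ectopic_procedure", "methotrexate"])]
    return {pid: sub["date"] for pid, sub in ect.groupby("person_id")}


def _has_proximate_evidence(
    dates: Optional[pd.Series], end: pd.Timestamp, window_days: int
) -> bool:
    if dates is None or pd.isna(end):
        return False
    w = pd.Timedelta(days=window_days)
    return bool(((dates >= end - w) & (dates <= end + w)).any())


def refine_outcomes(
    assignments: pd.DataFrame,
    episodes: pd.DataFrame,
    grouped_records: pd.DataFrame,
    evidence: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Apply the refinement rules R1–R3 in fixed order.

    Returns the assignment table with ``final_outcome``, ``final_end_date``,
    ``final_anchor_ga`` (the final anchor record's own, non-temporary,
    gestational age, if any), and the per-pregnancy ``refinement_trail``.
    When the outcome changes, the end date is re-anchored to the earliest
    record of the new outcome type.
    """
    epi_idx = episodes.set_index(["person_id", "series_index"])
    rec_groups = dict(iter(grouped_records.groupby(["person_id", "series_index"])))
    ev_by_person = _evidence_dates_by_person(evidence)
    w = config.ectopic_window_days

    out_rows = []
    for a in assignments.itertuples(index=False):
        key = (a.person_id, a.series_index)
        ep = epi_idx.loc[key]
        sub = rec_groups.get(key)
        dates = ev_by_person.get(a.person_id)
        outcome = a.initial_outcome
        level = a.hierarchy_level
        end = a.initial_end_date
        anchor_ga = a.initial_ga_weeks
        anchor_lmp = a.initial_lmp
        trail: list[str] = []

        def re_anchor(new_outcome: str, new_level) -> None:
            nonlocal end, anchor_ga, anchor_lmp
            if sub is None:
                return
            basis = (
                sub[sub["outcome_class"].isin(["LB", "LB_SB"])]
                if new_level == 2
                else sub[sub["outcome_class"] == new_outcome]
            )
            if basis.empty:
                basis = sub
            rec = basis.sort_values(["service_date", "code"], kind="stable").iloc[0]
            end = rec["service_date"]
            temporary = bool(rec["ga_is_temporary"])
            anchor_ga = pd.NA if temporary else rec["ga_weeks"]
            anchor_lmp = pd.NaT if temporary else rec["lmp"]

        # R1: induced abortion with ectopic codes and proximate evidence
        if (
            config.enable_rule_iab_to_ect
            and outcome == "IAB"
            and any(oc == "ECT" for oc, _ in ep["indicators"])
        ):
            ect_recs = sub[sub["outcome_class"] == "ECT"] if sub is not None else None
            cand_end = (
                ect_recs.sort_values(["service_date", "code"]).iloc[0]["service_date"]
                if ect_recs is not None and not ect_recs.empty
                else end
            )
            if _has_proximate_evidence(dates, cand_end, w):
                outcome = "ECT"
                level = pd.NA
                re_anchor("ECT", None)
                trail.append("R1")

        # R2: ectopic outcomes require proximate procedure/methotrexate
        if config.enable_rule_ectopic_verification and outcome == "ECT":
            if not _has_proximate_evidence(dates, end, w):
                new_level, new_outcome = first_applicable_level(
                    ep["indicators"], bool(a.linked), bool(ep["sole_code_is_drg_lb"]),
                    skip_ect=True,
                )
                if new_outcome is None:
                    outcome = "MISSING"
                    level = pd.NA
                    end, anchor_ga, anchor_lmp = pd.NaT, pd.NA, pd.NaT
                else:
                    outcome = new_outcome
                    level = new_level
                    re_anchor(new_outcome, new_level)
                trail.append("R2")

        # R3: stillbirth adjustment
        if config.enable_rule_stillbirth_adjustment and outcome == "SB":
            sab_present = any(oc == "SAB" for oc, _ in ep["indicators"])
            lb_present = any(oc == "LB" for oc, _ in ep["indicators"])
            ga0 = a.initial_ga_weeks
            if (
                sab_present
                and pd.notna(ga0)
                and int(ga0) < config.stillbirth_ga_cut_weeks
            ):
                outcome = "SAB"
                level = pd.NA
                re_anchor("SAB", None)
                trail.append("R3")
            elif lb_present and bool(a.linked):
                outcome = "LB"
                level = pd.NA
                re_anchor("LB", None)
                trail.append("R3")

        out_rows.append(
            {
                "person_id": a.person_id,
                "series_index": a.series_index,
                "initial_outcome": a.initial_outcome,
                "hierarchy_level": a.hierarchy_level,
                "anchor_date": a.anchor_date,
                "initial_end_date": a.initial_end_date,
                "initial_ga_weeks": a.initial_ga_weeks,
                "initial_lmp": a.initial_lmp,
                "final_outcome": outcome,
                "final_end_date": end,
                "final_anchor_ga": anchor_ga,
                "final_anchor_lmp": anchor_lmp,
                "refinement_trail": ";".join(trail),
                "linked": bool(a.linked),
            }
        )
    out = pd.DataFrame(
        out_rows,
        columns=["person_id", "series_index", "initial_outcome", "hierarchy_level",
                 "anchor_date", "initial_end_date", "initial_ga_weeks",
                 "initial_lmp", "final_outcome", "final_end_date",
                 "final_anchor_ga", "final_anchor_lmp", "refinement_trail",
                 "linked"],
    )
    out["initial_ga_weeks"] = out["initial_ga_weeks"].astype("Int64")
    out["final_anchor_ga"] = out["final_anchor_ga"].astype("Int64")
    out["hierarchy_level"] = out["hierarchy_level"].astype("Int64")
    return out
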