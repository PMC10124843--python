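"""The two sensitivity analyses run as pipeline modes.

1.  Fertility-procedure LMP comparison: embryo-transfer and insemination
    procedure dates approximate conception, which typically occurs 14 days
    after LMP, so ``procedure date − 14`` gives an independent LMP estimate
    to compare with the algorithm's.
2.  Gestational age without direct codes: the whole pipeline is re-run with
    direct gestational-age entries masked from the code set, and per-
    pregnancy gestational ages are paired across the two runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .codesets import CodeSet
from .config import RunConfig
from .gestage import ga_bin
from .pipeline import PipelineResult, run_identify

log = logging.getLogger(__name__)

COMPARISON_COLUMNS = [
    "person_id", "series_index", "fertility_procedure_date", "fertility_lmp",
    "algorithm_lmp", "diff_days", "outcome_group", "era",
]


def compare_fertility_lmp(
    cohort: pd.DataFrame,
    evidence: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare algorithm LMP with fertility-procedure-based LMP.

    For each pregnancy, the *last* fertility procedure dated from 56 days
    before the algorithm's LMP through the end of pregnancy qualifies;
    ``fertility_lmp = procedure date − 14 days`` and ``diff_days =
    algorithm LMP − fertility LMP``.  A procedure can serve at most one
    pregnancy (duplicates are dropped with a log message).  Returns the
    per-pregnancy table and a summary (n, mean, median, quartiles of
    diff_days) by outcome group, era, and overall.
    """
    fert = evidence[evidence["kind"] == "fertility_procedure"]
    rows = []
    used: set[tuple[str, pd.Timestamp]] = set()
    lookback = pd.Timedelta(days=config.fertility_lookback_days)
    offset = pd.Timedelta(days=config.conception_offset_days)
    ordered = cohort.sort_values(["person_id", "end_date"], kind="stable")
    by_person = {pid: sub["date"] for pid, sub in fert.groupby("person_id")}
    for row in ordered.itertuples(index=False):
        dates = by_person.get(row.person_id)
        if dates is None or pd.isna(row.final_lmp):
            continue
        ok = dates[(dates >= row.final_lmp - lookback) & (dates <= row.end_date)]
        ok = ok[~ok.map(lambda d: (row.person_id, d) in used)]
        if ok.empty:
            continue
        proc = ok.max()
        if (row.person_id, proc) in used:  # pragma: no cover - filtered above
            continue
        used.add((row.person_id, proc))
        fertility_lmp = proc - offset
        rows.append(
            {
                "person_id": row.person_id,
                "series_index": row.series_index,
                "fertility_procedure_date": proc,
                "fertility_lmp": fertility_lmp,
                "algorithm_lmp": row.final_lmp,
                "diff_days": int((row.final_lmp - fertility_lmp).days),
                "outcome_group": "live_birth"
                if row.final_outcome in ("LB", "LB_SB")
                else "non_live_birth",
                "era": getattr(row, "era", ""),
            }
        )
    table = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)

    def _stats(sub: pd.DataFrame, group: str, era: str) -> dict:
        d = sub["diff_days"]
        return {
            "outcome_group": group,
            "era": era,
            "n": len(d),
            "mean": float(d.mean()) if len(d) else np.nan,
            "median": float(d.median()) if len(d) else np.nan,
            "q1": float(d.quantile(0.25)) if len(d) else np.nan,
            "q3": float(d.quantile(0.75)) if len(d) else np.nan,
        }

    summaries = [_stats(table, "all", "all")]
    for group, sub in table.groupby("outcome_group"):
        summaries.append(_stats(sub, group, "all"))
    for (group, era), sub in table.groupby(["outcome_group", "era"]):
        summaries.append(_stats(sub, group, era))
    summary = pd.DataFrame(
        summaries, columns=["outcome_group", "era", "n", "mean", "median", "q1", "q3"]
    )
    return table, summary


def _match_pairs(with_df: pd.DataFrame, without_df: pd.DataFrame) -> pd.DataFrame:
    """Pair pregnancies across two pipeline runs of the same person by
    greatest overlap of their [LMP, end] intervals."""
    rows = []
    without_by_person = {p: sub for p, sub in without_df.groupby("person_id")}
    for pid, sub_with in with_df.groupby("person_id"):
        sub_wo = without_by_person.get(pid)
        taken: set[int] = set()
        for row in sub_with.sort_values("end_date").itertuples():
            best, best_overlap = None, pd.Timedelta(days=-1)
            if sub_wo is not None:
                for cand in sub_wo.itertuples():
                    if cand.Index in taken:
                        continue
                    lo = max(row.final_lmp, cand.final_lmp)
                    hi = min(row.end_date, cand.end_date)
                    overlap = hi - lo
                    if overlap >= pd.Timedelta(0) and overlap > best_overlap:
                        best, best_overlap = cand, overlap
            rows.append(
                {
                    "person_id": pid,
                    "series_index": row.series_index,
                    "ga_with": int(row.ga_weeks_final),
                    "ga_without": int(best.ga_weeks_final) if best is not None else pd.NA,
                    "bin_with": ga_bin(row.ga_weeks_final),
                    "bin_without": ga_bin(best.ga_weeks_final)
                    if best is not None
                    else "unknown",
                    "era": row.era,
                }
            )
            if best is not None:
                taken.add(best.Index)
    out = pd.DataFrame(
        rows,
        columns=["person_id", "series_index", "ga_with", "ga_without",
                 "bin_with", "bin_without", "era"],
    )
    out["ga_without"] = out["ga_without"].astype("Int64")
    return out


def rerun_without_direct_ga(
    enrollment: pd.DataFrame,
    claims: pd.DataFrame,
    code_set: CodeSet,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PipelineResult, PipelineResult]:
    """Re-run the pipeline with direct gestational-age codes masked.

    Episode construction is recomputed from scratch in the masked run (the
    grouping itself changes, because temporary gestational ages replace the
    directly coded ones).  Returns the paired per-pregnancy gestational-age
    table, a cross-tabulation of gestational-age bins (with × without) by
    era, and both pipeline results.
    """
    full = run_identify(enrollment, claims, code_set, config)
    masked = run_identify(enrollment, claims, code_set.without_direct_ga(), config)
    pairs = _match_pairs(full.cohort, masked.cohort)
    if pairs.empty:
        crosstab = pd.DataFrame()
    else:
        crosstab = pd.crosstab(
            [pairs["era"], pairs["bin_with"]], pairs["bin_without"], dropna=False
        )
    return pairs, crosstab, full, masked
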