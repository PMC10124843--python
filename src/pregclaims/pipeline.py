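"""End-to-end orchestration of the identification pipeline.

Stage order mirrors the algorithm: population selection → record
extraction → episode grouping → infant linkage → outcome hierarchy and
refinement → gestational-age finalization → imputation/censoring → cohort
filters.  The run report reconciles a funnel count at every stage and adds
the descriptive stratifications (outcome × era, gestational-age bins, age
bands, region, plan type, continuous enrollment), all unweighted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import claims_io, episodes as episodes_mod, gestage, infant_link, outcomes
from .codesets import CodeSet
from .config import RunConfig


@dataclass
class PipelineResult:
    """All intermediate and final tables of one identification run."""

    women: set[str]
    infant_ids: set[str]
    records: pd.DataFrame
    grouped_records: pd.DataFrame
    episodes: pd.DataFrame
    infants: pd.DataFrame
    linkage: pd.DataFrame
    assignments: pd.DataFrame
    pregnancies: pd.DataFrame
    cohort: pd.DataFrame
    excluded: pd.DataFrame
    evidence: pd.DataFrame
    report: dict = field(default_factory=dict)


AGE_BANDS = [(15, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 44), (45, 49)]


def _age_band(age: float) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return "other"


def _value_counts(series: pd.Series) -> dict:
    return {str(k): int(v) for k, v in series.value_counts().sort_index().items()}


def build_report(
    result: "PipelineResult", enrollment: pd.DataFrame, config: RunConfig
) -> dict:
    cohort = result.cohort
    excl_counts = _value_counts(result.excluded["excluded_reason"]) if not result.excluded.empty else {}
    funnel = {
        "n_enrollees": int(enrollment["person_id"].nunique()),
        "n_women_selected": len(result.women),
        "n_women_with_records": int(result.records["person_id"].nunique()),
        "n_records": int(len(result.records)),
        "n_episodes": int(len(result.episodes)),
        "n_infants": len(result.infant_ids),
        "n_infants_linked": int(len(result.linkage)),
        "n_missing_outcome_imputed": int(
            (result.pregnancies["ga_source"] == "imputed_39").sum()
        ),
        "exclusions": excl_counts,
        "n_excluded": int(len(result.excluded)),
        "n_final_pregnancies": int(len(cohort)),
        "n_final_women": int(cohort["person_id"].nunique()) if not cohort.empty else 0,
    }
    strata: dict = {}
    if not cohort.empty:
        strata["outcome"] = _value_counts(cohort["final_outcome"])
        strata["outcome_by_era"] = {
            era: _value_counts(sub["final_outcome"])
            for era, sub in cohort.groupby("era")
        }
        strata["ga_bin"] = _value_counts(
            cohort["ga_weeks_final"].map(gestage.ga_bin)
        )
        birth_year = enrollment.groupby("person_id")["birth_year"].first()
        age = cohort["end_date"].dt.year - cohort["person_id"].map(birth_year).astype(
            "float"
        )
        strata["age_band"] = _value_counts(age.map(_age_band))
        person_attrs = enrollment.groupby("person_id").agg(
            region=("region", "first"), plan_type=("plan_type", "first")
        )
        strata["region"] = _value_counts(cohort["person_id"].map(person_attrs["region"]))
        strata["plan_type"] = _value_counts(
            cohort["person_id"].map(person_attrs["plan_type"])
        )
        strata["continuous_enrollment"] = _value_counts(
            cohort["continuous_enrollment"].astype(str)
        )
        strata["ga_source"] = _value_counts(cohort["ga_source"])
    return {"funnel": funnel, "strata": strata}


def run_identify(
    enrollment: pd.DataFrame,
    claims: pd.DataFrame,
    code_set: CodeSet,
    config: RunConfig,
) -> PipelineResult:
    """Execute the full identification pipeline on in-memory tables."""
    women = claims_io.select_women(enrollment, config)
    infant_ids = claims_io.select_infants(enrollment, config)

    records = claims_io.extract_records(claims, code_set, women, config)
    evidence = claims_io.extract_evidence(
        claims, code_set, women | infant_ids, config
    )

    with_temp = episodes_mod.impute_temporary_ga(records, config)
    grouped = episodes_mod.group_records(with_temp, config)
    epi = episodes_mod.summarize_episodes(grouped, config)

    infants = infant_link.build_infant_records(
        claims, code_set, enrollment, infant_ids, config
    )
    linkage = infant_link.link_infants(epi, infants, enrollment, config)

    initial = outcomes.assign_initial_outcomes(epi, grouped, linkage, config)
    refined = outcomes.refine_outcomes(initial, epi, grouped, evidence, config)

    pregnancies = gestage.finalize_ga(
        refined, epi, grouped, linkage, infants, evidence, config
    )
    pregnancies = gestage.impute_missing_and_censor(pregnancies, enrollment, config)
    cohort, excluded = gestage.apply_cohort_filters(pregnancies, enrollment, config)

    result = PipelineResult(
        women=women,
        infant_ids=infant_ids,
        records=records,
        grouped_records=grouped,
        episodes=epi,
        infants=infants,
        linkage=linkage,
        assignments=refined,
        pregnancies=pregnancies,
        cohort=cohort,
        excluded=excluded,
        evidence=evidence,
    )
    result.report = build_report(result, enrollment, config)
    return result


def _frame_for_csv(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, list)).any():
            out[col] = out[col].map(lambda v: "|".join(v) if isinstance(v, list) else "")
    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage output as delimited text plus the JSON report.

    Output is deterministic: identical inputs yield byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    episodes_mod.episodes_to_flat(result.episodes).to_csv(
        outdir / "episodes.csv", index=False
    )
    result.linkage.to_csv(outdir / "linkage.csv", index=False)
    result.assignments.to_csv(outdir / "outcomes.csv", index=False)
    _frame_for_csv(result.cohort).to_csv(outdir / "cohort.csv", index=False)
    _frame_for_csv(result.excluded).to_csv(outdir / "excluded.csv", index=False)
    with open(outdir / "report.json", "w") as f:
        json.dump(result.report, f, indent=2, sort_keys=True)
        f.write("\n")
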