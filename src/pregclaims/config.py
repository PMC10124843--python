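"""Run configuration for the pregnancy-identification pipeline.

Every numeric constant of the algorithm (gap rules, temporary gestational
ages, verification windows, gestational-age defaults) lives here so that
stage logic contains no hard-coded clinical parameters.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

OutcomeClass = Literal["LB", "SB", "LB_SB", "SAB", "IAB", "ECT", "UNKNOWN"]

#: Outcome classes that behave as live-birth evidence for gap rules and linkage.
LIVE_BIRTH_CLASSES = frozenset({"LB", "LB_SB"})

#: Outcome classes treated as "live birth or stillbirth" for temporary GA.
LB_SB_CLASSES = frozenset({"LB", "SB", "LB_SB"})


class RunConfig(BaseModel):
    """All tunable parameters of the identification pipeline.

    Defaults reproduce the published algorithm: 2008–2019 study window with a
    one-year claims lookback, the 2015-10-01 ICD-9 → ICD-10 transition as the
    era boundary, 120/42-day episode gap rules, 20/6-week temporary
    gestational ages, a [−7, +30]-day infant linkage window, a ±30-day
    ectopic-verification window, and live-birth imputation at 39 weeks for
    pregnancies with missing outcomes.

    Unknown keys are rejected at construction, so a misspelled rule toggle
    is a startup error rather than a silent no-op.
    """

    model_config = ConfigDict(extra="forbid")

    study_start: dt.date = dt.date(2008, 1, 1)
    study_end: dt.date = dt.date(2019, 12, 31)
    data_end: dt.date = dt.date(2019, 12, 31)
    era_boundary: dt.date = dt.date(2015, 10, 1)
    lookback_days: int = Field(365, ge=0)

    # episode grouping
    gap_live_birth_days: int = Field(120, gt=0)
    gap_other_days: int = Field(42, gt=0)
    temporary_ga_lb_sb_weeks: int = Field(20, ge=1, le=45)
    temporary_ga_other_weeks: int = Field(6, ge=1, le=45)
    grouping_mode: Literal["transitive", "sequential"] = "transitive"

    # infant linkage window relative to episode service-date extrema
    infant_window_before_days: int = Field(7, ge=0)
    infant_window_after_days: int = Field(30, ge=0)

    # outcome refinement
    enable_rule_iab_to_ect: bool = True
    enable_rule_ectopic_verification: bool = True
    enable_rule_stillbirth_adjustment: bool = True
    ectopic_window_days: int = Field(30, ge=0)
    stillbirth_ga_cut_weeks: int = Field(20, ge=1)

    # gestational-age finalization
    ga_defaults: Dict[str, int] = Field(
        default_factory=lambda: {
            "LB": 39, "LB_SB": 39, "SB": 20, "SAB": 9, "IAB": 9, "ECT": 7,
        }
    )
    ga_preterm_weeks: int = Field(35, ge=1, le=45)
    ga_prolonged_weeks: int = Field(42, ge=1, le=45)
    imputed_ga_weeks: int = Field(39, ge=1, le=45)
    direct_ga_after_end_tolerance_days: int = Field(30, ge=0)

    # cohort filters
    age_min: int = Field(15, ge=0)
    age_max: int = Field(49, ge=0)
    max_enrollment_gap_months: int = Field(2, ge=0)

    # fertility-procedure sensitivity analysis
    fertility_lookback_days: int = Field(56, ge=0)
    conception_offset_days: int = Field(14, ge=0)

    @model_validator(mode="after")
    def _check_windows(self) -> "RunConfig":
        if not (self.study_start < self.study_end <= self.data_end):
            raise ValueError(
                "require study_start < study_end <= data_end, got "
                f"{self.study_start} / {self.study_end} / {self.data_end}"
            )
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")
        return self

    def gap_days_for(self, outcome_class: str | None) -> int:
        """Gap required after a record, by its outcome class.

        Live-birth records (including combined live birth + stillbirth)
        require the long gap; every other record — stillbirth-only,
        abortion, ectopic, unknown, or a pure gestational-age record with no
        outcome — requires the short gap.
        """
        if outcome_class in LIVE_BIRTH_CLASSES:
            return self.gap_live_birth_days
        return self.gap_other_days

    def temporary_ga_for(self, outcome_class: str | None) -> int:
        if outcome_class in LB_SB_CLASSES:
            return self.temporary_ga_lb_sb_weeks
        return self.temporary_ga_other_weeks
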