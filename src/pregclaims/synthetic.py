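"""Seeded synthetic claims generator with a ground-truth pregnancy ledger.

The generator emulates the structure of commercial-insurance claims data:
women aged 15–49 with multi-year enrollment spans, family-linked infants
whose birth year equals their first enrollment year, and era-dependent
coding (direct gestational-age codes rare before the ICD-10 transition on
2015-10-01, common after).  Every pregnancy is recorded in a truth table so
each pipeline stage has a recoverable target.

Emission model, per pregnancy: prenatal visits at whole-week offsets from
the true LMP emit week-of-gestation codes (``Z3A.NN``) in the ICD-10 era;
the delivery/end date emits outcome diagnosis codes plus, for deliveries,
DRG and procedure codes, each retained independently with probability
``p_outcome_code_emitted`` (a hospital delivery generates several claims, so
single-code dropout rarely hides the whole event); conflicting outcome codes
are planted with ``p_conflicting_code`` using class pairs the outcome
hierarchy and refinement rules are designed to resolve; ectopic pregnancies
emit a proximate ectopic procedure or methotrexate claim; fertility-conceived
pregnancies emit an embryo-transfer/insemination procedure exactly 14 days
after the true LMP.

Each woman draws from her own random stream keyed by ``(seed, index)``, so
generation is order-independent and byte-identical across runs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import LIVE_BIRTH_CLASSES, RunConfig
from .pipeline import PipelineResult

TRUTH_COLUMNS = [
    "person_id", "pregnancy_index", "true_outcome", "true_lmp", "true_end_date",
    "true_ga_weeks", "multiple_gestation", "infant_ids", "conception_via_fertility",
]

#: conflicting-code class planted on top of each true outcome; pairs chosen
#: so that the hierarchy/refinements are exercised rather than defeated
CONFLICT_MAP = {
    "LB": "SAB", "LB_SB": "LB", "SB": "SAB",
    "SAB": "IAB", "IAB": "ECT", "ECT": "IAB",
}

# outcome DX codes by (class, era)
DX_CODE = {
    ("LB", "icd9"): ("650", "ICD9-DX"),
    ("LB", "icd10"): ("O80", "ICD10-DX"),
    ("SB", "icd9"): ("656.41", "ICD9-DX"),
    ("SB", "icd10"): ("Z37.1", "ICD10-DX"),
    ("LB_SB", "icd9"): ("V27.3", "ICD9-DX"),
    ("LB_SB", "icd10"): ("Z37.3", "ICD10-DX"),
    ("SAB", "icd9"): ("634.91", "ICD9-DX"),
    ("SAB", "icd10"): ("O03.9", "ICD10-DX"),
    ("IAB", "icd9"): ("635.92", "ICD9-DX"),
    ("IAB", "icd10"): ("O04.9", "ICD10-DX"),
    ("ECT", "icd9"): ("633.90", "ICD9-DX"),
    ("ECT", "icd10"): ("O00.90", "ICD10-DX"),
}
SECONDARY_LB_DX = {"icd9": ("V27.0", "ICD9-DX"), "icd10": ("Z37.0", "ICD10-DX")}
UNKNOWN_OUTCOME_DX = {"icd9": ("V27.9", "ICD9-DX"), "icd10": ("Z37.9", "ICD10-DX")}
DRG_CODE = {"LB": "775", "LB_SB": "775", "SAB": "779", "IAB": "770", "ECT": "777"}
PX_CODE = {
    "LB": ("59400", "CPT"), "LB_SB": ("59400", "CPT"), "SAB": ("59812", "CPT"),
    "IAB": ("59840", "CPT"), "ECT": ("59120", "CPT"), "SB": ("10E0XZZ", "ICD10-PX"),
}
BIRTH_HOSP_DX = {"icd9": ("V30.00", "ICD9-DX"), "icd10": ("Z38.00", "ICD10-DX")}
PRETERM_INFANT_DX = {"icd9": ("765.10", "ICD9-DX"), "icd10": ("P07.30", "ICD10-DX")}
PROLONGED_INFANT_DX = {"icd9": ("766.22", "ICD9-DX"), "icd10": ("P08.21", "ICD10-DX")}
PRETERM_MATERNAL_DX = {"icd9": ("644.21", "ICD9-DX"), "icd10": ("O60.14X0", "ICD10-DX")}
PROLONGED_MATERNAL_DX = {"icd9": ("645.11", "ICD9-DX"), "icd10": ("O48.0", "ICD10-DX")}

# ICD-9 765.2X weeks-of-gestation codes and their assigned single week
ICD9_GA_CODES = [
    ("765.21", 20), ("765.22", 24), ("765.23", 26), ("765.24", 28),
    ("765.25", 30), ("765.26", 32), ("765.27", 34), ("765.28", 36), ("765.29", 39),
]

PRENATAL_SCHEDULE = (8, 12, 16, 20, 24, 28, 31, 34, 36, 38, 39, 40)

# gestational-age distributions per outcome, in completed weeks; shaped to
# put live births mostly at term, stillbirths bimodal at 20 and late term,
# and losses early — the ranges the generator enforces per outcome
_GA_DISTS: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _ga_dist(outcome: str) -> tuple[np.ndarray, np.ndarray]:
    if outcome in _GA_DISTS:
        return _GA_DISTS[outcome]
    if outcome in ("LB",):
        weeks = np.arange(24, 43)
        w = np.array([.003, .003, .003, .003, .003, .008, .008, .008, .008, .008,
                      .02, .03, .05, .09, .15, .28, .20, .09, .025])
    elif outcome == "LB_SB":
        weeks = np.arange(28, 41)
        w = np.array([.04, .05, .06, .07, .08, .09, .10, .11, .11, .11, .10, .05, .03])
    elif outcome == "SB":
        weeks = np.arange(20, 40)
        w = np.array([.30, .05, .04, .03, .03, .02, .03, .02, .04, .02,
                      .04, .02, .05, .02, .05, .03, .07, .08, .09, .10])
    elif outcome == "SAB":
        weeks = np.arange(6, 20)
        w = np.array([.08, .12, .16, .16, .14, .10, .08, .05, .04, .03, .02, .01, .005, .005])
    elif outcome == "IAB":
        weeks = np.arange(6, 25)
        w = np.array([.10, .13, .15, .14, .12, .09, .07, .05, .04, .03,
                      .02, .015, .01, .01, .005, .005, .005, .005, .005])
    elif outcome == "ECT":
        weeks = np.arange(5, 11)
        w = np.ones(6)
    else:  # pragma: no cover
        raise ValueError(outcome)
    probs = w / w.sum()
    _GA_DISTS[outcome] = (weeks, probs)
    return weeks, probs


class EmissionConfig(BaseModel):
    """Parameters of the synthetic emission model (all probabilities in [0, 1])."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    era_boundary: dt.date = dt.date(2015, 10, 1)
    data_end: dt.date = dt.date(2019, 12, 31)
    enrollment_start_year_min: int = 2008
    enrollment_start_year_max: int = 2017
    enrollment_months_min: int = 24
    enrollment_months_max: int = 96

    outcome_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "LB": 0.779, "SAB": 0.162, "IAB": 0.045,
            "ECT": 0.007, "SB": 0.006, "LB_SB": 0.001,
        }
    )
    pregnancy_count_probs: tuple[float, ...] = (0.15, 0.55, 0.25, 0.05)

    p_outcome_code_emitted: float = 0.95
    p_conflicting_code: float = 0.02
    p_direct_ga_per_visit_icd10: float = 0.8
    p_direct_ga_at_delivery_icd10: float = 0.9
    p_direct_ga_at_delivery_icd9: float = 0.05
    p_unknown_outcome_dx: float = 0.05
    visits_mean: float = 5.0
    p_secondary_lb_dx: float = 0.6
    p_drg_delivery: float = 0.6
    p_px_delivery: float = 0.7
    p_drg_abortion: float = 0.3
    p_px_abortion: float = 0.5
    p_px_stillbirth: float = 0.3
    p_infant_enrolled_same_family: float = 0.75
    p_infant_birth_code: float = 0.9
    p_infant_preterm_code: float = 0.8
    p_maternal_preterm_code: float = 0.5
    p_twin_live_birth: float = 0.02
    p_ect_evidence: float = 0.9
    p_fertility_conception: float = 0.03
    p_enrollment_gap: float = 0.05
    p_out_of_age_range: float = 0.02
    min_interpregnancy_margin_days: int = 30
    adversarial: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EmissionConfig":
        for name, val in self.__dict__.items():
            if name.startswith("p_") and not 0.0 <= float(val) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        total = sum(self.outcome_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome_mix must sum to 1, got {total}")
        if abs(sum(self.pregnancy_count_probs) - 1.0) > 1e-9:
            raise ValueError("pregnancy_count_probs must sum to 1")
        return self


def noiseless_config(seed: int = 0, **overrides) -> EmissionConfig:
    """Noiseless regime: every code emitted, no conflicts, no coverage gaps,
    all infants enrolled, all pregnancies in the ICD-10 era with a direct
    gestational-age code on the delivery claim."""
    base = dict(
        seed=seed,
        enrollment_start_year_min=2016,
        enrollment_start_year_max=2017,
        p_outcome_code_emitted=1.0,
        p_conflicting_code=0.0,
        p_direct_ga_per_visit_icd10=1.0,
        p_direct_ga_at_delivery_icd10=1.0,
        p_direct_ga_at_delivery_icd9=1.0,
        p_unknown_outcome_dx=0.0,
        p_infant_enrolled_same_family=1.0,
        p_infant_birth_code=1.0,
        p_maternal_preterm_code=0.0,
        p_ect_evidence=1.0,
        p_enrollment_gap=0.0,
        p_out_of_age_range=0.0,
        p_fertility_conception=0.1,
    )
    base.update(overrides)
    return EmissionConfig(**base)


def noisy_config(seed: int = 0, **overrides) -> EmissionConfig:
    """Stress regime: 10% per-code outcome dropout, 5% conflicting codes,
    10% enrollment gaps."""
    base = dict(
        seed=seed,
        p_outcome_code_emitted=0.9,
        p_conflicting_code=0.05,
        p_enrollment_gap=0.1,
    )
    base.update(overrides)
    return EmissionConfig(**base)


@dataclass
class SyntheticData:
    """One generated cohort: the pipeline's input tables plus ground truth."""

    enrollment: pd.DataFrame
    claims: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        enr = self.enrollment.copy()
        enr["month_start"] = enr["month_start"].astype(str)
        enr["month_end"] = enr["month_end"].astype(str)
        enr.to_csv(outdir / "enrollment.csv", index=False)
        clm = self.claims.copy()
        clm["service_date"] = clm["service_date"].dt.strftime("%Y-%m-%d")
        clm.to_csv(outdir / "claims.csv", index=False)
        tru = self.truth.copy()
        for col in ("true_lmp", "true_end_date"):
            tru[col] = tru[col].dt.strftime("%Y-%m-%d")
        tru.to_csv(outdir / "truth.csv", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    tru = pd.read_csv(path, dtype={"person_id": str, "infant_ids": str},
                      keep_default_na=False)
    tru["true_lmp"] = pd.to_datetime(tru["true_lmp"])
    tru["true_end_date"] = pd.to_datetime(tru["true_end_date"])
    tru["multiple_gestation"] = tru["multiple_gestation"].astype(bool)
    tru["conception_via_fertility"] = tru["conception_via_fertility"].astype(bool)
    return tru


def _era(day: dt.date, boundary: dt.date) -> str:
    return "icd10" if day >= boundary else "icd9"


def _icd9_ga_code(ga: int) -> tuple[str, int]:
    """Nearest 765.2X code for a true gestational age (ties to the earlier)."""
    best = min(ICD9_GA_CODES, key=lambda cw: (abs(cw[1] - ga), cw[1]))
    return best


class _WomanBuilder:
    """Accumulates one woman's rows; keeps claim numbering deterministic."""

    def __init__(self, pid: str, fid: str):
        self.pid = pid
        self.fid = fid
        self.n_claims = 0
        self.enrollment: list[dict] = []
        self.claims: list[dict] = []
        self.truth: list[dict] = []

    def add_claim(self, pid: str, day: dt.date, setting: str, code: str, system: str) -> None:
        self.n_claims += 1
        self.claims.append(
            {
                "person_id": pid,
                "claim_id": f"{self.pid}-C{self.n_claims:04d}",
                "service_date": day,
                "setting": setting,
                "code": code,
                "code_system": system,
            }
        )

    def add_spans(self, pid: str, fid: str, sex: str, birth_year: int,
                  months: list[pd.Period], plan: str, region: str) -> None:
        if not months:
            return
        months = sorted(set(months))
        start = prev = months[0]
        spans = []
        for m in months[1:]:
            if m != prev + 1:
                spans.append((start, prev))
                start = m
            prev = m
        spans.append((start, prev))
        for s, e in spans:
            self.enrollment.append(
                {
                    "person_id": pid, "family_id": fid, "sex": sex,
                    "birth_year": birth_year, "month_start": s, "month_end": e,
                    "plan_type": plan, "region": region,
                }
            )


def _generate_woman(i: int, cfg: EmissionConfig) -> _WomanBuilder:
    rng = np.random.default_rng([cfg.seed % (2**31), i])
    pid = f"W{i:06d}"
    b = _WomanBuilder(pid, f"F{i:06d}")
    boundary = cfg.era_boundary
    data_end = cfg.data_end
    window_end_month = pd.Period(data_end.strftime("%Y-%m"), freq="M")

    start_year = int(rng.integers(cfg.enrollment_start_year_min,
                                  cfg.enrollment_start_year_max + 1))
    start_month = pd.Period(f"{start_year}-{int(rng.integers(1, 13)):02d}", freq="M")
    n_months = int(rng.integers(cfg.enrollment_months_min, cfg.enrollment_months_max + 1))
    end_month = min(start_month + n_months - 1, window_end_month)

    if rng.random() < cfg.p_out_of_age_range:
        birth_year = start_year - int(rng.choice([13, 52]))
    else:
        birth_year = start_year - int(rng.integers(18, 42))
    plan = str(rng.choice(["large_employer", "small_plan"], p=[0.55, 0.45]))
    region = str(rng.choice(
        ["Northeast", "Midwest", "South", "West", "Unknown"],
        p=[0.18, 0.22, 0.39, 0.19, 0.02],
    ))

    months = list(pd.period_range(start_month, end_month, freq="M"))
    if rng.random() < cfg.p_enrollment_gap and len(months) > 12:
        if rng.random() < 0.5:  # truncation: woman disenrolls early
            cut = int(rng.integers(9, len(months) - 2))
            months = months[:cut]
        else:  # internal hole of 1-4 months
            at = int(rng.integers(6, len(months) - 5))
            width = int(rng.integers(1, 5))
            months = months[:at] + months[at + width:]
    covered = set(months)
    b.add_spans(pid, b.fid, "F", birth_year, months, plan, region)

    cov_start = months[0].to_timestamp().date()
    cov_end = (months[-1] + 1).to_timestamp().date() - dt.timedelta(days=1)

    classes = sorted(cfg.outcome_mix)
    probs = np.array([cfg.outcome_mix[c] for c in classes])
    n_preg = int(rng.choice(len(cfg.pregnancy_count_probs), p=cfg.pregnancy_count_probs))

    def on_record(day: dt.date) -> bool:
        return day <= data_end and pd.Period(day.strftime("%Y-%m"), freq="M") in covered

    cursor = cov_start + dt.timedelta(days=int(rng.integers(30, 400)))
    infant_counter = 0
    for k in range(n_preg):
        lmp = cursor
        if lmp > cov_end - dt.timedelta(days=30):
            break
        outcome = str(rng.choice(classes, p=probs))
        weeks, w_probs = _ga_dist(outcome)
        ga = int(rng.choice(weeks, p=w_probs))
        end = lmp + dt.timedelta(days=7 * ga)
        fertility = bool(rng.random() < cfg.p_fertility_conception)
        twin = outcome == "LB" and rng.random() < cfg.p_twin_live_birth

        # prenatal visits at whole-week offsets from the true LMP
        eligible = [w for w in PRENATAL_SCHEDULE if w < ga]
        n_visits = min(len(eligible), int(rng.poisson(cfg.visits_mean)))
        if n_visits and n_visits < len(eligible):
            visit_weeks = sorted(
                int(w) for w in rng.choice(eligible, size=n_visits, replace=False)
            )
        else:
            visit_weeks = eligible if n_visits else []
        for w in visit_weeks:
            day = lmp + dt.timedelta(days=7 * w)
            if not on_record(day):
                continue
            era = _era(day, boundary)
            if era == "icd10" and 8 <= w <= 42 and rng.random() < cfg.p_direct_ga_per_visit_icd10:
                b.add_claim(pid, day, "outpatient", f"Z3A.{w:02d}", "ICD10-DX")

        infant_ids: list[str] = []
        if on_record(end):
            era = _era(end, boundary)
            setting = "inpatient" if outcome in LIVE_BIRTH_CLASSES else "outpatient"
            if rng.random() < cfg.p_outcome_code_emitted:
                code, system = DX_CODE[(outcome, era)]
                b.add_claim(pid, end, setting, code, system)
            if outcome in LIVE_BIRTH_CLASSES:
                if outcome == "LB" and rng.random() < cfg.p_secondary_lb_dx * cfg.p_outcome_code_emitted:
                    code, system = SECONDARY_LB_DX[era]
                    b.add_claim(pid, end, setting, code, system)
                if rng.random() < cfg.p_drg_delivery * cfg.p_outcome_code_emitted:
                    b.add_claim(pid, end, setting, DRG_CODE[outcome], "DRG")
                if rng.random() < cfg.p_px_delivery * cfg.p_outcome_code_emitted:
                    code, system = PX_CODE[outcome]
                    b.add_claim(pid, end, setting, code, system)
            elif outcome == "SB":
                if era == "icd10" and rng.random() < cfg.p_px_stillbirth * cfg.p_outcome_code_emitted:
                    code, system = PX_CODE["SB"]
                    b.add_claim(pid, end, setting, code, system)
            else:
                if rng.random() < cfg.p_drg_abortion * cfg.p_outcome_code_emitted:
                    b.add_claim(pid, end, setting, DRG_CODE[outcome], "DRG")
                if rng.random() < cfg.p_px_abortion * cfg.p_outcome_code_emitted:
                    code, system = PX_CODE[outcome]
                    b.add_claim(pid, end, setting, code, system)
            # direct gestational age on the delivery/end claim
            if era == "icd10":
                if 8 <= ga <= 42 and rng.random() < cfg.p_direct_ga_at_delivery_icd10:
                    b.add_claim(pid, end, setting, f"Z3A.{ga:02d}", "ICD10-DX")
            elif outcome in ("LB", "SB", "LB_SB"):
                if rng.random() < cfg.p_direct_ga_at_delivery_icd9:
                    code, _ = _icd9_ga_code(ga)
                    b.add_claim(pid, end, setting, code, "ICD9-DX")
            if rng.random() < cfg.p_conflicting_code:
                code, system = DX_CODE[(CONFLICT_MAP[outcome], era)]
                b.add_claim(pid, end, setting, code, system)
            if rng.random() < cfg.p_unknown_outcome_dx:
                code, system = UNKNOWN_OUTCOME_DX[era]
                b.add_claim(pid, end, setting, code, system)
            # maternal preterm / prolonged codes
            if outcome in LIVE_BIRTH_CLASSES and ga < 37:
                if rng.random() < cfg.p_maternal_preterm_code:
                    code, system = PRETERM_MATERNAL_DX[era]
                    b.add_claim(pid, end, setting, code, system)
            if outcome in LIVE_BIRTH_CLASSES and ga >= 42:
                if rng.random() < 0.5 * cfg.p_maternal_preterm_code:
                    code, system = PROLONGED_MATERNAL_DX[era]
                    b.add_claim(pid, end, setting, code, system)
            # ectopic verification evidence
            if outcome == "ECT" and rng.random() < cfg.p_ect_evidence:
                off = int(rng.integers(-2, 11))
                day = min(end + dt.timedelta(days=off), data_end)
                if rng.random() < 0.5:
                    b.add_claim(pid, day, "outpatient", "59120", "CPT")
                else:
                    b.add_claim(pid, day, "outpatient", "J9250", "HCPCS")
            # infants enrolled in the same family
            if outcome in LIVE_BIRTH_CLASSES and end <= data_end:
                n_inf = 2 if twin else 1
                if rng.random() < cfg.p_infant_enrolled_same_family:
                    for j in range(n_inf):
                        infant_counter += 1
                        iid = f"I{i:06d}X{infant_counter}"
                        infant_ids.append(iid)
                        birth_month = pd.Period(end.strftime("%Y-%m"), freq="M")
                        inf_end = min(birth_month + int(rng.integers(12, 37)),
                                      window_end_month)
                        inf_months = list(pd.period_range(birth_month, inf_end, freq="M"))
                        b.add_spans(iid, b.fid, str(rng.choice(["F", "M"])), end.year,
                                    inf_months, plan, region)
                        if rng.random() < cfg.p_infant_birth_code:
                            off = int(rng.integers(0, 4))
                            day = min(end + dt.timedelta(days=off),
                                      dt.date(end.year, 12, 31), data_end)
                            code, system = BIRTH_HOSP_DX[_era(day, boundary)]
                            b.add_claim(iid, day, "inpatient", code, system)
                            if ga < 37 and rng.random() < cfg.p_infant_preterm_code:
                                code, system = PRETERM_INFANT_DX[_era(day, boundary)]
                                b.add_claim(iid, day, "inpatient", code, system)
                            if ga >= 42 and rng.random() < 0.5:
                                code, system = PROLONGED_INFANT_DX[_era(day, boundary)]
                                b.add_claim(iid, day, "inpatient", code, system)
        if fertility:
            day = lmp + dt.timedelta(days=14)
            if on_record(day):
                b.add_claim(pid, day, "outpatient", "58974", "CPT")

        b.truth.append(
            {
                "person_id": pid,
                "pregnancy_index": k + 1,
                "true_outcome": outcome,
                "true_lmp": lmp,
                "true_end_date": end,
                "true_ga_weeks": ga,
                "multiple_gestation": twin or outcome == "LB_SB",
                "infant_ids": "|".join(infant_ids),
                "conception_via_fertility": fertility,
            }
        )
        gap = 120 if outcome in LIVE_BIRTH_CLASSES else 42
        cursor = end + dt.timedelta(
            days=gap + cfg.min_interpregnancy_margin_days + int(rng.integers(0, 300))
        )
    return b


def _adversarial_women() -> list[_WomanBuilder]:
    """Hand-planted hard cases: a back-to-back loss/live-birth pair inside
    the mergeable zone, an infant claim just outside the linkage window, and
    an unverifiable ectopic pregnancy."""
    out = []

    # (a) SAB then LB conceived 30 days later: LMP inside the 42-day gap,
    # so the two true pregnancies merge into one episode
    b = _WomanBuilder("XADV1W", "XADV1F")
    months = list(pd.period_range("2017-01", "2019-12", freq="M"))
    b.add_spans("XADV1W", "XADV1F", "F", 1988, months, "large_employer", "South")
    sab_lmp, sab_ga = dt.date(2017, 3, 1), 8
    sab_end = sab_lmp + dt.timedelta(days=7 * sab_ga)
    b.add_claim("XADV1W", sab_end, "outpatient", "O03.9", "ICD10-DX")
    lb_lmp = sab_end + dt.timedelta(days=30)
    lb_ga = 39
    lb_end = lb_lmp + dt.timedelta(days=7 * lb_ga)
    b.add_claim("XADV1W", lb_end, "inpatient", "O80", "ICD10-DX")
    b.add_claim("XADV1W", lb_end, "inpatient", f"Z3A.{lb_ga}", "ICD10-DX")
    b.truth.append({"person_id": "XADV1W", "pregnancy_index": 1, "true_outcome": "SAB",
                    "true_lmp": sab_lmp, "true_end_date": sab_end, "true_ga_weeks": sab_ga,
                    "multiple_gestation": False, "infant_ids": "",
                    "conception_via_fertility": False})
    b.truth.append({"person_id": "XADV1W", "pregnancy_index": 2, "true_outcome": "LB",
                    "true_lmp": lb_lmp, "true_end_date": lb_end, "true_ga_weeks": lb_ga,
                    "multiple_gestation": False, "infant_ids": "",
                    "conception_via_fertility": False})
    out.append(b)

    # (b) live birth whose infant's first claim is 31 days after the
    # episode end: one day outside the linkage window
    b = _WomanBuilder("XADV2W", "XADV2F")
    months = list(pd.period_range("2017-06", "2019-12", freq="M"))
    b.add_spans("XADV2W", "XADV2F", "F", 1990, months, "small_plan", "West")
    lmp = dt.date(2018, 1, 5)
    ga = 39
    end = lmp + dt.timedelta(days=7 * ga)
    b.add_claim("XADV2W", end, "inpatient", "O80", "ICD10-DX")
    b.add_claim("XADV2W", end, "inpatient", f"Z3A.{ga}", "ICD10-DX")
    inf_day = end + dt.timedelta(days=31)
    inf_months = list(pd.period_range(end.strftime("%Y-%m"), "2019-12", freq="M"))
    b.add_spans("XADV2I", "XADV2F", "M", end.year, inf_months, "small_plan", "West")
    b.add_claim("XADV2I", inf_day, "inpatient", "Z38.00", "ICD10-DX")
    b.truth.append({"person_id": "XADV2W", "pregnancy_index": 1, "true_outcome": "LB",
                    "true_lmp": lmp, "true_end_date": end, "true_ga_weeks": ga,
                    "multiple_gestation": False, "infant_ids": "XADV2I",
                    "conception_via_fertility": False})
    out.append(b)

    # (c) ectopic pregnancy with no proximate procedure or methotrexate:
    # must be demoted by the verification rule, with the trail recorded
    b = _WomanBuilder("XADV3W", "XADV3F")
    months = list(pd.period_range("2017-01", "2019-12", freq="M"))
    b.add_spans("XADV3W", "XADV3F", "F", 1992, months, "large_employer", "Midwest")
    lmp = dt.date(2018, 5, 1)
    ga = 7
    end = lmp + dt.timedelta(days=7 * ga)
    b.add_claim("XADV3W", end, "outpatient", "O00.90", "ICD10-DX")
    b.truth.append({"person_id": "XADV3W", "pregnancy_index": 1, "true_outcome": "ECT",
                    "true_lmp": lmp, "true_end_date": end, "true_ga_weeks": ga,
                    "multiple_gestation": False, "infant_ids": "",
                    "conception_via_fertility": False})
    out.append(b)
    return out


def generate_cohort(config: EmissionConfig, n_women: int) -> SyntheticData:
    """Generate a synthetic cohort; deterministic given (config, n_women)."""
    builders = [_generate_woman(i, config) for i in range(n_women)]
    if config.adversarial:
        builders.extend(_adversarial_women())

    enrollment = pd.DataFrame(
        [row for b in builders for row in b.enrollment],
        columns=["person_id", "family_id", "sex", "birth_year", "month_start",
                 "month_end", "plan_type", "region"],
    )
    enrollment["birth_year"] = enrollment["birth_year"].astype("Int64")
    claims = pd.DataFrame(
        [row for b in builders for row in b.claims],
        columns=["person_id", "claim_id", "service_date", "setting", "code",
                 "code_system"],
    )
    claims["service_date"] = pd.to_datetime(claims["service_date"])
    truth = pd.DataFrame(
        [row for b in builders for row in b.truth], columns=TRUTH_COLUMNS
    )
    truth["true_lmp"] = pd.to_datetime(truth["true_lmp"])
    truth["true_end_date"] = pd.to_datetime(truth["true_end_date"])
    return SyntheticData(enrollment=enrollment, claims=claims, truth=truth)


# ---------------------------------------------------------------------------
# recovery evaluation


def _covered_months_by_person(enrollment: pd.DataFrame) -> dict[str, set]:
    out: dict[str, set] = {}
    for row in enrollment.itertuples(index=False):
        out.setdefault(row.person_id, set()).update(
            pd.period_range(row.month_start, row.month_end, freq="M")
        )
    return out


def evaluate_recovery(
    truth: pd.DataFrame,
    result: PipelineResult,
    enrollment: pd.DataFrame,
    config: RunConfig,
) -> tuple[dict, pd.DataFrame]:
    """Compare the pipeline's recovered cohort with the generator's truth.

    Truth and recovered pregnancies of one woman are matched greedily by
    overlap of their [LMP, end] intervals.  Sensitivity denominators are
    restricted to *observable* truth pregnancies — those ending on or before
    the data end, in a month the woman was enrolled — because a pregnancy
    that generates no claim is unrecoverable by construction.  Returns the
    metrics dict and the matched truth↔recovered table.
    """
    truth_persons = set(truth["person_id"])
    enrolled = set(enrollment["person_id"])
    if not truth_persons <= enrolled:
        raise ValueError("truth and enrollment tables are from different runs")

    covered = _covered_months_by_person(enrollment)
    data_end = pd.Timestamp(config.data_end)

    tru = truth.copy()
    tru["observable"] = [
        (e <= data_end) and (e.to_period("M") in covered.get(p, set()))
        for p, e in zip(tru["person_id"], tru["true_end_date"])
    ]

    cohort = result.cohort
    rec_by_person = dict(iter(cohort.groupby("person_id"))) if not cohort.empty else {}
    has_direct = {
        (r.person_id, r.series_index): bool(r.has_direct_ga)
        for r in result.episodes.itertuples(index=False)
    }
    linked_methods = {
        (r.person_id, r.series_index): r.method
        for r in result.linkage.itertuples(index=False)
    }

    matches = []
    matched_rec_keys: set[tuple] = set()
    for pid, tsub in tru.groupby("person_id"):
        rsub = rec_by_person.get(pid)
        pairs = []
        if rsub is not None:
            for t in tsub.itertuples():
                for r in rsub.itertuples():
                    lo = max(t.true_lmp, r.final_lmp)
                    hi = min(t.true_end_date, r.end_date)
                    if hi >= lo:
                        pairs.append(((hi - lo).days, t.Index, r.Index))
        pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_t: set[int] = set()
        used_r: set[int] = set()
        for _, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            used_t.add(ti)
            used_r.add(ri)
            t = tru.loc[ti]
            r = cohort.loc[ri]
            key = (r["person_id"], r["series_index"])
            matched_rec_keys.add(key)
            matches.append(
                {
                    "person_id": pid,
                    "pregnancy_index": t["pregnancy_index"],
                    "true_outcome": t["true_outcome"],
                    "true_lmp": t["true_lmp"],
                    "true_end_date": t["true_end_date"],
                    "true_ga_weeks": t["true_ga_weeks"],
                    "observable": bool(t["observable"]),
                    "series_index": r["series_index"],
                    "final_outcome": r["final_outcome"],
                    "final_lmp": r["final_lmp"],
                    "end_date": r["end_date"],
                    "ga_weeks_final": r["ga_weeks_final"],
                    "ga_source": r["ga_source"],
                    "lmp_error_days": int((r["final_lmp"] - t["true_lmp"]).days),
                    "has_direct_ga": has_direct.get(key, False),
                    "n_linked_infants": len(r["linked_infant_ids"]),
                    "linkage_method": linked_methods.get(key, ""),
                }
            )
    matched = pd.DataFrame(matches)

    metrics: dict = {"n_truth": int(len(tru)),
                     "n_truth_observable": int(tru["observable"].sum()),
                     "n_recovered": int(len(cohort))}
    if tru.empty:
        return metrics, matched

    classes = sorted(tru["true_outcome"].unique())
    sens = {}
    for c in classes:
        denom = tru[(tru["true_outcome"] == c) & tru["observable"]]
        if denom.empty:
            sens[c] = None
            continue
        if matched.empty:
            sens[c] = 0.0
            continue
        hit = matched[
            (matched["true_outcome"] == c)
            & matched["observable"]
            & (matched["final_outcome"] == c)
        ]
        sens[c] = len(hit) / len(denom)
    metrics["sensitivity"] = sens

    ppv = {}
    if not cohort.empty:
        for c in sorted(cohort["final_outcome"].unique()):
            denom_n = int((cohort["final_outcome"] == c).sum())
            if matched.empty:
                ppv[c] = 0.0
                continue
            hit = matched[(matched["final_outcome"] == c) & (matched["true_outcome"] == c)]
            ppv[c] = len(hit) / denom_n
    metrics["ppv"] = ppv

    if not matched.empty:
        obs = matched[matched["observable"]]
        lb = obs[obs["true_outcome"].isin(["LB", "LB_SB"])]
        metrics["lmp_exact_frac_lb"] = (
            float((lb["lmp_error_days"] == 0).mean()) if not lb.empty else None
        )
        lb_direct = lb[lb["has_direct_ga"]]
        metrics["lmp_within_7d_frac_lb_direct"] = (
            float((lb_direct["lmp_error_days"].abs() <= 7).mean())
            if not lb_direct.empty
            else None
        )
        metrics["lmp_abs_error_median_days"] = float(obs["lmp_error_days"].abs().median())

        # linkage among observable live births with an enrolled infant
        lb_link = obs[
            obs["true_outcome"].isin(["LB", "LB_SB"])
        ].merge(
            tru[["person_id", "pregnancy_index", "infant_ids"]],
            on=["person_id", "pregnancy_index"],
        )
        lb_link = lb_link[lb_link["infant_ids"] != ""]
        if not lb_link.empty:
            metrics["linkage_sensitivity"] = float(
                (lb_link["n_linked_infants"] > 0).mean()
            )
            metrics["linkage_date_window_frac"] = float(
                (lb_link["linkage_method"] == "date_window").mean()
            )

    # split/merge accounting: map each episode to overlapping truth intervals
    splits = merges = 0
    epi = result.episodes
    tru_by_person = dict(iter(tru.groupby("person_id")))
    truth_hit_counts: dict[tuple, int] = {}
    for e in epi.itertuples(index=False):
        tsub = tru_by_person.get(e.person_id)
        if tsub is None:
            continue
        n_overlap = 0
        for t in tsub.itertuples(index=False):
            lo = max(t.true_lmp, e.min_lmp)
            hi = min(t.true_end_date, e.max_service_date)
            if hi >= lo:
                n_overlap += 1
                k = (t.person_id, t.pregnancy_index)
                truth_hit_counts[k] = truth_hit_counts.get(k, 0) + 1
        merges += max(0, n_overlap - 1)
    splits = sum(max(0, v - 1) for v in truth_hit_counts.values())
    metrics["episode_merges"] = int(merges)
    metrics["episode_splits"] = int(splits)
    return metrics, matched
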