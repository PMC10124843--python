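# Methods

This note documents the model behind `pregclaims`: what the identification
pipeline assumes, which parameters matter, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## The identification model

The pipeline treats a pregnancy as a latent interval `[LMP, end]` observed
only through dated billing codes. Three code families carry signal:

* **outcome codes** (diagnosis, DRG, procedure) dated at or near the end of
  pregnancy, each mapped by the curated code list to one of six outcome
  classes — live birth (LB), stillbirth (SB), combined live birth +
  stillbirth (LB_SB), spontaneous abortion (SAB), induced abortion (IAB),
  ectopic pregnancy (ECT) — or to an explicit *unknown* class;
* **direct gestational-age codes** (`Z3A.NN` in ICD-10-CM, `765.2X` in
  ICD-9-CM) whose meaning is a specific completed week of gestation, dated
  anywhere in the pregnancy;
* **auxiliary codes** used only in verification: infant birth
  hospitalization, preterm/prolonged gestation, ectopic procedures,
  methotrexate, and fertility (embryo transfer / insemination) procedures.

All date arithmetic is exact calendar-day arithmetic on dates without
times; intervals include both endpoints. Gestational age is completed
weeks: `GA = ⌊(end − LMP)/7⌋`. Every cohort row satisfies this identity by
construction.

### Episode grouping

A record starts a new pregnancy only if its service date *and* its inferred
LMP both fall at least `gap` days after an earlier record's service date,
with `gap = 120` after live-birth records (including LB_SB) and `gap = 42`
after everything else, including pure gestational-age records with no
outcome. The conjunction matters: an LMP reaching back inside a previous
pregnancy is physiologically impossible, so such a record is treated as
belonging to that pregnancy regardless of how late its service date is.
Since LMP ≤ service date always (GA ≥ 1 week), the conjunctive test reduces
to the LMP test; both comparisons are coded for clarity.

Grouping is *transitive* by default: a record violating the gap with
respect to **any** earlier record — not only the most recent open episode —
merges the implicated episodes (union–find over all pairs). This makes the
partition exactly the connected components of the pairwise violation graph,
independent of processing order, and monotone in the gap parameters (wider
gaps never create more episodes). A stricter `sequential` mode that
compares a candidate only against the current open episode is available via
`RunConfig.grouping_mode` for comparison; the two differ only on unusual
configurations where a long-gestation record reaches back past an episode
boundary that an intermediate short-gestation record had cleared.

Records lacking a gestational age receive a temporary one for grouping
only — 20 weeks for LB/SB/LB_SB outcomes, 6 weeks otherwise — never used in
final estimates. Same-day records always share an episode.

### Outcome assignment

The 16-level precedence table is walked top-down over the episode's
(outcome class × code type) indicator set plus the infant-linkage flag;
the first applicable level wins. Design intuitions encoded in the order:
infant linkage is near-conclusive evidence of live birth; diagnosis codes
outrank DRGs, which outrank procedures, for abortion-type outcomes;
spontaneous abortion outranks induced abortion when both are coded; DRG
live-birth codes are non-specific and count only when they are the sole
pregnancy-related code of the episode; no DRG is specific to stillbirth.
The anchor record — the earliest record of the assigned outcome class (for
the linkage level, the earliest live-birth-coded record, else the
episode's earliest record) — supplies the initial end date, GA, and LMP.

Refinement rules run in fixed order, each appending its id to a
per-pregnancy audit trail:

* **R1** — initial IAB with any ectopic indicator *and* an ectopic
  procedure or methotrexate claim within ±`W` days of the candidate
  ectopic anchor → recoded ECT.
* **R2** — any ECT outcome must have such evidence within ±`W` days of its
  end date; otherwise the episode is demoted to the next applicable
  hierarchy level with ectopic rows skipped (keeping one source of
  precedence truth), or to MISSING when none applies.
* **R3** — SB with an estimated GA below 20 weeks and a co-occurring SAB
  indicator → SAB; SB with co-occurring LB records and a linked infant →
  LB; SB as the sole outcome type is retained. The 20-week cut
  operationalizes the clinical boundary between fetal loss and stillbirth.

`W` defaults to 30 days, symmetric. Refinement is a pure function of the
initial assignment, indicators, and evidence, hence idempotent. In the
standard pipeline the R3 live-birth branch is unreachable (a linked episode
is assigned LB at level 2 before SB can apply); the rule remains for runs
with linkage or individual levels disabled.

### Gestational age, imputation, censoring

Preference order for the final GA: (1) the **last** direct GA record of the
episode — ties on the same day resolve to the larger week; records dated
more than 30 days after the end (likely a next pregnancy's claim) or whose
implied LMP postdates the end are ignored; (2) a GA assigned to the anchor
outcome code itself; (3) preterm/prolonged flags on the maternal or linked
infant record → 35 / 42 weeks; (4) outcome defaults LB 39, LB_SB 39, SB 20,
SAB 9, IAB 9, ECT 7 weeks. The stillbirth default reflects the earlier mode
of the bimodal stillbirth GA distribution; single-digit defaults for losses
reflect their early-GA mass. All are `RunConfig` parameters.

Missing-outcome pregnancies are imputed as live births at 39 weeks with
`end = max episode LMP + 273 days`. Imputed ends after the data end
(2019-12-31 by default) are right-censored; ends after the woman's last
enrolled month are unobservable; both are excluded with a reason code, as
are deliveries outside the study window or the 15–49 age band (age by year
arithmetic — claims carry only birth year). Era is tagged at the 2015-10-01
ICD-10 transition. Continuous enrollment means at least one covered day in
every month from the LMP month to the end month, tolerating uncovered runs
of at most two consecutive months (the consecutive reading of the "two
month gap" allowance).

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `gap_live_birth_days` / `gap_other_days` | 120 / 42 | days | episode split thresholds |
| `temporary_ga_lb_sb_weeks` / `_other_weeks` | 20 / 6 | weeks | grouping-only GA |
| `infant_window_before/after_days` | 7 / 30 | days | infant linkage window |
| `ectopic_window_days` (`W`) | 30 | days | ectopic verification |
| `ga_defaults` | LB 39, SB 20, SAB 9, IAB 9, ECT 7 | weeks | fallback GA |
| `ga_preterm_weeks` / `ga_prolonged_weeks` | 35 / 42 | weeks | flag-based GA |
| `imputed_ga_weeks` | 39 | weeks | missing-outcome imputation |
| `direct_ga_after_end_tolerance_days` | 30 | days | stray-claim guard |
| `lookback_days` | 365 | days | claims before study start |
| `fertility_lookback_days` / `conception_offset_days` | 56 / 14 | days | fertility LMP analysis |

## The synthetic generator

`EmissionConfig` defines a per-woman generative model: an enrollment span
of 2–8 years starting 2008–2017, 0–3 pregnancies (probabilities
0.15/0.55/0.25/0.05) with outcome mix LB 77.9%, SAB 16.2%, IAB 4.5%, ECT
0.7%, SB 0.6%, LB_SB 0.1% — a realism preset derived from published
claims-cohort composition, not from the algorithm — and outcome-specific GA
distributions (live births concentrated at 38–41 weeks, stillbirths bimodal
at 20 weeks and late term, losses early; ECT ≤ 12, SAB ≤ 19, IAB ≤ 24, SB
and LB ≥ 20 weeks enforced). Successive pregnancies are separated by at
least the grouping gap plus a 30-day margin, so noise-free grouping is
exact by construction; the `adversarial` flag additionally plants known
hard cases (a loss and a conception 30 days later that legitimately merge,
an infant claim one day outside the linkage window, an unverifiable
ectopic).

Emission: prenatal visits sit at whole-week offsets from the true LMP and
emit `Z3A` codes in the ICD-10 era with probability 0.8 per visit; the end
date emits the class's diagnosis code plus, for deliveries, DRG and CPT
codes, *each* retained independently with `p_outcome_code_emitted` — a
delivery generates several claims, so one dropped code rarely hides the
event, which is how real hospital billing behaves. Deliveries also emit a
direct GA code (`Z3A.GA` post-transition with probability 0.9; a coarse
`765.2X` pre-transition with probability 0.05, matching the rarity of
direct GA codes in the ICD-9 era). Conflicting codes are planted with
class pairs the hierarchy is designed to resolve (e.g. SAB on a live
birth, IAB on an ectopic). Live births spawn family-linked infant
enrollees with birth-hospitalization claims 0–3 days after delivery;
ectopics emit a proximate procedure or methotrexate claim; fertility
conceptions emit a procedure at exactly LMP + 14 days. Every woman draws
from a stream keyed by `(seed, index)`, so output is byte-identical across
runs and independent of generation order.

What the generator does **not** emulate: billing-level detail (revenue
codes, adjudication, costs), rule-out and miscoded diagnoses beyond the
single conflicting-code mechanism, transfer of care across insurers,
multi-employer family structures (one woman per family), and week-offset
jitter in prenatal visit dates. Consequently, passing recovery tests shows
the pipeline implements its stated rules exactly and is robust to the
modeled noise; it does not certify accuracy on real claims, where coding
behavior is richer.

Recovery metrics restrict sensitivity denominators to *observable* truth
pregnancies — those ending on or before the data end, in a month the woman
was enrolled — because a pregnancy that generates no claim is unrecoverable
by any claims-based method. The censoring contract is exact on the imputed
end (max LMP + 273 days): a truth pregnancy with GA > 39 weeks can end
after the data boundary while its imputed end falls inside it, in which
case it is retained as an imputed live birth rather than censored; this is
the documented behavior of the imputation rule, and the acceptance test
asserts that such pregnancies are only ever recovered through the
imputation path.

## Problem sizes

The shipped test suite and acceptance script use 1,000 women for the
noiseless exact-recovery regime, 10,000 for the stress regime (10% per-code
dropout, 5% conflicting codes, 10% enrollment gaps), 2,000 for the
censoring audit, and 1,000 seeded random record sets (≤ 12 records) for the
grouping-oracle comparison — sizes chosen so every rare outcome class and
exclusion path is exercised with comfortable margins.

## Known limitations

* The curated code list ships as a documented fixture subset; production
  use requires a complete, licensed code list in the same schema.
* Code matching is exact-string after trimming/uppercasing; wildcard
  families must be expanded in the code list.
* Era validity is not enforced at classification time: an ICD-9 code on a
  post-transition claim is still classified, since real claims contain
  transition-period mixtures and the declared code system is trusted.
* Mother disambiguation when two women in one family both qualify uses a
  deterministic nearest-end-date rule; probabilistic record linkage is out
  of scope, as are distinct episodes for concurrent multi-fetal
  pregnancies and national survey weighting.
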