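# pregclaims

Identify pregnancies — their outcomes, gestational ages, and last-menstrual-
period (LMP) dates — in healthcare claims data spanning the ICD-9 and ICD-10
coding eras.

Administrative claims carry no explicit marker of pregnancy status, outcome,
or delivery date. `pregclaims` reconstructs pregnancies from the codes that
*are* billed: outcome diagnoses (e.g. ICD-10-CM `O80`, `Z37.x`, ICD-9-CM
`650`, `V27.x`), delivery DRGs and procedures (CPT `59400`, DRG `775`), and
direct week-of-gestation codes (`Z3A.NN`, `765.2X`). It is aimed at
reproductive-health and pharmacoepidemiology researchers who need pregnancy
episodes with dated starts and ends from enrollment + claims tables, without
access to birth certificates or medical records.

Because real claims databases are proprietary, the package ships a seeded
synthetic-claims generator with a ground-truth pregnancy ledger, so the whole
pipeline is testable end to end with zero external data.

## The algorithm

1. **Population.** Women aged 15–49 (by enrollment-year arithmetic; only
   birth year is available in claims) and infants — enrollees whose birth
   year equals their first enrolled year — are selected from enrollment.
2. **Records.** Claims carrying an outcome or direct gestational-age code
   are de-duplicated into records: distinct (person, service date, code,
   system) combinations. The service date proxies the end of pregnancy, and
   `LMP = service date − 7 × GA` whenever the code carries a gestational age
   in completed weeks. Records lacking one get a *temporary* GA — 20 weeks
   for live-birth/stillbirth outcomes, 6 weeks otherwise — used for grouping
   only.
3. **Episodes.** Records belong to distinct pregnancies only if the later
   record's service date *and* inferred LMP both fall ≥ 120 days after any
   live-birth record, or ≥ 42 days after any other record. Violating the gap
   with respect to any earlier record merges the two (grouping equals the
   connected components of the pairwise violation graph).
4. **Infant linkage.** Infants are matched to episodes of women sharing
   their family ID: via the earliest infant birth-hospitalization or
   preterm/prolonged claim landing in `[episode min − 7 d, episode max +
   30 d]`, or, for infants without such claims, via birth year = delivery
   year. The earliest live-birth-coded episode wins ties.
5. **Outcome hierarchy.** Each episode gets the first applicable of 16
   ordered (code type × outcome) levels: multiple-birth diagnosis, infant
   linkage, then stillbirth/live-birth/spontaneous-abortion/induced-
   abortion/ectopic diagnoses, abortion-type DRGs, procedures, and last, DRG
   live birth (only when it is the sole code present). Refinement rules then
   recode induced abortions with proximate ectopic evidence, demote ectopics
   lacking an ectopic procedure or methotrexate claim within ±30 days, and
   adjust stillbirths using GA estimates and co-occurring codes.
6. **Gestational age.** The *last* direct GA code of the episode fixes the
   final LMP; GA is recomputed as `⌊(end − LMP)/7⌋` completed weeks.
   Fallbacks: a GA assigned to the anchor outcome code, preterm (35 wk) or
   prolonged (42 wk) defaults when only flag-level evidence exists, and
   outcome-specific defaults (LB 39, SB 20, SAB 9, IAB 9, ECT 7 weeks).
7. **Missing outcomes and censoring.** Pregnancies with no classifiable
   outcome are assumed live births at 39 weeks, delivered at the episode's
   maximum LMP + 273 days. Imputed deliveries past the end of data are
   right-censored; deliveries after the woman's last enrolled month are
   unobservable. Both are excluded, as are deliveries outside the study
   years or age range.

Two sensitivity modes mirror common validation analyses: comparing the
algorithm LMP against fertility-procedure-based LMP (procedure date − 14
days, the approximate conception-to-LMP offset), and re-running the whole
pipeline with direct GA codes masked.

## Worked example

```bash
pregclaims simulate --seed 11 --n-women 200 --out sim
# wrote 341 enrollment spans, 1164 claims, 234 truth pregnancies to sim
pregclaims identify --in sim --out run
pregclaims evaluate --in sim --out eval
```

`identify` prints the funnel of the run (and writes `episodes.csv`,
`linkage.csv`, `outcomes.csv`, `cohort.csv`, `excluded.csv`, `report.json`):

```json
{
  "exclusions": {"censored_after_data_end": 4, "disenrolled_before_end": 3},
  "n_enrollees": 336,
  "n_episodes": 228,
  "n_excluded": 7,
  "n_final_pregnancies": 221,
  "n_final_women": 168,
  "n_infants": 136,
  "n_infants_linked": 135,
  "n_missing_outcome_imputed": 8,
  "n_records": 990,
  "n_women_selected": 195,
  "n_women_with_records": 168
}
```

228 episodes were built from 990 records; 8 had no classifiable outcome and
were imputed as 39-week live births, of which 4 would have delivered after
the 2019-12-31 data end (right-censored) and 3 after disenrollment — leaving
221 pregnancies in the cohort. `evaluate` scores the run against the
generator's truth ledger:

```json
{
  "sensitivity": {"ECT": 1.0, "IAB": 1.0, "LB": 0.989, "SAB": 1.0, "SB": 1.0},
  "ppv":         {"ECT": 1.0, "IAB": 1.0, "LB": 1.0,   "SAB": 1.0, "SB": 1.0},
  "lmp_within_7d_frac_lb_direct": 1.0,
  "linkage_sensitivity": 1.0,
  "episode_merges": 0,
  "episode_splits": 0
}
```

i.e. every observable synthetic pregnancy class was recovered (one live
birth ending in an uncovered month was not), every live birth carrying a
week-of-gestation code had its LMP recovered within a week, and every
enrolled infant was linked to the correct pregnancy.

The same pipeline runs on real extracts via a YAML config pointing at your
enrollment, claims, and curated code-list files; the bundled code list is a
documented fixture subset, not a production list.

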