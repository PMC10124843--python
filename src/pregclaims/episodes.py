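"""Group a woman's pregnancy records into pregnancy episodes.

Two records belong to the same pregnancy unless the later record's service
date AND inferred LMP both fall at least *gap* days after the earlier
record's service date, where the gap is 120 days after any live-birth record
(including combined live birth + stillbirth) and 42 days after every other
record.  Records without a gestational age receive a temporary one (20 weeks
for live-birth/stillbirth outcomes, 6 weeks otherwise) used for grouping
only.

The default grouping semantics are *transitive*: a record that violates the
gap rule with respect to ANY earlier record is merged into that record's
episode (union–find over all pairs), which makes grouping equal to the
connected components of the pairwise violation graph and monotone in the gap
parameters.  A stricter ``sequential`` mode that only compares a record to
the members of the most recent open episode is available for comparison.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .config import RunConfig

EPISODE_COLUMNS = [
    "person_id", "series_index", "min_service_date", "max_service_date",
    "min_lmp", "max_lmp", "indicators", "sole_code_is_drg_lb",
    "has_direct_ga", "n_records",
]


def impute_temporary_ga(records: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Fill records lacking a gestational age with a temporary one.

    Live-birth and stillbirth outcome records get 20 weeks; all other
    records get 6 weeks.  The LMP is recomputed from the temporary value and
    ``ga_is_temporary`` is set, so that downstream finalization never treats
    these as measured gestational ages.  Records that already carry a
    gestational age are returned unchanged.
    """
    out = records.copy()
    missing = out["ga_weeks"].isna()
    if not missing.any():
        return out
    temp = out.loc[missing, "outcome_class"].map(
        lambda oc: config.temporary_ga_for(oc if pd.notna(oc) else None)
    )
    out.loc[missing, "ga_weeks"] = temp.astype("Int64")
    out.loc[missing, "ga_is_temporary"] = True
    out.loc[missing, "lmp"] = out.loc[missing, "service_date"] - pd.to_timedelta(
        temp.astype(int) * 7, unit="D"
    )
    out["ga_weeks"] = out["ga_weeks"].astype("Int64")
    return out


def _group_one_person(
    service: np.ndarray,
    lmp: np.ndarray,
    gaps: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Component labels for one person's records, already sorted by
    (service date, lmp).  ``service``/``lmp`` are integer day numbers;
    ``gaps`` is the required gap after each record."""
    n = len(service)
    labels = np.zeros(n, dtype=int)
    if n == 0:
        return labels
    if mode == "transitive":
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for j in range(1, n):
            for i in range(j):
                thr = service[i] + gaps[i]
                if not (service[j] >= thr and lmp[j] >= thr):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        roots = [find(i) for i in range(n)]
        # renumber components in order of first (earliest) record
        order: dict[int, int] = {}
        for r in roots:
            if r not in order:
                order[r] = len(order)
        labels = np.array([order[r] for r in roots], dtype=int)
    elif mode == "sequential":
        current: list[int] = []
        ep = -1
        for j in range(n):
            clears_all = all(
                service[j] >= service[i] + gaps[i] and lmp[j] >= service[i] + gaps[i]
                for i in current
            )
            if not current or not clears_all:
                if not current:
                    ep += 1
                    current = [j]
                else:
                    current.append(j)
            else:
                ep += 1
                current = [j]
            labels[j] = ep
    else:  # pragma: no cover - guarded by RunConfig Literal
        raise ValueError(f"unknown grouping mode {mode!r}")
    return labels


def group_records(
    records: pd.DataFrame,
    config: RunConfig,
    mode: Literal["transitive", "sequential"] | None = None,
) -> pd.DataFrame:
    """Assign each record to a pregnancy episode.

    Returns the record table with ``series_index`` added: 1 for the
    episode with the earliest first record, 2 for the next, and so on,
    within each person.  Every record must carry an LMP (run
    :func:`impute_temporary_ga` first).  Empty input yields empty output.
    """
    mode = mode or config.grouping_mode
    if records.empty:
        out = records.copy()
        out["series_index"] = pd.Series(dtype=int)
        return out
    if records["lmp"].isna().any():
        raise ValueError(
            "all records need an (possibly temporary) LMP before grouping; "
            "run impute_temporary_ga first"
        )
    out = records.sort_values(
        ["person_id", "service_date", "lmp", "code", "system"],
        kind="stable",
        ignore_index=True,
    )
    epoch = pd.Timestamp("2000-01-01")
    out["_svc_day"] = (out["service_date"] - epoch).dt.days.to_numpy()
    out["_lmp_day"] = (out["lmp"] - epoch).dt.days.to_numpy()
    out["_gap"] = [
        config.gap_days_for(oc if pd.notna(oc) else None)
        for oc in out["outcome_class"]
    ]
    labels = np.empty(len(out), dtype=int)
    for _, idx in out.groupby("person_id", sort=False).indices.items():
        sub = out.iloc[idx]
        labels[idx] = _group_one_person(
            sub["_svc_day"].to_numpy(),
            sub["_lmp_day"].to_numpy(),
            np.asarray(sub["_gap"]),
            mode,
        )
    out["series_index"] = labels + 1
    return out.drop(columns=["_svc_day", "_lmp_day", "_gap"])


def summarize_episodes(grouped: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """One summary row per pregnancy episode.

    Service-date extrema are taken over the outcome-bearing records when the
    episode has any (pure gestational-age records are prenatal visits, not
    end-of-pregnancy proxies), else over all records.  LMP extrema prefer
    measured (non-temporary) LMPs and fall back to temporary ones.
    ``indicators`` is the frozenset of (outcome_class, code_type) pairs
    present; ``sole_code_is_drg_lb`` marks episodes whose only records are
    DRG live-birth codes.
    """
    rows = []
    if grouped.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    for (pid, series), sub in grouped.groupby(["person_id", "series_index"], sort=True):
        has_outcome = sub["outcome_class"].notna()
        svc_basis = sub.loc[has_outcome, "service_date"] if has_outcome.any() else sub["service_date"]
        real_lmp = sub.loc[~sub["ga_is_temporary"], "lmp"]
        lmp_basis = real_lmp if not real_lmp.empty else sub["lmp"]
        indicators = frozenset(
            (oc, ct)
            for oc, ct in zip(sub["outcome_class"], sub["code_type"])
            if pd.notna(oc)
        )
        sole_drg_lb = bool(
            len(sub) > 0
            and ((sub["code_type"] == "DRG") & (sub["outcome_class"] == "LB")).all()
        )
        rows.append(
            {
                "person_id": pid,
                "series_index": int(series),
                "min_service_date": svc_basis.min(),
                "max_service_date": svc_basis.max(),
                "min_lmp": lmp_basis.min(),
                "max_lmp": lmp_basis.max(),
                "indicators": indicators,
                "sole_code_is_drg_lb": sole_drg_lb,
                "has_direct_ga": bool((sub["category"] == "direct_gestational_age").any()),
                "n_records": len(sub),
            }
        )
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def episodes_to_flat(episodes: pd.DataFrame) -> pd.DataFrame:
    """Episode table with the indicator set expanded to one 0/1 column per
    (outcome class × code type) pair, for delimited-text output."""
    flat = episodes.drop(columns=["indicators"]).copy()
    pairs = sorted({p for ind in episodes["indicators"] for p in ind})
    for oc, ct in pairs:
        flat[f"ind_{oc}_{ct}"] = [
            int((oc, ct) in ind) for ind in episodes["indicators"]
        ]
    return flat
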