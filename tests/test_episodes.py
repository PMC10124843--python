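"""Episode grouping: gap rules, temporary gestational ages, summaries.

The independent oracle is brute force: build the graph joining any two
records that violate the gap rule (evaluated with the earlier record as the
existing one) and take connected components via networkx.
"""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pregclaims.config import RunConfig
from pregclaims.episodes import (
    group_records,
    impute_temporary_ga,
    summarize_episodes,
)

from conftest import rec, records_frame

OUTCOME_POOL = ["LB", "SB", "LB_SB", "SAB", "IAB", "ECT", None]


def oracle_components(df: pd.DataFrame, config: RunConfig) -> list[frozenset]:
    """Connected components of the pairwise gap-violation graph."""
    rows = df.sort_values(["service_date", "lmp"], kind="stable").reset_index(drop=True)
    g = nx.Graph()
    g.add_nodes_from(range(len(rows)))
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            gap = config.gap_days_for(
                rows.loc[i, "outcome_class"]
                if pd.notna(rows.loc[i, "outcome_class"])
                else None
            )
            thr = rows.loc[i, "service_date"] + pd.Timedelta(days=gap)
            if not (rows.loc[j, "service_date"] >= thr and rows.loc[j, "lmp"] >= thr):
                g.add_edge(i, j)
    return [
        frozenset(rows.loc[list(comp), "code"]) for comp in nx.connected_components(g)
    ]


def grouped_codes(df: pd.DataFrame, config: RunConfig, **kw) -> list[frozenset]:
    out = group_records(df, config, **kw)
    return [frozenset(sub["code"]) for _, sub in out.groupby("series_index")]


def random_records(rng: np.random.Generator, n: int) -> pd.DataFrame:
    rows = []
    for i in range(n):
        outcome = rng.choice(OUTCOME_POOL)
        ga = int(rng.integers(1, 44))
        day = int(rng.integers(0, 900))
        rows.append(
            rec("W", day, outcome=outcome, ga=ga, code=f"r{i}",
                direct=outcome is None)
        )
    return records_frame(rows)


# --- temporary gestational age -------------------------------------------

def test_temporary_ga_live_birth_is_20_weeks(config):
    df = records_frame([rec("W", 100, outcome="LB")])
    out = impute_temporary_ga(df, config)
    assert out.loc[0, "ga_weeks"] == 20
    assert out.loc[0, "ga_is_temporary"]
    assert (out.loc[0, "service_date"] - out.loc[0, "lmp"]).days == 140


def test_temporary_ga_other_outcomes_is_6_weeks(config):
    df = records_frame([rec("W", 100, outcome="SAB", code="779", system="DRG")])
    out = impute_temporary_ga(df, config)
    assert out.loc[0, "ga_weeks"] == 6
    assert (out.loc[0, "service_date"] - out.loc[0, "lmp"]).days == 42


def test_temporary_ga_leaves_measured_ga_alone(config):
    df = records_frame([rec("W", 100, outcome="SAB", ga=12)])
    out = impute_temporary_ga(df, config)
    assert out.loc[0, "ga_weeks"] == 12 and not out.loc[0, "ga_is_temporary"]


# --- gap rule -------------------------------------------------------------

def _pair(outcome1: str, svc2: int, lmp2: int, outcome2: str = "SAB") -> pd.DataFrame:
    """Two records: the first at day 0 with the given outcome, the second at
    day ``svc2`` with LMP forced to day ``lmp2``."""
    first = rec("W", 0, outcome=outcome1, ga=20 if outcome1 == "LB" else 6, code="first")
    second = rec("W", svc2, outcome=outcome2, ga=max(1, (svc2 - lmp2) // 7), code="second")
    df = records_frame([first, second])
    df.loc[df["code"] == "second", "lmp"] = pd.Timestamp("2016-01-01") + pd.Timedelta(days=lmp2)
    return df


@pytest.mark.parametrize(
    "outcome1, svc2, lmp2, n_expected",
    [
        ("LB", 100, 60, 1),    # service 100 < 120 after a live birth: join
        ("LB", 200, 130, 2),   # both 200 and 130 clear the 120-day gap
        ("LB", 150, 100, 1),   # lmp 100 < 120 fails the conjunctive test
        ("SAB", 50, 45, 2),    # 42-day gap after a loss: 50 and 45 both clear
    ],
)
def test_gap_rule_examples(config, outcome1, svc2, lmp2, n_expected):
    assert len(grouped_codes(_pair(outcome1, svc2, lmp2), config)) == n_expected


def test_same_day_records_share_an_episode(config):
    df = records_frame(
        [rec("W", 0, outcome="LB", ga=39, code="a"),
         rec("W", 0, outcome=None, ga=39, code="b", direct=True)]
    )
    assert len(grouped_codes(df, config)) == 1


def test_grouping_requires_lmp(config):
    df = records_frame([rec("W", 0, outcome="LB")])
    with pytest.raises(ValueError, match="impute_temporary_ga"):
        group_records(df, config)


def test_empty_input_gives_empty_output(config):
    df = records_frame([])
    out = group_records(df, config)
    assert out.empty


# --- properties against the oracle ---------------------------------------

def test_sequential_grouping_matches_connected_components(config):
    rng = np.random.default_rng(20160101)
    for _ in range(200):
        df = random_records(rng, int(rng.integers(1, 13)))
        df = impute_temporary_ga(df, config)
        assert sorted(grouped_codes(df, config)) == sorted(
            oracle_components(df, config)
        )


def test_partition_every_record_in_exactly_one_episode(config):
    rng = np.random.default_rng(7)
    df = impute_temporary_ga(random_records(rng, 12), config)
    out = group_records(df, config)
    assert len(out) == len(df)
    assert set(out["code"]) == set(df["code"])
    assert out.groupby("code")["series_index"].nunique().eq(1).all()


def test_grouping_invariant_to_input_order(config):
    rng = np.random.default_rng(11)
    df = impute_temporary_ga(random_records(rng, 10), config)
    base = sorted(grouped_codes(df, config))
    for seed in range(5):
        shuffled = df.sample(frac=1, random_state=seed).reset_index(drop=True)
        assert sorted(grouped_codes(shuffled, config)) == base


def test_wider_gaps_never_increase_episode_count(config):
    rng = np.random.default_rng(23)
    wide = RunConfig(gap_live_birth_days=240, gap_other_days=84)
    for _ in range(100):
        df = impute_temporary_ga(random_records(rng, int(rng.integers(1, 9))), config)
        assert len(grouped_codes(df, wide)) <= len(grouped_codes(df, config))


record_tuples = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=900),          # service day
        st.integers(min_value=1, max_value=43),           # gestational age
        st.sampled_from(OUTCOME_POOL),                    # outcome class
    ),
    min_size=1,
    max_size=10,
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(record_tuples)
def test_grouping_properties_hold_for_arbitrary_records(tuples):
    """Partition, oracle equivalence, and shuffle invariance hold for any
    physiologically representable record set."""
    config = RunConfig()
    rows = [
        rec("W", day, outcome=outcome, ga=ga, code=f"r{i}", direct=outcome is None)
        for i, (day, ga, outcome) in enumerate(tuples)
    ]
    df = impute_temporary_ga(records_frame(rows), config)
    groups = grouped_codes(df, config)
    # partition
    assert sorted(c for g in groups for c in g) == sorted(df["code"])
    # equality with the brute-force connected-components oracle
    assert sorted(groups) == sorted(oracle_components(df, config))
    # input-order invariance
    shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
    assert sorted(grouped_codes(shuffled, config)) == sorted(groups)


def test_series_index_increases_with_time(config):
    df = records_frame(
        [rec("W", 500, outcome="SAB", ga=8, code="late"),
         rec("W", 0, outcome="LB", ga=39, code="early")]
    )
    out = group_records(df, config)
    first = out[out["series_index"] == 1]
    assert set(first["code"]) == {"early"}


# --- episode summaries ----------------------------------------------------

def test_summary_indicators_and_extrema(config):
    df = records_frame(
        [
            rec("W", 10, outcome="LB", ga=39, code="lbdx"),
            rec("W", 10, outcome=None, ga=39, code="Z3A.39", direct=True),
        ]
    )
    out = summarize_episodes(group_records(df, config), config)
    assert len(out) == 1
    ep = out.iloc[0]
    assert ep["indicators"] == frozenset({("LB", "DX")})
    assert ep["min_service_date"] == ep["max_service_date"]
    assert ep["has_direct_ga"]


def test_summary_multiple_indicator_pairs(config):
    df = impute_temporary_ga(
        records_frame(
            [
                rec("W", 0, outcome="SAB", code="sabdx"),
                rec("W", 0, outcome="IAB", code="770", system="DRG"),
            ]
        ),
        config,
    )
    out = summarize_episodes(group_records(df, config), config)
    assert out.iloc[0]["indicators"] == frozenset({("SAB", "DX"), ("IAB", "DRG")})


def test_sole_drg_live_birth_flag(config):
    solo = impute_temporary_ga(
        records_frame([rec("W", 0, outcome="LB", code="775", system="DRG")]), config
    )
    out = summarize_episodes(group_records(solo, config), config)
    assert out.iloc[0]["sole_code_is_drg_lb"]

    mixed = impute_temporary_ga(
        records_frame(
            [rec("W", 0, outcome="LB", code="775", system="DRG"),
             rec("W", 0, outcome="SAB", code="sabdx")]
        ),
        config,
    )
    out = summarize_episodes(group_records(mixed, config), config)
    assert not out.iloc[0]["sole_code_is_drg_lb"]


def test_outcome_records_define_service_extrema(config):
    df = records_frame(
        [
            rec("W", 200, outcome="LB", ga=39, code="lbdx"),
            rec("W", 60, outcome=None, ga=19, code="Z3A.19", direct=True),
        ]
    )
    out = summarize_episodes(group_records(df, config), config)
    ep = out.iloc[0]
    assert ep["min_service_date"] == ep["max_service_date"]  # the outcome record
    assert ep["n_records"] == 2
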