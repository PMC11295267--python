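"""Episode-of-care construction: chaining rule, partitioning, oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import frame
from episode_oracle import maximal_partitions
from sihvalid.episodes import build_episodes, chain_predicate, episode_summary


def _rec(**kw):
    base = dict(billing_reason="2", discharge_date="2021-11-12",
                admission_date="2021-11-10")
    base.update(kw)
    for k in ("admission_date", "discharge_date"):
        base[k] = pd.Timestamp(base[k])
    return base


@pytest.mark.parametrize("prev,nxt,expected", [
    (_rec(billing_reason="2"), _rec(admission_date="2021-11-12"), True),   # gap 0
    (_rec(billing_reason="2"), _rec(admission_date="2021-11-13"), True),   # gap 1
    (_rec(billing_reason="2"), _rec(admission_date="2021-11-14"), False),  # gap 2
    (_rec(billing_reason="1"), _rec(admission_date="2021-11-12"), False),  # routine
    (_rec(billing_reason="2"), _rec(admission_date="2021-11-11"), False),  # overlap
])
def test_chain_predicate(prev, nxt, expected):
    assert chain_predicate(prev, nxt) is expected


def test_continuing_stay_chains_same_person(rb):
    df = frame(rb, [
        dict(aih_number="A", billing_reason="2", admission_date="2021-11-10",
             discharge_date="2021-11-12"),
        dict(aih_number="B", billing_reason="1", admission_date="2021-11-13",
             discharge_date="2021-11-15"),
    ])
    build = build_episodes(df)
    assert len(build.episodes) == 1
    ep = build.episodes.iloc[0]
    assert ep.n_aihs == 2 and ep.first_aih == "A" and ep.last_aih == "B"
    assert ep.admission_date == pd.Timestamp("2021-11-10")
    assert ep.discharge_date == pd.Timestamp("2021-11-15")
    assert not ep.unresolved_continuation


def test_different_facility_never_chains(rb):
    df = frame(rb, [
        dict(aih_number="A", billing_reason="2", discharge_date="2021-11-12"),
        dict(aih_number="B", cnes="2000000", admission_date="2021-11-12"),
    ])
    assert len(build_episodes(df).episodes) == 2


def test_transitive_chain_of_three(rb):
    df = frame(rb, [
        dict(aih_number="A", billing_reason="2", admission_date="2021-11-01",
             discharge_date="2021-11-03"),
        dict(aih_number="B", billing_reason="2", admission_date="2021-11-03",
             discharge_date="2021-11-06"),
        dict(aih_number="C", billing_reason="1", admission_date="2021-11-07",
             discharge_date="2021-11-08"),
    ])
    build = build_episodes(df)
    assert len(build.episodes) == 1 and build.episodes.iloc[0].n_aihs == 3
    assert episode_summary(build)["multi_aih_episodes"] == 1


def test_unresolved_continuation_flagged(rb):
    df = frame(rb, [dict(aih_number="A", billing_reason="2")])
    build = build_episodes(df)
    assert build.episodes.iloc[0].unresolved_continuation


def test_same_day_admissions_without_token_stay_separate(rb):
    df = frame(rb, [
        dict(aih_number="A", billing_reason="1"),
        dict(aih_number="B", billing_reason="1"),
    ])
    assert len(build_episodes(df).episodes) == 2


def test_ambiguous_successor_takes_earliest_then_smallest_aih(rb):
    df = frame(rb, [
        dict(aih_number="P", billing_reason="2", admission_date="2021-11-01",
             discharge_date="2021-11-02"),
        dict(aih_number="S2", billing_reason="1", admission_date="2021-11-03"),
        dict(aih_number="S1", billing_reason="1", admission_date="2021-11-02"),
    ])
    build = build_episodes(df)
    chains = {tuple(g.sort_values("position")["aih_number"])
              for _, g in build.crosswalk.groupby("episode_id")}
    assert chains == {("P", "S1"), ("S2",)}


def test_partition_and_order_invariance(rb, default_noise_run):
    sim, result = default_noise_run
    build = result.build
    # partition: every AIH in exactly one episode
    assert build.crosswalk["aih_number"].is_unique
    assert build.episodes["n_aihs"].sum() == len(result.records)
    # order invariance: shuffle input rows, same chains
    shuffled = result.records.sample(frac=1.0, random_state=3).reset_index(drop=True)
    build2 = build_episodes(shuffled)
    chains1 = {tuple(g.sort_values("position")["aih_number"])
               for _, g in build.crosswalk.groupby("episode_id")}
    chains2 = {tuple(g.sort_values("position")["aih_number"])
               for _, g in build2.crosswalk.groupby("episode_id")}
    assert chains1 == chains2


def test_without_continuing_token_all_singletons(rb, default_noise_run):
    _, result = default_noise_run
    records = result.records.copy()
    records["billing_reason"] = records["billing_reason"].replace("2", "1")
    build = build_episodes(records)
    assert (build.episodes["n_aihs"] == 1).all()


@st.composite
def person_group(draw):
    """Up to 6 AIHs for one person key with adversarial dates/reasons."""
    n = draw(st.integers(1, 6))
    rows = []
    for i in range(n):
        adm = draw(st.integers(0, 8))
        los = draw(st.integers(0, 3))
        rows.append(dict(
            aih_number=f"{i:03d}",
            billing_reason=draw(st.sampled_from(["1", "2", "2", "3"])),
            admission_date=pd.Timestamp("2021-11-01") + pd.Timedelta(days=adm),
            discharge_date=pd.Timestamp("2021-11-01") + pd.Timedelta(days=adm + los),
        ))
    return rows


@settings(max_examples=150, deadline=None, derandomize=True)
@given(person_group())
def test_builder_matches_brute_force_oracle(rows):
    """Chains equal a maximal partition found by exhaustive enumeration."""
    rb = __import__("sihvalid").load_rulebook()
    df = frame(rb, rows)
    build = build_episodes(df)
    got = tuple(sorted(
        tuple(g.sort_values("position")["aih_number"])
        for _, g in build.crosswalk.groupby("episode_id")
    ))
    maximal = maximal_partitions([dict(aih_number=r["aih_number"],
                                       billing_reason=r["billing_reason"],
                                       admission_date=r["admission_date"],
                                       discharge_date=r["discharge_date"])
                                  for r in rows])
    assert got in maximal
    if len(maximal) == 1:
        assert got == next(iter(maximal))
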