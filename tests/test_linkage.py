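"""Multi-pass deterministic linkage: pass structure, ties, one-to-one."""

import numpy as np
import pandas as pd
import pytest

from sihvalid.linkage import (
    DEFAULT_PASSES,
    LINK_KEYS,
    deterministic_link,
    link_report,
)


def _side(idcol, rows):
    df = pd.DataFrame(rows)
    for c in ("dob", "admission_date", "discharge_date"):
        df[c] = pd.to_datetime(df[c])
    df[idcol] = [f"{idcol[0]}{i}" for i in range(len(rows))]
    return df


def _row(**kw):
    base = dict(cnes="1000000", dob="1990-05-01", admission_date="2021-11-10",
                discharge_date="2021-11-12", race_color="1", postcode="12345678")
    base.update(kw)
    return base


def test_identical_keys_match_in_pass_one():
    res = deterministic_link(_side("episode_id", [_row()]),
                             _side("reference_id", [_row()]))
    assert res.pairs["pass_number"].tolist() == [1]
    assert res.ambiguity_count == 0


@pytest.mark.parametrize("claims_kw,expected_pass", [
    (dict(postcode=""), 2),                      # missing postcode -> drop it
    (dict(postcode="99999999"), 2),              # differing postcode
    (dict(postcode="", race_color="5"), 3),      # race differs too
    (dict(postcode="", race_color="5",
          discharge_date="2021-11-13"), 4),      # discharge off by one day
])
def test_relaxation_passes(claims_kw, expected_pass):
    res = deterministic_link(_side("episode_id", [_row(**claims_kw)]),
                             _side("reference_id", [_row()]))
    assert res.pairs["pass_number"].tolist() == [expected_pass]


def test_discharge_two_days_off_never_matches():
    res = deterministic_link(
        _side("episode_id", [_row(postcode="", discharge_date="2021-11-14")]),
        _side("reference_id", [_row()]))
    assert res.pairs.empty


def test_ambiguous_block_left_unmatched():
    res = deterministic_link(_side("episode_id", [_row(), _row()]),
                             _side("reference_id", [_row()]))
    assert res.pairs.empty
    assert res.ambiguity_count >= 1
    assert len(res.unmatched_episodes) == 2 and len(res.unmatched_reference) == 1


def test_duplicate_reference_ids_error():
    ref = _side("reference_id", [_row(), _row(cnes="2000000")])
    ref["reference_id"] = ["R0", "R0"]
    with pytest.raises(ValueError, match="reference_id"):
        deterministic_link(_side("episode_id", [_row()]), ref)


def test_empty_reference_zero_pairs():
    empty = _side("reference_id", [_row()]).iloc[0:0]
    res = deterministic_link(_side("episode_id", [_row()]), empty)
    assert res.pairs.empty


def test_matches_agree_on_pass_keys_brute_force():
    """Every emitted pair must agree on its pass's keys (all-pairs check)."""
    rng = np.random.default_rng(5)
    rows = []
    for i in range(60):
        rows.append(_row(
            cnes=f"{1000000 + rng.integers(3)}",
            dob=(pd.Timestamp("1990-01-01")
                 + pd.Timedelta(days=int(rng.integers(40)))).date().isoformat(),
            admission_date=(pd.Timestamp("2021-11-01")
                            + pd.Timedelta(days=int(rng.integers(10)))).date().isoformat(),
            postcode=f"{rng.integers(3):08d}",
            race_color=str(rng.integers(1, 4)),
        ))
    left = _side("episode_id", rows)
    right = _side("reference_id", rows)
    res = deterministic_link(left, right)
    li = left.set_index("episode_id")
    ri = right.set_index("reference_id")
    for _, p in res.pairs.iterrows():
        spec = DEFAULT_PASSES[p.pass_number - 1]
        for k in spec.keys:
            lv, rv = li.loc[p.episode_id, k], ri.loc[p.reference_id, k]
            if k == "discharge_date" and spec.discharge_tolerance_days:
                assert abs((lv - rv).days) <= spec.discharge_tolerance_days
            else:
                assert lv == rv, (k, p.pass_number)
    assert res.pairs["episode_id"].is_unique
    assert res.pairs["reference_id"].is_unique


def test_pass_monotonicity():
    """Adding looser passes never reduces the number of matches."""
    claims = _side("episode_id", [_row(), _row(dob="1991-01-01", postcode="")])
    ref = _side("reference_id", [_row(), _row(dob="1991-01-01")])
    n = []
    for k in range(1, len(DEFAULT_PASSES) + 1):
        n.append(len(deterministic_link(claims, ref, DEFAULT_PASSES[:k]).pairs))
    assert n == sorted(n)


def test_corruption_lowers_match_rate_but_stays_one_to_one(zero_noise_run):
    sim, result = zero_noise_run
    claims = result.obstetric[["episode_id", *LINK_KEYS]]
    corrupted = claims.copy()
    rng = np.random.default_rng(0)
    hit = rng.random(len(corrupted)) < 0.10
    corrupted.loc[hit, "dob"] += pd.Timedelta(days=500)
    res = deterministic_link(corrupted, result.reference)
    rep = link_report(res, len(corrupted), len(result.reference))
    assert rep["match_rate_reference_pct"] < 100.0
    assert res.pairs["episode_id"].is_unique and res.pairs["reference_id"].is_unique


def test_clean_synthetic_link_recovers_ground_truth(zero_noise_run):
    sim, result = zero_noise_run
    assert len(result.link.pairs) == len(sim.reference)
    xw = result.build.crosswalk.merge(sim.truth.pairing, on="aih_number")
    truth = xw.drop_duplicates(["episode_id", "reference_id"])
    merged = result.link.pairs.merge(truth, on="episode_id",
                                     suffixes=("", "_truth"))
    assert (merged["reference_id"] == merged["reference_id_truth"]).all()
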