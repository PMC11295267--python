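"""Obstetric detection, reason/discharge classification, morbidity flags."""

import pandas as pd
import pytest

from conftest import frame
from sihvalid.classify import (
    classify_discharge,
    classify_episodes,
    classify_reason,
    flag_criteria,
    is_obstetric,
)
from sihvalid.episodes import build_episodes
from sihvalid.ingest import ActsJoin
from sihvalid.rulebook import CRITERION_NAMES, RuleBookError


def _acts(mapping):
    return ActsJoin({k: frozenset(v) for k, v in mapping.items()}, 0, ())


def test_obstetric_any_field_any_position(rb):
    df = frame(rb, [
        dict(aih_number="A", billing_reason="2", discharge_date="2021-11-11"),
        dict(aih_number="B", admission_date="2021-11-11", diag_secondary="O721"),
    ])
    assert is_obstetric(df, rb)


def test_non_obstetric_stay(rb):
    df = frame(rb, [dict(diag_primary="J128", primary_procedure="0301010010")])
    assert not is_obstetric(df, rb)


def test_obstetric_by_procedure_without_o_code(rb):
    df = frame(rb, [dict(primary_procedure="0310010012")])
    assert is_obstetric(df, rb)


@pytest.mark.parametrize("primary,proc,expected", [
    ("O800", None, "delivery"),
    ("O800", "0303100036", "delivery"),
    ("O039", "0310010012", "abortion"),       # abortion ICD beats delivery proc
    ("O141", "0310010012", "delivery"),       # delivery proc beats complication ICD
    ("O141", "0303100036", "pregnancy_complication"),
    ("O219", None, "pregnancy_complication"),
    ("O861", None, "puerperium_complication"),
    (None, "0303100010", "puerperium_complication"),
    ("J128", None, "pregnancy_complication"),  # catch-all: other-group ICD
    ("O759", None, "delivery"),                # O75 prefix
    (None, "0301010010", "other"),
    (None, None, "missing"),
])
def test_classify_reason(rb, primary, proc, expected):
    df = frame(rb, [dict(diag_primary=primary, primary_procedure=proc)])
    assert classify_reason(df, rb) == expected


def test_reason_uses_first_aih_only(rb):
    df = frame(rb, [
        dict(aih_number="A", billing_reason="2", discharge_date="2021-11-11",
             diag_primary="O219"),
        dict(aih_number="B", admission_date="2021-11-11", diag_primary="O800",
             primary_procedure="0310010012"),
    ])
    assert classify_reason(df, rb) == "pregnancy_complication"


@pytest.mark.parametrize("token,expected", [
    ("6.3", "routine"), ("1", "routine"), ("5", "administrative"),
    ("2", "continuing_stay"), ("6.6", "death"), ("4", "death"),
    ("3", "transfer"), ("", "blank"),
])
def test_classify_discharge(rb, token, expected):
    assert classify_discharge(token, rb) == expected


def test_classify_discharge_unknown_token_errors(rb):
    with pytest.raises(RuleBookError, match="7"):
        classify_discharge("7", rb)


def test_flag_by_icd_and_icu_days(rb):
    df = frame(rb, [dict(diag_sec_3="O141", icu_days=3)])
    flags, sources = flag_criteria(df, None, rb)
    assert flags["severe_preeclampsia"] and sources["severe_preeclampsia"] == {"ICD"}
    assert flags["icu"] and sources["icu"] == {"ICU_DAYS"}
    assert not flags["hellp_syndrome"]


def test_hellp_and_severe_preeclampsia_are_distinct(rb):
    df = frame(rb, [dict(diag_secondary="O142")])
    flags, _ = flag_criteria(df, None, rb)
    assert flags["hellp_syndrome"] and not flags["severe_preeclampsia"]


def test_transfusion_counted_once_across_aihs(rb):
    df = frame(rb, [
        dict(aih_number="A", billing_reason="2", discharge_date="2021-11-11"),
        dict(aih_number="B", admission_date="2021-11-11"),
    ])
    acts = _acts({"A": {"0306020068"}, "B": {"0306020076"}})
    build = build_episodes(df)
    assert len(build.episodes) == 1
    classified = classify_episodes(df, build, acts, rb)
    row = classified.iloc[0]
    assert row["flag_transfusion"] and row["ev_transfusion_PROF_ACT"]
    assert int(classified["flag_transfusion"].sum()) == 1


def test_flag_monotonicity_under_added_aih(rb):
    base = [dict(aih_number="A", billing_reason="2", discharge_date="2021-11-11",
                 diag_sec_1="O450")]
    extra = base + [dict(aih_number="B", admission_date="2021-11-11",
                         diag_sec_2="O710")]
    f1, _ = flag_criteria(frame(rb, base), None, rb)
    f2, _ = flag_criteria(frame(rb, extra), None, rb)
    assert all(f2[c] or not f1[c] for c in CRITERION_NAMES)
    assert f2["uterine_rupture"] and not f1["uterine_rupture"]


def test_total_flag_is_union_of_channels(rb, default_noise_run):
    _, result = default_noise_run
    cls = result.classified
    for crit in CRITERION_NAMES:
        chans = [c for c in cls.columns if c.startswith(f"ev_{crit}_")]
        assert chans, crit
        assert (cls[f"flag_{crit}"] == cls[chans].any(axis=1)).all()


def test_reason_only_for_obstetric_episodes(rb, default_noise_run):
    _, result = default_noise_run
    cls = result.classified
    assert cls.loc[~cls["is_obstetric"], "reason"].isna().all()
    assert cls.loc[cls["is_obstetric"], "reason"].notna().all()
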