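"""Coverage, confusion, likelihood ratios, bands, report assembly."""

import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sihvalid.metrics import (
    ConfusionTable,
    confusion,
    coverage,
    format_lr,
    interpret,
    lr_from_rates,
    missingness_exclusion,
    round_half_away,
    validity,
)


@pytest.mark.parametrize("n_index,n_ref,pct,adequate,over", [
    (32212, 33867, 95.1, True, False),
    (22176, 22125, 100.2, True, False),
    (10036, 11742, 85.5, False, False),
    (111, 100, 111.0, True, True),
    (90, 100, 90.0, True, False),
])
def test_coverage_worked_examples(n_index, n_ref, pct, adequate, over):
    c = coverage(n_index, n_ref)
    assert c.pct == pct
    assert c.adequate is adequate and c.over_recording is over


def test_coverage_zero_reference_errors():
    with pytest.raises(ValueError, match="reference"):
        coverage(10, 0)


def test_round_half_away_from_zero():
    assert round_half_away(0.05, 1) == 0.1   # banker's rounding would give 0.0
    assert round_half_away(85.45, 1) == 85.5
    assert round_half_away(-0.05, 1) == -0.1
    assert round_half_away(0.635, 2) == 0.64


def test_confusion_counts():
    ct = confusion([1, 1, 0, 0], [1, 0, 0, 1])
    assert (ct.tp, ct.fn, ct.fp, ct.tn) == (1, 1, 1, 1)
    ct = confusion([1, 0, 1], [1, 0, 1])
    assert ct.fp == ct.fn == 0
    ct = confusion([1, 0, 1], [0, 0, 0])
    assert ct.tp == 0
    with pytest.raises(ValueError):
        confusion([1, 0], [1])


@pytest.mark.parametrize("sens,spec,lr_neg,lr_pos", [
    (0.380, 0.974, 0.64, None),   # severe pre-eclampsia, all hospitals
    (0.337, 0.964, None, 9.4),    # severe pre-eclampsia, private
    (0.504, 0.975, 0.51, None),   # blood-product transfusion, all
    (0.202, 0.985, 0.81, None),   # eclampsia, public
])
def test_likelihood_ratios_from_printed_rates(sens, spec, lr_neg, lr_pos):
    lp, ln = lr_from_rates(sens, spec)
    if lr_neg is not None:
        assert round_half_away(ln, 2) == lr_neg
    if lr_pos is not None:
        assert round_half_away(lp, 1) == lr_pos


def test_validity_sentinels_and_errors():
    v = validity(ConfusionTable(tp=15, fp=0, fn=25, tn=1000))
    assert math.isinf(v.lr_pos) and format_lr(v.lr_pos) == "-"
    v = validity(ConfusionTable(tp=5, fp=10, fn=5, tn=0))
    assert math.isnan(v.lr_neg) and format_lr(v.lr_neg, "neg") == "-"
    with pytest.raises(ValueError, match="positives"):
        validity(ConfusionTable(tp=0, fp=1, fn=0, tn=1))
    with pytest.raises(ValueError, match="negatives"):
        validity(ConfusionTable(tp=1, fp=0, fn=1, tn=0))


@pytest.mark.parametrize("lr_pos,band", [
    (17.0, "strong"), (10.0, "strong"), (9.9, "moderate"), (5.0, "moderate"),
    (4.9, "weak"), (2.0, "weak"), (1.9, "very weak"), (1.0, "very weak"),
    (0.5, "unclassified"), (math.inf, "strong"),
])
def test_positive_bands(lr_pos, band):
    assert interpret(lr_pos, 0.5)[0] == band


@pytest.mark.parametrize("lr_neg,band", [
    (0.07, "strong"), (0.099, "strong"), (0.1, "moderate"), (0.20, "moderate"),
    (0.21, "weak"), (0.50, "weak"), (0.51, "very weak"), (1.0, "very weak"),
    (1.2, "unclassified"),
])
def test_negative_bands(lr_neg, band):
    assert interpret(5.0, lr_neg)[1] == band


@given(st.integers(1, 200), st.integers(1, 200), st.integers(0, 200),
       st.integers(1, 200))
def test_lr_identities(tp, fn, fp, tn):
    v = validity(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
    assert 0.0 <= v.sens <= 1.0 and 0.0 <= v.spec <= 1.0
    # LR+ >= 1 exactly when sens >= 1 - spec
    if not math.isinf(v.lr_pos):
        assert (v.lr_pos >= 1) == (v.sens >= 1 - v.spec)
    # monotonicity: one more true positive never lowers either figure of merit
    v2 = validity(ConfusionTable(tp=tp + 1, fp=fp, fn=fn, tn=tn))
    assert v2.sens > v.sens
    if not math.isinf(v.lr_pos):
        assert v2.lr_pos > v.lr_pos
    assert math.isnan(v.lr_neg) or v2.lr_neg < v.lr_neg


def test_missingness_exclusion_threshold():
    ref = pd.DataFrame({
        "cnes": ["A"] * 100 + ["B"] * 100 + ["C"] * 10,
        "reason_missing": [True] * 11 + [False] * 89   # A: 11%
                         + [True] * 10 + [False] * 90  # B: exactly 10%
                         + [False] * 10,               # C: 0%
    })
    kept = missingness_exclusion(ref)
    assert set(kept["cnes"]) == {"B", "C"}


def test_stratified_report_shapes(default_noise_run):
    _, result = default_noise_run
    r = result.reports
    assert set(r.coverage["stratum"]) == {"public", "private", "total"}
    assert len(r.per_hospital_coverage) == 9
    assert r.validity_table.groupby("stratum").size().nunique() == 1
    # channel consistency: TOTAL >= each single channel count
    vt = r.validity_table
    assert (vt["n_total"] >= vt[["n_icd", "n_proc_rea", "n_prof_act"]].max(axis=1)).all()
    # claims-side counts are computed on the linked morbidity denominator
    assert (vt["n_total"] <= vt["n_linked"]).all()
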