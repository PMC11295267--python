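"""Coverage, diagnostic validity and stratified report tables.

Coverage is the claims-side obstetric hospitalization count as a percentage
of the reference-standard count (>= 90% adequate; > 110% flags
over-recording).  Validity of each severe-morbidity criterion is judged on
the deterministically linked subset of reference stays *with* morbidity:

* sensitivity  = tp / (tp + fn)
* specificity  = tn / (fp + tn)
* LR+          = sens / (1 - spec)   (how much a recorded code raises the odds)
* LR-          = (1 - sens) / spec   (how much an absent code lowers them)

Interpretation bands: LR+ >= 10 strong, 5-9.9 moderate, 2-4.9 weak, 1-2 very
weak; LR- < 0.1 strong, 0.1-0.20 moderate, 0.21-0.50 weak, 0.51-1 very weak.
Bands are assigned on the LR as computed (before rounding it for display);
the boundary values 0.205 / 0.505 close the printed gaps between bands.
Percentages are rounded half away from zero to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "round_half_away",
    "CoverageResult",
    "ConfusionTable",
    "ValidityResult",
    "coverage",
    "confusion",
    "validity",
    "lr_from_rates",
    "interpret",
    "format_lr",
    "missingness_exclusion",
    "stratified_report",
    "ReportBundle",
]

STRATA = ("public", "private", "total")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (matches the printed tables, unlike
    banker's rounding)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    if isinstance(x, float) and math.isinf(x):
        return x
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CoverageResult:
    stratum: str
    n_index: int
    n_ref: int
    pct: float
    adequate: bool
    over_recording: bool


def coverage(
    n_index: int,
    n_ref: int,
    stratum: str = "total",
    adequacy_threshold: float = 90.0,
    over_threshold: float = 110.0,
) -> CoverageResult:
    """Record-coverage ratio, to one decimal; may exceed 100."""
    if n_ref <= 0:
        raise ValueError("coverage undefined: reference count is zero")
    pct = round_half_away(100.0 * n_index / n_ref, 1)
    return CoverageResult(
        stratum=stratum,
        n_index=int(n_index),
        n_ref=int(n_ref),
        pct=pct,
        adequate=pct >= adequacy_threshold,
        over_recording=pct > over_threshold,
    )


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(ref_flags, index_flags) -> ConfusionTable:
    """2x2 table of reference truth vs claims flag over aligned pairs."""
    ref = np.asarray(ref_flags, dtype=bool)
    idx = np.asarray(index_flags, dtype=bool)
    if ref.shape != idx.shape:
        raise ValueError("flag vectors must have equal length")
    return ConfusionTable(
        tp=int((ref & idx).sum()),
        fp=int((~ref & idx).sum()),
        fn=int((ref & ~idx).sum()),
        tn=int((~ref & ~idx).sum()),
    )


def lr_from_rates(sens: float, spec: float) -> tuple[float, float]:
    """(LR+, LR-) from sensitivity and specificity as proportions.

    LR+ is ``inf`` when specificity is 1 (no false positives, rendered "-");
    LR- is ``nan`` when specificity is 0.
    """
    lr_pos = math.inf if spec >= 1.0 else sens / (1.0 - spec)
    lr_neg = math.nan if spec <= 0.0 else (1.0 - sens) / spec
    return lr_pos, lr_neg


_POS_BANDS = ((10.0, "strong"), (5.0, "moderate"), (2.0, "weak"), (1.0, "very weak"))
_NEG_BANDS = ((0.1, "strong"), (0.205, "moderate"), (0.505, "weak"), (1.0 + 1e-12, "very weak"))


def interpret(lr_pos: float, lr_neg: float) -> tuple[str, str]:
    """Interpretation band labels for a (LR+, LR-) pair."""
    if math.isinf(lr_pos):
        band_pos = "strong"
    elif math.isnan(lr_pos):
        band_pos = "undefined"
    else:
        band_pos = "unclassified"
        for lo, label in _POS_BANDS:
            if lr_pos >= lo:
                band_pos = label
                break
    if math.isnan(lr_neg):
        band_neg = "undefined"
    else:
        band_neg = "unclassified"
        for hi, label in _NEG_BANDS:
            if lr_neg < hi:
                band_neg = label
                break
    return band_pos, band_neg


@dataclass(frozen=True)
class ValidityResult:
    criterion: str
    stratum: str
    table: ConfusionTable
    sens: float  # proportion
    spec: float
    lr_pos: float  # inf sentinel when spec == 1
    lr_neg: float  # nan sentinel when spec == 0
    band_pos: str
    band_neg: str

    @property
    def sens_pct(self) -> float:
        return round_half_away(100.0 * self.sens, 1)

    @property
    def spec_pct(self) -> float:
        return round_half_away(100.0 * self.spec, 1)


def validity(ct: ConfusionTable, criterion: str = "", stratum: str = "total") -> ValidityResult:
    """Sensitivity, specificity, likelihood ratios and bands from a 2x2 table."""
    if ct.tp + ct.fn == 0:
        raise ValueError("validity undefined: no reference positives")
    if ct.fp + ct.tn == 0:
        raise ValueError("validity undefined: no reference negatives")
    sens = ct.tp / (ct.tp + ct.fn)
    spec = ct.tn / (ct.fp + ct.tn)
    lr_pos, lr_neg = lr_from_rates(sens, spec)
    band_pos, band_neg = interpret(lr_pos, lr_neg)
    return ValidityResult(criterion, stratum, ct, sens, spec, lr_pos, lr_neg,
                          band_pos, band_neg)


def format_lr(value: float, kind: str = "pos") -> str:
    """Render an LR the way the report tables print it: "-" for the infinite /
    undefined sentinels, one decimal for LR+ (with thousands separator), two
    decimals for LR- below 1 and one at or above 1."""
    if value is None or math.isinf(value) or math.isnan(value):
        return "-"
    if kind == "pos":
        return f"{round_half_away(value, 1):,.1f}"
    v = round_half_away(value, 2)
    return f"{v:.1f}" if v >= 1 else f"{v:.2f}"


def missingness_exclusion(
    reference: pd.DataFrame, threshold_pct: float = 10.0,
    hospital_col: str = "cnes", missing_col: str = "reason_missing",
) -> pd.DataFrame:
    """Drop hospitals whose share of stays without a recorded reason exceeds
    the threshold (strictly greater); used for the reason-comparison only."""
    share = reference.groupby(hospital_col)[missing_col].mean() * 100.0
    kept = share[share <= threshold_pct].index
    return reference[reference[hospital_col].isin(kept)].copy()


# ---------------------------------------------------------------------------
# stratified reporting

@dataclass
class ReportBundle:
    coverage: pd.DataFrame          # stratum-level coverage
    per_hospital_coverage: pd.DataFrame
    reason_table: pd.DataFrame      # reason distribution, reference vs claims
    discharge_table: pd.DataFrame   # discharge distribution, reference vs claims
    validity_table: pd.DataFrame    # per criterion x stratum


def _strata_masks(hospital_type: pd.Series) -> dict[str, pd.Series]:
    return {
        "public": hospital_type == "public",
        "private": hospital_type == "private",
        "total": pd.Series(True, index=hospital_type.index),
    }


def _distribution(series: pd.Series, categories: tuple[str, ...]) -> pd.Series:
    n = len(series)
    out = {}
    for cat in categories:
        out[cat] = round_half_away(100.0 * (series == cat).sum() / n, 1) if n else float("nan")
    return pd.Series(out)


def stratified_report(
    classified: pd.DataFrame,
    reference: pd.DataFrame,
    pairs: pd.DataFrame,
    criteria: tuple[str, ...],
    reason_categories: tuple[str, ...] = (
        "delivery", "abortion", "pregnancy_complication",
        "puerperium_complication", "other", "missing"),
    discharge_categories: tuple[str, ...] = (
        "routine", "administrative", "continuing_stay", "death",
        "transfer", "blank"),
    missingness_threshold_pct: float = 10.0,
) -> ReportBundle:
    """Build the three report tables for all hospitals together and for public
    and private hospitals separately.

    ``classified`` holds obstetric claims episodes (with flags and reason),
    ``reference`` the census stays (with ``hospital_type``, ``reason``,
    ``reason_missing``, ``discharge`` and ``flag_*``), ``pairs`` the linked
    episode/reference id pairs.  Validity is computed on linked reference
    stays with at least one morbidity flag.
    """
    hosp_type = reference.drop_duplicates("cnes").set_index("cnes")["hospital_type"]
    classified = classified.copy()
    classified["hospital_type"] = classified["cnes"].map(hosp_type)

    # --- coverage -----------------------------------------------------------
    cov_rows = []
    for stratum, mask in _strata_masks(reference["hospital_type"]).items():
        n_ref = int(mask.sum())
        cmask = _strata_masks(classified["hospital_type"])[stratum]
        n_index = int(cmask.sum())
        if n_ref:
            c = coverage(n_index, n_ref, stratum)
            cov_rows.append(vars(c) | {"stratum": stratum})
    cov = pd.DataFrame(cov_rows)

    per_hosp = []
    ref_by_hosp = reference.groupby("cnes").size()
    idx_by_hosp = classified.groupby("cnes").size()
    for cnes, n_ref in ref_by_hosp.items():
        c = coverage(int(idx_by_hosp.get(cnes, 0)), int(n_ref), "hospital")
        per_hosp.append({
            "cnes": cnes, "hospital_type": hosp_type[cnes],
            "n_index": c.n_index, "n_ref": c.n_ref, "pct": c.pct,
            "adequate": c.adequate, "over_recording": c.over_recording,
        })
    per_hosp = pd.DataFrame(per_hosp)

    # --- reason / discharge distributions -----------------------------------
    ref_reason = missingness_exclusion(reference, missingness_threshold_pct)
    kept_hosps = set(ref_reason["cnes"])
    cls_reason = classified[classified["cnes"].isin(kept_hosps)]
    reason_rows, discharge_rows = [], []
    for stratum in STRATA:
        rmask = _strata_masks(ref_reason["hospital_type"])[stratum]
        cmask = _strata_masks(cls_reason["hospital_type"])[stratum]
        reason_rows.append(
            _distribution(ref_reason.loc[rmask, "reason"], reason_categories)
            .rename(("reference", stratum)))
        reason_rows.append(
            _distribution(cls_reason.loc[cmask, "reason"], reason_categories)
            .rename(("claims", stratum)))
        rall = _strata_masks(reference["hospital_type"])[stratum]
        call = _strata_masks(classified["hospital_type"])[stratum]
        discharge_rows.append(
            _distribution(reference.loc[rall, "discharge"], discharge_categories)
            .rename(("reference", stratum)))
        discharge_rows.append(
            _distribution(classified.loc[call, "discharge"], discharge_categories)
            .rename(("claims", stratum)))
    reason_table = pd.DataFrame(reason_rows)
    discharge_table = pd.DataFrame(discharge_rows)

    # --- validity on the linked morbidity subset ----------------------------
    flag_cols = [f"flag_{c}" for c in criteria]
    morbid = reference[reference[flag_cols].any(axis=1)]
    linked = pairs.merge(
        morbid, left_on="reference_id", right_on="reference_id", how="inner"
    ).merge(
        classified, on="episode_id", how="inner", suffixes=("_ref", "_idx")
    )
    rows = []
    for stratum, mask in _strata_masks(linked["hospital_type_ref"]).items():
        sub = linked[mask]
        denom = len(sub)
        for crit in criteria:
            ref_flag = sub[f"flag_{crit}_ref"]
            idx_flag = sub[f"flag_{crit}_idx"]
            row = {
                "criterion": crit, "stratum": stratum, "n_linked": denom,
                "n_ref_pos": int(ref_flag.sum()),
                "ref_pct": round_half_away(100 * ref_flag.mean(), 1) if denom else float("nan"),
            }
            # evidence-channel counts; ICU stay-days evidence is reported in
            # the reduced-database column alongside ICD evidence
            for ch, col in (("icd", "ICD"), ("proc_rea", "PROC_REA"),
                            ("prof_act", "PROF_ACT")):
                cols = [f"ev_{crit}_{col}"]
                if col == "ICD" and f"ev_{crit}_ICU_DAYS" in sub.columns:
                    cols.append(f"ev_{crit}_ICU_DAYS")
                present = [c for c in cols if c in sub.columns]
                row[f"n_{ch}"] = int(sub[present].any(axis=1).sum()) if present else 0
            row["n_total"] = int(idx_flag.sum())
            row["claims_pct"] = (
                round_half_away(100 * idx_flag.mean(), 1) if denom else float("nan"))
            if denom and 0 < ref_flag.sum() < denom:
                v = validity(confusion(ref_flag, idx_flag), crit, stratum)
                row |= {
                    "sens_pct": v.sens_pct, "spec_pct": v.spec_pct,
                    "lr_pos": v.lr_pos, "lr_neg": v.lr_neg,
                    "band_pos": v.band_pos, "band_neg": v.band_neg,
                }
            else:
                row |= {"sens_pct": float("nan"), "spec_pct": float("nan"),
                        "lr_pos": float("nan"), "lr_neg": float("nan"),
                        "band_pos": "", "band_neg": ""}
            rows.append(row)
    validity_table = pd.DataFrame(rows)

    return ReportBundle(cov, per_hosp, reason_table, discharge_table, validity_table)
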