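"""Reading and filtering the claims tables.

The working representation is a pandas DataFrame with one row per admission
authorization (AIH) — the "reduced" table — and one with one row per
professional act.  Logical column names (the :data:`REDUCED_FIELDS` schema)
are fixed; a column dictionary maps whatever physical header a given extract
uses onto them, so layout differences stay out of the pipeline code.

Rows that cannot be interpreted (unparseable dates, malformed codes,
duplicated AIH numbers) are never dropped silently: they are moved to a
quarantine frame with a per-row reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .rulebook import RuleBook, RuleBookError, normalize_icd, normalize_procedure

__all__ = [
    "REDUCED_FIELDS",
    "ACT_FIELDS",
    "ReadResult",
    "ActsJoin",
    "read_reduced",
    "read_acts",
    "stage1_filter",
    "attach_acts",
]

#: Non-diagnosis logical fields of the reduced table.  Diagnosis fields are
#: whatever the rulebook's ``diagnosis_fields`` names (default: 14 fields).
REDUCED_FIELDS = (
    "aih_number",
    "cnes",
    "aih_type",
    "dob",
    "age",
    "sex",
    "race_color",
    "postcode",
    "admission_date",
    "discharge_date",
    "billing_reason",
    "primary_procedure",
    "icu_days",
)

MANDATORY_FIELDS = ("aih_number", "cnes", "admission_date")

ACT_FIELDS = ("aih_number", "procedure")

_FEMALE_TOKENS = {"F", "FEM", "FEMININO", "3"}
_MALE_TOKENS = {"M", "MASC", "MASCULINO", "1"}


@dataclass
class ReadResult:
    """Parsed rows plus the quarantine of rows that could not be used."""

    records: pd.DataFrame
    quarantine: pd.DataFrame  # original row + 'quarantine_reason'
    warnings: list[str] = field(default_factory=list)


@dataclass
class ActsJoin:
    """AIH number -> set of act procedure codes, plus join accounting."""

    acts_by_aih: dict[str, frozenset[str]]
    orphan_count: int
    orphan_aihs: tuple[str, ...]

    def acts_for(self, aih_number: str) -> frozenset[str]:
        return self.acts_by_aih.get(aih_number, frozenset())


def _apply_dictionary(df: pd.DataFrame, dictionary: Mapping[str, str] | None) -> pd.DataFrame:
    if dictionary:
        df = df.rename(columns=dict(dictionary))
    return df


def _clean_str(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.strip()


def read_reduced(
    path: str | Path | pd.DataFrame,
    rulebook: RuleBook,
    dictionary: Mapping[str, str] | None = None,
    sep: str = ",",
) -> ReadResult:
    """Read the reduced (one row per AIH) table.

    ``path`` may also be an already-loaded DataFrame (the synthetic generator
    hands tables over in memory).  Dates are parsed as ISO ``YYYY-MM-DD``;
    rows with an unparseable admission, discharge or birth date, a malformed
    primary-procedure code, or a duplicated AIH number (first occurrence kept)
    are quarantined with a reason.
    """
    if isinstance(path, pd.DataFrame):
        raw = path.copy()
    else:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = _apply_dictionary(raw, dictionary)

    missing = [c for c in MANDATORY_FIELDS if c not in raw.columns]
    if missing:
        raise RuleBookError(f"reduced table missing mandatory columns: {missing}")

    diag_fields = [f for f in rulebook.diagnosis_fields if f in raw.columns]
    for col in REDUCED_FIELDS:
        if col not in raw.columns:
            raw[col] = ""
    df = raw.copy()
    df["source_row"] = np.arange(len(df))

    for col in ("aih_number", "cnes", "sex", "race_color", "postcode", "billing_reason"):
        df[col] = _clean_str(df[col])
    df["sex"] = df["sex"].str.upper().map(
        lambda t: "F" if t in _FEMALE_TOKENS else ("M" if t in _MALE_TOKENS else None)
    )
    df["aih_type"] = pd.to_numeric(df["aih_type"], errors="coerce").astype("Int64")
    df["age"] = pd.to_numeric(df["age"], errors="coerce").astype("Int64")
    df["icu_days"] = (
        pd.to_numeric(df["icu_days"], errors="coerce").fillna(0).astype(int)
    )

    warnings: list[str] = []
    bad = pd.Series("", index=df.index)

    for col in ("dob", "admission_date", "discharge_date"):
        parsed = pd.to_datetime(_clean_str(df[col]), format="%Y-%m-%d", errors="coerce")
        had_value = _clean_str(df[col]) != ""
        invalid = had_value & parsed.isna()
        if col == "dob":
            pass  # dob may legitimately be blank; invalid non-blank quarantines
        else:
            invalid = invalid | ~had_value if col == "admission_date" else invalid
        bad[invalid & (bad == "")] = f"unparseable {col}"
        df[col] = parsed

    def _norm_icd_or_none(v: str):
        try:
            return normalize_icd(v)
        except RuleBookError:
            return "!"  # sentinel: malformed

    for col in diag_fields:
        normed = _clean_str(df[col]).map(_norm_icd_or_none)
        malformed = normed == "!"
        if malformed.any():
            warnings.append(f"{int(malformed.sum())} malformed ICD value(s) in {col}")
        df[col] = normed.where(~malformed, None)

    proc = _clean_str(df["primary_procedure"])

    def _norm_proc(v: str):
        if v == "":
            return None
        try:
            return normalize_procedure(v)
        except RuleBookError:
            return "!"

    proc_norm = proc.map(_norm_proc)
    bad[(proc_norm == "!") & (bad == "")] = "malformed primary procedure"
    df["primary_procedure"] = proc_norm.where(proc_norm != "!", None)

    swapped = df["discharge_date"].notna() & (df["discharge_date"] < df["admission_date"])
    bad[swapped & (bad == "")] = "discharge before admission"

    dup = df["aih_number"].duplicated(keep="first") & (df["aih_number"] != "")
    bad[dup & (bad == "")] = "duplicate AIH number"

    quarantine = df[bad != ""].copy()
    quarantine["quarantine_reason"] = bad[bad != ""]
    records = df[bad == ""].copy().reset_index(drop=True)
    for reason in quarantine["quarantine_reason"].unique():
        warnings.append(
            f"{int((quarantine['quarantine_reason'] == reason).sum())} row(s) quarantined: {reason}"
        )
    keep_cols = list(REDUCED_FIELDS) + diag_fields + ["source_row"]
    return ReadResult(records[keep_cols], quarantine, warnings)


def read_acts(
    path: str | Path | pd.DataFrame,
    dictionary: Mapping[str, str] | None = None,
    sep: str = ",",
) -> ReadResult:
    """Read the professional-services table (one row per act)."""
    if isinstance(path, pd.DataFrame):
        raw = path.copy()
    else:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = _apply_dictionary(raw, dictionary)
    missing = [c for c in ACT_FIELDS if c not in raw.columns]
    if missing:
        raise RuleBookError(f"acts table missing mandatory columns: {missing}")
    df = raw.copy()
    df["aih_number"] = _clean_str(df["aih_number"])

    def _norm(v: str):
        try:
            return normalize_procedure(v)
        except RuleBookError:
            return None

    proc = _clean_str(df["procedure"]).map(_norm)
    bad = proc.isna()
    quarantine = df[bad].copy()
    quarantine["quarantine_reason"] = "malformed act procedure"
    df = df[~bad].copy()
    df["procedure"] = proc[~bad]
    warnings = (
        [f"{int(bad.sum())} act row(s) quarantined: malformed procedure"] if bad.any() else []
    )
    return ReadResult(df[list(ACT_FIELDS)].reset_index(drop=True), quarantine, warnings)


def age_at_admission(df: pd.DataFrame) -> pd.Series:
    """Completed years between date of birth and admission; falls back to the
    recorded age column where dob is missing."""
    have_dob = df["dob"].notna() & df["admission_date"].notna()
    adm, dob = df["admission_date"], df["dob"]
    years = adm.dt.year - dob.dt.year
    before_birthday = (adm.dt.month < dob.dt.month) | (
        (adm.dt.month == dob.dt.month) & (adm.dt.day < dob.dt.day)
    )
    computed = (years - before_birthday.astype(int)).where(have_dob)
    recorded = df["age"].astype("Float64")
    return computed.fillna(recorded).astype("Float64")


def stage1_filter(
    records: pd.DataFrame, age_min: int = 10, age_max: int = 49
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Stage-1 population filter: type-1 AIHs of women aged 10-49 at admission.

    Returns the kept rows and exclusion counts by cause (first matching cause
    per row, in the order type -> sex -> age).  Age bounds are inclusive; age
    is computed from date of birth when present, else the recorded age.
    """
    age = age_at_admission(records)
    not_type1 = records["aih_type"].isna() | (records["aih_type"] != 1)
    sex_unknown = records["sex"].isna()
    not_female = ~sex_unknown & (records["sex"] != "F")
    age_unknown = age.isna()
    age_out = ~age_unknown & ((age < age_min) | (age > age_max))

    cause = pd.Series("", index=records.index)
    for name, mask in (
        ("not_type1", not_type1),
        ("sex_unknown", sex_unknown),
        ("not_female", not_female),
        ("age_unknown", age_unknown),
        ("age_out_of_range", age_out),
    ):
        cause[mask & (cause == "")] = name
    kept = records[cause == ""].reset_index(drop=True)
    counts = {k: int((cause == k).sum()) for k in
              ("not_type1", "sex_unknown", "not_female", "age_unknown", "age_out_of_range")}
    assert sum(counts.values()) + len(kept) == len(records)
    return kept, counts


def attach_acts(records: pd.DataFrame, acts: pd.DataFrame) -> ActsJoin:
    """Join professional acts to admissions by AIH number.

    Loss-free on the AIH side (an AIH with no acts simply maps to the empty
    set); acts whose AIH number does not occur in ``records`` are orphans.
    Duplicate acts on one AIH collapse (set semantics).
    """
    known = set(records["aih_number"])
    grouped: dict[str, set[str]] = {}
    orphans: list[str] = []
    for aih, proc in zip(acts["aih_number"], acts["procedure"]):
        if aih in known:
            grouped.setdefault(aih, set()).add(proc)
        else:
            orphans.append(aih)
    mapping = {aih: frozenset(grouped.get(aih, ())) for aih in known}
    return ActsJoin(mapping, len(orphans), tuple(sorted(set(orphans))))
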