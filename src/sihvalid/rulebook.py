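"""Declarative codebook for obstetric claims classification.

The operational definitions — which ICD-10 codes and SIGTAP procedure codes
mark an obstetric stay, each reason-for-hospitalization category, each
discharge category, and the 11 severe-maternal-morbidity criteria — live in a
versioned YAML document (packaged default: ``data/box1_default.yaml``) and are
loaded into an immutable :class:`RuleBook`.

Matching semantics
------------------
ICD-10 patterns are normalized (uppercase, dots stripped); patterns of one to
three characters are prefixes, four-character patterns are exact codes, and
``"A to B"`` entries expand to the inclusive prefix range.  Procedure patterns
are 10-digit SIGTAP codes matched exactly after punctuation removal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CodePattern",
    "CriterionRule",
    "ReasonRule",
    "RuleBook",
    "RuleBookError",
    "normalize_icd",
    "normalize_procedure",
    "expand_icd_entry",
    "match",
    "load_rulebook",
    "default_rulebook_path",
]

REASON_CATEGORIES = (
    "abortion",
    "delivery",
    "pregnancy_complication",
    "puerperium_complication",
)

DISCHARGE_CATEGORIES = (
    "routine",
    "administrative",
    "continuing_stay",
    "death",
    "transfer",
    "blank",
)

#: Billing-reason token that closes an AIH because the stay continues on a
#: new authorization; the episode builder chains on it.
CONTINUING_STAY_TOKEN = "2"

CRITERION_NAMES = (
    "severe_preeclampsia",
    "eclampsia",
    "hellp_syndrome",
    "abruptio_placentae",
    "hemorrhage",
    "uterine_rupture",
    "ectopic_pregnancy",
    "hysterectomy",
    "laparotomy",
    "transfusion",
    "icu",
)

_ICD_RE = re.compile(r"^[A-Z][A-Z0-9]{0,3}$")
_RANGE_RE = re.compile(r"^\s*([A-Za-z][0-9]{2})\s+to\s+([A-Za-z][0-9]{2})\s*$")


class RuleBookError(ValueError):
    """Raised when a codebook document fails validation."""


def normalize_icd(raw: str | None) -> str | None:
    """Canonicalize an ICD-10 code: uppercase, strip dots and whitespace.

    Returns ``None`` for empty / whitespace-only input (no diagnosis
    recorded).  Raises :class:`RuleBookError` for values that cannot be an
    ICD-10 code after normalization.
    """
    if raw is None:
        return None
    code = str(raw).strip().upper().replace(".", "").replace(" ", "")
    if not code:
        return None
    if not _ICD_RE.match(code):
        raise RuleBookError(f"not an ICD-10 code: {raw!r}")
    return code


def normalize_procedure(raw: str) -> str:
    """Canonicalize a SIGTAP procedure code to its 10-digit form."""
    digits = re.sub(r"\D", "", str(raw))
    if len(digits) != 10:
        raise RuleBookError(
            f"procedure code must have 10 digits, got {raw!r} -> {digits!r}"
        )
    return digits


@dataclass(frozen=True)
class CodePattern:
    """A single normalized code or prefix with its matching mode."""

    pattern: str
    system: str  # ICD10 | PROCEDURE | BILLING_REASON | SPECIAL
    match_mode: str  # exact | prefix

    def matches(self, code: str) -> bool:
        if self.match_mode == "prefix":
            return code.startswith(self.pattern)
        return code == self.pattern


def _icd_pattern(code: str) -> CodePattern:
    code = normalize_icd(code)
    mode = "exact" if len(code) == 4 else "prefix"
    return CodePattern(code, "ICD10", mode)


def expand_icd_entry(entry: str) -> tuple[CodePattern, ...]:
    """Expand one codebook ICD entry into patterns.

    ``"O00 to O08"`` becomes the nine prefix patterns O00..O08; a plain code
    becomes a single pattern (prefix if 1-3 characters, exact if 4).
    """
    m = _RANGE_RE.match(str(entry))
    if m is None:
        return (_icd_pattern(str(entry)),)
    lo, hi = m.group(1).upper(), m.group(2).upper()
    if lo[0] != hi[0] or int(lo[1:]) > int(hi[1:]):
        raise RuleBookError(f"malformed ICD range: {entry!r}")
    return tuple(
        CodePattern(f"{lo[0]}{i:02d}", "ICD10", "prefix")
        for i in range(int(lo[1:]), int(hi[1:]) + 1)
    )


def match(code: str | None, codeset: Iterable[CodePattern]) -> bool:
    """True iff the normalized ``code`` matches any pattern in ``codeset``."""
    if code is None or code == "":
        return False
    return any(p.matches(code) for p in codeset)


@dataclass(frozen=True)
class ReasonRule:
    category: str
    primary_icd: tuple[CodePattern, ...]
    procedures: frozenset[str]
    catch_all: bool = False


@dataclass(frozen=True)
class CriterionRule:
    name: str
    icd: tuple[CodePattern, ...]
    procedures: frozenset[str]
    uses_icu_days: bool = False

    @property
    def channels(self) -> tuple[str, ...]:
        """Evidence channels through which this criterion can be recorded."""
        out: list[str] = []
        if self.icd:
            out.append("ICD")
        if self.procedures:
            out.extend(["PROC_REA", "PROF_ACT"])
        if self.uses_icu_days:
            out.append("ICU_DAYS")
        return tuple(out)


@dataclass(frozen=True)
class RuleBook:
    """Validated, immutable codebook."""

    version: int
    diagnosis_fields: tuple[str, ...]
    obstetric_icd: tuple[CodePattern, ...]
    obstetric_procedures: frozenset[str]
    reason_rules: tuple[ReasonRule, ...]  # in precedence order
    delivery_procedures: frozenset[str]
    discharge_map: Mapping[str, str]  # billing token -> category
    criteria: Mapping[str, CriterionRule]

    def discharge_category(self, billing_token: str | None) -> str:
        token = "" if billing_token is None else str(billing_token).strip()
        try:
            return self.discharge_map[token]
        except KeyError:
            raise RuleBookError(f"unknown billing-reason token: {token!r}") from None

    def to_dict(self) -> dict:
        """Serialize back to the document form (round-trips via load)."""

        def fmt_proc(p: str) -> str:
            return f"{p[0:2]}.{p[2:4]}.{p[4:6]}.{p[6:9]}-{p[9]}"

        reason: dict = {}
        for r in self.reason_rules:
            d: dict = {"primary_icd": [p.pattern for p in r.primary_icd]}
            if r.procedures:
                d["procedures"] = sorted(fmt_proc(p) for p in r.procedures)
            if r.catch_all:
                d["catch_all"] = True
            reason[r.category] = d
        discharge: dict[str, list[str]] = {c: [] for c in DISCHARGE_CATEGORIES}
        for token, cat in self.discharge_map.items():
            discharge[cat].append(token)
        criteria: dict = {}
        for name, c in self.criteria.items():
            d = {}
            if c.icd:
                d["icd"] = [p.pattern for p in c.icd]
            if c.procedures:
                d["procedures"] = sorted(fmt_proc(p) for p in c.procedures)
            if c.uses_icu_days:
                d["uses_icu_days"] = True
            criteria[name] = d
        return {
            "version": self.version,
            "diagnosis_fields": list(self.diagnosis_fields),
            "obstetric": {
                "icd": [p.pattern for p in self.obstetric_icd],
                "procedures": sorted(fmt_proc(p) for p in self.obstetric_procedures),
            },
            "reason": reason,
            "discharge": discharge,
            "criteria": criteria,
        }


def default_rulebook_path() -> Path:
    return Path(resources.files("sihvalid") / "data" / "box1_default.yaml")


def _icd_set(entries: Iterable[str]) -> tuple[CodePattern, ...]:
    out: list[CodePattern] = []
    for entry in entries:
        out.extend(expand_icd_entry(entry))
    return tuple(out)


def _proc_set(entries: Iterable[str] | None) -> frozenset[str]:
    return frozenset(normalize_procedure(e) for e in (entries or []))


def load_rulebook(source: str | Path | Mapping | None = None) -> RuleBook:
    """Load and validate a codebook from YAML (default: packaged codebook).

    ``source`` may be a path, an already-parsed mapping, or ``None`` for the
    packaged default.  Raises :class:`RuleBookError` describing the first
    schema violation found.
    """
    if source is None:
        source = default_rulebook_path()
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise RuleBookError("codebook document must be a mapping")

    for key in ("diagnosis_fields", "obstetric", "reason", "discharge", "criteria"):
        if key not in doc:
            raise RuleBookError(f"codebook missing section {key!r}")

    fields = tuple(str(f) for f in doc["diagnosis_fields"])
    if len(fields) != len(set(fields)) or not fields:
        raise RuleBookError("diagnosis_fields must be a non-empty unique list")

    obstetric_icd = _icd_set(doc["obstetric"].get("icd", []))
    obstetric_proc = _proc_set(doc["obstetric"].get("procedures"))

    reason_doc = doc["reason"]
    missing = [c for c in REASON_CATEGORIES if c not in reason_doc]
    if missing:
        raise RuleBookError(f"reason section missing categories: {missing}")
    extra = [c for c in reason_doc if c not in REASON_CATEGORIES]
    if extra:
        raise RuleBookError(f"unknown reason categories: {extra}")
    reason_rules = tuple(
        ReasonRule(
            category=cat,
            primary_icd=_icd_set(reason_doc[cat].get("primary_icd", [])),
            procedures=_proc_set(reason_doc[cat].get("procedures")),
            catch_all=bool(reason_doc[cat].get("catch_all", False)),
        )
        for cat in REASON_CATEGORIES
    )
    delivery_procedures = next(
        r.procedures for r in reason_rules if r.category == "delivery"
    )
    if sum(r.catch_all for r in reason_rules) != 1:
        raise RuleBookError("exactly one reason category must be the catch-all")

    discharge_doc = doc["discharge"]
    unknown = [c for c in discharge_doc if c not in DISCHARGE_CATEGORIES]
    if unknown:
        raise RuleBookError(f"unknown discharge categories: {unknown}")
    discharge_map: dict[str, str] = {}
    for cat in DISCHARGE_CATEGORIES:
        for token in discharge_doc.get(cat, []):
            token = str(token).strip()
            if token in discharge_map:
                raise RuleBookError(f"billing token {token!r} mapped twice")
            discharge_map[token] = cat
    if CONTINUING_STAY_TOKEN not in discharge_map:
        raise RuleBookError("continuing-stay billing token missing from discharge map")
    if "" not in discharge_map:
        raise RuleBookError("blank billing token must be mapped")

    crit_doc = doc["criteria"]
    missing = [c for c in CRITERION_NAMES if c not in crit_doc]
    if missing:
        raise RuleBookError(f"criteria section missing: {missing}")
    extra = [c for c in crit_doc if c not in CRITERION_NAMES]
    if extra:
        raise RuleBookError(f"unknown criteria: {extra}")
    criteria = {
        name: CriterionRule(
            name=name,
            icd=_icd_set(crit_doc[name].get("icd", [])),
            procedures=_proc_set(crit_doc[name].get("procedures")),
            uses_icu_days=bool(crit_doc[name].get("uses_icu_days", False)),
        )
        for name in CRITERION_NAMES
    }
    for name, rule in criteria.items():
        if not rule.icd and not rule.procedures and not rule.uses_icu_days:
            raise RuleBookError(f"criterion {name!r} has no evidence rule")

    return RuleBook(
        version=int(doc.get("version", 1)),
        diagnosis_fields=fields,
        obstetric_icd=obstetric_icd,
        obstetric_procedures=obstetric_proc,
        reason_rules=reason_rules,
        delivery_procedures=delivery_procedures,
        discharge_map=discharge_map,
        criteria=criteria,
    )
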