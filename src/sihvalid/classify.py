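"""Obstetric classification of episodes of care.

Implements, over built episodes, the codebook's operational definitions:

* **obstetric stay** — any AIH in the episode carries a chapter-O diagnosis in
  any configured diagnosis field, or an obstetric primary procedure,
  regardless of the AIH's position in the episode;
* **reason for hospitalization** — evaluated on the *first* AIH only, in
  precedence order abortion, delivery, pregnancy complication, puerperium
  complication, with the pregnancy-complication row acting as catch-all for
  any other primary diagnosis when the procedure performed is not a delivery
  procedure;
* **discharge type** — the billing reason of the *last* AIH, mapped through
  the codebook;
* the 11 severe-morbidity criterion flags, counted once per episode, with the
  evidence channel (diagnosis field, primary procedure, professional act, or
  ICU stay-days) recorded separately so reports can break counts down by
  channel.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .episodes import EpisodeBuild
from .ingest import ActsJoin
from .rulebook import CodePattern, RuleBook, match

__all__ = [
    "CHANNELS",
    "match_series",
    "is_obstetric",
    "classify_reason",
    "classify_discharge",
    "flag_criteria",
    "classify_episodes",
]

CHANNELS = ("ICD", "PROC_REA", "PROF_ACT", "ICU_DAYS")

REASONS = (
    "delivery",
    "abortion",
    "pregnancy_complication",
    "puerperium_complication",
    "other",
    "missing",
)


def match_series(values: pd.Series, codeset: Iterable[CodePattern]) -> np.ndarray:
    """Vectorized :func:`sihvalid.rulebook.match` over a column of codes."""
    exact = {p.pattern for p in codeset if p.match_mode == "exact"}
    prefixes = tuple(p.pattern for p in codeset if p.match_mode == "prefix")
    s = values.fillna("").astype(str)
    out = s.isin(exact).to_numpy() if exact else np.zeros(len(s), dtype=bool)
    if prefixes:
        out |= s.str.startswith(prefixes).to_numpy()
    return out


def _diag_fields(records: pd.DataFrame, rb: RuleBook) -> list[str]:
    return [f for f in rb.diagnosis_fields if f in records.columns]


def _any_field_match(records: pd.DataFrame, rb: RuleBook,
                     codeset: Iterable[CodePattern]) -> np.ndarray:
    hit = np.zeros(len(records), dtype=bool)
    for f in _diag_fields(records, rb):
        hit |= match_series(records[f], codeset)
    return hit


# ---------------------------------------------------------------------------
# per-episode operations (the record-level contract; tests exercise these)

def is_obstetric(episode_records: pd.DataFrame, rb: RuleBook) -> bool:
    """Obstetric-stay rule over the rows of one episode."""
    if _any_field_match(episode_records, rb, rb.obstetric_icd).any():
        return True
    return episode_records["primary_procedure"].isin(rb.obstetric_procedures).any()


def classify_reason(episode_records: pd.DataFrame, rb: RuleBook) -> str:
    """Reason for hospitalization from the episode's first AIH."""
    first = episode_records.sort_values("admission_date").iloc[0]
    primary = first.get("diag_primary")
    primary = None if (primary is None or pd.isna(primary) or primary == "") else primary
    proc = first.get("primary_procedure")
    proc = None if (proc is None or pd.isna(proc) or proc == "") else proc
    for rule in rb.reason_rules:
        if primary is not None and match(primary, rule.primary_icd):
            return rule.category
        if proc is not None and proc in rule.procedures:
            return rule.category
    if primary is not None and proc not in rb.delivery_procedures:
        return next(r.category for r in rb.reason_rules if r.catch_all)
    if primary is None and proc is None:
        return "missing"
    return "other"


def classify_discharge(last_billing_reason: str | None, rb: RuleBook) -> str:
    """Discharge type from the last AIH's billing reason."""
    return rb.discharge_category(last_billing_reason)


def flag_criteria(
    episode_records: pd.DataFrame, acts: ActsJoin | None, rb: RuleBook
) -> tuple[dict[str, bool], dict[str, frozenset[str]]]:
    """Once-per-episode morbidity flags with their evidence channels."""
    flags: dict[str, bool] = {}
    sources: dict[str, frozenset[str]] = {}
    act_sets = [
        acts.acts_for(a) if acts is not None else frozenset()
        for a in episode_records["aih_number"]
    ]
    for name, crit in rb.criteria.items():
        ev = set()
        if crit.icd.__len__() and _any_field_match(episode_records, rb, crit.icd).any():
            ev.add("ICD")
        if crit.procedures:
            if episode_records["primary_procedure"].isin(crit.procedures).any():
                ev.add("PROC_REA")
            if any(s & crit.procedures for s in act_sets):
                ev.add("PROF_ACT")
        if crit.uses_icu_days and (episode_records["icu_days"].fillna(0) > 0).any():
            ev.add("ICU_DAYS")
        flags[name] = bool(ev)
        sources[name] = frozenset(ev)
    return flags, sources


# ---------------------------------------------------------------------------
# whole-table classification

def classify_episodes(
    records: pd.DataFrame,
    build: EpisodeBuild,
    acts: ActsJoin | None,
    rb: RuleBook,
) -> pd.DataFrame:
    """Classify every built episode.

    Returns one row per episode: ``is_obstetric``, ``reason`` (obstetric
    episodes only, else ``NA``), ``discharge``, one ``flag_<criterion>``
    boolean per criterion and one ``ev_<criterion>_<channel>`` boolean per
    available evidence channel.
    """
    df = records.merge(build.crosswalk, on="aih_number", how="inner")
    gb = df.groupby("episode_id", sort=True)

    # obstetric detection over all AIHs of the episode
    rec_obst = _any_field_match(df, rb, rb.obstetric_icd) | df[
        "primary_procedure"
    ].isin(rb.obstetric_procedures).to_numpy()
    obstetric = pd.Series(rec_obst, index=df.index).groupby(df["episode_id"]).any()

    out = build.episodes.set_index("episode_id").copy()
    out["is_obstetric"] = obstetric.reindex(out.index).fillna(False)

    # reason: first AIH only
    first = df[df["position"] == 0].set_index("episode_id")
    primary = first["diag_primary"].fillna("")
    proc = first["primary_procedure"].fillna("")
    reason = pd.Series(pd.NA, index=first.index, dtype="object")
    unset = reason.isna()
    for rule in rb.reason_rules:
        hit = match_series(primary, rule.primary_icd) | proc.isin(rule.procedures).to_numpy()
        sel = unset & hit
        reason[sel] = rule.category
        unset &= ~hit
    catch_all = next(r.category for r in rb.reason_rules if r.catch_all)
    sel = unset & (primary != "") & ~proc.isin(rb.delivery_procedures)
    reason[sel] = catch_all
    unset &= ~sel
    reason[unset & (primary == "") & (proc == "")] = "missing"
    reason[reason.isna()] = "other"
    out["reason"] = reason.reindex(out.index)
    out.loc[~out["is_obstetric"], "reason"] = pd.NA

    out["discharge"] = [
        classify_discharge(t, rb) for t in out["billing_reason_last"]
    ]

    # criterion flags by channel
    act_hits: dict[str, pd.Series] = {}
    if acts is not None:
        aih_to_acts = df["aih_number"].map(acts.acts_by_aih)
    for name, crit in rb.criteria.items():
        ev = {}
        if crit.icd:
            ev["ICD"] = _any_field_match(df, rb, crit.icd)
        if crit.procedures:
            ev["PROC_REA"] = df["primary_procedure"].isin(crit.procedures).to_numpy()
            if acts is not None:
                ev["PROF_ACT"] = np.array(
                    [bool(s & crit.procedures) if isinstance(s, frozenset) else False
                     for s in aih_to_acts],
                    dtype=bool,
                )
        if crit.uses_icu_days:
            ev["ICU_DAYS"] = (df["icu_days"].fillna(0) > 0).to_numpy()
        total = np.zeros(len(df), dtype=bool)
        for ch, arr in ev.items():
            per_ep = pd.Series(arr, index=df.index).groupby(df["episode_id"]).any()
            out[f"ev_{name}_{ch}"] = per_ep.reindex(out.index).fillna(False)
            total |= arr
        per_ep = pd.Series(total, index=df.index).groupby(df["episode_id"]).any()
        out[f"flag_{name}"] = per_ep.reindex(out.index).fillna(False)

    return out.reset_index()
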