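"""Deterministic multi-pass record linkage.

Claims episodes and reference-standard hospitalizations are matched on exact
agreement of key subsets, in an ordered sequence of passes that relax the key
set: (1) all six keys — facility code, date of birth, admission date,
discharge date, race/skin colour, residence postcode; (2) drop postcode;
(3) drop postcode and race; (4) drop postcode and race and allow the
discharge date to differ by at most one day (split billing can shift it).

Matched records are removed before later passes.  Within a pass, a key block
holding more than one candidate on either side is left unmatched (counted as
an ambiguity) rather than guessed at, so the result is one-to-one and fully
auditable.  Missing key values never satisfy equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["LINK_KEYS", "DEFAULT_PASSES", "LinkPass", "LinkResult",
           "deterministic_link", "link_report"]

LINK_KEYS = ("cnes", "dob", "admission_date", "discharge_date",
             "race_color", "postcode")


@dataclass(frozen=True)
class LinkPass:
    keys: tuple[str, ...]
    discharge_tolerance_days: int = 0


DEFAULT_PASSES: tuple[LinkPass, ...] = (
    LinkPass(LINK_KEYS),
    LinkPass(("cnes", "dob", "admission_date", "discharge_date", "race_color")),
    LinkPass(("cnes", "dob", "admission_date", "discharge_date")),
    LinkPass(("cnes", "dob", "admission_date", "discharge_date"),
             discharge_tolerance_days=1),
)


@dataclass
class LinkResult:
    pairs: pd.DataFrame  # episode_id, reference_id, pass_number
    unmatched_episodes: tuple
    unmatched_reference: tuple
    ambiguity_count: int
    pass_counts: dict[int, int] = field(default_factory=dict)


def _usable(df: pd.DataFrame, keys: tuple[str, ...]) -> pd.Series:
    ok = pd.Series(True, index=df.index)
    for k in keys:
        col = df[k]
        ok &= col.notna()
        if col.dtype == object:
            ok &= col.astype(str).str.strip() != ""
    return ok


def deterministic_link(
    episodes: pd.DataFrame,
    reference: pd.DataFrame,
    passes: tuple[LinkPass, ...] = DEFAULT_PASSES,
) -> LinkResult:
    """Link episodes (``episode_id`` + keys) to reference stays
    (``reference_id`` + keys); returns a one-to-one pairing."""
    if reference["reference_id"].duplicated().any():
        raise ValueError("duplicate reference_ids in reference table")
    if episodes["episode_id"].duplicated().any():
        raise ValueError("duplicate episode_ids in claims table")

    ep = episodes.copy()
    ref = reference.copy()
    pairs: list[pd.DataFrame] = []
    ambiguity = 0
    pass_counts: dict[int, int] = {}

    for pass_no, spec in enumerate(passes, start=1):
        tol = spec.discharge_tolerance_days
        block_keys = [k for k in spec.keys if not (tol and k == "discharge_date")]
        cmp_discharge = tol and "discharge_date" in spec.keys

        left = ep[_usable(ep, tuple(block_keys))]
        right = ref[_usable(ref, tuple(block_keys))]
        if len(left) == 0 or len(right) == 0:
            pass_counts[pass_no] = 0
            continue

        lc = left.groupby(block_keys, dropna=True).size().rename("n_left")
        rc = right.groupby(block_keys, dropna=True).size().rename("n_right")
        sizes = pd.concat([lc, rc], axis=1, join="inner")
        ambiguity += int(((sizes["n_left"] > 1) | (sizes["n_right"] > 1)).sum())
        unique_blocks = sizes[(sizes["n_left"] == 1) & (sizes["n_right"] == 1)].index

        li = left.set_index(block_keys).loc[left.set_index(block_keys).index.isin(unique_blocks)]
        ri = right.set_index(block_keys).loc[right.set_index(block_keys).index.isin(unique_blocks)]
        merged = li[["episode_id"] + (["discharge_date"] if cmp_discharge else [])].join(
            ri[["reference_id"] + (["discharge_date"] if cmp_discharge else [])],
            how="inner", lsuffix="_ep", rsuffix="_ref",
        )
        if cmp_discharge:
            diff = (merged["discharge_date_ep"] - merged["discharge_date_ref"]).abs()
            merged = merged[diff <= pd.Timedelta(days=tol)]
        matched = merged[["episode_id", "reference_id"]].reset_index(drop=True)
        matched["pass_number"] = pass_no
        pass_counts[pass_no] = len(matched)
        if len(matched):
            pairs.append(matched)
            ep = ep[~ep["episode_id"].isin(matched["episode_id"])]
            ref = ref[~ref["reference_id"].isin(matched["reference_id"])]

    all_pairs = (
        pd.concat(pairs, ignore_index=True)
        if pairs
        else pd.DataFrame(columns=["episode_id", "reference_id", "pass_number"])
    )
    assert not all_pairs["episode_id"].duplicated().any()
    assert not all_pairs["reference_id"].duplicated().any()
    return LinkResult(
        pairs=all_pairs,
        unmatched_episodes=tuple(ep["episode_id"]),
        unmatched_reference=tuple(ref["reference_id"]),
        ambiguity_count=ambiguity,
        pass_counts=pass_counts,
    )


def link_report(result: LinkResult, n_episodes: int, n_reference: int) -> dict:
    """Flow summary: matches per pass and match rate on each side."""
    n = len(result.pairs)
    return {
        "pairs": n,
        "pass_counts": dict(result.pass_counts),
        "match_rate_episodes_pct": 100.0 * n / n_episodes if n_episodes else 0.0,
        "match_rate_reference_pct": 100.0 * n / n_reference if n_reference else 0.0,
        "ambiguity_count": result.ambiguity_count,
        "unmatched_episodes": len(result.unmatched_episodes),
        "unmatched_reference": len(result.unmatched_reference),
    }
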