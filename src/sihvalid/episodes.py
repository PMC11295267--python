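"""Episode-of-care construction from split admission authorizations.

A hospital stay paid through the AIH system may be billed as several chained
authorizations: each non-final AIH is closed with the "continuing inpatient
stay" billing reason and a new AIH is opened.  Two AIHs belong to the same
episode of care when they share the person key — facility code (CNES) and
patient date of birth — the earlier one carries the continuing-stay billing
reason, and the later admission follows the earlier discharge by at most one
day.

Chaining is transitive, so an episode is a maximal chain under that
predicate.  When two candidate successors fall inside the one-day window the
earliest admission wins (ties broken by smallest AIH number), each AIH can
succeed at most one predecessor, and predecessors are served in chronological
order — a deterministic, order-invariant greedy rule.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .rulebook import CONTINUING_STAY_TOKEN

__all__ = ["chain_predicate", "build_episodes", "episode_summary", "EpisodeBuild"]

PERSON_KEY = ("cnes", "dob")


def chain_predicate(
    prev: Mapping, nxt: Mapping, continuing_token: str = CONTINUING_STAY_TOKEN
) -> bool:
    """True iff ``nxt`` may continue ``prev`` within one episode of care.

    Callers guarantee the two records share the person key.  The gap between
    the predecessor's discharge and the successor's admission must be 0 or 1
    day; negative gaps (overlapping stays) never chain.
    """
    if str(prev["billing_reason"]).strip() != continuing_token:
        return False
    dis, adm = prev["discharge_date"], nxt["admission_date"]
    if pd.isna(dis) or pd.isna(adm):
        return False
    gap = (pd.Timestamp(adm) - pd.Timestamp(dis)).days
    return 0 <= gap <= 1


class EpisodeBuild:
    """Result of :func:`build_episodes`: episode table + AIH crosswalk."""

    def __init__(self, episodes: pd.DataFrame, crosswalk: pd.DataFrame,
                 negative_gap_warnings: int):
        self.episodes = episodes
        self.crosswalk = crosswalk  # aih_number, episode_id, position
        self.negative_gap_warnings = negative_gap_warnings


def build_episodes(
    records: pd.DataFrame, continuing_token: str = CONTINUING_STAY_TOKEN
) -> EpisodeBuild:
    """Partition stage-1-filtered AIH rows into episodes of care.

    Returns an episode table (one row per episode, person key, first
    admission / last discharge dates, linkage attributes taken from the first
    AIH, ``unresolved_continuation`` when the final AIH still carries the
    continuing-stay reason) and a crosswalk assigning every input AIH to
    exactly one episode.  Output is independent of input row order.
    """
    df = records.sort_values(
        ["cnes", "dob", "admission_date", "aih_number"], kind="mergesort"
    ).reset_index(drop=True)

    succ = np.full(len(df), -1, dtype=np.int64)
    has_pred = np.zeros(len(df), dtype=bool)
    negative_gaps = 0

    adm = df["admission_date"].to_numpy()
    dis = df["discharge_date"].to_numpy()
    dob = df["dob"].to_numpy()
    reason = df["billing_reason"].astype(str).str.strip().to_numpy()

    for _, idx in df.groupby(["cnes", "dob"], sort=False, dropna=False).indices.items():
        idx = np.sort(idx)
        for pos, i in enumerate(idx):
            # a missing date of birth is not a usable person key: never chain
            if reason[i] != continuing_token or pd.isna(dis[i]) or pd.isna(dob[i]):
                continue
            chosen = -1
            saw_overlap = False
            for j in idx[pos + 1:]:
                if has_pred[j] or pd.isna(adm[j]):
                    continue
                gap = (adm[j] - dis[i]) / np.timedelta64(1, "D")
                if gap < 0:
                    saw_overlap = True
                    continue
                if gap > 1:
                    break  # sorted by admission: no later j can qualify
                chosen = j
                break
            if chosen >= 0:
                succ[i] = chosen
                has_pred[chosen] = True
            elif saw_overlap:
                negative_gaps += 1

    # walk chains from their heads
    episode_id = np.full(len(df), -1, dtype=np.int64)
    position = np.zeros(len(df), dtype=np.int64)
    eid = 0
    for i in range(len(df)):
        if has_pred[i]:
            continue
        j, pos = i, 0
        while j != -1:
            episode_id[j] = eid
            position[j] = pos
            j = succ[j]
            pos += 1
        eid += 1
    assert (episode_id >= 0).all()

    df = df.assign(episode_id=episode_id, position=position)
    grouped = df.groupby("episode_id", sort=True)
    first = df[df["position"] == 0].set_index("episode_id")
    last_pos = grouped["position"].max()
    last = df.set_index(["episode_id", "position"]).loc[
        list(zip(last_pos.index, last_pos.values))
    ].reset_index().set_index("episode_id")

    episodes = pd.DataFrame({
        "episode_id": first.index,
        "cnes": first["cnes"],
        "dob": first["dob"],
        "admission_date": first["admission_date"],
        "discharge_date": last["discharge_date"],
        "race_color": first["race_color"],
        "postcode": first["postcode"],
        "n_aihs": grouped.size(),
        "billing_reason_last": last["billing_reason"],
        "first_aih": first["aih_number"],
        "last_aih": last["aih_number"],
    }).reset_index(drop=True)
    episodes["unresolved_continuation"] = (
        episodes["billing_reason_last"].astype(str).str.strip() == continuing_token
    )

    crosswalk = df[["aih_number", "episode_id", "position"]].copy()
    return EpisodeBuild(episodes, crosswalk, negative_gaps)


def episode_summary(build: EpisodeBuild) -> dict[str, int]:
    """Flow-accounting totals for the episode-construction stage."""
    ep = build.episodes
    return {
        "episodes": int(len(ep)),
        "aihs": int(ep["n_aihs"].sum()),
        "multi_aih_episodes": int((ep["n_aihs"] > 1).sum()),
        "unresolved_continuations": int(ep["unresolved_continuation"].sum()),
        "negative_gap_warnings": int(build.negative_gap_warnings),
    }
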