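"""Independent brute-force oracle for episode construction.

Enumerates every order-respecting partition of a person-key group into
chains whose consecutive pairs satisfy the chaining rule, keeps the maximal
ones (no two chains could still be concatenated), and returns them.  The
production algorithm's output must always be one of the maximal partitions;
when there is exactly one, it must be that one.

Kept deliberately naive and separate from the production path.
"""

from __future__ import annotations

import pandas as pd

CONTINUING = "2"


def _ok_pair(prev: dict, nxt: dict) -> bool:
    if str(prev["billing_reason"]).strip() != CONTINUING:
        return False
    gap = (pd.Timestamp(nxt["admission_date"]) - pd.Timestamp(prev["discharge_date"])).days
    return 0 <= gap <= 1


def enumerate_partitions(records: list[dict]) -> list[tuple[tuple[str, ...], ...]]:
    """All valid partitions of the (sorted) records into chains.

    A record may either start a new chain or extend any open chain whose last
    element accepts it; records are consumed in chronological order, so every
    chain is automatically order-respecting.
    """
    records = sorted(
        records, key=lambda r: (pd.Timestamp(r["admission_date"]), r["aih_number"])
    )
    results: list[tuple[tuple[str, ...], ...]] = []

    def rec(i: int, chains: list[list[dict]]):
        if i == len(records):
            results.append(
                tuple(sorted(tuple(r["aih_number"] for r in c) for c in chains))
            )
            return
        r = records[i]
        for c in chains:
            if _ok_pair(c[-1], r):
                c.append(r)
                rec(i + 1, chains)
                c.pop()
        chains.append([r])
        rec(i + 1, chains)
        chains.pop()

    rec(0, [])
    return results


def maximal_partitions(records: list[dict]) -> set[tuple[tuple[str, ...], ...]]:
    """Valid partitions where no chain could still continue another.

    Concatenations must respect chronological order: chain ``b`` can only
    extend chain ``a`` when ``b`` starts at or after ``a``'s end in the
    (admission date, AIH number) sort order, the same order the enumeration
    consumes records in.
    """
    by_id = {r["aih_number"]: r for r in records}
    rank = {
        r["aih_number"]: i
        for i, r in enumerate(sorted(
            records,
            key=lambda r: (pd.Timestamp(r["admission_date"]), r["aih_number"])))
    }
    out = set()
    for part in enumerate_partitions(records):
        extendable = False
        for a in part:
            for b in part:
                if (a is not b and rank[b[0]] > rank[a[-1]]
                        and _ok_pair(by_id[a[-1]], by_id[b[0]])):
                    extendable = True
        if not extendable:
            out.add(part)
    return out
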