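"""Synthetic claims + reference-census generator with known ground truth.

Emulates the study design the pipeline is meant for: a 30-day obstetric
hospitalization census in a set of public and private hospitals (the
reference standard), paired with the two claims tables the admission-
authorization system produces — a reduced table (one row per AIH) and a
professional-acts table.  The generator controls, per condition and hospital
type, the probability that a true condition is coded (``record_sens``), the
probability a spurious code appears (``record_false_pos``), under-/over-
capture of whole stays, episode splitting through the continuing-stay billing
reason, and linkage-key corruption — so every pipeline stage has a known
truth to be checked against.

Evidence routing follows the codebook's channels: a recorded condition is
written through one channel chosen among those its criterion offers
(diagnosis field, primary procedure + act copy, professional act only for
blood transfusion, ICU stay-days or act for ICU), so the estimated
sensitivity of a criterion converges to ``record_sens`` for it.  With
``independent_channels=True`` every channel flips independently instead and
the expected flag sensitivity becomes the union 1 - prod(1 - p_channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .rulebook import CRITERION_NAMES, RuleBook, load_rulebook

__all__ = ["SimConfig", "GroundTruth", "SimResult", "generate",
           "expected_metrics", "evidence_union"]

HOSPITAL_TYPES = ("public", "private")

# defaults mirror the magnitudes the validation study reports: recording
# sensitivity / false-positive rate per condition and hospital type
_DEFAULT_RECORD_SENS = {
    "severe_preeclampsia": {"public": 0.393, "private": 0.337},
    "eclampsia": {"public": 0.202, "private": 0.313},
    "hellp_syndrome": {"public": 0.0, "private": 0.0},
    "abruptio_placentae": {"public": 0.426, "private": 0.255},
    "hemorrhage": {"public": 0.052, "private": 0.029},
    "uterine_rupture": {"public": 0.043, "private": 0.0},
    "ectopic_pregnancy": {"public": 0.935, "private": 0.902},
    "hysterectomy": {"public": 0.375, "private": 0.348},
    "laparotomy": {"public": 0.161, "private": 0.114},
    "transfusion": {"public": 0.460, "private": 0.616},
    "icu": {"public": 0.650, "private": 0.860},
}
_DEFAULT_FALSE_POS = {
    "severe_preeclampsia": {"public": 0.023, "private": 0.036},
    "eclampsia": {"public": 0.015, "private": 0.004},
    "hellp_syndrome": {"public": 0.0, "private": 0.0},
    "abruptio_placentae": {"public": 0.001, "private": 0.004},
    "hemorrhage": {"public": 0.010, "private": 0.017},
    "uterine_rupture": {"public": 0.0, "private": 0.001},
    "ectopic_pregnancy": {"public": 0.0, "private": 0.0},
    "hysterectomy": {"public": 0.0, "private": 0.0},
    "laparotomy": {"public": 0.0, "private": 0.001},
    "transfusion": {"public": 0.023, "private": 0.032},
    "icu": {"public": 0.003, "private": 0.006},
}
# per-stay prevalence of each condition in the census (order-of-magnitude
# from the study's morbidity frequencies spread over all stays)
_DEFAULT_PREVALENCE = {
    "severe_preeclampsia": 0.028,
    "eclampsia": 0.004,
    "hellp_syndrome": 0.005,
    "abruptio_placentae": 0.006,
    "hemorrhage": 0.022,
    "uterine_rupture": 0.001,
    "ectopic_pregnancy": 0.007,
    "hysterectomy": 0.002,
    "laparotomy": 0.007,
    "transfusion": 0.009,
    "icu": 0.011,
}

_REASON_PRIMARY_ICD = {
    "delivery": "O800",
    "abortion": "O039",
    "pregnancy_complication": "O219",
    "puerperium_complication": "O861",
}
_REASON_PROCEDURE = {
    "delivery": ("0310010012", "0411010034"),  # vaginal / cesarean
    "abortion": ("0411020021",),               # post-abortion curettage
    "pregnancy_complication": ("0303100044",),
    "puerperium_complication": ("0303100010",),
}
_DISCHARGE_TOKEN = {
    "routine": "1", "administrative": "5", "death": "4",
    "transfer": "3", "continuing_stay": "2", "blank": "",
}
_RACE_TOKENS = ("1", "2", "3", "4", "5")


def _norm_mix(mix: dict[str, float]) -> dict[str, float]:
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


@dataclass
class SimConfig:
    seed: int = 0
    n_hospitals_public: int = 50
    n_hospitals_private: int = 28
    episodes_per_hospital: int = 430
    condition_prevalence: dict = dc_field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    record_sens: dict = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_RECORD_SENS.items()})
    record_false_pos: dict = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_FALSE_POS.items()})
    p_undercapture: dict = dc_field(
        default_factory=lambda: {"public": 0.0, "private": 0.145})
    p_overcapture: dict = dc_field(
        default_factory=lambda: {"public": 0.002, "private": 0.0})
    p_split: float = 0.02
    p_key_corrupt: dict = dc_field(
        default_factory=lambda: {"dob": 0.0, "admission_date": 0.0,
                                 "discharge_date": 0.0, "race_color": 0.03,
                                 "postcode": 0.05})
    reason_mix: dict = dc_field(
        default_factory=lambda: {"delivery": 0.725, "abortion": 0.088,
                                 "pregnancy_complication": 0.165,
                                 "puerperium_complication": 0.022})
    discharge_mix: dict = dc_field(
        default_factory=lambda: {"routine": 0.971, "administrative": 0.013,
                                 "death": 0.001, "transfer": 0.015})
    p_reason_missing: float = 0.005
    p_background: float = 0.03  # non-eligible / non-obstetric noise rows
    #: probability a stay deliberately reuses another patient's date of birth
    #: at the same hospital, to measure the (CNES, dob) person-key collision
    #: risk; 0 keeps person keys unique so ground truth is exact
    p_person_collision: float = 0.0
    p_act_copy: float = 0.9     # primary procedure echoed in the acts table
    independent_channels: bool = False
    concentrate_field: dict = dc_field(default_factory=dict)  # criterion -> field

    def validate(self) -> None:
        for name, p in [("p_split", self.p_split),
                        ("p_reason_missing", self.p_reason_missing),
                        ("p_background", self.p_background)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for d in (self.p_undercapture, self.p_overcapture, self.p_key_corrupt,
                  self.condition_prevalence):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"proportion {k}={v} outside [0, 1]")
        for mix in (self.reason_mix, self.discharge_mix):
            if not mix or any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
                raise ValueError("mix distributions must be nonnegative, nonzero")


def _rate(table: dict, criterion: str, htype: str) -> float:
    v = table.get(criterion, 0.0)
    if isinstance(v, dict):
        return float(v[htype])
    return float(v)


def _routes(rb: RuleBook) -> dict[str, list[tuple]]:
    """Evidence routes per criterion: (channel, code) choices."""
    out: dict[str, list[tuple]] = {}
    for name, crit in rb.criteria.items():
        r: list[tuple] = []
        if crit.icd:
            r.append(("ICD", tuple(sorted(p.pattern for p in crit.icd))))
        if crit.procedures and name not in ("transfusion", "icu"):
            r.append(("PROC", tuple(sorted(crit.procedures))))
        if crit.procedures and name in ("transfusion", "icu"):
            r.append(("ACT", tuple(sorted(crit.procedures))))
        if crit.uses_icu_days:
            r.append(("ICU_DAYS", ()))
        out[name] = r
    return out


@dataclass
class GroundTruth:
    pairing: pd.DataFrame   # reference_id, aih_number (one row per claims AIH)
    captured: pd.DataFrame  # reference_id, captured bool
    expected: pd.DataFrame  # analytic sens/spec per criterion x stratum
    expected_coverage: dict[str, float]


@dataclass
class SimResult:
    reference: pd.DataFrame
    reduced: pd.DataFrame
    acts: pd.DataFrame
    truth: GroundTruth


def evidence_union(*probs: float) -> float:
    """Probability a flag is set by at least one independent channel."""
    out = 1.0
    for p in probs:
        out *= 1.0 - p
    return 1.0 - out


def expected_metrics(config: SimConfig, rb: RuleBook | None = None) -> GroundTruth:
    """Closed-form expectations implied by the configuration (no sampling)."""
    rb = rb or load_rulebook()
    routes = _routes(rb)
    rows = []
    for crit in CRITERION_NAMES:
        for htype in HOSPITAL_TYPES:
            p = _rate(config.record_sens, crit, htype)
            q = _rate(config.record_false_pos, crit, htype)
            n_routes = max(len(routes[crit]), 1)
            sens = evidence_union(*([p] * n_routes)) if config.independent_channels else p
            fp = evidence_union(*([q] * n_routes)) if config.independent_channels else q
            rows.append({"criterion": crit, "stratum": htype,
                         "expected_sens": sens, "expected_spec": 1.0 - fp})
    cov = {
        htype: 100.0 * (1.0 - config.p_undercapture.get(htype, 0.0)
                        + config.p_overcapture.get(htype, 0.0))
        for htype in HOSPITAL_TYPES
    }
    return GroundTruth(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(rows), cov)


def _empty_aih(rb: RuleBook) -> dict:
    row = {f: None for f in rb.diagnosis_fields}
    row.update(icu_days=0, primary_procedure=None)
    return row


def generate(config: SimConfig, rb: RuleBook | None = None) -> SimResult:
    """Draw the reference census, the paired claims tables and ground truth.

    Deterministic in ``config.seed``: the same configuration yields
    byte-identical tables.
    """
    config.validate()
    rb = rb or load_rulebook()
    routes = _routes(rb)
    rng = np.random.default_rng(config.seed)

    reason_mix = _norm_mix(config.reason_mix)
    discharge_mix = _norm_mix(config.discharge_mix)
    reason_cats = sorted(reason_mix)
    reason_p = [reason_mix[c] for c in reason_cats]
    discharge_cats = sorted(discharge_mix)
    discharge_p = [discharge_mix[c] for c in discharge_cats]
    secondary_fields = [f for f in rb.diagnosis_fields if f != "diag_primary"]

    hospitals = [("public", f"1{i:06d}") for i in range(config.n_hospitals_public)]
    hospitals += [("private", f"2{i:06d}") for i in range(config.n_hospitals_private)]

    ref_rows: list[dict] = []
    aih_rows: list[dict] = []
    act_rows: list[dict] = []
    pairing: list[dict] = []
    captured_rows: list[dict] = []
    ref_seq = 0
    aih_seq = 0
    base = date(2021, 11, 1)

    def next_aih() -> str:
        nonlocal aih_seq
        aih_seq += 1
        return f"{aih_seq:013d}"

    def record_evidence(crit: str, episode_aihs: list[dict], aih_ids: list[str]) -> None:
        """Write one condition's evidence through one of its channels."""
        chans = routes[crit]
        if chans:
            _write_channel(chans[int(rng.integers(len(chans)))],
                           episode_aihs, aih_ids, crit)

    def emit_claims(htype: str, cnes: str, admission: date, discharge: date,
                    dob: date, race: str, postcode: str, reason: str,
                    discharge_cat: str, flags: dict[str, bool],
                    reference_id: str | None) -> None:
        # linkage-key corruption (claims side, whole episode)
        if (rng.random() < config.p_key_corrupt.get("dob", 0.0)
                and (admission - dob).days > 12 * 365):
            # shift keeps the woman inside the eligible age band
            dob = dob + timedelta(days=int(rng.integers(40, 400)))
        if rng.random() < config.p_key_corrupt.get("admission_date", 0.0):
            admission = admission + timedelta(days=int(rng.integers(2, 6)))
            discharge = max(discharge, admission)
        if rng.random() < config.p_key_corrupt.get("discharge_date", 0.0):
            discharge = discharge + timedelta(
                days=1 if rng.random() < 0.5 else int(rng.integers(2, 6)))
        if rng.random() < config.p_key_corrupt.get("race_color", 0.0):
            race = _RACE_TOKENS[int(rng.integers(len(_RACE_TOKENS)))]
        if rng.random() < config.p_key_corrupt.get("postcode", 0.0):
            postcode = "".join(str(d) for d in rng.integers(0, 10, 8))

        split = rng.random() < config.p_split and (discharge - admission).days >= 1
        n_aih = 2 if split else 1
        aih_ids = [next_aih() for _ in range(n_aih)]
        episode: list[dict] = []
        last_token = _DISCHARGE_TOKEN[discharge_cat]
        if split:
            mid = admission + (discharge - admission) / 2
            gap = int(rng.integers(0, 2))  # successor 0 or 1 day later
            spans = [(admission, mid, "2"), (min(mid + timedelta(days=gap), discharge),
                                             discharge, last_token)]
        else:
            spans = [(admission, discharge, last_token)]
        for (adm, dis, token), aih_id in zip(spans, aih_ids):
            row = _empty_aih(rb)
            row.update(
                aih_number=aih_id, cnes=cnes, aih_type=1, dob=dob.isoformat(),
                age="", sex="F", race_color=race, postcode=postcode,
                admission_date=adm.isoformat(), discharge_date=dis.isoformat(),
                billing_reason=token,
            )
            episode.append(row)
        # reason-consistent primary diagnosis and procedure on the first AIH
        episode[0]["diag_primary"] = _REASON_PRIMARY_ICD[reason]
        procs = _REASON_PROCEDURE[reason]
        proc = procs[int(rng.integers(len(procs)))]
        episode[0]["primary_procedure"] = proc
        if rng.random() < config.p_act_copy:
            act_rows.append({"aih_number": aih_ids[0], "procedure": proc})

        for crit in CRITERION_NAMES:
            p = _rate(config.record_sens, crit, htype)
            q = _rate(config.record_false_pos, crit, htype)
            if config.independent_channels:
                for channel in routes[crit]:
                    prob = p if flags[crit] else q
                    if rng.random() < prob:
                        _write_channel(channel, episode, aih_ids, crit)
            else:
                prob = p if flags[crit] else q
                if rng.random() < prob:
                    record_evidence(crit, episode, aih_ids)
        aih_rows.extend(episode)
        if reference_id is not None:
            pairing.extend({"reference_id": reference_id, "aih_number": a}
                           for a in aih_ids)

    def _write_channel(channel_spec: tuple, episode: list[dict],
                       aih_ids: list[str], crit: str) -> None:
        channel, codes = channel_spec
        tgt = int(rng.integers(len(episode)))
        if channel == "ICD":
            field_name = config.concentrate_field.get(
                crit, secondary_fields[int(rng.integers(len(secondary_fields)))])
            episode[tgt][field_name] = codes[int(rng.integers(len(codes)))]
        elif channel == "PROC":
            code = codes[int(rng.integers(len(codes)))]
            episode[-1]["primary_procedure"] = code
            act_rows.append({"aih_number": aih_ids[-1], "procedure": code})
        elif channel == "ACT":
            code = codes[int(rng.integers(len(codes)))]
            act_rows.append({"aih_number": aih_ids[tgt], "procedure": code})
        elif channel == "ICU_DAYS":
            episode[tgt]["icu_days"] = int(rng.integers(1, 11))

    for htype, cnes in hospitals:
        window_start = base + timedelta(days=int(rng.integers(0, 90)))
        n_stays = config.episodes_per_hospital
        used_dobs: set[str] = set()

        def draw_dob(admission: date) -> date:
            for _ in range(64):
                age_days = int(rng.integers(10 * 365, 49 * 365)) + int(rng.integers(0, 330))
                dob = admission - timedelta(days=min(age_days, 49 * 365 + 300))
                if dob.isoformat() not in used_dobs:
                    break
            used_dobs.add(dob.isoformat())
            return dob

        for _ in range(n_stays):
            ref_seq += 1
            reference_id = f"R{ref_seq:07d}"
            admission = window_start + timedelta(days=int(rng.integers(0, 30)))
            los = 1 + int(rng.poisson(1.8))
            discharge = admission + timedelta(days=los)
            if used_dobs and rng.random() < config.p_person_collision:
                dob = date.fromisoformat(sorted(used_dobs)[int(rng.integers(len(used_dobs)))])
            else:
                dob = draw_dob(admission)
            race = _RACE_TOKENS[int(rng.integers(len(_RACE_TOKENS)))]
            postcode = "".join(str(d) for d in rng.integers(0, 10, 8))
            reason = reason_cats[int(rng.choice(len(reason_cats), p=reason_p))]
            discharge_cat = discharge_cats[int(rng.choice(len(discharge_cats),
                                                          p=discharge_p))]
            flags = {c: bool(rng.random() < config.condition_prevalence.get(c, 0.0))
                     for c in CRITERION_NAMES}
            reason_missing = rng.random() < config.p_reason_missing
            ref_rows.append({
                "reference_id": reference_id, "cnes": cnes, "hospital_type": htype,
                "dob": dob.isoformat(), "admission_date": admission.isoformat(),
                "discharge_date": discharge.isoformat(), "race_color": race,
                "postcode": postcode,
                "reason": "" if reason_missing else reason,
                "reason_missing": reason_missing,
                "discharge": discharge_cat,
                **{f"flag_{c}": flags[c] for c in CRITERION_NAMES},
            })
            captured = rng.random() >= config.p_undercapture.get(htype, 0.0)
            captured_rows.append({"reference_id": reference_id, "captured": captured})
            if captured:
                emit_claims(htype, cnes, admission, discharge, dob, race, postcode,
                            reason, discharge_cat, flags, reference_id)

        # spurious claims episodes with no reference stay
        n_extra = rng.binomial(n_stays, config.p_overcapture.get(htype, 0.0))
        for _ in range(int(n_extra)):
            admission = window_start + timedelta(days=int(rng.integers(0, 30)))
            discharge = admission + timedelta(days=1 + int(rng.poisson(1.8)))
            dob = draw_dob(admission)
            emit_claims(
                htype, cnes, admission, discharge, dob,
                _RACE_TOKENS[int(rng.integers(len(_RACE_TOKENS)))],
                "".join(str(d) for d in rng.integers(0, 10, 8)),
                reason_cats[int(rng.choice(len(reason_cats), p=reason_p))],
                discharge_cats[int(rng.choice(len(discharge_cats), p=discharge_p))],
                {c: False for c in CRITERION_NAMES}, None)

        # non-eligible noise: rows stage 1 / obstetric selection must reject
        n_bg = rng.binomial(n_stays, config.p_background)
        for _ in range(int(n_bg)):
            admission = window_start + timedelta(days=int(rng.integers(0, 30)))
            row = _empty_aih(rb)
            kind = int(rng.integers(3))
            row.update(
                aih_number=next_aih(), cnes=cnes, aih_type=5 if kind == 0 else 1,
                dob=(admission - timedelta(days=int(rng.integers(3650, 25000)))).isoformat(),
                age="", sex="M" if kind == 1 else "F",
                race_color=_RACE_TOKENS[int(rng.integers(5))],
                postcode="".join(str(d) for d in rng.integers(0, 10, 8)),
                admission_date=admission.isoformat(),
                discharge_date=(admission + timedelta(days=2)).isoformat(),
                billing_reason="1", diag_primary="J128",
                primary_procedure="0301010010",
            )
            if kind == 2:  # eligible woman, non-obstetric stay
                row["dob"] = (admission - timedelta(days=int(rng.integers(4000, 17000)))).isoformat()
            aih_rows.append(row)

    reduced_cols = ["aih_number", "cnes", "aih_type", "dob", "age", "sex",
                    "race_color", "postcode", "admission_date", "discharge_date",
                    "billing_reason", "primary_procedure", "icu_days",
                    *rb.diagnosis_fields]
    reduced = pd.DataFrame(aih_rows).reindex(columns=reduced_cols)
    reference = pd.DataFrame(ref_rows)
    acts = pd.DataFrame(act_rows, columns=["aih_number", "procedure"])
    truth = expected_metrics(config, rb)
    truth.pairing = pd.DataFrame(pairing, columns=["reference_id", "aih_number"])
    truth.captured = pd.DataFrame(captured_rows)
    return SimResult(reference, reduced, acts, truth)
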