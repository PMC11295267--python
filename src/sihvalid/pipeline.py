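"""End-to-end orchestration: ingest -> stage-1 filter -> episodes ->
obstetric selection -> acts join -> classification -> linkage -> metrics.

Each stage failure aborts with a stage-named error; the result carries the
flow accounting (how many records survived each stage) alongside every
intermediate table, so a run is auditable from raw AIH rows to the final
validity report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_episodes
from .episodes import EpisodeBuild, build_episodes, episode_summary
from .ingest import ActsJoin, attach_acts, read_acts, read_reduced, stage1_filter
from .linkage import DEFAULT_PASSES, LinkPass, LinkResult, deterministic_link, link_report
from .metrics import ReportBundle, stratified_report
from .rulebook import CRITERION_NAMES, RuleBook, load_rulebook

__all__ = ["RunConfig", "PipelineResult", "StageError", "read_reference",
           "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    reduced: object  # path or DataFrame
    acts: object
    reference: object
    rulebook: object | None = None  # path, mapping, or None for default
    sep: str = ","
    reduced_dictionary: dict | None = None
    acts_dictionary: dict | None = None
    out_dir: Path | None = None
    coverage_adequacy_pct: float = 90.0
    over_recording_pct: float = 110.0
    missingness_threshold_pct: float = 10.0
    passes: tuple[LinkPass, ...] = DEFAULT_PASSES


@dataclass
class PipelineResult:
    rulebook: RuleBook
    records: pd.DataFrame
    stage1_counts: dict
    build: EpisodeBuild
    acts: ActsJoin
    classified: pd.DataFrame
    obstetric: pd.DataFrame
    reference: pd.DataFrame
    link: LinkResult
    link_summary: dict
    reports: ReportBundle
    flow: dict
    quarantine: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_reference(source, sep: str = ",") -> pd.DataFrame:
    """Load the reference-standard census table (dates parsed, flags bool)."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    required = {"reference_id", "cnes", "hospital_type", "dob",
                "admission_date", "discharge_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    for col in ("dob", "admission_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    for col in df.columns:
        if col.startswith("flag_") or col == "reason_missing":
            if df[col].dtype == object:
                df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
            else:
                df[col] = df[col].astype(bool)
    return df


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage on the configured inputs and emit the report bundle."""
    rb = _stage("rulebook")(load_rulebook)(config.rulebook)

    @_stage("ingest")
    def _ingest():
        red = read_reduced(config.reduced, rb, config.reduced_dictionary, config.sep)
        act = read_acts(config.acts, config.acts_dictionary, config.sep)
        ref = read_reference(config.reference, config.sep)
        return red, act, ref

    red_result, act_result, reference = _ingest()
    if reference.empty:
        raise StageError("stage 'ingest' failed: reference table is empty")

    records, stage1_counts = _stage("stage1-filter")(stage1_filter)(red_result.records)
    build = _stage("episode-builder")(build_episodes)(records)
    acts = _stage("acts-join")(attach_acts)(records, act_result.records)
    classified = _stage("classification")(classify_episodes)(records, build, acts, rb)
    obstetric = classified[classified["is_obstetric"]].reset_index(drop=True)

    @_stage("linkage")
    def _link():
        res = deterministic_link(
            obstetric[["episode_id", "cnes", "dob", "admission_date",
                       "discharge_date", "race_color", "postcode"]],
            reference, config.passes)
        return res, link_report(res, len(obstetric), len(reference))

    link, link_summary = _link()

    reports = _stage("metrics")(stratified_report)(
        obstetric, reference, link.pairs, CRITERION_NAMES,
        missingness_threshold_pct=config.missingness_threshold_pct)

    flag_cols = [f"flag_{c}" for c in CRITERION_NAMES]
    morbid_ids = set(reference.loc[reference[flag_cols].any(axis=1), "reference_id"])
    flow = {
        "aihs_read": int(len(red_result.records) + len(red_result.quarantine)),
        "aihs_parsed": int(len(red_result.records)),
        "aihs_quarantined": int(len(red_result.quarantine)),
        "stage1_kept": int(len(records)),
        "stage1_exclusions": stage1_counts,
        **episode_summary(build),
        "obstetric_episodes": int(len(obstetric)),
        "acts_orphans": acts.orphan_count,
        "reference_stays": int(len(reference)),
        "reference_morbidity_stays": len(morbid_ids),
        "linked_pairs": int(len(link.pairs)),
        "linked_morbidity_pairs": int(
            link.pairs["reference_id"].isin(morbid_ids).sum()),
    }

    result = PipelineResult(
        rulebook=rb, records=records, stage1_counts=stage1_counts, build=build,
        acts=acts, classified=classified, obstetric=obstetric,
        reference=reference, link=link, link_summary=link_summary,
        reports=reports, flow=flow, quarantine=red_result.quarantine)

    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir), config)
    return result


def _write_outputs(result: PipelineResult, out: Path, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.build.episodes.to_csv(out / "episodes.csv", index=False)
    result.build.crosswalk.to_csv(out / "episode_crosswalk.csv", index=False)
    result.classified.to_csv(out / "classification.csv", index=False)
    result.link.pairs.to_csv(out / "link_pairs.csv", index=False)
    result.quarantine.to_csv(out / "quarantine.csv", index=False)
    r = result.reports
    r.coverage.to_csv(out / "coverage.csv", index=False)
    r.per_hospital_coverage.to_csv(out / "per_hospital_coverage.csv", index=False)
    r.reason_table.to_csv(out / "reason_table.csv")
    r.discharge_table.to_csv(out / "discharge_table.csv")
    r.validity_table.to_csv(out / "validity_table.csv", index=False)
    with open(out / "flow.json", "w", encoding="utf-8") as fh:
        json.dump(result.flow, fh, indent=2, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "linkage_passes": [
            {"keys": list(p.keys), "discharge_tolerance_days": p.discharge_tolerance_days}
            for p in config.passes],
        "thresholds": {
            "coverage_adequacy_pct": config.coverage_adequacy_pct,
            "over_recording_pct": config.over_recording_pct,
            "missingness_threshold_pct": config.missingness_threshold_pct,
        },
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
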