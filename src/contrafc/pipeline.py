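"""End-to-end orchestration: manifest -> preprocessing -> matrices -> scores
-> group table.

A cohort manifest lists, per subject, the surgery group, lesion side, one
pre-operative scan and one or more post-operative scans (each scan holding
one or more run files).  When several post-operative scans exist the most
recent one is analysed (longest interval after surgery); ties break on the
lexicographically smallest scan identifier.  Runs failing quality control
drop the whole subject, with the reason logged — never silently.

Everything here is deterministic: identical inputs and configuration yield
byte-identical output tables.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import ROITable, contralesional_indices, load_roi_table
from .compare import HEMISPHERE, PairScore, build_partition, score_subject
from .connectivity import correlation_matrix, read_timeseries_tsv
from .errors import PipelineError, ValidationError
from .preprocess import PreprocessParams, TimeSeriesRun, preprocess_run
from .simulate import Cohort
from .stats import build_results_table


@dataclass(frozen=True)
class ScanEntry:
    """One scan: identifier, acquisition date, and its run references."""

    scan_id: str
    date: _dt.date
    runs: tuple[str, ...]


@dataclass(frozen=True)
class SubjectEntry:
    """One manifest row: identity, grouping, and scan references."""

    subject_id: str
    group: str
    lesion_side: str
    pre: ScanEntry
    post: tuple[ScanEntry, ...]
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lesion_side not in ("L", "R"):
            raise ValidationError(
                f"subject {self.subject_id!r}: lesion_side must be 'L' or 'R'"
            )
        if len(self.post) < 1:
            raise ValidationError(
                f"subject {self.subject_id!r}: needs at least one post scan"
            )
        for scan in self.post:
            if scan.date < self.pre.date:
                raise ValidationError(
                    f"subject {self.subject_id!r}: post scan {scan.scan_id!r} "
                    f"predates the pre scan"
                )


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"unparseable scan date {value!r}") from exc


def _parse_scan(raw: Mapping) -> ScanEntry:
    return ScanEntry(
        scan_id=str(raw["scan_id"]),
        date=_parse_date(raw["date"]),
        runs=tuple(str(r) for r in raw["runs"]),
    )


def load_manifest(path) -> tuple[list[SubjectEntry], dict]:
    """Load a JSON cohort manifest; returns (subjects, top-level metadata)."""
    with open(path) as fh:
        raw = json.load(fh)
    meta = {k: v for k, v in raw.items() if k != "subjects"}
    subjects = []
    for entry in raw["subjects"]:
        post = entry["post"]
        if isinstance(post, Mapping):
            post = [post]
        subjects.append(
            SubjectEntry(
                subject_id=str(entry["subject_id"]),
                group=str(entry["group"]),
                lesion_side=str(entry["lesion_side"]),
                pre=_parse_scan(entry["pre"]),
                post=tuple(_parse_scan(s) for s in post),
                covariates=dict(entry.get("covariates", {})),
            )
        )
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject_id in manifest")
    return subjects, meta


def select_scan_pair(subject: SubjectEntry) -> tuple[ScanEntry, ScanEntry]:
    """The analysed pair: the pre scan and the most recent post scan.

    Ties on date break deterministically on the lexicographically smallest
    scan identifier.
    """
    chosen = min(subject.post, key=lambda s: (-s.date.toordinal(), s.scan_id))
    return subject.pre, chosen


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the end-to-end analysis, in one auditable place."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    corr2_mode: str = "full"
    tails: str = "one"
    alternative: str = "b_greater"
    group_a: str = "craniotomy"
    group_b: str = "LITT"
    adjust: str = "none"
    min_network_size: int = 3
    tr_seconds: float = 2.07

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pp = PreprocessParams(**raw.pop("preprocess", {}))
        return cls(preprocess=pp, **raw)


@dataclass
class SubjectLog:
    """Per-subject provenance: censoring and frame accounting."""

    subject_id: str
    included: bool
    reason: str = ""
    censored_fraction_pre: float = float("nan")
    censored_fraction_post: float = float("nan")
    frames_pre: int = 0
    frames_post: int = 0


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    results: pd.DataFrame
    logs: list[SubjectLog]
    excluded: list[str]


def _preprocess_scan(
    runs: Sequence[TimeSeriesRun], config: PipelineConfig
) -> tuple[list[TimeSeriesRun], float, bool, str]:
    """Preprocess every run of a scan; scan fails QC if any run fails."""
    out = []
    fractions = []
    for run in runs:
        cleaned, verdict = preprocess_run(run, config.preprocess)
        fractions.append(verdict.censored_fraction)
        if not verdict.passed:
            return [], max(fractions), False, (
                f"run {run.run_id!r}: {verdict.reason}"
            )
        out.append(cleaned)
    return out, max(fractions) if fractions else 0.0, True, ""


def analyze_subject(
    subject_id: str,
    lesion_side: str,
    pre_runs: Sequence[TimeSeriesRun],
    post_runs: Sequence[TimeSeriesRun],
    table: ROITable,
    config: PipelineConfig,
) -> tuple[list[PairScore], SubjectLog]:
    """Preprocess, correlate, truncate, and score one subject.

    Returns an empty score list when the subject is excluded by QC; the log
    carries the reason either way.
    """
    log = SubjectLog(subject_id=subject_id, included=False)
    pre_clean, frac_pre, ok_pre, reason_pre = _preprocess_scan(pre_runs, config)
    log.censored_fraction_pre = frac_pre
    if not ok_pre:
        log.reason = f"pre scan failed QC: {reason_pre}"
        return [], log
    post_clean, frac_post, ok_post, reason_post = _preprocess_scan(post_runs, config)
    log.censored_fraction_post = frac_post
    if not ok_post:
        log.reason = f"post scan failed QC: {reason_post}"
        return [], log

    pre_cm = correlation_matrix(pre_clean, table.roi_ids)
    post_cm = correlation_matrix(post_clean, table.roi_ids)
    log.frames_pre = pre_cm.n_frames_used
    log.frames_post = post_cm.n_frames_used

    indices = contralesional_indices(table, lesion_side)
    partition = build_partition(table, indices, min_size=config.min_network_size)
    scores = score_subject(
        subject_id, pre_cm, post_cm, indices, partition, mode=config.corr2_mode
    )
    log.included = True
    return scores, log


def _finalize(
    all_scores: list[PairScore],
    groups: dict[str, str],
    roi_counts: dict[str, int],
    logs: list[SubjectLog],
    config: PipelineConfig,
) -> PipelineResult:
    excluded = [log.subject_id for log in logs if not log.included]
    if not all_scores:
        raise PipelineError(
            "no subject survived preprocessing QC; nothing to compare"
        )
    scores_df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in all_scores],
            "group": [groups[s.subject_id] for s in all_scores],
            "network": [s.network for s in all_scores],
            "c": [s.c for s in all_scores],
        }
    )
    results = build_results_table(
        all_scores,
        groups,
        group_a=config.group_a,
        group_b=config.group_b,
        roi_counts=roi_counts,
        tails=config.tails,
        alternative=config.alternative,
        adjust=config.adjust,
    )
    return PipelineResult(scores=scores_df, results=results, logs=logs,
                          excluded=excluded)


def _roi_counts_for(table: ROITable, config: PipelineConfig) -> dict[str, int]:
    """Representative per-network ROI counts (left-hemisphere partition).

    Reported for reference in the results table; the per-subject partitions
    themselves depend on each lesion side.
    """
    idx = contralesional_indices(table, "R")
    partition = build_partition(table, idx, min_size=config.min_network_size)
    counts = {name: int(pos.size) for name, pos in partition.items()}
    counts[HEMISPHERE] = int(idx.size)
    return counts


def run_cohort(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on an in-memory synthetic cohort."""
    config = config or PipelineConfig()
    all_scores: list[PairScore] = []
    logs: list[SubjectLog] = []
    groups: dict[str, str] = {}
    for subject in cohort.subjects:
        groups[subject.subject_id] = subject.group
        try:
            scores, log = analyze_subject(
                subject.subject_id, subject.lesion_side,
                subject.pre_runs, subject.post_runs, cohort.table, config,
            )
        except ValidationError as exc:
            raise PipelineError(
                f"subject {subject.subject_id!r}: {exc}"
            ) from exc
        logs.append(log)
        all_scores.extend(scores)
    groups = {k: v for k, v in groups.items()
              if any(log.subject_id == k and log.included for log in logs)}
    roi_counts = _roi_counts_for(cohort.table, config)
    return _finalize(all_scores, groups, roi_counts, logs, config)


def run_pipeline(
    manifest_path,
    roi_table_path,
    config: PipelineConfig | None = None,
    midline: str = "error",
) -> PipelineResult:
    """Run the full analysis from on-disk manifest + ROI table + run TSVs."""
    config = config or PipelineConfig()
    table = load_roi_table(roi_table_path, midline=midline)
    subjects, meta = load_manifest(manifest_path)
    tr = float(meta.get("tr_seconds", config.tr_seconds))
    base = Path(manifest_path).parent

    all_scores: list[PairScore] = []
    logs: list[SubjectLog] = []
    groups: dict[str, str] = {}
    for subject in subjects:
        pre_scan, post_scan = select_scan_pair(subject)
        try:
            pre_runs = [
                read_timeseries_tsv(base / p, tr_seconds=tr, run_id=p)
                for p in pre_scan.runs
            ]
            post_runs = [
                read_timeseries_tsv(base / p, tr_seconds=tr, run_id=p)
                for p in post_scan.runs
            ]
            scores, log = analyze_subject(
                subject.subject_id, subject.lesion_side,
                pre_runs, post_runs, table, config,
            )
        except (OSError, ValidationError) as exc:
            raise PipelineError(
                f"subject {subject.subject_id!r}: {exc}"
            ) from exc
        logs.append(log)
        all_scores.extend(scores)
        if log.included:
            groups[subject.subject_id] = subject.group
    roi_counts = _roi_counts_for(table, config)
    return _finalize(all_scores, groups, roi_counts, logs, config)


def write_result(result: PipelineResult, outdir, header: dict | None = None) -> None:
    """Write scores/results TSVs plus a JSON log; stable byte-for-byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False,
                         float_format="%.10g")
    result.results.to_csv(outdir / "results.tsv", sep="\t", index=False,
                          float_format="%.10g")
    with open(outdir / "results.json", "w") as fh:
        json.dump(
            {"header": header or {},
             "comparisons": result.results.to_dict(orient="records")},
            fh, indent=2, sort_keys=True, allow_nan=True,
        )
        fh.write("\n")
    group_sizes = (
        result.scores[result.scores["network"] == HEMISPHERE]
        .groupby("group")["subject_id"].nunique().to_dict()
        if len(result.scores) else {}
    )
    log = {
        "header": header or {},
        "n_per_group": {k: int(v) for k, v in sorted(group_sizes.items())},
        "excluded": result.excluded,
        "subjects": [
            {
                "subject_id": s.subject_id,
                "included": s.included,
                "reason": s.reason,
                "censored_fraction_pre": s.censored_fraction_pre,
                "censored_fraction_post": s.censored_fraction_post,
                "frames_pre": s.frames_pre,
                "frames_post": s.frames_post,
            }
            for s in result.logs
        ],
    }
    with open(outdir / "pipeline_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
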