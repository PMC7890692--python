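"""CSV table dialects, schema validation, and the end-to-end pipeline runner.

All tables are UTF-8 CSV with a header row, "." decimal separator and times
in seconds from session start.  Readers validate schemas (column names,
types, status vocabularies) and raise :class:`SchemaError` naming the file
and offending column/row.  :func:`run_pipeline` chains
simulate -> preprocess -> features -> classify -> report with content-hash
stage caching recorded in a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    CVReport,
    evaluate_lopo,
    evaluate_repeated_kfold,
    majority_baseline,
    scheme_matrix,
)
from .config import RunConfig
from .features import extract_features
from .preprocess import STATUS_BLINK_INTERP, UniformTrace, preprocess_trace
from .simulate import (
    STATUS_AWAY,
    STATUS_BLINK,
    STATUS_MISSING,
    STATUS_VALID,
    GazeTrace,
    SutureTimeline,
    simulate_cohort,
)
from .stats import duration_t_test, render_report, report_json, summarize_groups

__all__ = [
    "SchemaError",
    "write_samples", "read_samples",
    "write_timelines", "read_timelines",
    "write_participants", "read_participants",
    "write_features", "read_features",
    "write_cv_reports",
    "run_pipeline",
]

log = logging.getLogger("gazemetrics")

_RAW_STATUS = {STATUS_VALID, STATUS_BLINK, STATUS_AWAY, STATUS_MISSING}
_DETAIL_STATUS = _RAW_STATUS | {STATUS_BLINK_INTERP}


class SchemaError(ValueError):
    """A table failed schema validation; the message names file and column."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_vocab(df: pd.DataFrame, col: str, vocab: set, path) -> None:
    bad = set(df[col].dropna().unique()) - vocab
    if bad:
        row = int(df.index[df[col].isin(bad)][0])
        raise SchemaError(
            f"{path}: column {col!r}, row {row}: unknown value(s) {sorted(bad)}"
        )


# ---------------------------------------------------------------- samples

def write_samples(path: str | Path, traces: list[GazeTrace]) -> None:
    df = pd.concat([tr.as_dataframe() for tr in traces], ignore_index=True)
    df.to_csv(path, index=False)


def read_samples(path: str | Path) -> list[GazeTrace]:
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "t", "pupil", "status"], path)
    _check_vocab(df, "status", _RAW_STATUS, path)
    traces = []
    for pid, sub in df.groupby("participant_id", sort=False):
        tr = GazeTrace(
            participant_id=str(pid),
            t=sub["t"].to_numpy(dtype=float),
            pupil=sub["pupil"].to_numpy(dtype=float),
            status=sub["status"].to_numpy(dtype="<U8"),
        )
        try:
            tr.validate()
        except ValueError as exc:
            raise SchemaError(f"{path}: participant {pid}: {exc}") from exc
        traces.append(tr)
    return traces


def write_processed(path: str | Path, utraces: dict[str, UniformTrace]) -> None:
    df = pd.concat([u.as_dataframe() for u in utraces.values()], ignore_index=True)
    df.to_csv(path, index=False)


def read_processed(path: str | Path, rate: float = 30.0) -> dict[str, UniformTrace]:
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "t", "pupil", "status_detail"], path)
    _check_vocab(df, "status_detail", _DETAIL_STATUS, path)
    out = {}
    for pid, sub in df.groupby("participant_id", sort=False):
        out[str(pid)] = UniformTrace(
            participant_id=str(pid),
            t0=float(sub["t"].iloc[0]),
            rate=rate,
            pupil=sub["pupil"].to_numpy(dtype=float),
            status=sub["status_detail"].to_numpy(dtype="<U16"),
        )
    return out


# -------------------------------------------------------------- timelines

def write_timelines(path: str | Path, timelines: list[SutureTimeline]) -> None:
    rows = []
    for tl in timelines:
        a, b = tl.away_interval if tl.away_interval else (np.nan, np.nan)
        for label, t0, t1 in tl.segments:
            rows.append(
                {
                    "participant_id": tl.participant_id,
                    "slot": tl.slot,
                    "suture_index": tl.suture_index,
                    "segment_label": label,
                    "t_start": t0,
                    "t_end": t1,
                    "success": tl.success,
                    "away_start": a,
                    "away_end": b,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timelines(
    path: str | Path, segment_vocab: set[str] | None = None
) -> list[SutureTimeline]:
    df = pd.read_csv(path)
    _check_columns(
        df,
        ["participant_id", "slot", "suture_index", "segment_label", "t_start",
         "t_end", "success"],
        path,
    )
    if segment_vocab is not None:
        _check_vocab(df, "segment_label", set(segment_vocab), path)
    out = []
    keys = df[["participant_id", "slot", "suture_index"]].drop_duplicates()
    for pid, slot, si in keys.itertuples(index=False):
        sub = df[
            (df["participant_id"] == pid)
            & (df["slot"] == slot)
            & (df["suture_index"] == si)
        ].sort_values("t_start")
        away = None
        if "away_start" in sub.columns and np.isfinite(sub["away_start"].iloc[0]):
            away = (float(sub["away_start"].iloc[0]), float(sub["away_end"].iloc[0]))
        tl = SutureTimeline(
            participant_id=str(pid),
            slot=int(slot),
            suture_index=int(si),
            segments=[
                (str(r.segment_label), float(r.t_start), float(r.t_end))
                for r in sub.itertuples()
            ],
            success=bool(sub["success"].iloc[0]),
            away_interval=away,
        )
        try:
            tl.validate()
        except ValueError as exc:
            raise SchemaError(f"{path}: suture ({pid}, {slot}, {si}): {exc}") from exc
        out.append(tl)
    return out


# ------------------------------------------------------------ participants

def write_participants(path: str | Path, participants: pd.DataFrame) -> None:
    participants.to_csv(path, index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "group"], path)
    _check_vocab(df, "group", {"novice", "expert"}, path)
    return df


# ---------------------------------------------------------------- features

def write_features(path: str | Path, suture_df: pd.DataFrame) -> None:
    suture_df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    from .features import SUTURE_FEATURE_COLUMNS

    df = pd.read_csv(
        path, dtype={"imputed_mask": str, "participant_id": str}
    )
    _check_columns(
        df,
        list(SUTURE_FEATURE_COLUMNS) + ["group", "participant_id", "slot",
                                        "suture_index", "imputed_mask"],
        path,
    )
    _check_vocab(df, "group", {"novice", "expert"}, path)
    return df


def write_segment_features(path: str | Path, segment_df: pd.DataFrame) -> None:
    segment_df.to_csv(path, index=False)


def read_segment_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(
        df,
        ["participant_id", "group", "slot", "suture_index", "segment_label",
         "apcps", "sdpcps", "imputed"],
        path,
    )
    return df


def write_cv_reports(path: str | Path, reports: list[CVReport]) -> None:
    recs = [rec for rep in reports for rec in rep.as_records()]
    pd.DataFrame(recs).to_csv(path, index=False)


# ---------------------------------------------------------------- pipeline

def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


STAGES = ("simulate", "preprocess", "features", "classify", "report")


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Run simulate -> preprocess -> features -> classify -> report.

    Each stage is skipped when its outputs exist and the hash of its inputs
    (config section + upstream files) matches the manifest from the previous
    run.  Returns the manifest, which records package version, seed, config
    hash and per-stage status.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _hash_obj(asdict(config)),
        "stages": {},
    }

    paths = {
        "samples": out / "samples.csv",
        "timelines": out / "timelines.csv",
        "participants": out / "participants.csv",
        "processed": out / "samples_processed.csv",
        "features": out / "features_suture.csv",
        "segment_features": out / "features_segment.csv",
        "cv_reports": out / "cv_reports.csv",
        "report_md": out / "report.md",
        "report_json": out / "report.json",
    }

    def stage(name: str, inputs_hash: str, outputs: list[Path], fn) -> None:
        entry = {"inputs_hash": inputs_hash, "outputs": [str(p) for p in outputs]}
        prev = previous.get(name)
        if (
            not force
            and prev
            and prev.get("inputs_hash") == inputs_hash
            and all(p.exists() for p in outputs)
        ):
            entry["status"] = "skipped"
            log.info("[%s] up to date; skipped", name)
        else:
            log.info("[%s] running", name)
            try:
                fn()
            except Exception as exc:
                entry["status"] = "failed"
                manifest["stages"][name] = entry
                manifest_path.write_text(json.dumps(manifest, indent=2))
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            entry["status"] = "ran"
        entry["outputs_hash"] = _hash_files([p for p in outputs if p.exists()])
        manifest["stages"][name] = entry

    # -- simulate
    sim_hash = _hash_obj(asdict(config.cohort))

    def _simulate():
        participants, traces, timelines = simulate_cohort(config.cohort)
        write_participants(paths["participants"], participants)
        write_samples(paths["samples"], traces)
        write_timelines(paths["timelines"], timelines)

    stage("simulate", sim_hash,
          [paths["participants"], paths["samples"], paths["timelines"]], _simulate)

    # -- preprocess
    pre_hash = _hash_obj(
        [asdict(config.preprocess), manifest["stages"]["simulate"]["outputs_hash"]]
    )

    def _preprocess():
        traces = read_samples(paths["samples"])
        timelines = read_timelines(paths["timelines"])
        utraces = {
            tr.participant_id: preprocess_trace(tr, timelines, config.preprocess)
            for tr in traces
        }
        write_processed(paths["processed"], utraces)

    stage("preprocess", pre_hash, [paths["processed"]], _preprocess)

    # -- features
    feat_hash = _hash_obj([manifest["stages"]["preprocess"]["outputs_hash"]])

    def _features():
        utraces = read_processed(paths["processed"], rate=config.preprocess.rate_hz)
        timelines = read_timelines(paths["timelines"])
        participants = read_participants(paths["participants"])
        groups = dict(zip(participants["participant_id"], participants["group"]))
        suture_df, segment_df, _ = extract_features(utraces, timelines, groups)
        write_features(paths["features"], suture_df)
        write_segment_features(paths["segment_features"], segment_df)

    stage("features", feat_hash,
          [paths["features"], paths["segment_features"]], _features)

    # -- classify
    cls_hash = _hash_obj(
        [asdict(config.classifier), list(config.schemes), config.include_lopo,
         manifest["stages"]["features"]["outputs_hash"]]
    )

    def _classify():
        suture_df = read_features(paths["features"])
        segment_df = read_segment_features(paths["segment_features"])
        reports: list[CVReport] = []
        for scheme in config.schemes:
            names = (
                [f"segment:{lb}" for lb in segment_df["segment_label"].unique()]
                if scheme == "segment"
                else [scheme]
            )
            for name in names:
                X, y, pids, use_pca = scheme_matrix(suture_df, name, segment_df)
                reports.append(
                    evaluate_repeated_kfold(X, y, config.classifier, name, use_pca)
                )
        if config.include_lopo:
            X, y, pids, _ = scheme_matrix(suture_df, "suture", segment_df)
            reports.extend(evaluate_lopo(X, y, pids, config.classifier))
        write_cv_reports(paths["cv_reports"], reports)

    stage("classify", cls_hash, [paths["cv_reports"]], _classify)

    # -- report
    rep_hash = _hash_obj(
        [manifest["stages"]["features"]["outputs_hash"],
         manifest["stages"]["classify"]["outputs_hash"]]
    )

    def _report():
        suture_df = read_features(paths["features"])
        timelines = read_timelines(paths["timelines"])
        summaries = summarize_groups(suture_df, timelines)
        t_res = duration_t_test(summaries)
        maj = majority_baseline(suture_df["group"].to_numpy())
        cv = pd.read_csv(paths["cv_reports"])
        reports = []
        for (scheme, left_out), sub in cv.groupby(
            ["scheme", cv["left_out"].fillna("")], sort=True
        ):
            reports.append(
                CVReport(
                    scheme=scheme,
                    means={r.metric: r.mean for r in sub.itertuples()},
                    ci_low={r.metric: r.ci_low for r in sub.itertuples()},
                    ci_high={r.metric: r.ci_high for r in sub.itertuples()},
                    n_folds_scored=int(sub["n_folds"].iloc[0]),
                    seed=int(sub["seed"].iloc[0]),
                    n_rows=int(sub["n_rows"].iloc[0]),
                    left_out=str(left_out) or None,
                )
            )
        paths["report_md"].write_text(render_report(summaries, reports, t_res, maj))
        paths["report_json"].write_text(report_json(summaries, reports, t_res, maj))

    stage("report", rep_hash, [paths["report_md"], paths["report_json"]], _report)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
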