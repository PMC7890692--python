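"""Baseline estimation, percentage change in pupil size (PCPS), and the
segment-/suture-level feature tables.

PCPS normalizes the pupil signal against a resting baseline::

    PCPS = (X - mu) / mu

where ``X`` is the measured pupil size and ``mu`` is the mean pupil size over
a 200-frame window immediately preceding the first suture of the task-board
slot (one baseline per slot — participants often begin a slot's second suture
straight after the first, so no per-suture window exists).

Per segment the pipeline extracts APCPS (mean PCPS) and SDPCPS (sample
standard deviation of PCPS, ddof=1); per suture it stacks the 10 APCPS and
10 SDPCPS values and appends the blink rate in blinks per minute of
on-microscope time, giving the 21-feature suture vector.  Segments with
fewer than two valued samples are marked missing and imputed from the mean
of the participant's other segments with the same label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig
from .preprocess import STATUS_BLINK_INTERP, UniformTrace
from .simulate import (
    STATUS_AWAY,
    STATUS_BLINK,
    STATUS_MISSING,
    STATUS_VALID,
    SutureTimeline,
)

__all__ = [
    "SlotBaseline",
    "BaselineError",
    "compute_baseline",
    "pcps",
    "segment_features",
    "blink_rate",
    "impute_missing",
    "assemble",
    "extract_features",
    "APCPS_COLUMNS",
    "SDPCPS_COLUMNS",
    "SUTURE_FEATURE_COLUMNS",
]

BASELINE_WINDOW_FRAMES = 200

APCPS_COLUMNS = tuple(f"apcps_{k:02d}" for k in range(1, 11))
SDPCPS_COLUMNS = tuple(f"sdpcps_{k:02d}" for k in range(1, 11))
#: canonical suture-level feature order: 10 APCPS, 10 SDPCPS, blink rate
SUTURE_FEATURE_COLUMNS = APCPS_COLUMNS + SDPCPS_COLUMNS + ("blink_rate",)


class BaselineError(ValueError):
    """No usable baseline window exists for a slot."""


@dataclass
class SlotBaseline:
    participant_id: str
    slot: int
    mu: float
    window: tuple[float, float]
    n_frames_used: int
    fallback: bool = False


def compute_baseline(
    trace: UniformTrace,
    slot: int,
    first_suture_start: float,
    window_frames: int = BASELINE_WINDOW_FRAMES,
    include_blink_interp: bool = False,
) -> SlotBaseline:
    """Mean pupil over the ``window_frames``-frame window ending at the
    slot's first suture start.

    Only measured (``valid``) frames contribute by default; blink-interpolated
    frames may be included via ``include_blink_interp``.  If the window holds
    no usable frame, the window slides back to end at the nearest preceding
    usable frame (flagged ``fallback``); if none exists anywhere, raises
    :class:`BaselineError`.
    """
    t = trace.t
    end = int(np.searchsorted(t, first_suture_start, side="left"))
    ok = trace.status == STATUS_VALID
    if include_blink_interp:
        ok |= trace.status == STATUS_BLINK_INTERP
    ok &= np.isfinite(trace.pupil)
    start = max(end - window_frames, 0)
    fallback = False
    if not ok[start:end].any():
        prior = np.nonzero(ok[:end])[0]
        if len(prior) == 0:
            raise BaselineError(
                f"no usable baseline frames before slot {slot} "
                f"(participant {trace.participant_id})"
            )
        end = int(prior[-1]) + 1
        start = max(end - window_frames, 0)
        fallback = True
    sel = ok[start:end]
    mu = float(trace.pupil[start:end][sel].mean())
    if mu <= 0:
        raise BaselineError(f"non-positive baseline for slot {slot}")
    return SlotBaseline(
        participant_id=trace.participant_id, slot=slot, mu=mu,
        window=(float(t[start]), float(t[end - 1]) if end > start else float(t[start])),
        n_frames_used=int(sel.sum()), fallback=fallback,
    )


def pcps(x, mu: float):
    """Percentage change in pupil size: ``(x - mu) / mu`` (dimensionless)."""
    if mu <= 0:
        raise ValueError("baseline mu must be > 0")
    return (np.asarray(x, dtype=float) - mu) / mu


def segment_features(
    pcps_values: np.ndarray, ddof: int = 1
) -> tuple[float, float] | None:
    """Mean and standard deviation of PCPS over a segment's valued samples.

    Returns ``None`` (a missing marker, consumed by :func:`impute_missing`)
    when fewer than two finite samples are available — one sample cannot
    support a spread estimate.
    """
    v = np.asarray(pcps_values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return None
    return float(v.mean()), float(v.std(ddof=ddof))


def blink_rate(
    status: np.ndarray,
    t: np.ndarray,
    span: tuple[float, float],
    rate_hz: float,
) -> float:
    """Blink events per minute of on-microscope time within ``span``.

    A blink is one contiguous run of blink-status samples regardless of
    duration; the denominator is the time spent not-away and not-missing
    (i.e. valid + blink time), per the away-frame exclusion rule.
    """
    a, b = span
    sel = (t >= a) & (t < b)
    st = np.asarray(status)[sel]
    if len(st) == 0:
        raise ValueError("span contains no samples")
    is_blink = np.isin(st, (STATUS_BLINK, STATUS_BLINK_INTERP))
    n_blinks = int(np.count_nonzero(is_blink[1:] & ~is_blink[:-1])) + int(is_blink[0])
    active = np.isin(st, (STATUS_VALID, STATUS_BLINK, STATUS_BLINK_INTERP))
    active_minutes = active.sum() / rate_hz / 60.0
    if active_minutes <= 0:
        raise ValueError("span has zero non-away time")
    return n_blinks / active_minutes


def _row_key(row: dict) -> tuple:
    return (row["participant_id"], row["slot"], row["suture_index"])


def impute_missing(suture_rows: list[dict]) -> list[dict]:
    """Replace missing per-segment (APCPS, SDPCPS) pairs by the mean over the
    participant's non-missing segments with the same label (any slot).

    Rows with a missing segment that has no donor anywhere for that
    participant are excluded with a warning.  Non-missing entries are never
    altered.
    """
    donors: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in suture_rows:
        if not row.get("success", True):
            continue
        for label, feat in zip(row["segment_labels"], row["segment_features"]):
            if feat is not None:
                donors.setdefault((row["participant_id"], label), []).append(feat)
    out = []
    for row in suture_rows:
        if not row.get("success", True):
            out.append(row)  # dropped later by assemble; nothing to impute
            continue
        feats = list(row["segment_features"])
        imputed = list(row.get("imputed_flags", [False] * len(feats)))
        ok = True
        for k, (label, feat) in enumerate(zip(row["segment_labels"], feats)):
            if feat is not None:
                continue
            pool = donors.get((row["participant_id"], label), [])
            if not pool:
                warnings.warn(
                    f"suture {_row_key(row)}: no donor segments for label "
                    f"{label!r}; row excluded"
                )
                ok = False
                break
            arr = np.asarray(pool, dtype=float)
            feats[k] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
            imputed[k] = True
        if ok:
            new = dict(row)
            new["segment_features"] = feats
            new["imputed_flags"] = imputed
            out.append(new)
    return out


def assemble(suture_rows: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the suture-level (21 features) and segment-level (2 features)
    tables from per-suture row dicts.

    Only successful sutures are kept; the number dropped is reported via a
    ``.attrs`` entry.  Duplicate (participant, slot, suture_index) keys raise.
    """
    seen = set()
    suture_recs, segment_recs = [], []
    n_dropped = 0
    for row in suture_rows:
        key = _row_key(row)
        if key in seen:
            raise ValueError(f"duplicate suture key {key}")
        seen.add(key)
        if not row["success"]:
            n_dropped += 1
            continue
        feats = row["segment_features"]
        if len(feats) != 10 or any(f is None for f in feats):
            raise ValueError(f"suture {key}: expected 10 complete segments")
        rec = {}
        for col, (ap, _sd) in zip(APCPS_COLUMNS, feats):
            rec[col] = ap
        for col, (_ap, sd) in zip(SDPCPS_COLUMNS, feats):
            rec[col] = sd
        rec["blink_rate"] = row["blink_rate"]
        rec["group"] = row["group"]
        rec["participant_id"] = row["participant_id"]
        rec["slot"] = row["slot"]
        rec["suture_index"] = row["suture_index"]
        rec["imputed_mask"] = "".join(
            "1" if f else "0" for f in row["imputed_flags"]
        )
        suture_recs.append(rec)
        for label, (ap, sd), imp in zip(
            row["segment_labels"], feats, row["imputed_flags"]
        ):
            segment_recs.append(
                {
                    "participant_id": row["participant_id"],
                    "group": row["group"],
                    "slot": row["slot"],
                    "suture_index": row["suture_index"],
                    "segment_label": label,
                    "apcps": ap,
                    "sdpcps": sd,
                    "imputed": bool(imp),
                }
            )
    suture_cols = list(SUTURE_FEATURE_COLUMNS) + [
        "group", "participant_id", "slot", "suture_index", "imputed_mask",
    ]
    segment_cols = [
        "participant_id", "group", "slot", "suture_index", "segment_label",
        "apcps", "sdpcps", "imputed",
    ]
    suture_df = pd.DataFrame(suture_recs, columns=suture_cols)
    segment_df = pd.DataFrame(segment_recs, columns=segment_cols)
    suture_df.attrs["n_dropped_unsuccessful"] = n_dropped
    return suture_df, segment_df


def extract_features(
    utraces: dict[str, UniformTrace],
    timelines: list[SutureTimeline],
    groups: dict[str, str],
    cohort_cfg: CohortConfig | None = None,
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SlotBaseline]]:
    """End-to-end feature extraction over preprocessed traces.

    ``groups`` maps participant id -> "novice"/"expert".  Returns the
    suture-level table, the segment-level table and the slot baselines used.
    """
    by_pid: dict[str, list[SutureTimeline]] = {}
    for tl in timelines:
        by_pid.setdefault(tl.participant_id, []).append(tl)

    rows: list[dict] = []
    baselines: list[SlotBaseline] = []
    for pid, tls in by_pid.items():
        ut = utraces[pid]
        tls = sorted(tls, key=lambda tl: tl.t_start)
        slot_first: dict[int, float] = {}
        for tl in tls:
            slot_first.setdefault(tl.slot, tl.t_start)
        slot_mu: dict[int, float] = {}
        for slot, start in sorted(slot_first.items()):
            bl = compute_baseline(ut, slot, start)
            baselines.append(bl)
            slot_mu[slot] = bl.mu
        t = ut.t
        valued = ut.valued_mask()
        for tl in tls:
            mu = slot_mu[tl.slot]
            series = pcps(ut.pupil, mu)
            feats = []
            for _label, a, b in tl.segments:
                sel = (t >= a) & (t < b) & valued
                feats.append(segment_features(series[sel], ddof=ddof))
            rows.append(
                {
                    "participant_id": pid,
                    "group": groups[pid],
                    "slot": tl.slot,
                    "suture_index": tl.suture_index,
                    "success": tl.success,
                    "segment_labels": [s[0] for s in tl.segments],
                    "segment_features": feats,
                    "imputed_flags": [False] * len(feats),
                    "blink_rate": blink_rate(
                        ut.status, t, (tl.t_start, tl.t_end), ut.rate
                    ),
                }
            )
    rows = impute_missing(rows)
    suture_df, segment_df = assemble(rows)
    return suture_df, segment_df, baselines
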