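"""Raw-trace conditioning: uniform 30 Hz resampling, blink interpolation,
zero-phase 4 Hz low-pass filtering, and event-log-driven away masking.

Blink gaps are bridged by linear interpolation and flagged ``blink_interp``
(a drop mode is available) because the pupil statistics downstream want a
continuous signal with blinks removed; away and missing gaps are never
bridged — their grid samples carry no value.  Filtering operates on each
contiguous valued run independently so no information leaks across an
off-microscope gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .config import PreprocessConfig
from .simulate import (
    STATUS_AWAY,
    STATUS_BLINK,
    STATUS_MISSING,
    STATUS_VALID,
    GazeTrace,
    SutureTimeline,
)

__all__ = [
    "UniformTrace",
    "STATUS_BLINK_INTERP",
    "resample_uniform",
    "lowpass",
    "mask_away",
    "preprocess_trace",
    "filter_gain",
]

STATUS_BLINK_INTERP = "blink_interp"

_STATUS_MAP = {
    STATUS_VALID: STATUS_VALID,
    STATUS_BLINK: STATUS_BLINK_INTERP,
    STATUS_AWAY: STATUS_AWAY,
    STATUS_MISSING: STATUS_MISSING,
}


@dataclass
class UniformTrace:
    """Uniformly sampled pupil signal with per-sample status detail
    (``valid | blink_interp | away | missing``)."""

    participant_id: str
    t0: float
    rate: float
    pupil: np.ndarray
    status: np.ndarray
    warnings_log: list[str] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.pupil)) / self.rate

    def valued_mask(self) -> np.ndarray:
        return np.isin(self.status, (STATUS_VALID, STATUS_BLINK_INTERP))

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "t": self.t,
                "pupil": self.pupil,
                "status_detail": self.status,
            }
        )


def resample_uniform(
    trace: GazeTrace, rate: float = 30.0, blink_mode: str = "interpolate"
) -> UniformTrace:
    """Linearly interpolate a trace onto a uniform grid at ``rate`` Hz.

    Grid points inside blink gaps are interpolated across the gap and flagged
    ``blink_interp`` (or left unvalued with ``blink_mode="drop"``); grid
    points inside away/missing gaps carry NaN.  Each grid point inherits the
    status of the raw inter-sample interval it falls into, which conserves
    gap durations to within one sample period.
    """
    if blink_mode not in ("interpolate", "drop"):
        raise ValueError("blink_mode must be 'interpolate' or 'drop'")
    valid = trace.status == STATUS_VALID
    if valid.sum() < 2:
        raise ValueError("resampling needs at least 2 valid samples")
    t0 = float(trace.t[0])
    n = int(np.floor((trace.t[-1] - t0) * rate)) + 1
    tg = t0 + np.arange(n) / rate
    values = np.interp(tg, trace.t[valid], trace.pupil[valid])
    idx = np.clip(np.searchsorted(trace.t, tg, side="right") - 1, 0, len(trace.t) - 1)
    raw_status = trace.status[idx]
    status = np.array([_STATUS_MAP[s] for s in raw_status], dtype="<U16")
    unvalued = ~np.isin(status, (STATUS_VALID, STATUS_BLINK_INTERP))
    if blink_mode == "drop":
        unvalued |= status == STATUS_BLINK_INTERP
        status[status == STATUS_BLINK_INTERP] = STATUS_BLINK
    values[unvalued] = np.nan
    return UniformTrace(
        participant_id=trace.participant_id, t0=t0, rate=rate,
        pupil=values, status=status,
    )


def filter_gain(freq_hz: float, cutoff_hz: float, rate_hz: float, order: int = 2) -> float:
    """Analytic amplitude gain of the zero-phase (forward-backward)
    digital Butterworth low-pass at ``freq_hz``.

    The bilinear-transform magnitude of an order-``n`` Butterworth is
    ``|H|^2 = 1 / (1 + (tan(pi f/fs) / tan(pi fc/fs))^(2n))``; applying the
    filter forward and backward squares the magnitude.
    """
    ratio = np.tan(np.pi * freq_hz / rate_hz) / np.tan(np.pi * cutoff_hz / rate_hz)
    return float(1.0 / (1.0 + ratio ** (2 * order)))


def _valued_runs(status: np.ndarray) -> list[tuple[int, int]]:
    mask = np.isin(status, (STATUS_VALID, STATUS_BLINK_INTERP))
    runs = []
    i, n = 0, len(status)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def lowpass(
    trace: UniformTrace, cutoff: float = 4.0, order: int = 2, min_run_s: float = 1.0
) -> UniformTrace:
    """Zero-phase Butterworth low-pass with unit DC gain, applied to each
    contiguous valued run independently (never across away/missing gaps).

    Runs shorter than ``min_run_s`` are passed through unfiltered and a
    warning record is appended to the output's ``warnings_log``.
    """
    if trace.rate <= 2 * cutoff:
        raise ValueError("sampling rate must exceed 2x the cutoff frequency")
    b, a = butter(order, cutoff, fs=trace.rate)
    padlen = 3 * max(len(a), len(b))
    min_run = max(int(round(min_run_s * trace.rate)), padlen + 1)
    out = trace.pupil.copy()
    logs = list(trace.warnings_log)
    for i, j in _valued_runs(trace.status):
        if j - i >= min_run:
            out[i:j] = filtfilt(b, a, trace.pupil[i:j], padtype="even", padlen=padlen)
        else:
            logs.append(
                f"run [{i}:{j}) shorter than the minimum filterable length; passed through"
            )
    return UniformTrace(
        participant_id=trace.participant_id, t0=trace.t0, rate=trace.rate,
        pupil=out, status=trace.status.copy(), warnings_log=logs,
    )


def mask_away(
    trace: UniformTrace, timelines: list[SutureTimeline]
) -> tuple[UniformTrace, int]:
    """Force samples inside logged away intervals (the event log's scissors
    gaps) to status ``away``; returns the trace and the count of samples
    newly excluded.  Intervals outside the trace span produce a warning."""
    t = trace.t
    status = trace.status.copy()
    pupil = trace.pupil.copy()
    n_excluded = 0
    for tl in timelines:
        if tl.participant_id != trace.participant_id or tl.away_interval is None:
            continue
        a, b = tl.away_interval
        if b <= t[0] or a > t[-1]:
            warnings.warn(
                f"away interval [{a:.2f}, {b:.2f}) outside trace span; ignored"
            )
            continue
        sel = (t >= a) & (t < b) & (status != STATUS_AWAY)
        n_excluded += int(sel.sum())
        status[sel] = STATUS_AWAY
        pupil[sel] = np.nan
    return (
        UniformTrace(
            participant_id=trace.participant_id, t0=trace.t0, rate=trace.rate,
            pupil=pupil, status=status, warnings_log=list(trace.warnings_log),
        ),
        n_excluded,
    )


def preprocess_trace(
    trace: GazeTrace,
    timelines: list[SutureTimeline],
    cfg: PreprocessConfig | None = None,
    blink_mode: str = "interpolate",
) -> UniformTrace:
    """Full conditioning chain: resample -> confirm away mask -> low-pass."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    ut = resample_uniform(trace, rate=cfg.rate_hz, blink_mode=blink_mode)
    ut, _ = mask_away(ut, timelines)
    return lowpass(ut, cutoff=cfg.cutoff_hz, order=cfg.filter_order,
                   min_run_s=cfg.min_filter_run_s)
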