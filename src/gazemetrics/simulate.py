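"""Synthetic eye-tracker cohort generator.

Produces monocular pupil-size traces, suture event timelines and participant
metadata with the statistical structure the downstream analysis assumes:

* two experience groups whose suture durations follow truncated-normal
  distributions and whose pupils show a tonic (group-level) plus phasic
  (segment-level) task-evoked dilation above a per-slot resting baseline;
* blinks as short (100-400 ms) signal-loss events occurring at a configured
  rate per minute of on-microscope time;
* an "away" gap at the end of every suture while the scissors are picked up;
* measurement noise containing an explicit above-2 Hz component, so the 4 Hz
  low-pass stage has measurable work to do;
* occasional unsuccessful sutures (fewer than 10 segments, flagged) and
  missing segments.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``CohortConfig.seed``, so a fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import CohortConfig, ConfigError, GroupParams

__all__ = [
    "GazeTrace",
    "SutureTimeline",
    "simulate_cohort",
    "simulate_suture",
    "simulate_durations",
    "simulate_illumination",
    "STATUS_VALID",
    "STATUS_BLINK",
    "STATUS_AWAY",
    "STATUS_MISSING",
]

STATUS_VALID = "valid"
STATUS_BLINK = "blink"
STATUS_AWAY = "away"
STATUS_MISSING = "missing"


@dataclass
class GazeTrace:
    """Time-ordered monocular pupil samples for one participant session.

    ``pupil`` is NaN exactly where ``status != "valid"``.
    """

    participant_id: str
    t: np.ndarray
    pupil: np.ndarray
    status: np.ndarray
    nominal_rate: float = 30.0

    def validate(self) -> None:
        if not (len(self.t) == len(self.pupil) == len(self.status)):
            raise ValueError("GazeTrace arrays must have equal length")
        if len(self.t) and not np.all(np.diff(self.t) > 0):
            raise ValueError("GazeTrace timestamps must be strictly increasing")
        valid = self.status == STATUS_VALID
        if np.any(~np.isfinite(self.pupil[valid])):
            raise ValueError("valid samples must carry a finite pupil value")
        if np.any(np.isfinite(self.pupil[~valid])):
            raise ValueError("non-valid samples must not carry a pupil value")

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "t": self.t,
                "pupil": self.pupil,
                "status": self.status,
            }
        )


@dataclass
class SutureTimeline:
    """Event-log entry for one attempted suture.

    ``segments`` is an ordered list of ``(label, t_start, t_end)`` with
    contiguous, non-overlapping half-open intervals ``[t_start, t_end)``;
    successful sutures have exactly 10.  ``away_interval`` records the logged
    off-microscope gap (scissors pick) inside the final segment, if any.
    """

    participant_id: str
    slot: int
    suture_index: int
    segments: list[tuple[str, float, float]]
    success: bool = True
    away_interval: tuple[float, float] | None = None

    @property
    def t_start(self) -> float:
        return self.segments[0][1]

    @property
    def t_end(self) -> float:
        return self.segments[-1][2]

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def validate(self) -> None:
        if self.success and len(self.segments) != 10:
            raise ValueError("successful sutures must have exactly 10 segments")
        for (_, a, b), (_, c, _d) in zip(self.segments, self.segments[1:]):
            if not (b > a):
                raise ValueError("segment t_end must exceed t_start")
            if abs(c - b) > 1e-9:
                raise ValueError("segments must be contiguous")
        _, a, b = self.segments[-1]
        if not (b > a):
            raise ValueError("segment t_end must exceed t_start")


def simulate_durations(
    params: GroupParams, n: int, rng: np.random.Generator, floor_s: float = 10.0
) -> np.ndarray:
    """Draw ``n`` suture durations from the group's truncated-normal model."""
    if params.duration_sd_s == 0:
        return np.full(n, max(params.duration_mean_s, floor_s))
    a = (floor_s - params.duration_mean_s) / params.duration_sd_s
    return truncnorm.rvs(
        a, np.inf, loc=params.duration_mean_s, scale=params.duration_sd_s,
        size=n, random_state=rng,
    )


def expected_duration(params: GroupParams, floor_s: float = 10.0) -> float:
    """Exact mean of the truncated-normal duration model (analytic)."""
    if params.duration_sd_s == 0:
        return max(params.duration_mean_s, floor_s)
    a = (floor_s - params.duration_mean_s) / params.duration_sd_s
    return float(
        truncnorm.mean(a, np.inf, loc=params.duration_mean_s, scale=params.duration_sd_s)
    )


def _place_blinks(
    total_s: float,
    rate_per_min: float,
    rng: np.random.Generator,
    dur_lo: float,
    dur_hi: float,
    min_gap_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Place non-overlapping blink intervals in ``[0, total_s)``.

    The blink count is Poisson(rate x time) exactly, and intervals are laid
    out with at least ``min_gap_s`` of open eye between them (a spacings
    construction), so that discretized status runs never merge and the
    blinks-per-minute estimator of the count is unbiased.
    """
    if rate_per_min <= 0 or total_s <= 0:
        return np.empty(0), np.empty(0)
    n = int(rng.poisson(rate_per_min / 60.0 * total_s))
    durs = np.empty(0)
    while n > 0:
        durs = rng.uniform(dur_lo, dur_hi, n)
        slack = total_s - durs.sum() - (n + 1) * min_gap_s
        if slack >= 0:
            break
        n -= 1
    if n == 0:
        return np.empty(0), np.empty(0)
    slack = total_s - durs.sum() - (n + 1) * min_gap_s
    u = np.sort(rng.uniform(0.0, slack, n))
    onsets = u + np.concatenate(([0.0], np.cumsum(durs)[:-1])) + min_gap_s * np.arange(1, n + 1)
    return onsets, durs


#: reference pupil size at which ``noise_sd`` is specified; measurement noise
#: scales proportionally with the baseline so relative precision is uniform
#: across participants (a 600-unit pupil is not measured more precisely in
#: relative terms than a 400-unit one)
NOISE_REF_BASELINE = 500.0


def _noise(
    n: int,
    tt: np.ndarray,
    cfg: CohortConfig,
    rng: np.random.Generator,
    baseline: float = NOISE_REF_BASELINE,
) -> np.ndarray:
    """White Gaussian noise plus one sinusoid above 2 Hz (random phase)."""
    sd = cfg.noise_sd * baseline / NOISE_REF_BASELINE
    out = rng.normal(0.0, sd, n)
    phase = rng.uniform(0.0, 2 * np.pi)
    out += sd * np.sin(2 * np.pi * cfg.high_freq_noise_hz * tt + phase)
    return out


def simulate_suture(
    group: GroupParams,
    cfg: CohortConfig,
    slot_baseline: float,
    t0: float,
    rng: np.random.Generator,
    participant_id: str = "P00",
    slot: int = 1,
    suture_index: int = 1,
    success: bool | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], SutureTimeline]:
    """Generate one suture's trace fragment ``(t, pupil, status)`` + timeline.

    The pupil model is ``baseline * (1 + tonic + phasic(segment)) + noise``;
    blinks are placed over the on-microscope part of the suture and an away
    gap covers the tail of the final (cutting) segment.
    """
    if slot_baseline <= 0:
        raise ConfigError("slot_baseline: must be > 0")
    fs = cfg.sampling_rate_hz
    dur = float(simulate_durations(group, 1, rng, cfg.duration_floor_s)[0])
    if success is None:
        success = bool(rng.uniform() >= cfg.p_failed_suture)
    n_seg = 10 if success else int(rng.integers(3, 10))
    fracs = rng.dirichlet(np.full(n_seg, cfg.segment_concentration))
    bounds = np.concatenate(([0.0], np.cumsum(fracs))) * dur
    bounds[-1] = dur
    n = max(int(round(dur * fs)), 2)
    tt = np.arange(n) / fs
    seg_idx = np.clip(np.searchsorted(bounds, tt, side="right") - 1, 0, n_seg - 1)
    amps = np.asarray(cfg.segment_phasic_amplitudes[:n_seg], dtype=float)
    tonic = group.pcps_offset
    if cfg.tonic_jitter_sd > 0:
        tonic = tonic + rng.normal(0.0, cfg.tonic_jitter_sd)
    pupil = slot_baseline * (1.0 + tonic + amps[seg_idx])
    pupil = pupil + _noise(n, tt, cfg, rng, baseline=slot_baseline)
    status = np.full(n, STATUS_VALID, dtype="<U8")

    # away gap (scissors pick) in the tail of the final segment
    away_len = min(cfg.away_gap_s, 0.8 * (bounds[-1] - bounds[-2]))
    active_end = dur - away_len
    away_interval = None
    if away_len > 0:
        status[tt >= active_end] = STATUS_AWAY
        away_interval = (t0 + active_end, t0 + dur)

    onsets, durs = _place_blinks(
        active_end, group.blink_rate_per_min, rng, cfg.blink_min_s, cfg.blink_max_s
    )
    for o, d in zip(onsets, durs):
        status[(tt >= o) & (tt < o + d)] = STATUS_BLINK

    if success and cfg.p_missing_segment > 0:
        for k in range(n_seg):
            if rng.uniform() < cfg.p_missing_segment:
                status[(seg_idx == k) & (status != STATUS_AWAY)] = STATUS_MISSING

    pupil[status != STATUS_VALID] = np.nan
    labels = cfg.segment_labels[:n_seg]
    segments = [
        (labels[k], t0 + bounds[k], t0 + bounds[k + 1]) for k in range(n_seg)
    ]
    timeline = SutureTimeline(
        participant_id=participant_id,
        slot=slot,
        suture_index=suture_index,
        segments=segments,
        success=success,
        away_interval=away_interval,
    )
    return (t0 + tt, pupil, status), timeline


def _rest_fragment(
    cfg: CohortConfig,
    slot_baseline: float,
    rate_per_min: float,
    t0: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-slot rest period at the resting baseline (feeds the 200-frame
    baseline window downstream)."""
    fs = cfg.sampling_rate_hz
    n = max(int(round(cfg.rest_s * fs)), 2)
    tt = np.arange(n) / fs
    pupil = slot_baseline + _noise(n, tt, cfg, rng, baseline=slot_baseline)
    status = np.full(n, STATUS_VALID, dtype="<U8")
    onsets, durs = _place_blinks(
        cfg.rest_s, rate_per_min, rng, cfg.blink_min_s, cfg.blink_max_s
    )
    for o, d in zip(onsets, durs):
        status[(tt >= o) & (tt < o + d)] = STATUS_BLINK
    pupil[status != STATUS_VALID] = np.nan
    return t0 + tt, pupil, status


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[pd.DataFrame, list[GazeTrace], list[SutureTimeline]]:
    """Generate a full cohort: participants table, one trace per participant,
    one timeline per attempted suture.

    Unsuccessful sutures are flagged (``success=False``), never deleted.
    Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate_hz

    roster: list[tuple[str, str]] = []
    roster += [(f"N{i + 1:02d}", "novice") for i in range(cfg.n_novices)]
    roster += [(f"E{i + 1:02d}", "expert") for i in range(cfg.n_experts)]

    part_rows = []
    traces: list[GazeTrace] = []
    timelines: list[SutureTimeline] = []
    for pid, grp in roster:
        group = cfg.group(grp)
        if grp == "expert":
            months_micro = float(np.round(rng.uniform(24, 240), 1))
            months_surg = float(np.round(months_micro + rng.uniform(12, 120), 1))
            tlx = float(np.round(rng.uniform(30, 70), 1))
        else:
            months_micro = 0.0
            months_surg = float(np.round(rng.uniform(0, 24), 1))
            tlx = float(np.round(rng.uniform(60, 110), 1))
        part_rows.append(
            {
                "participant_id": pid,
                "group": grp,
                "months_surgical": months_surg,
                "months_microsurgical": months_micro,
                "surg_tlx_total": tlx,
            }
        )

        base = rng.uniform(*cfg.pupil_baseline_range)
        t_cursor = 0.0
        frags: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for slot in range(1, cfg.slots + 1):
            slot_baseline = base * (1.0 + rng.uniform(-0.02, 0.02))
            frag = _rest_fragment(cfg, slot_baseline, group.blink_rate_per_min, t_cursor, rng)
            frags.append(frag)
            t_cursor = frag[0][-1] + 1.0 / fs
            for si in range(1, cfg.sutures_per_slot + 1):
                frag, tl = simulate_suture(
                    group, cfg, slot_baseline, t_cursor, rng,
                    participant_id=pid, slot=slot, suture_index=si,
                )
                frags.append(frag)
                timelines.append(tl)
                t_cursor = frag[0][-1] + 1.0 / fs
        trace = GazeTrace(
            participant_id=pid,
            t=np.concatenate([f[0] for f in frags]),
            pupil=np.concatenate([f[1] for f in frags]),
            status=np.concatenate([f[2] for f in frags]),
            nominal_rate=fs,
        )
        trace.validate()
        traces.append(trace)

    participants = pd.DataFrame(part_rows)
    return participants, traces, timelines


def simulate_illumination(
    trace: GazeTrace,
    rng: np.random.Generator,
    coupling: float = 0.0,
    level: float = 128.0,
    noise_sd: float = 8.0,
) -> np.ndarray:
    """Per-sample scene illumination (grayscale mean), by default independent
    of pupil size.

    ``coupling`` injects the centered pupil signal into the illumination
    series (coupling 1 with zero noise gives perfect correlation); the default
    0 emulates the evenly lit operating setup.
    """
    if len(trace.t) == 0:
        raise ValueError("trace must be nonempty")
    centered = np.where(
        np.isfinite(trace.pupil), trace.pupil - np.nanmean(trace.pupil), 0.0
    )
    illum = level + coupling * centered + noise_sd * rng.standard_normal(len(trace.t))
    return illum
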