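"""Baselines, PCPS, segment/suture feature extraction, imputation, blink
rate."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazemetrics.config import CohortConfig, GroupParams
from gazemetrics.features import (
    APCPS_COLUMNS,
    BaselineError,
    SUTURE_FEATURE_COLUMNS,
    assemble,
    blink_rate,
    compute_baseline,
    extract_features,
    impute_missing,
    pcps,
    segment_features,
)
from gazemetrics.preprocess import STATUS_BLINK_INTERP, UniformTrace, preprocess_trace
from gazemetrics.simulate import (
    STATUS_AWAY,
    STATUS_BLINK,
    STATUS_VALID,
    simulate_cohort,
)


def _uniform(values, status=None, rate=30.0):
    values = np.asarray(values, dtype=float)
    if status is None:
        status = np.full(len(values), STATUS_VALID, dtype="<U16")
    return UniformTrace(participant_id="P01", t0=0.0, rate=rate,
                        pupil=values, status=np.asarray(status, dtype="<U16"))


# ------------------------------------------------------------- baseline

def test_baseline_constant_window():
    ut = _uniform(np.full(300, 500.0))
    bl = compute_baseline(ut, slot=1, first_suture_start=10.0)
    assert bl.mu == pytest.approx(500.0)
    assert bl.n_frames_used == 200
    assert not bl.fallback


def test_baseline_ramp_gives_midpoint():
    # mean of an arithmetic sequence = midpoint of the window
    vals = np.concatenate([np.full(100, 400.0), np.linspace(400, 600, 200)])
    ut = _uniform(vals)
    bl = compute_baseline(ut, slot=1, first_suture_start=300 / 30.0)
    assert bl.mu == pytest.approx(np.linspace(400, 600, 200).mean())


def test_baseline_skips_blink_interpolated_by_default():
    status = np.array([STATUS_VALID] * 300, dtype="<U16")
    status[100:200] = STATUS_BLINK_INTERP
    vals = np.full(300, 500.0)
    vals[100:200] = 900.0  # corrupted interpolation values must not leak in
    bl = compute_baseline(_uniform(vals, status), 1, 300 / 30.0)
    assert bl.mu == pytest.approx(500.0)
    assert bl.n_frames_used == 100
    bl2 = compute_baseline(
        _uniform(vals, status), 1, 300 / 30.0, include_blink_interp=True
    )
    assert bl2.mu > 500.0


def test_baseline_fallback_to_preceding_window():
    status = np.array([STATUS_VALID] * 100 + [STATUS_AWAY] * 200, dtype="<U16")
    vals = np.where(status == STATUS_VALID, 480.0, np.nan)
    bl = compute_baseline(_uniform(vals, status), 1, 300 / 30.0)
    assert bl.fallback
    assert bl.mu == pytest.approx(480.0)
    all_away = np.full(300, STATUS_AWAY, dtype="<U16")
    with pytest.raises(BaselineError):
        compute_baseline(_uniform(np.full(300, np.nan), all_away), 1, 10.0)


# ----------------------------------------------------------------- pcps

def test_pcps_identities():
    assert pcps(500.0, 500.0) == pytest.approx(0.0)
    assert pcps(550.0, 500.0) == pytest.approx(0.10)
    assert pcps(450.0, 500.0) == pytest.approx(-0.10)
    with pytest.raises(ValueError):
        pcps(500.0, 0.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(c=st.floats(1e-3, 1e3), mu=st.floats(1.0, 1000.0),
       x=st.floats(0.0, 2000.0))
def test_pcps_scale_invariant(c, mu, x):
    assert pcps(c * x, c * mu) == pytest.approx(pcps(x, mu), rel=1e-9, abs=1e-9)


def test_mean_pcps_over_own_baseline_window_is_zero():
    vals = np.concatenate([np.linspace(480, 520, 200), np.full(100, 600.0)])
    ut = _uniform(vals)
    bl = compute_baseline(ut, 1, 200 / 30.0)
    window = pcps(vals[:200], bl.mu)
    assert abs(window.mean()) < 1e-9


# ----------------------------------------------------- segment features

def test_segment_features_values():
    assert segment_features(np.full(50, 0.05)) == pytest.approx((0.05, 0.0))
    ap, sd = segment_features(np.array([0.0, 0.1, 0.2]))
    assert ap == pytest.approx(0.1)
    assert sd == pytest.approx(0.1)  # sample SD (ddof=1)
    _, sd0 = segment_features(np.array([0.0, 0.1, 0.2]), ddof=0)
    assert sd0 == pytest.approx(0.081649658, abs=1e-8)
    assert segment_features(np.array([])) is None
    assert segment_features(np.array([0.1, np.nan])) is None  # one point


# ------------------------------------------------------------ blink rate

def _status_with_blinks(n, blink_slices, away_slices=()):
    st_ = np.full(n, STATUS_VALID, dtype="<U16")
    for sl in blink_slices:
        st_[sl] = STATUS_BLINK
    for sl in away_slices:
        st_[sl] = STATUS_AWAY
    return st_


def test_blink_rate_simple_and_away_exclusion():
    n = 1800  # 60 s at 30 Hz
    t = np.arange(n) / 30.0
    blinks = [slice(100 * k, 100 * k + 5) for k in range(5)]
    st_ = _status_with_blinks(n, blinks)
    assert blink_rate(st_, t, (0.0, 60.0), 30.0) == pytest.approx(5.0)
    st_ = _status_with_blinks(n, blinks, away_slices=[slice(900, 1800)])
    assert blink_rate(st_, t, (0.0, 60.0), 30.0) == pytest.approx(10.0)
    st_ = _status_with_blinks(n, [])
    assert blink_rate(st_, t, (0.0, 60.0), 30.0) == 0.0
    with pytest.raises(ValueError):
        blink_rate(_status_with_blinks(n, [], [slice(0, n)]), t, (0.0, 60.0), 30.0)


def test_blink_counted_once_per_contiguous_run():
    n = 300
    t = np.arange(n) / 30.0
    st_ = _status_with_blinks(n, [slice(50, 80)])  # one long blink
    assert blink_rate(st_, t, (0.0, 10.0), 30.0) == pytest.approx(6.0)


# ------------------------------------------------------------ imputation

def _row(pid, slot, si, feats, labels=None, success=True):
    labels = labels or [f"seg{k}" for k in range(len(feats))]
    return {
        "participant_id": pid, "group": "expert", "slot": slot,
        "suture_index": si, "success": success, "segment_labels": labels,
        "segment_features": feats, "imputed_flags": [False] * len(feats),
        "blink_rate": 4.0,
    }


def test_impute_mean_of_same_label_segments():
    donors = [
        _row("P1", s, 1, [(v, 0.01)] + [(0.0, 0.0)] * 9, labels=None)
        for s, v in ((1, 0.1), (2, 0.2), (3, 0.3))
    ]
    target = _row("P1", 4, 1, [None] + [(0.0, 0.0)] * 9)
    out = impute_missing(donors + [target])
    imputed = out[-1]["segment_features"][0]
    assert imputed[0] == pytest.approx(0.2)
    assert out[-1]["imputed_flags"][0]


def test_impute_identity_and_no_mutation_of_complete_rows():
    rows = [_row("P1", s, 1, [(0.1 * s, 0.01)] * 10) for s in (1, 2)]
    digest = hashlib.sha256(repr(rows).encode()).hexdigest()
    out = impute_missing(rows)
    assert hashlib.sha256(repr(out).encode()).hexdigest() == digest


def test_impute_disjoint_labels_use_their_own_pools():
    rows = [
        _row("P1", 1, 1, [(0.1, 0.01), (0.5, 0.02)] + [(0.0, 0.0)] * 8),
        _row("P1", 2, 1, [(0.3, 0.03), (0.7, 0.04)] + [(0.0, 0.0)] * 8),
        _row("P1", 3, 1, [None, None] + [(0.0, 0.0)] * 8),
    ]
    out = impute_missing(rows)
    f = out[-1]["segment_features"]
    # brute-force recomputation of the per-label donor means
    assert f[0] == pytest.approx(((0.1 + 0.3) / 2, (0.01 + 0.03) / 2))
    assert f[1] == pytest.approx(((0.5 + 0.7) / 2, (0.02 + 0.04) / 2))


def test_impute_no_donor_excludes_row_with_warning():
    rows = [_row("P1", 1, 1, [None] + [(0.0, 0.0)] * 9)]
    with pytest.warns(UserWarning, match="no donor"):
        out = impute_missing(rows)
    assert out == []


# -------------------------------------------------------------- assemble

def test_assemble_bookkeeping_109_sutures():
    rows = []
    k = 0
    for pid in range(12):
        for si in range(10):
            k += 1
            rows.append(
                _row(f"P{pid}", si + 1, (k % 2) + 1,
                     [(0.1, 0.01)] * 10, success=k > 11)
            )
    suture_df, segment_df = assemble(rows)
    assert len(suture_df) == 109
    assert len(segment_df) == 1090
    assert list(suture_df.columns[:21]) == list(SUTURE_FEATURE_COLUMNS)
    assert suture_df.attrs["n_dropped_unsuccessful"] == 11


def test_assemble_duplicate_key_raises_and_empty_ok():
    rows = [_row("P1", 1, 1, [(0.1, 0.01)] * 10)] * 2
    with pytest.raises(ValueError, match="duplicate"):
        assemble(rows)
    suture_df, segment_df = assemble([])
    assert suture_df.empty and segment_df.empty


# ----------------------------------------------- end-to-end recovery

def test_apcps_recovers_tonic_plus_phasic(fast_cohort_cfg):
    """Generative-model recovery: mean APCPS of segment k across sutures
    approaches the segment's phasic amplitude plus the group tonic offset."""
    cfg = fast_cohort_cfg
    participants, traces, timelines = simulate_cohort(cfg)
    uts = {tr.participant_id: preprocess_trace(tr, timelines) for tr in traces}
    groups = dict(zip(participants["participant_id"], participants["group"]))
    suture_df, _, _ = extract_features(uts, timelines, groups)
    for grp, offset in (("expert", 0.03), ("novice", 0.10)):
        sub = suture_df[suture_df["group"] == grp]
        for k, col in enumerate(APCPS_COLUMNS):
            expected = offset + cfg.segment_phasic_amplitudes[k]
            assert sub[col].mean() == pytest.approx(expected, abs=0.02)


def test_feature_scale_invariance_end_to_end(fast_cohort_cfg):
    """Multiplying the pupil trace by a constant leaves all PCPS features
    unchanged (the baseline scales with it)."""
    cfg = fast_cohort_cfg
    participants, traces, timelines = simulate_cohort(cfg)
    groups = dict(zip(participants["participant_id"], participants["group"]))
    uts = {tr.participant_id: preprocess_trace(tr, timelines) for tr in traces}
    df1, _, _ = extract_features(uts, timelines, groups)
    for tr in traces:
        tr.pupil = tr.pupil * 3.7
    uts2 = {tr.participant_id: preprocess_trace(tr, timelines) for tr in traces}
    df2, _, _ = extract_features(uts2, timelines, groups)
    pd.testing.assert_frame_equal(df1, df2, atol=1e-9, rtol=0)
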