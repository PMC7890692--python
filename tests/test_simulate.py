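"""Synthetic cohort generator: structure, determinism, parameter recovery."""

import io

import numpy as np
import pytest

from gazemetrics.config import CohortConfig, ConfigError, GroupParams
from gazemetrics.io import write_samples, write_timelines
from gazemetrics.simulate import (
    STATUS_AWAY,
    STATUS_BLINK,
    STATUS_VALID,
    expected_duration,
    simulate_cohort,
    simulate_durations,
    simulate_illumination,
    simulate_suture,
)

EXPERT = GroupParams(70.6, 14.9, 4.69, 0.03)


def _quiet_cfg(**kw):
    base = dict(
        p_failed_suture=0.0, p_missing_segment=0.0, seed=11, tonic_jitter_sd=0.0,
        expert=GroupParams(14, 3, 6, 0.03), novice=GroupParams(20, 5, 6, 0.10),
        slots=2, sutures_per_slot=2, n_novices=2, n_experts=2, rest_s=7.5,
    )
    base.update(kw)
    return CohortConfig(**base)


def test_cohort_structure_counts():
    cfg = CohortConfig(p_failed_suture=0.0, seed=5)
    participants, traces, timelines = simulate_cohort(cfg)
    assert len(traces) == 10
    assert len(timelines) == 10 * 6 * 2
    assert len(participants) == 10
    assert set(participants["group"]) == {"novice", "expert"}
    for tl in timelines:
        assert tl.success and len(tl.segments) == 10
        tl.validate()


def test_fixed_seed_is_byte_identical():
    cfg = _quiet_cfg()
    out = []
    for _ in range(2):
        _, traces, timelines = simulate_cohort(cfg)
        buf_s, buf_t = io.StringIO(), io.StringIO()
        write_samples(buf_s, traces)
        write_timelines(buf_t, timelines)
        out.append(buf_s.getvalue() + buf_t.getvalue())
    assert out[0] == out[1]


def test_trace_invariants(fast_cohort_cfg):
    _, traces, _ = simulate_cohort(fast_cohort_cfg)
    for tr in traces:
        assert np.all(np.diff(tr.t) > 0)
        valid = tr.status == STATUS_VALID
        assert np.all(np.isfinite(tr.pupil[valid]))
        assert not np.any(np.isfinite(tr.pupil[~valid]))


def test_expert_duration_mean_matches_configured():
    # law of large numbers against the direct average of drawn durations;
    # expert-group truncation at 10 s is a >4-sigma tail and negligible
    rng = np.random.default_rng(42)
    durs = simulate_durations(EXPERT, 10_000, rng)
    se = durs.std(ddof=1) / np.sqrt(len(durs))
    assert abs(durs.mean() - 70.6) < 2 * se


def test_timeline_duration_equals_drawn_duration():
    # the duration written into the timeline is the generative draw itself
    cfg = _quiet_cfg()
    rng = np.random.default_rng(0)
    (t, pupil, status), tl = simulate_suture(cfg.expert, cfg, 500.0, 100.0, rng)
    assert tl.t_start == pytest.approx(100.0)
    assert len(t) == pytest.approx(tl.duration * cfg.sampling_rate_hz, abs=1)
    assert tl.duration >= cfg.duration_floor_s


def test_zero_effects_give_constant_baseline_pupil():
    cfg = _quiet_cfg(
        noise_sd=0.0,
        segment_phasic_amplitudes=(0.0,) * 10,
        expert=GroupParams(14, 0.0, 0.0, 0.0),
    )
    rng = np.random.default_rng(1)
    (t, pupil, status), _ = simulate_suture(cfg.expert, cfg, 500.0, 0.0, rng)
    assert np.allclose(pupil[status == STATUS_VALID], 500.0)


def test_zero_blink_rate_gives_no_blink_samples():
    cfg = _quiet_cfg(expert=GroupParams(14, 3, 0.0, 0.03))
    rng = np.random.default_rng(1)
    (_, _, status), _ = simulate_suture(cfg.expert, cfg, 500.0, 0.0, rng)
    assert not np.any(status == STATUS_BLINK)


def test_phasic_amplitude_appears_in_segment_mean():
    # closed form: pupil over segment k averages baseline*(1 + tonic + a_k)
    amps = [0.0] * 10
    amps[4] = 0.1
    cfg = _quiet_cfg(
        noise_sd=0.0, segment_phasic_amplitudes=tuple(amps),
        expert=GroupParams(30, 0.0, 0.0, 0.02),
    )
    rng = np.random.default_rng(2)
    (t, pupil, status), tl = simulate_suture(cfg.expert, cfg, 500.0, 0.0, rng)
    label, a, b = tl.segments[4]
    sel = (t >= a) & (t < b) & (status == STATUS_VALID)
    mean_pcps = pupil[sel].mean() / 500.0 - 1.0
    assert mean_pcps == pytest.approx(0.1 + 0.02, abs=1e-9)


def test_empirical_blink_rate_converges():
    cfg = _quiet_cfg(expert=GroupParams(30, 0.0, 12.0, 0.0), away_gap_s=0.0)
    rng = np.random.default_rng(3)
    n_blinks, active_min = 0, 0.0
    for _ in range(400):
        (_, _, status), _ = simulate_suture(cfg.expert, cfg, 500.0, 0.0, rng)
        is_b = status == STATUS_BLINK
        n_blinks += int(np.count_nonzero(is_b[1:] & ~is_b[:-1])) + int(is_b[0])
        active_min += np.isin(status, (STATUS_VALID, STATUS_BLINK)).sum() / 30.0 / 60.0
    rate = n_blinks / active_min
    # Poisson count over ~200 active minutes: SE ~ sqrt(12/200) ~ 0.25
    assert rate == pytest.approx(12.0, abs=0.8)


def test_away_gap_in_final_segment():
    cfg = _quiet_cfg(away_gap_s=2.0)
    rng = np.random.default_rng(4)
    (t, _, status), tl = simulate_suture(cfg.expert, cfg, 500.0, 0.0, rng)
    assert tl.away_interval is not None
    a, b = tl.away_interval
    assert a >= tl.segments[-1][1] and b == pytest.approx(tl.t_end)
    assert np.all(status[t >= a] == STATUS_AWAY)


def test_unsuccessful_sutures_flagged_not_deleted():
    cfg = _quiet_cfg(p_failed_suture=1.0)
    _, _, timelines = simulate_cohort(cfg)
    assert len(timelines) == 4 * 2 * 2
    assert all(not tl.success for tl in timelines)
    assert all(len(tl.segments) < 10 for tl in timelines)


def test_invalid_config_error_names_field():
    with pytest.raises(ConfigError, match="p_failed_suture"):
        CohortConfig(p_failed_suture=1.5).validate()
    with pytest.raises(ConfigError, match="segment_labels"):
        CohortConfig(segment_labels=("a",) * 10).validate()
    with pytest.raises(ConfigError, match="slot_baseline"):
        simulate_suture(
            EXPERT, CohortConfig(), -1.0, 0.0, np.random.default_rng(0)
        )


def test_novice_truncation_shifts_mean_as_predicted():
    # the 10 s floor raises the novice mean by ~1.9 s; the sample mean must
    # track the analytic truncated-normal expectation, not drift further
    novice = GroupParams(168.8, 68.7, 4.68, 0.1)
    rng = np.random.default_rng(9)
    durs = simulate_durations(novice, 10_000, rng)
    mu = expected_duration(novice)
    assert 169.5 < mu < 172.0
    se = durs.std(ddof=1) / np.sqrt(len(durs))
    assert abs(durs.mean() - mu) < 3 * se


def test_illumination_independent_by_default(fast_cohort_cfg):
    from gazemetrics.eye_image import illumination_pupil_correlation

    _, traces, _ = simulate_cohort(fast_cohort_cfg)
    tr = traces[0]
    illum = simulate_illumination(tr, np.random.default_rng(5), coupling=0.0)
    rho = illumination_pupil_correlation(tr.pupil, illum)
    assert abs(rho) < 0.1


def test_illumination_full_coupling(fast_cohort_cfg):
    from gazemetrics.eye_image import illumination_pupil_correlation

    _, traces, _ = simulate_cohort(fast_cohort_cfg)
    tr = traces[0]
    illum = simulate_illumination(tr, np.random.default_rng(5), coupling=1.0, noise_sd=0.0)
    rho = illumination_pupil_correlation(tr.pupil, illum)
    assert rho == pytest.approx(1.0, abs=1e-9)
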