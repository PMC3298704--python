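"""Event-marker detection: baseline stats, persistence rule, end rule."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sptphase import (DetectionConfig, EventMarkers, EventNotFoundError,
                      SyntheticSpec, baseline_stats, detect_events,
                      generate_trial, preprocess_trial, resolve_end,
                      sustained_crossing)
from conftest import make_processed


class TestBaselineStats:
    def test_constant_series(self):
        b = baseline_stats(np.full(40, 5.0), 20)
        assert b.mean == 5.0 and b.sd == 0.0 and b.n == 20

    def test_alternating_series_sample_sd(self):
        series = np.tile([0.0, 1.0], 20)
        b = baseline_stats(series, 20)
        assert b.mean == pytest.approx(0.5)
        # 10 zeros + 10 ones: var = 20*0.25/19
        assert b.sd == pytest.approx(np.sqrt(5.0 / 19.0), abs=1e-12)

    def test_series_shorter_than_n_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            baseline_stats(np.zeros(10), 20)


def brute_force_crossing(series, threshold, direction, run, search_from=0):
    """O(n*run) reference scan over all candidate windows."""
    cond = (series > threshold) if direction == "above" else (series < threshold)
    for f in range(search_from, len(series) - run + 1):
        if all(cond[f:f + run]):
            return f
    return None


class TestSustainedCrossing:
    def test_simple_run_found(self):
        series = np.array([0, 0, 9, 9, 9, 0], dtype=float)
        f = sustained_crossing(series, 5.0, "above", hold_s=3.0, fs=1.0)
        assert f == 2

    def test_no_run_of_required_length(self):
        series = np.array([0, 9, 0, 9, 0, 9], dtype=float)
        with pytest.raises(EventNotFoundError):
            sustained_crossing(series, 5.0, "above", hold_s=2.0, fs=1.0)

    def test_window_truncated_by_trial_end_does_not_qualify(self):
        series = np.array([0, 0, 0, 9, 9], dtype=float)
        with pytest.raises(EventNotFoundError):
            sustained_crossing(series, 5.0, "above", hold_s=3.0, fs=1.0)

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(5, 120)
            series = rng.normal(size=n)
            thr = rng.normal(scale=0.5)
            run = int(rng.integers(1, 10))
            direction = "above" if rng.random() < 0.5 else "below"
            start = int(rng.integers(0, n))
            expected = brute_force_crossing(series, thr, direction, run, start)
            if expected is None:
                with pytest.raises(EventNotFoundError):
                    sustained_crossing(series, thr, direction, run, 1.0, start)
            else:
                got = sustained_crossing(series, thr, direction, run, 1.0,
                                         start)
                assert got == expected

    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=3,
                    max_size=60),
           st.integers(min_value=1, max_value=6))
    def test_property_equivalence_with_oracle(self, values, run):
        series = np.array(values, dtype=float)
        expected = brute_force_crossing(series, 0.0, "above", run)
        try:
            got = sustained_crossing(series, 0.0, "above", run, 1.0)
        except EventNotFoundError:
            got = None
        assert got == expected


class TestResolveEnd:
    def test_exact_plateau_found_at_its_first_frame(self):
        # quiet zero baseline, steep rise, then an exactly constant plateau
        fs, e4, k = 60.0, 60, 25
        x = np.concatenate([np.zeros(e4),
                            np.linspace(0, 700, k, endpoint=False),
                            np.full(120, 700.0)])
        cfg = DetectionConfig()
        assert resolve_end(x, e4, cfg, fs) == e4 + k

    def test_never_settling_ramp_not_found(self):
        x = np.linspace(0.0, 700.0, 240)
        with pytest.raises(EventNotFoundError, match="stabilize"):
            resolve_end(x, 30, DetectionConfig(), 60.0)

    def test_noisy_plateau_found_near_ramp_end(self, noisy_processed):
        proc, gt = noisy_processed
        cfg = DetectionConfig()
        e4 = round(gt.e4 * 60)
        f = resolve_end(proc.f_target_seat, e4, cfg, 60.0)
        assert abs(f - round(gt.e5 * 60)) <= 2


class TestDetectEvents:
    def test_noise_free_recovery_within_two_frames(self, noiseless_processed):
        proc, gt = noiseless_processed
        markers = detect_events(proc)
        true_frames = [round(t * 60) for t in gt.times]
        for got, want in zip(markers.frames, true_frames):
            assert abs(got - want) <= 2

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            EventMarkers(0.5, 0.4, 1.0, 1.5, 2.0)

    def test_never_lifting_subject_reports_e3_not_found(self):
        n = 400
        trail = np.zeros(n)
        trail[100:] = 100.0
        initial = np.full(n, 700.0)   # buttocks never leave the seat
        speed = np.zeros(n)
        speed[60:] = 0.5
        proc = make_processed(f_trailing=trail, f_initial=initial,
                              f_target=np.zeros(n), c7_speed=speed, n=n)
        with pytest.raises(EventNotFoundError) as exc:
            detect_events(proc)
        assert exc.value.event == "e3_liftpivot_start"

    def test_all_zero_target_seat_fails_at_landing(self):
        n = 400
        trail = np.zeros(n); trail[100:220] = 100.0
        initial = np.full(n, 700.0); initial[150:] = 0.0
        speed = np.zeros(n); speed[60:] = 0.5
        proc = make_processed(f_trailing=trail, f_initial=initial,
                              f_target=np.zeros(n), c7_speed=speed, n=n)
        with pytest.raises(EventNotFoundError) as exc:
            detect_events(proc)
        assert exc.value.event in ("e4_postlift_start", "e5_end")

    def test_threshold_fraction_monotonicity(self):
        """Raising the relative force threshold can only delay force-rise
        events (E2, E4) and advance the force-fall event (E3)."""
        lo, hi = DetectionConfig(), DetectionConfig(force_fraction=0.10)
        for seed in range(5):
            raw, _ = generate_trial(SyntheticSpec(seed=seed))
            proc = preprocess_trial(raw)
            m_lo = detect_events(proc, lo)
            m_hi = detect_events(proc, hi)
            assert m_hi.frames[1] >= m_lo.frames[1]
            assert m_hi.frames[3] >= m_lo.frames[3]
            assert m_hi.frames[2] <= m_lo.frames[2]

    def test_scale_and_translation_invariance(self, noisy_processed):
        """x10 force gain and a constant C7 offset change no detected event."""
        proc, _ = noisy_processed
        ref = detect_events(proc).frames
        scaled = dataclasses.replace(
            proc,
            f_trailing_hand=proc.f_trailing_hand * 10,
            f_initial_seat=proc.f_initial_seat * 10,
            f_target_seat=proc.f_target_seat * 10,
            c7_xyz=proc.c7_xyz + np.array([5.0, -3.0, 2.0]),
        )
        assert detect_events(scaled).frames == ref

    def test_timing_jitter_stability(self):
        """Shifting every true transition by one frame moves each detected
        event by at most two frames."""
        base = SyntheticSpec(noise_sd_N=0.0, marker_noise_sd_m=0.0, seed=6)
        shift = dataclasses.replace(base, baseline_s=base.baseline_s + 1 / 60)
        f_base = detect_events(preprocess_trial(generate_trial(base)[0])).frames
        f_shift = detect_events(preprocess_trial(generate_trial(shift)[0])).frames
        for a, b in zip(f_base, f_shift):
            assert abs((b - 1) - a) <= 2
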