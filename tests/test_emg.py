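"""EMG processing chain: rectification, baseline, detection, area, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imepmap import (DegenerateBaselineError, EMGTrace, PrestimStats,
                     SyntheticConfig, average_rectified, detect_imep,
                     imep_area, prestim_stats, pooled_prestim_stats, rectify,
                     rank_sites, simulate_trial, summarize_site)
from imepmap.emg import SiteSummary, check_background_stability

from conftest import FS, brute_force_detect, make_trace, step_trace


class TestRectify:
    def test_zero_trace_stays_zero(self):
        tr = make_trace(np.zeros(500))
        assert np.all(rectify(tr).samples == 0)

    def test_sign_flip_symmetry(self, rng):
        x = rng.normal(0, 10, 500)
        a = rectify(make_trace(x)).samples
        b = rectify(make_trace(-x)).samples
        assert np.allclose(a, b)

    def test_constant_trace_becomes_zero(self):
        # DC offset (prestimulus mean) removed before rectification
        tr = make_trace(np.full(500, 7.3))
        assert np.allclose(rectify(tr).samples, 0.0)

    def test_output_nonnegative(self, rng):
        tr = make_trace(rng.normal(-5, 20, 500))
        assert np.all(rectify(tr).samples >= 0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            EMGTrace(np.array([]), FS, 0)


class TestPrestimStats:
    def test_constant_baseline(self):
        tr = make_trace(np.full(520, 5.0))
        st_ = prestim_stats(tr, 100.0)
        assert st_.mean == 5.0 and st_.sd == 0.0

    def test_window_sample_count_at_2khz(self):
        # 100 ms at 2 kHz covers exactly 200 samples: constructing a trace
        # whose last 200 prestimulus samples are 1 and earlier ones 99
        x = np.full(520, 99.0)
        x[40:240] = 1.0
        st_ = prestim_stats(make_trace(x, stim=240), 100.0)
        assert st_.mean == 1.0 and st_.sd == 0.0

    def test_alternating_sequence_mean_and_sample_sd(self):
        x = np.zeros(520)
        x[40:240:2] = 10.0   # alternating 0/10 in the window
        st_ = prestim_stats(make_trace(x, stim=240), 100.0)
        vals = x[40:240]
        assert st_.mean == pytest.approx(vals.mean())
        assert st_.sd == pytest.approx(np.std(vals, ddof=1))
        assert st_.mean == pytest.approx(5.0)

    def test_window_longer_than_prestimulus_rejected(self):
        tr = make_trace(np.zeros(520), stim=100)
        with pytest.raises(ValueError):
            prestim_stats(tr, 100.0)


class TestDetectImep:
    def test_flat_at_mean_not_detected(self, flat_stats):
        tr = make_trace(np.full(520, flat_stats.mean))
        assert not detect_imep(tr, flat_stats).detected

    def test_square_burst_onset_offset(self, flat_stats):
        tr = step_trace(baseline=10, level=20, start_ms=20, stop_ms=45)
        res = detect_imep(tr, flat_stats)
        assert res.detected
        assert res.onset_ms == pytest.approx(20.0)
        assert res.offset_ms == pytest.approx(45.0)
        assert res.duration_ms == pytest.approx(25.0)

    def test_short_excursion_not_detected(self, flat_stats):
        # 4 ms above threshold is below the 5 ms minimum run
        tr = step_trace(start_ms=20, stop_ms=24)
        assert not detect_imep(tr, flat_stats).detected

    def test_five_ms_excursion_is_detected(self, flat_stats):
        tr = step_trace(start_ms=20, stop_ms=25)
        assert detect_imep(tr, flat_stats).detected

    def test_missing_offset_clamps_to_window_end(self, flat_stats):
        tr = step_trace(start_ms=20, stop_ms=200)   # never comes back down
        res = detect_imep(tr, flat_stats, search_window_ms=(10, 60))
        assert res.offset_ms == pytest.approx(60.0)

    def test_degenerate_window_rejected(self, flat_stats):
        tr = step_trace()
        with pytest.raises(ValueError):
            detect_imep(tr, flat_stats, search_window_ms=(60, 10))

    def test_agrees_with_brute_force_on_random_traces(self, rng):
        for _ in range(100):
            x = np.abs(rng.normal(10, 6, 520))
            tr = make_trace(x)
            st_ = prestim_stats(tr)
            res = detect_imep(tr, st_)
            oracle = brute_force_detect(x, FS, 240, st_.mean, st_.sd)
            if oracle is None:
                assert not res.detected
            else:
                assert res.detected
                assert res.onset_ms == pytest.approx(oracle[0])
                assert res.offset_ms == pytest.approx(oracle[1])


class TestImepArea:
    def test_window_at_baseline_mean_is_100_percent(self, flat_stats):
        # timing from a real excursion, area measured on a flat trace whose
        # window equals the baseline mean
        res = detect_imep(step_trace(baseline=10, level=20), flat_stats)
        rel = imep_area(step_trace(baseline=10, level=10), res, flat_stats)
        assert rel == pytest.approx(100.0)

    def test_window_at_twice_mean_is_200_percent(self, flat_stats):
        tr = step_trace(baseline=10, level=20, start_ms=20, stop_ms=45)
        res = detect_imep(tr, flat_stats)
        assert imep_area(tr, res, flat_stats) == pytest.approx(200.0)

    def test_zero_baseline_raises(self):
        tr = step_trace()
        res = detect_imep(tr, PrestimStats(10.0, 2.0))
        with pytest.raises(DegenerateBaselineError):
            imep_area(tr, res, PrestimStats(0.0, 0.0))

    def test_undetected_result_rejected(self, flat_stats):
        from imepmap import IMEPResult
        with pytest.raises(ValueError):
            imep_area(step_trace(), IMEPResult(False), flat_stats)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        # scaling the whole trace scales baseline and area alike
        rng = np.random.default_rng(5)
        x = np.abs(rng.normal(10, 4, 520))
        x[280:340] += 25.0
        tr1, tr2 = make_trace(x), make_trace(c * x)
        s1, s2 = prestim_stats(tr1), prestim_stats(tr2)
        r1, r2 = detect_imep(tr1, s1), detect_imep(tr2, s2)
        assert r1.detected and r2.detected
        assert r1.onset_ms == r2.onset_ms and r1.offset_ms == r2.offset_ms
        a1 = imep_area(tr1, r1, s1)
        a2 = imep_area(tr2, r2, s2)
        assert a1 == pytest.approx(a2, rel=1e-9)


class TestSummarizeSite:
    def _burst_traces(self, n, gain, seed0=0):
        cfg = SyntheticConfig()
        out = []
        for k in range(n):
            tr, _ = simulate_trial(cfg, gain, seed=seed0 + k, onset_ms=20.0,
                                   duration_ms=24.0)
            out.append(rectify(tr))
        return out

    def test_identical_trials_mean_area_and_persistence(self):
        tr = step_trace(baseline=10, level=25, start_ms=20, stop_ms=45)
        st_ = prestim_stats(tr)
        res = detect_imep(tr, st_)
        single = imep_area(tr, res, st_)
        s = summarize_site([tr] * 10, detection_mode="per_trial")
        assert s.persistence == 1.0
        assert s.mean_relative_area == pytest.approx(single)

    def test_partial_persistence(self):
        with_burst = step_trace(baseline=10, level=25)
        flat = step_trace(baseline=10, level=10)
        s = summarize_site([with_burst] * 5 + [flat] * 5,
                           detection_mode="per_trial")
        assert s.persistence == 0.5

    def test_no_detection_gives_zero_weight(self):
        flat = step_trace(baseline=10, level=10)
        s = summarize_site([flat] * 4)
        assert s.mean_relative_area == 0.0
        assert s.persistence == 0.0

    def test_averaged_mode_recovers_burst_timing(self):
        rects = self._burst_traces(10, gain=4.0)
        s = summarize_site(rects, detection_mode="averaged")
        assert s.mean_relative_area > 150.0
        assert abs(s.mean_onset_ms - 20.0) < 2.0
        assert abs(s.mean_duration_ms - 24.0) < 2.0

    def test_detection_probability_monotone_in_gain(self):
        # per-trial detection rate should not decrease with burst gain
        rates = []
        for gain in (0.0, 2.0, 6.0):
            rects = self._burst_traces(40, gain, seed0=1000)
            s = summarize_site(rects, detection_mode="per_trial")
            rates.append(s.persistence)
        assert rates[0] <= rates[1] + 0.1
        assert rates[1] <= rates[2] + 0.1
        assert rates[2] > rates[0]

    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_site([])


class TestRankSites:
    def _summ(self, sid, area):
        return SiteSummary(sid, area, None, None, 0.0, 1)

    def test_rank_order(self):
        ss = [self._summ(0, 300.0), self._summ(1, 100.0), self._summ(2, 200.0)]
        rank_sites(ss)
        assert [s.rank for s in ss] == [1, 3, 2]

    def test_ties_broken_by_site_id(self):
        ss = [self._summ(i, 150.0) for i in (3, 1, 2)]
        rank_sites(ss)
        by_id = {s.site_id: s.rank for s in ss}
        assert by_id == {1: 1, 2: 2, 3: 3}

    def test_ranks_are_permutation(self, rng):
        ss = [self._summ(i, float(a))
              for i, a in enumerate(rng.uniform(0, 400, 9))]
        rank_sites(ss)
        assert sorted(s.rank for s in ss) == list(range(1, 10))


def test_background_stability_warns_on_drift():
    with pytest.warns(UserWarning):
        ok = check_background_stability({"iBB": 50.0, "bBB": 90.0,
                                         "iBB-cAE": 52.0})
    assert not ok
    assert check_background_stability({"iBB": 50.0, "bBB": 52.0,
                                       "iBB-cAE": 49.0})


def test_pooled_stats_match_averaged_trace_mean(rng):
    traces = [rectify(make_trace(rng.normal(0, 10, 520))) for _ in range(5)]
    pooled = pooled_prestim_stats(traces)
    avg = average_rectified(traces)
    assert pooled.mean == pytest.approx(prestim_stats(avg).mean)
    # pooled single-sweep SD exceeds the averaged-trace SD
    assert pooled.sd > prestim_stats(avg).sd
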