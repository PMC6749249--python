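import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mosdetect as m
from mosdetect.detection import (
    Candidate,
    CriticalValues,
    RuleWeights,
    score_r1,
    score_r2,
    score_r3,
    score_r4,
    score_r5,
)
from oracles import brute_force_detect

CV = CriticalValues()


def make_candidate(onset=0, run=4, g_onset=0.0, g_peak=1.0):
    return Candidate(onset_i=onset, peak_i=onset + run, g_onset=g_onset, g_peak=g_peak)


def table_from(g, T=None, g_amp=None, t0=0.0):
    g = np.asarray(g, float)
    n = g.size
    return pd.DataFrame({
        "t": t0 + np.arange(n, dtype=float),
        "gsr": g if g_amp is None else np.asarray(g_amp, float),
        "st": np.full(n, 33.0) if T is None else np.asarray(T, float),
        "phasic": g,
        "tonic": 0.0,
        "lat": np.nan, "lon": np.nan,
    })


class TestFindCandidates:
    def test_flat_series_has_no_candidates(self):
        assert m.find_candidates(np.array([1.0, 1.0, 1.0])) == []

    def test_single_rise_onset_and_peak(self):
        c, = m.find_candidates(np.array([1.0, 2.0, 3.0, 4.0, 3.0]))
        assert (c.onset_i, c.peak_i, c.rise_run) == (0, 3, 3)
        assert (c.g_onset, c.g_peak) == (1.0, 4.0)

    def test_two_separated_rises(self):
        g = np.array([1.0, 2.0, 1.5, 1.0, 2.0, 3.0, 2.0])
        cands = m.find_candidates(g)
        assert [(c.onset_i, c.peak_i) for c in cands] == [(0, 1), (3, 5)]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-3, max_value=3), min_size=3, max_size=40))
    def test_matches_exhaustive_sign_scan(self, steps):
        g = np.cumsum(np.asarray(steps, float))
        cands = m.find_candidates(g)
        # oracle: every maximal run of positive diffs, by direct enumeration
        expected = []
        i = 0
        while i < len(g) - 1:
            if g[i + 1] > g[i]:
                j = i
                while j < len(g) - 1 and g[j + 1] > g[j]:
                    j += 1
                expected.append((i, j))
                i = j
            else:
                i += 1
        assert [(c.onset_i, c.peak_i) for c in cands] == expected


class TestRuleScores:
    @pytest.mark.parametrize("run,expected", [
        (2, 1.0), (3, 1.0), (5, 1.0), (6, 0.5), (7, 0.5), (8, 0.5), (1, 0.0), (9, 0.0),
    ])
    def test_r1_run_length_bands(self, run, expected):
        assert score_r1(make_candidate(run=run)) == expected

    def test_r2_decrease_starting_at_three_seconds_scores_full(self):
        T = np.full(20, 33.0)
        T[8:13] = 33.0 - 0.1 * np.arange(1, 6)   # falls from index 8; onset 5 -> starts at +3
        assert score_r2(T, make_candidate(onset=5, run=3)) == 1.0

    def test_r2_decrease_starting_at_five_seconds_scores_half(self):
        T = np.full(20, 33.0)
        T[10:15] = 33.0 - 0.1 * np.arange(1, 6)  # onset 5 -> starts at +5
        assert score_r2(T, make_candidate(onset=5, run=3)) == 0.5

    def test_r2_constant_st_scores_zero(self):
        assert score_r2(np.full(20, 33.0), make_candidate(onset=5, run=3)) == 0.0

    def test_r2_short_series_warns_and_scores_zero(self):
        with pytest.warns(UserWarning, match="ST series"):
            assert score_r2(np.full(6, 33.0), make_candidate(onset=3, run=2)) == 0.0

    @pytest.mark.parametrize("run,expected", [
        (4, 1.0), (1, 1.0), (5, 1.0), (6, 0.5), (10, 0.5), (15, 0.5), (16, 0.0),
    ])
    def test_r3_rising_time_bands(self, run, expected):
        assert score_r3(make_candidate(run=run)) == expected

    @pytest.mark.parametrize("dg,run,expected", [
        (1.0, 4, 1.0),    # arctan(0.25) = 14.04 deg
        (0.6, 4, 0.5),    # arctan(0.15) = 8.53 deg
        (0.0, 4, 0.0),
        (0.71, 4, 1.0),   # arctan(0.1775) = 10.07 deg, just above threshold
    ])
    def test_r4_slope_bands(self, dg, run, expected):
        assert score_r4(make_candidate(run=run, g_onset=0.0, g_peak=dg)) == expected

    def test_r4_slope_value_is_arctangent_in_degrees(self):
        c = make_candidate(run=4, g_onset=0.0, g_peak=1.0)
        assert c.slope_deg == pytest.approx(math.degrees(math.atan(0.25)))
        assert c.slope_deg == pytest.approx(14.04, abs=0.01)

    def test_r4_amplitude_series_override(self):
        c = make_candidate(onset=0, run=4, g_onset=0.0, g_peak=0.5)
        amp = np.array([0.0, 0.2, 0.5, 0.8, 1.2])
        assert score_r4(c) == 0.0
        assert score_r4(c, g_amplitude=amp) == 1.0

    @pytest.mark.parametrize("prior,expected", [
        ([], 1.0), ([5.0], 0.0), ([-1.0], 1.0), ([0.0], 0.0), ([4.9], 0.0),
    ])
    def test_r5_refractory_window(self, prior, expected):
        assert score_r5(10.0, prior) == expected
        # gap of exactly the refractory period still blocks; 11 s frees
        assert score_r5(10.0, [0.0]) == 0.0
        assert score_r5(11.0, [0.0]) == 1.0


class TestTotalScore:
    def test_all_ones_is_hundred_for_any_valid_weights(self):
        for w in [RuleWeights(), RuleWeights(30, 25, 15, 15, 15), RuleWeights(20, 20, 20, 20, 20)]:
            assert m.total_score((1, 1, 1, 1, 1), w) == 100.0

    def test_all_zeros_is_zero(self):
        assert m.total_score((0, 0, 0, 0, 0), RuleWeights()) == 0.0

    def test_weighted_sum_hand_computed(self):
        w = RuleWeights(30, 25, 15, 15, 15)
        assert m.total_score((1, 1, 1, 0.5, 1), w) == pytest.approx(92.5)

    def test_invalid_weights_rejected(self):
        with pytest.raises(m.ConfigurationError):
            RuleWeights(10, 10, 10, 10, 10)
        with pytest.raises(m.ConfigurationError):
            RuleWeights(-5, 40, 25, 25, 15)

    def test_invalid_score_value_rejected(self):
        with pytest.raises(m.ParameterError):
            m.total_score((1, 0.3, 1, 1, 1), RuleWeights())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0.0, 0.5, 1.0]), min_size=5, max_size=5))
    def test_total_score_bounds_and_extremes(self, scores):
        ts = m.total_score(tuple(scores), RuleWeights())
        assert 0.0 <= ts <= 100.0
        assert (ts == 100.0) == all(s == 1.0 for s in scores)


class TestDetect:
    def test_flat_signals_detect_nothing(self):
        assert m.detect_mos(table_from(np.full(60, 2.0))) == []

    def test_single_canonical_event_detected_near_onset(self, quiet_session):
        *_, truth, table = quiet_session
        events = m.detect_mos(table)
        assert len(events) == len(truth.events)
        for ev, expect in zip(events, truth.expected_mos_times):
            assert abs(ev.t - expect) <= 2.0

    def test_event_within_refractory_suppressed(self):
        # two steep rises 8 s apart: only the first is accepted
        g = np.zeros(40)
        g[10:14] = [0.5, 1.0, 1.5, 2.0]
        g[14:18] = [1.5, 1.0, 0.5, 0.2]
        g[18:22] = [0.7, 1.2, 1.7, 2.2]
        g[22:] = 1.0
        T = 33.0 - 0.02 * np.arange(40.0)  # always-decreasing ST satisfies R2
        events = m.detect_mos(table_from(g, T=T))
        assert len(events) == 1 and events[0].t == 9.0
        # moved apart by more than the refractory period, both fire
        g2 = np.concatenate([g[:18], np.zeros(4), g[18:]])
        T2 = 33.0 - 0.02 * np.arange(44.0)
        assert len(m.detect_mos(table_from(g2, T=T2))) == 2

    def test_every_event_scores_at_least_critical(self, canonical_session):
        *_, table = canonical_session
        for ev in m.detect_mos(table):
            assert ev.total_score >= 75.0

    def test_raising_cs_never_detects_more(self, canonical_session):
        *_, table = canonical_session
        counts = [len(m.detect_mos(table, cs=cs)) for cs in (60, 70, 75, 80, 90, 100)]
        assert counts == sorted(counts, reverse=True)

    def test_detected_events_carry_location(self, canonical_session):
        *_, table = canonical_session
        events = m.detect_mos(table)
        assert events and all(not math.isnan(e.lat) for e in events)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=10, max_value=60))
    def test_agrees_with_brute_force_on_random_series(self, seed, n):
        rng = np.random.default_rng(seed)
        g = np.cumsum(rng.normal(0.0, 0.3, size=n))
        g_amp = g + np.cumsum(rng.normal(0.0, 0.05, size=n))
        T = 33.0 + np.cumsum(rng.normal(0.0, 0.05, size=n))
        table = table_from(g, T=T, g_amp=g_amp)
        got = [(e.onset_i, e.total_score) for e in m.detect_mos(table)]
        expected = brute_force_detect(g, T, m.DEFAULT_WEIGHTS, cs=75.0, g_amp=g_amp)
        assert len(got) == len(expected)
        for (i1, ts1), (i2, ts2) in zip(got, expected):
            assert i1 == i2
            assert ts1 == pytest.approx(ts2, abs=1e-10)


class TestEvaluate:
    def test_perfect_detection(self):
        events = [m.MOSEvent(t=t, total_score=100.0, scores=(1,) * 5) for t in (50.0, 150.0)]
        res = m.evaluate(events, [50.0, 150.0])
        assert (res["tp"], res["fp"], res["fn"]) == (2, 0, 0)
        assert res["accuracy"] == 1.0

    def test_no_events_all_missed(self):
        res = m.evaluate([], [50.0, 150.0])
        assert (res["tp"], res["fp"], res["fn"]) == (0, 0, 2)
        assert res["accuracy"] == 0.0

    def test_spurious_event_counts_false_positive(self):
        events = [m.MOSEvent(t=t, total_score=100.0, scores=(1,) * 5)
                  for t in (50.0, 90.0, 150.0)]
        res = m.evaluate(events, [50.0, 150.0])
        assert (res["tp"], res["fp"], res["fn"]) == (2, 1, 0)
        assert res["accuracy"] == pytest.approx(2 / 3)

    def test_matching_is_one_to_one(self):
        # two events near one stimulus: only one may match
        events = [m.MOSEvent(t=t, total_score=100.0, scores=(1,) * 5) for t in (48.0, 52.0)]
        res = m.evaluate(events, [50.0])
        assert (res["tp"], res["fp"], res["fn"]) == (1, 1, 0)


@pytest.fixture(scope="module")
def session_pair():
    out = []
    for seed in (21, 22):
        gsr, st, geo, truth = m.generate_session(m.SessionSpec(seed=seed))
        out.append((m.preprocess_session(gsr, st, geo), truth))
    return out


class TestCalibration:
    def test_finds_setting_detecting_all_events(self, session_pair):
        w, cs, report = m.calibrate_weights(session_pair, n_samples=20, seed=0)
        best = report["objective"].max()
        assert best == 20  # 10 TP per session, 0 FP
        tp = report.loc[report["objective"].idxmax(), "tp"]
        assert tp == 20

    def test_deterministic_given_seed(self, session_pair):
        w1, cs1, _ = m.calibrate_weights(session_pair, n_samples=10, seed=7)
        w2, cs2, _ = m.calibrate_weights(session_pair, n_samples=10, seed=7)
        assert w1.as_tuple() == w2.as_tuple() and cs1 == cs2

    def test_infinite_fp_penalty_minimises_false_positives(self, session_pair):
        w, cs, report = m.calibrate_weights(session_pair, n_samples=10,
                                            fp_penalty=1e9, seed=0)
        row = report[(report["w1"] == w.w1) & (report["cs"] == cs)].iloc[0]
        assert row["fp"] == report["fp"].min()

    def test_empty_inputs_rejected(self):
        with pytest.raises(m.ConfigurationError):
            m.calibrate_weights([])
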