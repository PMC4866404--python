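"""Displacement series and the rule-based contraction detector."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dartpulse.scoring import (
    DisplacementTrace,
    detect_contractions,
    displacement_series,
    score_trial,
)
from dartpulse.tracking import MarkerTrack

from conftest import make_trace


def _counts(events):
    return (
        sum(e.segment == "control" for e in events),
        sum(e.segment == "response" for e in events),
    )


class TestDisplacementSeries:
    def test_constant_position_gives_zero(self):
        t = 5.0 * np.arange(301)
        tr = MarkerTrack("diverticulum", t, np.full(301, 3.0), np.full(301, 4.0))
        trace = displacement_series(tr)
        assert np.all(trace.d == 0)
        assert trace.d.size == 240  # pause intervals dropped

    def test_three_four_five_step(self):
        tr = MarkerTrack("diverticulum", [0.0, 5.0], [0.0, 3.0], [0.0, 4.0])
        trace = displacement_series(tr, segments={"control": (0.0, 5.0)})
        assert trace.d.tolist() == [5.0]

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        t = 5.0 * np.arange(50)
        x, y = rng.normal(size=50), rng.normal(size=50)
        seg = {"control": (0.0, 245.0)}
        a = displacement_series(MarkerTrack("m", t, x, y), segments=seg)
        b = displacement_series(MarkerTrack("m", t, x + 137.0, y - 42.5), segments=seg)
        np.testing.assert_allclose(a.d, b.d, atol=1e-9)

    def test_missing_grid_points_rejected(self):
        t = np.array([0.0, 5.0, 15.0, 20.0])
        tr = MarkerTrack("m", t, np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError, match="grid"):
            displacement_series(tr)


class TestDetectContractions:
    def test_flat_trace_no_events(self):
        trace = make_trace(np.zeros(120), np.zeros(120))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert detect_contractions(trace) == []

    def test_single_clear_peak_per_segment(self):
        dc = np.zeros(120)
        dc[30] = 1.0
        dr = np.zeros(120)
        dr[50] = 1.2
        dr[80] = 0.9
        events = detect_contractions(make_trace(dc, dr))
        assert _counts(events) == (1, 2)

    def test_one_more_response_peak_scores_induced_one(self):
        """A track like the worked example: one extra suprathreshold peak in
        the response period gives induced = 1."""
        dc = np.zeros(120)
        dc[20] = dc[70] = 1.0
        dr = np.zeros(120)
        dr[10] = dr[55] = dr[100] = 1.0
        trace = make_trace(dc, dr)
        events = detect_contractions(trace)
        score = score_trial(events, trace)
        assert score.induced == 1
        assert score.responded

    def test_run_longer_than_three_minutes_discarded(self):
        dc = np.zeros(120)
        dc[10:47] = 1.0  # 37 samples * 5 s = 185 s above threshold
        dr = np.zeros(120)
        dr[20] = 1.0
        events = detect_contractions(make_trace(dc, dr))
        assert _counts(events) == (0, 1)

    def test_exactly_180s_run_kept(self):
        dc = np.zeros(120)
        dc[10:46] = 1.0  # 36 samples = 180 s: "more than 3 min" not triggered
        dr = np.zeros(120)
        dr[20] = 1.0
        events = detect_contractions(make_trace(dc, dr))
        assert _counts(events) == (1, 1)

    def test_peaks_10s_apart_merge_into_one(self):
        dc = np.zeros(120)
        dc[30] = 1.0
        dc[32] = 0.8  # 10 s later, separate runs
        dr = np.zeros(120)
        dr[60] = 1.0
        events = detect_contractions(make_trace(dc, dr))
        assert _counts(events) == (1, 1)
        ctrl = [e for e in events if e.segment == "control"][0]
        assert ctrl.peak_value == 1.0

    def test_peaks_15s_apart_stay_separate(self):
        dc = np.zeros(120)
        dc[30] = 1.0
        dc[33] = 0.8
        dr = np.zeros(120)
        events = detect_contractions(make_trace(dc, dr))
        assert _counts(events) == (2, 0)

    def test_threshold_is_joint_over_both_segments(self):
        """A bump clearing 25% of its own segment's range but not of the
        trial range is not an event."""
        dc = np.zeros(120)
        dc[30] = 0.2  # small control bump
        dr = np.zeros(120)
        dr[60] = 2.0  # sets the trial range; T = 0.5
        events = detect_contractions(make_trace(dc, dr))
        assert _counts(events) == (0, 1)

    def test_degenerate_range_warns_and_returns_nothing(self):
        trace = make_trace(np.full(120, 0.01), np.full(120, 0.012))
        with pytest.warns(UserWarning, match="degenerate"):
            assert detect_contractions(trace) == []

    def test_runs_cannot_bridge_the_pause(self):
        """Suprathreshold samples at the end of control and start of response
        are separate events even though adjacent in the stored arrays."""
        dc = np.zeros(120)
        dc[-1] = 1.0
        dr = np.zeros(120)
        dr[0] = 1.0
        events = detect_contractions(make_trace(dc, dr))
        assert _counts(events) == (1, 1)

    @given(
        scale=st.floats(min_value=0.25, max_value=8.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance_of_counts(self, scale, seed):
        """Multiplying all displacements by c > 0 changes no event counts
        (the threshold is relative) and scales intensity by c."""
        rng = np.random.default_rng(seed)
        dc = np.where(rng.random(120) < 0.03, rng.uniform(0.8, 1.5, 120), 0.0)
        dr = np.where(rng.random(120) < 0.04, rng.uniform(0.8, 1.5, 120), 0.0)
        dc += rng.uniform(0, 0.1, 120)
        dr += rng.uniform(0, 0.1, 120)
        t1 = make_trace(dc, dr)
        t2 = make_trace(scale * dc, scale * dr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1, e2 = detect_contractions(t1), detect_contractions(t2)
        assert _counts(e1) == _counts(e2)
        s1, s2 = score_trial(e1, t1), score_trial(e2, t2)
        assert s2.intensity == pytest.approx(scale * s1.intensity, rel=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_bruteforce_oracle(self, seed):
        """The production detector matches an independent O(n^2) re-statement
        of the rules on random traces."""
        rng = np.random.default_rng(seed)
        dc = rng.gamma(1.0, 0.2, 120)
        dr = rng.gamma(1.0, 0.25, 120)
        for k in rng.integers(0, 120, 4):
            dc[k] += rng.uniform(0.5, 1.5)
        for k in rng.integers(0, 120, 5):
            dr[k] += rng.uniform(0.5, 1.5)
        trace = make_trace(dc, dr)
        events = detect_contractions(trace)
        assert _counts(events) == _bruteforce_counts(trace)


def _bruteforce_counts(trace, frac=0.25, min_sep=15.0, max_dur=180.0):
    """Slow independent implementation of the counting rules."""
    d, t, seg = trace.d, trace.t, trace.segment
    T = d.min() + frac * (d.max() - d.min())
    peaks = []  # (time, value, segment)
    i = 0
    while i < len(d):
        if d[i] > T:
            j = i
            while (
                j + 1 < len(d)
                and d[j + 1] > T
                and t[j + 1] - t[j] <= trace.dt + 1e-9
            ):
                j += 1
            if (j - i + 1) * trace.dt <= max_dur:
                k = i + int(np.argmax(d[i : j + 1]))
                peaks.append([t[k], d[k], seg[k]])
            i = j + 1
        else:
            i += 1
    merged = []
    for pk in sorted(peaks):
        if merged and pk[0] - merged[-1][0] < min_sep:
            if pk[1] > merged[-1][1]:
                merged[-1] = pk
        else:
            merged.append(pk)
    return (
        sum(1 for pk in merged if pk[2] == "control"),
        sum(1 for pk in merged if pk[2] == "response"),
    )


class TestScoreTrial:
    def test_score_arithmetic(self):
        dc = np.zeros(120)
        dc[10] = dc[40] = 1.0
        dr = np.zeros(120)
        dr[10] = dr[40] = dr[80] = 1.0
        trace = make_trace(dc, dr)
        s = score_trial(detect_contractions(trace), trace)
        assert (s.n_control, s.n_response, s.induced) == (2, 3, 1)
        assert s.responded
        assert s.intensity == 1.0

    def test_equal_counts_not_a_responder(self):
        dc = np.zeros(120)
        dc[10] = dc[40] = dc[70] = 1.0
        dr = np.zeros(120)
        dr[10] = dr[40] = dr[80] = 1.0
        trace = make_trace(dc, dr)
        s = score_trial(detect_contractions(trace), trace)
        assert s.induced == 0
        assert not s.responded

    def test_count_conservation_over_a_day(self, params):
        """Summed induced equals sum(n_response) - sum(n_control)."""
        import dartpulse as dp

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = [
                dp.run_trial(params, spec)[0]
                for spec in dp.simulate_day(params, day_id=2)
            ]
        assert sum(r["induced"] for r in rows) == sum(r["n_response"] for r in rows) - sum(
            r["n_control"] for r in rows
        )
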