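"""Synthetic-data generator: protocol structure, ground truth, determinism."""

import dataclasses
import warnings

import numpy as np
import pytest

from dartpulse.pipeline import run_trial
from dartpulse.phylo import read_newick, vcv
from dartpulse.simulate import (
    SimulationParams,
    TrialSpec,
    simulate_bm_traits,
    simulate_day,
    simulate_lengths,
    simulate_trace,
)


class TestSimulateTrace:
    def test_flat_trace_yields_zero_contractions(self, quiet_params, control_spec):
        """No noise and no events: the detector must stay silent."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row, truth = run_trial(quiet_params, control_spec, n_events={"control": 0, "response": 0})
        assert truth.induced == 0
        assert row["n_control"] == row["n_response"] == 0

    def test_planted_events_recovered_exactly(self, quiet_params, control_spec):
        """2 control + 3 response well-separated events -> induced = 1."""
        row, truth = run_trial(quiet_params, control_spec, n_events={"control": 2, "response": 3})
        assert (truth.n_control, truth.n_response) == (2, 3)
        assert (row["n_control"], row["n_response"]) == (2, 3)
        assert row["induced"] == 1

    def test_grid_sample_counts(self, params, control_spec):
        """600-s control at 5-s sampling: 121 coordinate samples on the grid."""
        from dartpulse.scoring import displacement_series
        from dartpulse.tracking import resample_5s

        tracks, _ = simulate_trace(params, control_spec)
        tr5 = resample_5s(tracks["diverticulum"], dt=5.0)
        # full trial: 1500 s -> 301 grid points
        assert len(tr5) == 301
        trace = displacement_series(tr5, segments=params.segments)
        assert int((trace.segment == "control").sum()) == 120
        assert int((trace.segment == "response").sum()) == 120

    def test_truth_counts_match_event_list(self, params, control_spec):
        _, truth = simulate_trace(params, control_spec, n_events={"control": 2, "response": 4})
        assert truth.n_control == sum(e.segment == "control" for e in truth.events)
        assert truth.n_response == sum(e.segment == "response" for e in truth.events)
        assert truth.induced == truth.n_response - truth.n_control

    def test_events_within_segment_bounds_and_separated(self, params, control_spec):
        _, truth = simulate_trace(params, control_spec, n_events={"control": 4, "response": 4})
        for seg, (s0, s1) in params.segments.items():
            evs = sorted(
                (e for e in truth.events if e.segment == seg), key=lambda e: e.start_s
            )
            for e in evs:
                assert s0 <= e.start_s and e.end_s <= s1
            for a, b in zip(evs, evs[1:]):
                assert b.start_s - a.end_s >= 15.0

    def test_determinism(self, params, control_spec):
        t1, u1 = simulate_trace(params, control_spec)
        t2, u2 = simulate_trace(params, control_spec)
        for m in t1:
            np.testing.assert_array_equal(t1[m].x, t2[m].x)
            np.testing.assert_array_equal(t1[m].y, t2[m].y)
        assert u1 == u2

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            SimulationParams(control_duration=601.0)
        with pytest.raises(ValueError, match="positive"):
            SimulationParams(control_duration=-5.0)
        with pytest.raises(ValueError, match="negative"):
            SimulationParams(event_rate_response={"C_aspersum": -1.0})


class TestSimulateDay:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_controls_bracket_the_day(self, seed):
        p = SimulationParams(seed=seed)
        specs = simulate_day(p, day_id=1)
        assert specs[0].species == specs[-1].species == p.focal_species
        assert specs[0].is_control and specs[-1].is_control
        assert not any(s.is_control for s in specs[1:-1])

    @pytest.mark.parametrize("seed", range(5))
    def test_no_species_repeated_within_day(self, seed):
        specs = simulate_day(SimulationParams(seed=seed), day_id=3)
        middle = [s.species for s in specs[1:-1]]
        assert len(middle) == len(set(middle)) == 5

    def test_orderings_vary_across_seeds(self):
        orders = {
            tuple(s.species for s in simulate_day(SimulationParams(seed=s), day_id=1))
            for s in range(100)
        }
        assert len(orders) > 1

    def test_requires_non_control_species(self):
        p = SimulationParams(species_labels=("C_aspersum",))
        with pytest.raises(ValueError, match="non-control"):
            simulate_day(p, 1)


class TestSimulateLengths:
    def test_zero_effect_zero_noise_is_flat(self):
        p = SimulationParams(
            shortening_effect={"X": 0.0}, length_noise_sd_mm=0.0, length_between_sd_mm=0.0
        )
        tab = simulate_lengths(p, "X")
        assert tab.groupby("timepoint")["length_mm"].mean().nunique() == 1

    def test_largest_reported_effect_geometry(self):
        """effect 0.196 on a 29.1-mm organ: delta 5.7 mm, 19.6%."""
        p = SimulationParams(
            shortening_effect={"X": 0.196},
            length_mm=29.1,
            length_noise_sd_mm=0.0,
            length_between_sd_mm=0.0,
        )
        tab = simulate_lengths(p, "X")
        m = tab.groupby("timepoint")["length_mm"].mean()
        delta = m[0] - m[15]
        assert delta == pytest.approx(5.7, abs=0.01)
        assert 100 * delta / m[0] == pytest.approx(19.6, abs=0.05)

    def test_noisy_mean_effect_recovered(self):
        """Monte-Carlo: recovered mean shortening % within 2 SE of truth."""
        from dartpulse.shortening import records_from_table, summarize_shortening
        from dartpulse.pipeline import simulate_shortening_dataset

        p = SimulationParams(shortening_effect={"X": 0.10}, length_mm=29.1)
        tab = simulate_shortening_dataset(p, {"X": 200}, seed=9)
        summ = summarize_shortening(records_from_table(tab))
        row = summ.iloc[0]
        assert abs(row.mean_delta_pct - 10.0) < 2 * row.se_delta_pct + 0.2

    def test_effect_of_one_rejected(self):
        p = SimulationParams(shortening_effect={"X": 0.5})
        p.shortening_effect["X"] = 1.0  # past construction-time validation
        with pytest.raises(ValueError):
            simulate_lengths(p, "X")


class TestSimulateBMTraits:
    def test_zero_rate_returns_root_state(self, ten_tip_newick):
        tree = read_newick(ten_tip_newick)
        traits = simulate_bm_traits(tree, sigma2=0.0, seed=0, root_state=3.5)
        assert set(traits.values()) == {3.5}

    def test_tip_covariance_matches_sigma2_v(self):
        """Sample covariance over 5000 replicates ~ sigma2 * V entrywise."""
        nwk = "(((t1:0.4,t2:0.4):0.6,t3:1.0):0.5,(t4:0.7,t5:0.7):0.8);"
        tree = read_newick(nwk)
        labels, V = vcv(tree)
        X = simulate_bm_traits(tree, sigma2=2.0, seed=17, size=5000)
        S = np.cov(X[labels].to_numpy().T)
        big = 2.0 * V >= 0.2 * np.max(np.diag(2.0 * V))
        rel = np.abs(S - 2.0 * V) / (2.0 * V + 1e-12)
        assert np.max(rel[big]) < 0.05

    def test_zero_length_tree_rejected(self):
        tree = read_newick("(a:0,b:0);")
        with pytest.raises(ValueError, match="zero total"):
            simulate_bm_traits(tree, sigma2=1.0, seed=0)
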