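"""End-to-end drivers tying simulation, scoring and summaries together.

These helpers run the full measurement chain in memory — simulate a trial's
marker tracks, resample onto the 5-s grid, form the displacement trace,
detect contractions, score — for single trials, whole days, or the whole
multi-day experiment, returning tidy tables ready for the inference layer.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .scoring import detect_contractions, displacement_series, score_trial
from .simulate import (
    PlantedTruth,
    SimulationParams,
    TrialSpec,
    simulate_day,
    simulate_lengths,
    simulate_trace,
)
from .tracking import resample_5s

__all__ = [
    "run_trial",
    "run_experiment",
    "simulate_shortening_dataset",
    "tracks_to_table",
]


def run_trial(
    params: SimulationParams,
    spec: TrialSpec,
    n_events: Mapping[str, int] | None = None,
) -> tuple[dict, PlantedTruth]:
    """Simulate and score one trial; returns (score row, planted truth)."""
    tracks, truth = simulate_trace(params, spec, n_events=n_events)
    track5 = resample_5s(tracks[spec.organ], dt=params.dt_sample)
    trace = displacement_series(
        track5,
        segments=params.segments,
        trial_id=spec.trial_id,
        organ=spec.organ,
        dt=params.dt_sample,
    )
    events = detect_contractions(trace)
    score = score_trial(
        events,
        trace,
        species=spec.species,
        day=spec.day,
        order_index=spec.order_index,
        is_control=spec.is_control,
    )
    return score.as_row(), truth


def run_experiment(
    params: SimulationParams,
    organ: str = "diverticulum",
) -> tuple[pd.DataFrame, list[PlantedTruth]]:
    """Simulate and score the full multi-day experiment for one organ.

    Days are numbered 1..n_days; each day is two bracketing positive
    controls around up to five randomly ordered species extracts.
    """
    rows, truths = [], []
    for day in range(1, params.n_days + 1):
        for spec in simulate_day(params, day, organ=organ):
            row, truth = run_trial(params, spec)
            rows.append(row)
            truths.append(truth)
    return pd.DataFrame(rows), truths


def simulate_shortening_dataset(
    params: SimulationParams,
    n_per_species: Mapping[str, int],
    seed: int | None = None,
) -> pd.DataFrame:
    """Long measurement table for the shortening analysis.

    ``n_per_species`` gives the number of organs measured per extract
    species (the focal species appears once per control time point in the
    study; pass its total here).
    """
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    tables = []
    i = 0
    for species, n in n_per_species.items():
        for _ in range(n):
            tables.append(simulate_lengths(params, species, rng=rng, trial_id=f"s{i:04d}"))
            i += 1
    return pd.concat(tables, ignore_index=True)


def tracks_to_table(tracks_by_trial: Mapping[str, Mapping[str, object]]) -> pd.DataFrame:
    """Flatten {trial_id: {marker_id: MarkerTrack}} into the tracks dialect.

    Columns: ``trial_id marker_id time_s x y``.
    """
    rows = []
    for trial_id, markers in tracks_by_trial.items():
        for marker_id, tr in markers.items():
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": trial_id,
                        "marker_id": marker_id,
                        "time_s": tr.time_s,
                        "x": tr.x,
                        "y": tr.y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
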