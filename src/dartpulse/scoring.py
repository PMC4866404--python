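"""Contraction scoring of marker displacement traces.

The measurement chain is: marker track on the 5-s grid -> per-interval
Euclidean displacement magnitudes labelled control/response (the 5-min pause
is dropped) -> rule-based contraction detection -> per-trial score.

Three counting rules define a relevant contraction:

* a threshold at 25% of the min-max displacement range of the whole trial
  (control and response jointly) — only excursions above it count;
* excursions that stay above threshold for more than 3 min are discarded
  (slow repositioning of the preparation, not a contraction);
* retained peaks must be at least 15 s apart; closer peaks are merged,
  keeping the larger.

A trial's score is the contraction count in each segment, the induced count
(response minus control), the intensity (maximum displacement anywhere in
the trial) and a responder flag (strictly more response than control
contractions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tracking import MarkerTrack

__all__ = [
    "DisplacementTrace",
    "ContractionEvent",
    "TrialScore",
    "displacement_series",
    "detect_contractions",
    "score_trial",
]

#: default analysis windows (seconds): 10-min control, 5-min pause (dropped),
#: 10-min response
DEFAULT_SEGMENTS = {"control": (0.0, 600.0), "response": (900.0, 1500.0)}


@dataclass
class DisplacementTrace:
    """5-s-sampled displacement magnitudes of one trial.

    ``d[k]`` is the planar distance between marker positions at grid times
    ``t[k]`` and ``t[k] + dt``; ``segment[k]`` labels the interval by the
    window containing its start.  Pause intervals are not stored.
    """

    trial_id: str
    organ: str
    t: np.ndarray  # interval start times, seconds
    d: np.ndarray  # displacement magnitude per interval, >= 0
    segment: np.ndarray  # 'control' | 'response' per interval
    dt: float = 5.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.segment = np.asarray(self.segment)
        if not (self.t.shape == self.d.shape == self.segment.shape):
            raise ValueError("t, d and segment must have equal length")
        if np.any(self.d < 0):
            raise ValueError("displacement magnitudes must be >= 0")


@dataclass(frozen=True)
class ContractionEvent:
    """One retained contraction: its above-threshold run and peak."""

    segment: str
    start_s: float
    end_s: float
    peak_time_s: float
    peak_value: float


@dataclass
class TrialScore:
    """Per-trial summary feeding the inference layer."""

    trial_id: str
    organ: str
    species: str
    day: int
    order_index: int
    n_control: int
    n_response: int
    intensity: float
    is_control: bool = False

    @property
    def induced(self) -> int:
        return self.n_response - self.n_control

    @property
    def responded(self) -> bool:
        return self.n_response > self.n_control

    def as_row(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "organ": self.organ,
            "species": self.species,
            "day": self.day,
            "order": self.order_index,
            "is_control": self.is_control,
            "n_control": self.n_control,
            "n_response": self.n_response,
            "induced": self.induced,
            "intensity": self.intensity,
            "responded": self.responded,
        }


def displacement_series(
    track: MarkerTrack,
    segments: dict[str, tuple[float, float]] | None = None,
    trial_id: str = "",
    organ: str = "",
    dt: float = 5.0,
) -> DisplacementTrace:
    """Euclidean displacement per 5-s interval, labelled by segment.

    The track must already be on the regular ``dt`` grid (resample first).
    Intervals whose start falls in neither window (the pause) are dropped.
    """
    t = track.time_s
    if t.size < 2:
        raise ValueError("track too short for displacement")
    diffs = np.diff(t)
    if not np.allclose(diffs, dt, atol=1e-6):
        raise ValueError(f"track is not on a regular {dt}-s grid (missing samples?)")
    if segments is None:
        segments = DEFAULT_SEGMENTS
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    t_start = t[:-1]
    labels = np.full(t_start.shape, "", dtype=object)
    for name, (s0, s1) in segments.items():
        inside = (t_start >= s0 - 1e-9) & (t_start < s1 - 1e-9)
        labels[inside] = name
    keep = labels != ""
    return DisplacementTrace(
        trial_id=trial_id,
        organ=organ or track.marker_id,
        t=t_start[keep],
        d=d[keep],
        segment=labels[keep].astype(str),
        dt=dt,
    )


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def detect_contractions(
    trace: DisplacementTrace,
    threshold_frac: float = 0.25,
    min_sep: float = 15.0,
    max_dur: float = 180.0,
    range_epsilon: float = 0.05,
    keep_boundary: bool = True,
) -> list[ContractionEvent]:
    """Rule-based contraction detection on one trial's displacement trace.

    The threshold ``T = d_min + threshold_frac * (d_max - d_min)`` is
    computed over the whole trial, control and response jointly, keeping the
    two segments comparable within a trial.  Candidate events are maximal
    runs of samples with ``d > T`` within a contiguous block of the trace (a
    run cannot bridge the pause); a run of n samples is above threshold for
    ``n * dt`` seconds and is discarded when that exceeds ``max_dur``.  The
    peak of a run is its maximum sample; peaks closer than ``min_sep`` are
    merged keeping the larger peak and the union of run extents.  Events are
    attributed to the segment containing their peak.

    Traces whose total range is below ``range_epsilon`` (in displacement
    units) are treated as quiescent: no events, with a warning.  With
    ``keep_boundary=False``, runs truncated by a block edge are dropped.
    """
    d = trace.d
    if d.size == 0:
        return []
    d_min, d_max = float(d.min()), float(d.max())
    if d_max - d_min <= range_epsilon:
        warnings.warn(
            f"degenerate displacement range ({d_max - d_min:.3g} du): no events",
            stacklevel=2,
        )
        return []
    T = d_min + threshold_frac * (d_max - d_min)
    above = d > T
    dt = trace.dt

    # contiguous blocks (time jumps > dt separate control from response)
    block_breaks = np.flatnonzero(np.diff(trace.t) > dt + 1e-9) + 1
    blocks = np.split(np.arange(d.size), block_breaks)

    events: list[ContractionEvent] = []
    for block in blocks:
        if block.size == 0:
            continue
        sub = above[block]
        for i0, i1 in _runs_above(sub):
            g0, g1 = block[i0], block[i1 - 1]  # inclusive global indices
            duration = (i1 - i0) * dt
            if duration > max_dur:
                continue
            if not keep_boundary and (i0 == 0 or i1 == sub.size):
                continue
            seg_d = d[g0 : g1 + 1]
            pk = g0 + int(np.argmax(seg_d))
            events.append(
                ContractionEvent(
                    segment=str(trace.segment[pk]),
                    start_s=float(trace.t[g0]),
                    end_s=float(trace.t[g1] + dt),
                    peak_time_s=float(trace.t[pk]),
                    peak_value=float(d[pk]),
                )
            )

    events.sort(key=lambda e: e.peak_time_s)
    merged: list[ContractionEvent] = []
    for ev in events:
        if merged and ev.peak_time_s - merged[-1].peak_time_s < min_sep:
            prev = merged[-1]
            keep, other = (prev, ev) if prev.peak_value >= ev.peak_value else (ev, prev)
            merged[-1] = ContractionEvent(
                segment=keep.segment,
                start_s=min(prev.start_s, ev.start_s),
                end_s=max(prev.end_s, ev.end_s),
                peak_time_s=keep.peak_time_s,
                peak_value=keep.peak_value,
            )
        else:
            merged.append(ev)
    return merged


def score_trial(
    events: list[ContractionEvent],
    trace: DisplacementTrace,
    species: str = "",
    day: int = 0,
    order_index: int = 0,
    is_control: bool = False,
) -> TrialScore:
    """Summarize one trial from its detected events.

    The induced count is the response-period count minus the control-period
    count; the intensity is the maximum displacement reached anywhere in the
    trial (not only within retained events); the responder flag requires the
    response count to strictly exceed the control count.
    """
    n_control = sum(e.segment == "control" for e in events)
    n_response = sum(e.segment == "response" for e in events)
    intensity = float(trace.d.max()) if trace.d.size else 0.0
    return TrialScore(
        trial_id=trace.trial_id,
        organ=trace.organ,
        species=species,
        day=day,
        order_index=order_index,
        n_control=n_control,
        n_response=n_response,
        intensity=intensity,
        is_control=is_control,
    )
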