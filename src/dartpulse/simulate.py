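"""Synthetic organ-bath experiment generator with known ground truth.

Everything the scoring and inference pipeline consumes can be generated
here: marker trajectories with planted contraction events, the daily trial
designs (two focal-species positive controls bracketing up to five randomly
ordered species extracts), paired diverticulum length measurements, Brownian
trait vectors on a tree, and optionally rendered grayscale frame stacks.

The protocol constants mirror the study design: a 10-min control recording,
a 5-min pause while the mucous extract takes effect, a 10-min response
recording, marker displacement analysed every 5 s, 29 experimental days.
Each planted contraction is a raised-cosine displacement pulse (smooth,
single-peaked, controllable duration) riding on a slowly drifting baseline
with smooth, band-limited noise.  Identical parameters and seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .tracking import MarkerTrack, MARKER_LABELS

__all__ = [
    "SimulationParams",
    "TrialSpec",
    "PlantedEvent",
    "PlantedTruth",
    "simulate_trace",
    "simulate_day",
    "simulate_lengths",
    "simulate_bm_traits",
    "render_frames",
    "SPECIES",
    "FOCAL_SPECIES",
    "SYNTHETIC_SPECIES_TREE",
]

FOCAL_SPECIES = "C_aspersum"

#: the nine donor species whose mucous extracts are tested on the focal
#: preparation (eight helicids and the bradybaenid F_fruticum)
SPECIES = (
    "C_aspersum",
    "C_nemoralis",
    "C_hortensis",
    "A_arbustorum",
    "H_pomatia",
    "H_lucorum",
    "T_pisana",
    "E_vermiculata",
    "F_fruticum",
)

#: Synthetic stand-in topology for the nine donor species.  This is NOT an
#: estimated phylogeny: it is a plausible hand-written tree (congeners
#: grouped, the bradybaenid as the outgroup) used only to exercise the
#: phylogenetic-signal machinery on labelled synthetic data.
SYNTHETIC_SPECIES_TREE = (
    "(F_fruticum:0.080,"
    "(((H_pomatia:0.020,H_lucorum:0.020):0.030,A_arbustorum:0.048):0.012,"
    "((C_nemoralis:0.015,C_hortensis:0.015):0.030,"
    "(C_aspersum:0.035,(T_pisana:0.020,E_vermiculata:0.020):0.015):0.010):0.015):0.020);"
)

# Response-period contraction rates (events per 10 min) by donor species for
# the diverticulum stream.  The focal extract roughly doubles the spontaneous
# rate; the two Helix species and the diverticulum-less bradybaenid barely
# move it, matching the qualitative cross-reactivity pattern.
_DEFAULT_RESPONSE_RATES = MappingProxyType({
    "C_aspersum": 3.0,
    "C_nemoralis": 3.0,
    "C_hortensis": 3.0,
    "A_arbustorum": 2.6,
    "H_pomatia": 1.2,
    "H_lucorum": 1.0,
    "T_pisana": 3.0,
    "E_vermiculata": 2.8,
    "F_fruticum": 1.2,
})

# Relative amplitude of response-period events (weak extracts also contract
# less forcefully, driving the intensity contrasts).
_DEFAULT_AMPLITUDE_SCALE = MappingProxyType({
    "H_pomatia": 0.6,
    "H_lucorum": 0.5,
    "F_fruticum": 0.5,
})

# Fractional diverticulum length reduction 15 min after extract addition.
# Significant rows follow the published per-species means (mm / % pairs are
# mutually consistent with a ~29 mm organ); species without a significant
# shortening effect are set to zero.
_DEFAULT_SHORTENING_EFFECT = MappingProxyType({
    "C_aspersum": 0.077,
    "C_nemoralis": 0.0,
    "C_hortensis": 0.066,
    "A_arbustorum": 0.0,
    "H_pomatia": 0.054,
    "H_lucorum": 0.065,
    "T_pisana": 0.155,
    "E_vermiculata": 0.196,
    "F_fruticum": 0.0,
})


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic experiment.

    Durations are in seconds and must be positive multiples of ``dt_sample``.
    Displacement is measured in abstract "displacement units" (du); an
    optional px<->mm scale is metadata only since every downstream criterion
    is relative.  ``event_rate_*`` are expected contraction counts per 10-min
    segment.  ``dose_mg`` (the 2.2 mg extract portion) is carried purely as
    an annotation.
    """

    seed: int = 0
    dt_sample: float = 5.0
    frame_interval: float = 1.0  # native webcam sampling; only the 5-s grid is published
    control_duration: float = 600.0
    pause_duration: float = 300.0
    response_duration: float = 600.0
    event_rate_control: float = 1.0
    event_rate_response: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_RESPONSE_RATES))
    amplitude_mean: float = 1.0  # du, peak displacement of a planted contraction
    amplitude_sd: float = 0.15
    amplitude_scale: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDE_SCALE))
    event_duration_mean: float = 30.0  # s, well under the 180-s counting cutoff
    noise_sd: float = 0.05  # du, marginal SD of the smooth baseline wobble
    noise_corr_s: float = 10.0  # correlation scale of the wobble
    drift_slope: float = 1e-4  # du per second of linear baseline drift
    drift_wobble: float = 0.005  # du, amplitude of the slow sinusoidal drift
    drift_period_s: float = 600.0
    n_days: int = 29
    species_labels: Sequence[str] = SPECIES
    focal_species: str = FOCAL_SPECIES
    trials_per_day: int = 7  # two controls + up to five extracts
    shortening_effect: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SHORTENING_EFFECT))
    length_mm: float = 29.1  # mean resting diverticulum length
    length_between_sd_mm: float = 2.0  # organ-to-organ variation
    length_noise_sd_mm: float = 1.0  # per-measurement digitization error
    bm_sigma2: float = 1.0
    control2_inflation: float = 0.0  # optional response-rate add-on for the day's 2nd control
    dose_mg: float = 2.2  # annotation only

    def __post_init__(self) -> None:
        for name in ("control_duration", "pause_duration", "response_duration"):
            dur = getattr(self, name)
            if dur <= 0:
                raise ValueError(f"{name} must be positive")
            if abs(dur / self.dt_sample - round(dur / self.dt_sample)) > 1e-9:
                raise ValueError(f"{name}={dur} not a multiple of dt_sample={self.dt_sample}")
        if self.dt_sample <= 0 or self.frame_interval <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.frame_interval > self.dt_sample + 1e-9:
            raise ValueError("frame_interval must not exceed dt_sample")
        if self.event_rate_control < 0:
            raise ValueError("event_rate_control must be >= 0")
        for sp, rate in self.event_rate_response.items():
            if rate < 0:
                raise ValueError(f"negative response rate for {sp}")
        for sp, eff in self.shortening_effect.items():
            if not (0.0 <= eff < 1.0):
                raise ValueError(f"shortening_effect[{sp!r}] must be in [0, 1)")
        if self.event_duration_mean <= 0:
            raise ValueError("event_duration_mean must be positive")

    @property
    def total_duration(self) -> float:
        return self.control_duration + self.pause_duration + self.response_duration

    @property
    def segments(self) -> dict[str, tuple[float, float]]:
        """Analysis windows: control and response (the pause is dropped)."""
        c0 = 0.0
        c1 = self.control_duration
        r0 = c1 + self.pause_duration
        r1 = r0 + self.response_duration
        return {"control": (c0, c1), "response": (r0, r1)}


@dataclass(frozen=True)
class TrialSpec:
    """One mucus application: which extract, on which day, in which slot."""

    trial_id: str
    day: int
    order_index: int
    species: str
    organ: str = "diverticulum"
    is_control: bool = False


@dataclass(frozen=True)
class PlantedEvent:
    segment: str
    start_s: float
    end_s: float
    peak_amplitude: float


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one simulated trial."""

    trial_id: str
    events: tuple[PlantedEvent, ...]
    n_control: int
    n_response: int

    @property
    def induced(self) -> int:
        return self.n_response - self.n_control

    def to_json(self) -> str:
        return json.dumps(
            {
                "trial_id": self.trial_id,
                "events": [asdict(e) for e in self.events],
                "n_control": self.n_control,
                "n_response": self.n_response,
                "induced": self.induced,
            },
            indent=2,
        )


def _trial_rng(params: SimulationParams, spec: TrialSpec) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((params.seed, spec.day, spec.order_index, 101))
    )


def _place_events(
    rng: np.random.Generator,
    n: int,
    seg_start: float,
    seg_end: float,
    duration: float,
    min_gap: float = 20.0,
    edge_margin: float = 15.0,
) -> list[float]:
    """Non-overlapping event start times, >= min_gap apart edge to edge.

    Draws sorted uniform candidates and retries; if the segment cannot hold
    n events, as many as fit are placed on an even grid (the planted-truth
    list always reflects what was actually placed).
    """
    lo = seg_start + edge_margin
    hi = seg_end - duration - edge_margin
    if n <= 0 or hi < lo:
        return []
    pitch = duration + min_gap
    capacity = int((hi - lo) // pitch) + 1
    n = min(n, capacity)
    for _ in range(200):
        starts = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.all(np.diff(starts) >= pitch):
            return list(starts)
    return list(lo + pitch * np.arange(n))


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, corr_samples: float) -> np.ndarray:
    """Smooth, bounded baseline wobble with marginal SD ~``sd``.

    A Gaussian-kernel-filtered white process (correlation scale
    ``corr_samples``) passed through a soft saturation at 2.5 SD: resting
    preparations wobble smoothly within a limited envelope rather than
    producing spike-like excursions, which is what keeps the relative
    25%-of-range contraction threshold meaningful on quiet baselines.
    """
    if sd <= 0 or n == 0:
        return np.zeros(n)
    sigma = max(corr_samples / 2.0, 1e-6)
    half = int(np.ceil(4 * sigma))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kern /= np.sqrt(np.sum(kern**2))  # unit output variance
    white = rng.standard_normal(n + 2 * half)
    smooth = sd * np.convolve(white, kern, mode="valid")[:n]
    bound = 2.5 * sd
    return bound * np.tanh(smooth / bound)


def simulate_trace(
    params: SimulationParams,
    spec: TrialSpec,
    n_events: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, MarkerTrack], PlantedTruth]:
    """Simulate the marker trajectories of one trial.

    Returns one track per marker at the native frame interval, covering
    control + pause + response, plus the planted ground truth for the marker
    of the organ under study (``spec.organ``); the other markers carry only
    baseline motion.  Event counts per segment are Poisson draws from the
    per-species rates unless ``n_events`` overrides them, e.g.
    ``{"control": 2, "response": 3}``.
    """
    if rng is None:
        rng = _trial_rng(params, spec)
    dt = params.dt_sample
    n_steps = int(round(params.total_duration / dt))
    t_grid = dt * np.arange(n_steps + 1)
    t_mid = t_grid[:-1] + dt / 2.0

    seg_windows = params.segments
    rate_resp = params.event_rate_response.get(spec.species, params.event_rate_control)
    if spec.is_control and spec.order_index > 0:
        rate_resp += params.control2_inflation
    rates = {"control": params.event_rate_control, "response": rate_resp}
    amp_scale = {
        "control": 1.0,
        "response": params.amplitude_scale.get(spec.species, 1.0),
    }

    events: list[PlantedEvent] = []
    pulse = np.zeros(n_steps)
    for segment, (s0, s1) in seg_windows.items():
        rate = rates[segment] * (s1 - s0) / 600.0
        n = rng.poisson(rate) if n_events is None else int(n_events.get(segment, 0))
        duration = params.event_duration_mean
        starts = _place_events(rng, n, s0, s1, duration)
        for start in starts:
            lo, hi = params.amplitude_mean - 2 * params.amplitude_sd, params.amplitude_mean + 2 * params.amplitude_sd
            amp = float(np.clip(rng.normal(params.amplitude_mean, params.amplitude_sd), lo, hi))
            amp *= amp_scale[segment]
            inside = (t_mid >= start) & (t_mid <= start + duration)
            phase = (t_mid[inside] - start) / duration
            pulse[inside] += amp / 2.0 * (1.0 - np.cos(2.0 * np.pi * phase))
            events.append(PlantedEvent(segment, float(start), float(start + duration), amp))

    baseline = params.drift_slope * dt + params.drift_wobble * np.abs(
        np.sin(2.0 * np.pi * t_mid / params.drift_period_s)
    )
    noise = _smooth_noise(rng, n_steps, params.noise_sd, params.noise_corr_s / dt)
    step_mag = np.maximum(pulse + baseline + noise, 0.0)

    # Step directions: fixed per event (a contraction pulls the marker along
    # one axis of motion), slowly wandering for baseline steps.  Direction
    # never affects the displacement magnitudes used downstream.
    theta = np.cumsum(rng.normal(0.0, 0.3, size=n_steps))
    for ev in events:
        inside = (t_mid >= ev.start_s) & (t_mid <= ev.end_s)
        theta[inside] = rng.uniform(0.0, 2.0 * np.pi)
    steps = step_mag[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])

    anchors = np.vstack([[60.0, 60.0], np.cumsum(steps, axis=0) + [60.0, 60.0]])

    # Native-resolution track: linear interpolation of the 5-s anchors, so
    # resampling back onto the analysis grid is exact.
    n_native = int(round(params.total_duration / params.frame_interval))
    t_native = params.frame_interval * np.arange(n_native + 1)
    tracks: dict[str, MarkerTrack] = {}
    for marker in MARKER_LABELS:
        if marker == spec.organ:
            ax, ay = anchors[:, 0], anchors[:, 1]
        else:
            # quiet marker: baseline-only motion with its own noise stream
            sub = np.random.default_rng(rng.integers(2**31))
            mag = np.maximum(
                baseline + _smooth_noise(sub, n_steps, params.noise_sd, params.noise_corr_s / dt), 0.0
            )
            th = np.cumsum(sub.normal(0.0, 0.3, size=n_steps))
            offset = {"diverticulum": (60.0, 60.0), "copulatory_canal": (200.0, 60.0), "atrium": (130.0, 160.0)}[marker]
            pos = np.vstack([[0.0, 0.0], np.cumsum(mag[:, None] * np.column_stack([np.cos(th), np.sin(th)]), axis=0)])
            ax, ay = pos[:, 0] + offset[0], pos[:, 1] + offset[1]
        x = np.interp(t_native, t_grid, ax)
        y = np.interp(t_native, t_grid, ay)
        tracks[marker] = MarkerTrack(marker, t_native, x, y, units="du")

    n_ctrl = sum(e.segment == "control" for e in events)
    n_resp = sum(e.segment == "response" for e in events)
    truth = PlantedTruth(spec.trial_id, tuple(events), n_ctrl, n_resp)
    return tracks, truth


def simulate_day(params: SimulationParams, day_id: int, rng: np.random.Generator | None = None,
                 organ: str = "diverticulum") -> list[TrialSpec]:
    """Trial order for one experimental day.

    The focal species is used as positive control once at the beginning and
    once at the end of the day; in between, up to five other species are
    drawn without replacement in random order (each extract used once).
    """
    others = [s for s in params.species_labels if s != params.focal_species]
    if not others:
        raise ValueError("need at least one non-control species")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, day_id, 202)))
    n_mid = min(params.trials_per_day - 2, 5, len(others))
    middle = list(rng.choice(others, size=n_mid, replace=False))
    order = [params.focal_species] + middle + [params.focal_species]
    specs = []
    for idx, sp in enumerate(order):
        is_control = idx == 0 or idx == len(order) - 1
        specs.append(
            TrialSpec(
                trial_id=f"d{day_id:02d}_t{idx}",
                day=day_id,
                order_index=idx,
                species=sp,
                organ=organ,
                is_control=is_control,
            )
        )
    return specs


def simulate_lengths(
    params: SimulationParams,
    species: str,
    rng: np.random.Generator | None = None,
    trial_id: str = "t0",
):
    """Paired diverticulum length measurements for one trial.

    Three digitized measurements per side of the organ at time 0 around a
    true length L0, and six more 15 min later around ``L0 * (1 - effect)``
    where ``effect`` is the species' fractional shortening.  Returns a
    pandas DataFrame in the long measurement dialect
    ``trial_id species timepoint side rep length_mm``.
    """
    import pandas as pd

    effect = params.shortening_effect.get(species, 0.0)
    if not (0.0 <= effect < 1.0):
        raise ValueError("shortening effect must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, hash(species) % 2**31, 303)))
    L0 = params.length_mm + rng.normal(0.0, params.length_between_sd_mm)
    rows = []
    for timepoint, mean in ((0, L0), (15, L0 * (1.0 - effect))):
        for side in ("left", "right"):
            for rep in (1, 2, 3):
                length = mean + rng.normal(0.0, params.length_noise_sd_mm)
                rows.append(
                    {
                        "trial_id": trial_id,
                        "species": species,
                        "timepoint": timepoint,
                        "side": side,
                        "rep": rep,
                        "length_mm": length,
                    }
                )
    return pd.DataFrame(rows)


def simulate_bm_traits(tree, sigma2: float, seed: int | None = None,
                       root_state: float = 0.0, size: int | None = None):
    """Brownian-motion trait draw(s) on a tree.

    The tip values are multivariate-normal draws with mean ``root_state``
    and covariance ``sigma2 * V`` where ``V[i, j]`` is the shared root-to-MRCA
    path length.  ``sigma2 = 0`` returns the root state at every tip.
    With ``size=None`` returns one tip-keyed dict; with an integer ``size``
    returns a pandas DataFrame of ``size`` replicate rows (tips as columns).
    """
    import pandas as pd

    from .phylo import vcv

    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    labels, V = vcv(tree)
    n = len(labels)
    if np.max(np.diag(V)) <= 0:
        raise ValueError("tree has zero total branch length")
    rng = np.random.default_rng(seed)
    m = 1 if size is None else int(size)
    if sigma2 == 0:
        X = np.full((m, n), float(root_state))
    else:
        jitter = 1e-12 * np.max(np.diag(V))
        L = np.linalg.cholesky(sigma2 * V + jitter * np.eye(n))
        X = root_state + rng.standard_normal((m, n)) @ L.T
    if size is None:
        return {lab: float(v) for lab, v in zip(labels, X[0])}
    return pd.DataFrame(X, columns=labels)


def render_frames(
    tracks: Sequence[MarkerTrack],
    frame_size: tuple[int, int] = (220, 260),
    marker_px: int = 5,
) -> np.ndarray:
    """Render tracks as a grayscale stack: light background, dark squares.

    Each marker is drawn as a ``marker_px``-sided dark square centred on its
    (x, y) coordinate with sub-pixel box coverage, so the intensity-weighted
    centroid of the rendered blob recovers the input coordinate.  All
    coordinates must lie inside the frame with a half-marker margin.
    """
    if not tracks:
        raise ValueError("no tracks to render")
    times = tracks[0].time_s
    for tr in tracks[1:]:
        if not np.array_equal(tr.time_s, times):
            raise ValueError("all tracks must share the same time grid")
    h, w = frame_size
    half = marker_px / 2.0
    for tr in tracks:
        if (tr.x.min() < half + 1 or tr.x.max() > w - half - 2
                or tr.y.min() < half + 1 or tr.y.max() > h - half - 2):
            raise ValueError(f"track {tr.marker_id!r} leaves the frame bounds")
    stack = np.full((len(times), h, w), 255, dtype=np.uint8)
    cols = np.arange(w)
    rows = np.arange(h)
    for k in range(len(times)):
        frame = np.zeros((h, w))
        for tr in tracks:
            cx, cy = tr.x[k], tr.y[k]
            cov_x = np.clip(np.minimum(cols + 0.5, cx + half) - np.maximum(cols - 0.5, cx - half), 0.0, 1.0)
            cov_y = np.clip(np.minimum(rows + 0.5, cy + half) - np.maximum(rows - 0.5, cy - half), 0.0, 1.0)
            frame += np.outer(cov_y, cov_x)
        stack[k] = np.clip(255.0 * (1.0 - frame), 0, 255).round().astype(np.uint8)
    return stack
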