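"""Minimal marker tracking for organ-bath video stacks.

The study preparation carries three ~2 mm^2 squares of black electrical tape
(on the diverticulum, the copulatory canal and the genital atrium) whose
positions are followed frame by frame.  This module provides a small,
deterministic re-implementation of that step: dark-blob segmentation by Otsu
threshold on the inverted image, intensity-weighted centroids, and
nearest-neighbour identity linking, plus resampling of the resulting tracks
onto the 5-second analysis grid.

Coordinates follow the image convention: origin top-left, x to the right
(columns), y down (rows).  All downstream quantities are displacement
magnitudes, so the convention never leaks into results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "MarkerTrack",
    "TrackingResult",
    "track_markers",
    "resample_5s",
]

#: canonical marker labels, in the order they are glued onto the preparation
MARKER_LABELS = ("diverticulum", "copulatory_canal", "atrium")


@dataclass
class MarkerTrack:
    """One marker's (time, x, y) series.

    Parameters
    ----------
    marker_id:
        Label of the marker (``diverticulum``, ``copulatory_canal`` or
        ``atrium`` in the standard preparation; arbitrary labels allowed).
    time_s:
        Strictly increasing sample times in seconds.
    x, y:
        Coordinates, in pixels or abstract displacement units (``units``).
    """

    marker_id: str
    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    units: str = "px"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time_s.shape == self.x.shape == self.y.shape):
            raise ValueError("time_s, x and y must have equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass
class TrackingResult:
    """Tracks plus usability flags from :func:`track_markers`."""

    tracks: list[MarkerTrack]
    usable: bool
    gap_fraction: float
    notes: list[str] = field(default_factory=list)


def _frame_centroids(frame: np.ndarray, n_markers: int) -> np.ndarray:
    """Centroids (x, y) of the ``n_markers`` largest dark blobs of a frame.

    Segmentation is Otsu on the inverted intensity, which makes the result
    invariant to global affine rescaling of the frame intensities.  Centroids
    are intensity-weighted so that anti-aliased marker edges contribute
    sub-pixel information.
    """
    inv = frame.max() - frame.astype(float)
    if np.ptp(inv) == 0:
        return np.empty((0, 2))
    mask = inv > threshold_otsu(inv)
    props = regionprops(label(mask), intensity_image=inv)
    props.sort(key=lambda p: p.area, reverse=True)
    cents = []
    h, w = inv.shape
    for p in props[:n_markers]:
        # weighted centroid over the bounding box grown by one pixel: the
        # anti-aliased marker edges fall below the Otsu cut but carry the
        # sub-pixel information, while background weight is ~zero there
        r0, c0, r1, c1 = p.bbox
        r0, c0 = max(r0 - 1, 0), max(c0 - 1, 0)
        r1, c1 = min(r1 + 1, h), min(c1 + 1, w)
        win = inv[r0:r1, c0:c1]
        tot = win.sum()
        rr = (win.sum(axis=1) @ np.arange(r0, r1)) / tot
        cc = (win.sum(axis=0) @ np.arange(c0, c1)) / tot
        cents.append((cc, rr))
    return np.asarray(cents, dtype=float)


def track_markers(
    stack: np.ndarray,
    n_markers: int,
    init_positions=None,
    *,
    times=None,
    search_radius: float = 20.0,
    max_gap: int = 3,
    max_gap_fraction: float = 0.10,
) -> TrackingResult:
    """Track ``n_markers`` dark markers through a grayscale frame stack.

    Per frame, dark pixels are thresholded (Otsu on inverted intensity),
    connected components give candidate centroids, and candidates are linked
    to the previous marker positions by globally optimal nearest-neighbour
    assignment.  A marker with no candidate within ``search_radius`` px is a
    gap; gaps of at most ``max_gap`` consecutive frames are bridged by linear
    interpolation, anything longer (or an overall gap fraction above
    ``max_gap_fraction``) marks the result unusable.

    Parameters
    ----------
    stack:
        Array of shape (n_frames, height, width).
    n_markers:
        Number of markers to follow (3 in the standard preparation).
    init_positions:
        Optional (n_markers, 2) array of (x, y) seeds used to assign marker
        identities on the first frame; defaults to the detection order.
    times:
        Optional per-frame times in seconds; defaults to frame index.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, height, width)")
    n_frames = stack.shape[0]
    if times is None:
        times = np.arange(n_frames, dtype=float)
    times = np.asarray(times, dtype=float)

    pos = np.full((n_frames, n_markers, 2), np.nan)
    notes: list[str] = []

    first = _frame_centroids(stack[0], n_markers)
    if first.shape[0] < n_markers:
        raise ValueError(
            f"first frame has {first.shape[0]} candidate markers, expected {n_markers}"
        )
    if init_positions is not None:
        init_positions = np.asarray(init_positions, dtype=float)
        cost = np.linalg.norm(first[None, :, :] - init_positions[:, None, :], axis=-1)
        rows, cols = linear_sum_assignment(cost)
        pos[0, rows] = first[cols]
    else:
        pos[0] = first[:n_markers]

    last_known = pos[0].copy()
    for k in range(1, n_frames):
        cand = _frame_centroids(stack[k], n_markers)
        if cand.shape[0] == 0:
            continue
        cost = np.linalg.norm(last_known[:, None, :] - cand[None, :, :], axis=-1)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] <= search_radius:
                pos[k, r] = cand[c]
                last_known[r] = cand[c]

    usable = True
    total_gaps = int(np.isnan(pos[:, :, 0]).sum())
    gap_fraction = total_gaps / (n_frames * n_markers)
    if gap_fraction > max_gap_fraction:
        usable = False
        notes.append(f"gap fraction {gap_fraction:.2%} exceeds {max_gap_fraction:.0%}")

    tracks: list[MarkerTrack] = []
    for m in range(n_markers):
        xy = pos[:, m, :]
        missing = np.isnan(xy[:, 0])
        if missing.any():
            run = _longest_run(missing)
            if run > max_gap:
                usable = False
                notes.append(f"marker {m}: {run} consecutive lost frames (> {max_gap})")
            good = ~missing
            for d in range(2):
                xy[missing, d] = np.interp(times[missing], times[good], xy[good, d])
        label_m = MARKER_LABELS[m] if m < len(MARKER_LABELS) else f"marker_{m}"
        tracks.append(MarkerTrack(label_m, times.copy(), xy[:, 0], xy[:, 1]))

    return TrackingResult(tracks=tracks, usable=usable, gap_fraction=gap_fraction, notes=notes)


def _longest_run(mask: np.ndarray) -> int:
    longest = run = 0
    for v in mask:
        run = run + 1 if v else 0
        longest = max(longest, run)
    return longest


def resample_5s(track: MarkerTrack, dt: float = 5.0, method: str = "linear") -> MarkerTrack:
    """Resample a track onto the 0, dt, 2*dt, ... analysis grid.

    The study analyses marker displacement every 5 seconds; recordings are
    made at a (finer) native frame interval, so tracks are reduced onto the
    5-s grid either by linear interpolation (default) or by taking the
    nearest native sample.

    The grid starts at the track's first sample time.  A 600-s segment
    sampled this way has 121 grid points (120 displacement intervals).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = track.time_s
    if t.size < 2 or t[-1] - t[0] < dt:
        raise ValueError("track shorter than one resampling interval")
    native_dt = np.max(np.diff(t))
    if native_dt > dt + 1e-9:
        raise ValueError(f"native sampling ({native_dt} s) coarser than dt={dt} s")
    n_out = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    grid = t[0] + dt * np.arange(n_out)
    if method == "linear":
        x = np.interp(grid, t, track.x)
        y = np.interp(grid, t, track.y)
    elif method == "nearest":
        idx = np.abs(t[None, :] - grid[:, None]).argmin(axis=1)
        x = track.x[idx]
        y = track.y[idx]
    else:
        raise ValueError(f"unknown method {method!r}")
    return replace(track, time_s=grid, x=x, y=y)
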