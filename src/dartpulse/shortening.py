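"""Diverticulum-shortening measurements and summaries.

Within seconds of adding certain species' mucous extract the diverticulum
becomes shorter.  The measurement protocol: photograph the preparation
after the control period (time 0) and after the response period (15 min
later); digitize the organ length from tip to the branching of the bursa
copulatrix tract, three measurements per side of the organ at each time
point.  The record keeps the grand mean of the six raw measurements at each
time point, the shortening in mm (mean_L0 - mean_L15) and in percent of the
time-0 length.

Lengths enter in millimetres (digitized polyline lengths);
:func:`polyline_length_mm` converts a traced polyline of image coordinates
with a mm/px scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import one_way_anova

__all__ = [
    "ShorteningRecord",
    "records_from_table",
    "summarize_shortening",
    "log_length_long",
    "baseline_recovery_check",
    "polyline_length_mm",
]

#: provenance note stored with every record
MEASUREMENT_LANDMARKS = "tip to the branching of the bursa copulatrix tract"


@dataclass(frozen=True)
class ShorteningRecord:
    """Paired length measurements of one trial (six per time point, mm)."""

    trial_id: str
    species: str
    lengths_t0: tuple[float, ...]
    lengths_t15: tuple[float, ...]
    landmarks: str = MEASUREMENT_LANDMARKS

    def __post_init__(self) -> None:
        for vals in (self.lengths_t0, self.lengths_t15):
            if any(v <= 0 for v in vals):
                raise ValueError("lengths must be positive")
        if not self.lengths_t0 or not self.lengths_t15:
            raise ValueError("both time points need measurements")

    @property
    def mean_L0(self) -> float:
        return float(np.mean(self.lengths_t0))

    @property
    def mean_L15(self) -> float:
        return float(np.mean(self.lengths_t15))

    @property
    def delta_mm(self) -> float:
        return self.mean_L0 - self.mean_L15

    @property
    def delta_pct(self) -> float:
        # computed from the means, not per measurement
        return 100.0 * self.delta_mm / self.mean_L0


def records_from_table(table: pd.DataFrame) -> list[ShorteningRecord]:
    """Build records from the long measurement dialect.

    Expects columns ``trial_id species timepoint side rep length_mm`` with
    timepoints 0 and 15.
    """
    records = []
    for (trial_id, species), grp in table.groupby(["trial_id", "species"], sort=True):
        t0 = tuple(grp.loc[grp["timepoint"] == 0, "length_mm"].astype(float))
        t15 = tuple(grp.loc[grp["timepoint"] == 15, "length_mm"].astype(float))
        records.append(ShorteningRecord(str(trial_id), str(species), t0, t15))
    return records


def summarize_shortening(records: list[ShorteningRecord]) -> pd.DataFrame:
    """Per-species mean shortening in mm and percent, with SE and n."""
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "delta_mm": [r.delta_mm for r in records],
            "delta_pct": [r.delta_pct for r in records],
        }
    )
    out = (
        df.groupby("species")
        .agg(
            n=("delta_mm", "size"),
            mean_delta_mm=("delta_mm", "mean"),
            se_delta_mm=("delta_mm", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
            mean_delta_pct=("delta_pct", "mean"),
            se_delta_pct=("delta_pct", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
        )
        .reset_index()
    )
    return out


def log_length_long(records: list[ShorteningRecord]) -> pd.DataFrame:
    """Long-format log-lengths for the mixed ANOVA (subject = trial)."""
    rows = []
    for r in records:
        rows.append({"subject": r.trial_id, "species": r.species, "time": 0, "value": np.log(r.mean_L0)})
        rows.append({"subject": r.trial_id, "species": r.species, "time": 15, "value": np.log(r.mean_L15)})
    return pd.DataFrame(rows)


def baseline_recovery_check(records: list[ShorteningRecord], order: dict[str, int]):
    """One-way ANOVA of time-0 lengths across trial-order positions.

    A significant order effect would mean the organ did not regain its
    resting length between trials.  ``order`` maps trial_id to its position
    in the day.  Returns ``(F, df, p, recovered)`` with ``recovered`` True
    when p >= 0.05.
    """
    by_order: dict[int, list[float]] = {}
    for r in records:
        by_order.setdefault(order[r.trial_id], []).append(r.mean_L0)
    groups = [v for _, v in sorted(by_order.items())]
    F, df, p = one_way_anova(groups)
    return F, df, p, p >= 0.05


def polyline_length_mm(points: np.ndarray, mm_per_px: float = 1.0) -> float:
    """Length of a digitized polyline of (x, y) image coordinates, in mm."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
        raise ValueError("need an (n >= 2, 2) array of points")
    return float(mm_per_px * np.hypot(*np.diff(points, axis=0).T).sum())
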