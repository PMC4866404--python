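"""Daily-control normalization and species-level response summaries.

The diverticulum's responsiveness drifts within an experimental day (the
second positive control tends to score higher than the first), so species
responses are expressed relative to that day's two focal-species controls:

* ``induced_rel`` — a trial's induced contraction count minus the mean
  induced count of the day's two controls (the controls of a day therefore
  average exactly 0);
* ``intensity_rel_pct`` — trial intensity on a 0-100 scale where 100 is the
  day's mean control intensity and 0 is a configured zero-response baseline
  (0 displacement units for synthetic data).

Species-level responder percentages count how often the response period
beat the control period; for the focal species the two control time points
are averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "apply_exclusions",
    "relative_response",
    "percent_responders",
]


def apply_exclusions(
    scores: pd.DataFrame,
    drop_atrium: bool = True,
    drop_nonresponsive_days: bool = False,
) -> pd.DataFrame:
    """Mirror the study's exclusion rules on a scores table.

    The atrium stream shows very low reaction and is excluded by default.
    With ``drop_nonresponsive_days``, days on which an organ responded to no
    species' mucus at all are dropped for that organ.
    """
    out = scores.copy()
    if drop_atrium:
        out = out[out["organ"] != "atrium"]
    if drop_nonresponsive_days:
        keep = []
        for (organ, day), grp in out.groupby(["organ", "day"]):
            if grp["responded"].any():
                keep.append((organ, day))
        mask = out.set_index(["organ", "day"]).index.isin(keep)
        out = out[mask]
    return out.reset_index(drop=True)


def _day_controls(day_scores: pd.DataFrame) -> pd.DataFrame:
    ctrl = day_scores[day_scores["is_control"]]
    if len(ctrl) != 2:
        raise ValueError(
            f"day {day_scores['day'].iloc[0]}: expected exactly 2 control trials, got {len(ctrl)}"
        )
    return ctrl


def relative_response(scores: pd.DataFrame, zero_baseline: float = 0.0) -> pd.DataFrame:
    """Per-trial relative responses, normalized within experimental day.

    Requires columns ``trial_id species organ day induced intensity
    is_control`` and exactly two control trials per (organ, day).  The
    intensity anchor requires ``zero_baseline`` below each day's mean
    control intensity.
    """
    rows = []
    for (organ, day), grp in scores.groupby(["organ", "day"], sort=True):
        ctrl = _day_controls(grp)
        ctrl_induced = ctrl["induced"].mean()
        ctrl_intensity = ctrl["intensity"].mean()
        if zero_baseline >= ctrl_intensity:
            raise ValueError(
                f"zero-response baseline ({zero_baseline}) must lie below the "
                f"day-{day} control mean intensity ({ctrl_intensity})"
            )
        for _, tr in grp.iterrows():
            rows.append(
                {
                    "trial_id": tr["trial_id"],
                    "species": tr["species"],
                    "organ": organ,
                    "day": day,
                    "order": tr.get("order", np.nan),
                    "is_control": tr["is_control"],
                    "induced_rel": tr["induced"] - ctrl_induced,
                    "intensity_rel_pct": 100.0
                    * (tr["intensity"] - zero_baseline)
                    / (ctrl_intensity - zero_baseline),
                }
            )
    return pd.DataFrame(rows)


def percent_responders(scores: pd.DataFrame) -> pd.DataFrame:
    """Percentage of trials in which each organ responded, per species.

    A trial responds when its response-period contraction count strictly
    exceeds its control-period count.  For the focal (control) species the
    day's two control time points are tallied separately and the two
    percentages averaged, so each day contributes equally.
    Returns columns ``organ species n_trials pct_responded``.
    """
    rows = []
    for (organ, species), grp in scores.groupby(["organ", "species"], sort=True):
        if len(grp) < 1:
            continue
        ctrl = grp[grp["is_control"]]
        if len(ctrl):
            # average the first-of-day and last-of-day control percentages
            first_order = ctrl["order"].min()
            pct1 = 100.0 * ctrl[ctrl["order"] == first_order]["responded"].mean()
            late = ctrl[ctrl["order"] > first_order]
            pct = float(np.mean([pct1, 100.0 * late["responded"].mean()])) if len(late) else float(pct1)
            rows.append({"organ": organ, "species": species, "n_trials": len(ctrl), "pct_responded": pct})
        else:
            rows.append(
                {
                    "organ": organ,
                    "species": species,
                    "n_trials": len(grp),
                    "pct_responded": 100.0 * grp["responded"].mean(),
                }
            )
    return pd.DataFrame(rows).sort_values(["organ", "species"]).reset_index(drop=True)
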