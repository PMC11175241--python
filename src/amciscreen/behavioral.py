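"""The six virtual-kiosk behavioral features, computed from raw session logs.

Eye movement: *scanpath length* (cumulative 3-D gaze travel, m) and
*proportion of fixation duration* (% of menu-dwell time spent on the target
item). Hand movement: *hand movement distance* (cumulative 3-D hand travel,
m) and *hand movement speed* (distance / task time, m/s). Performance:
*time to completion* (s, through the step-6 completion event) and *number
of errors* (count of error events).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import VRSessionLog

BEHAVIORAL_FEATURE_NAMES = (
    "scanpath_length",
    "fixation_proportion",
    "hand_distance",
    "hand_speed",
    "time_to_completion",
    "n_errors",
)


@dataclass(frozen=True)
class BehavioralFeatures:
    """The six per-session kiosk features."""

    scanpath_length: float      # m
    fixation_proportion: float  # % of menu dwell time on the target item
    hand_distance: float        # m
    hand_speed: float           # m/s
    time_to_completion: float   # s
    n_errors: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in BEHAVIORAL_FEATURE_NAMES}


def _path_length(df: pd.DataFrame) -> float:
    """Sum of consecutive Euclidean distances; rows with missing coordinates
    (blinks / tracking dropouts) are removed, never interpolated."""
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    xyz = xyz[~np.isnan(xyz).any(axis=1)]
    if len(xyz) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())


def _dwell_times(t: np.ndarray) -> np.ndarray:
    """Per-sample dwell durations: forward differences, last sample 0."""
    dt = np.zeros_like(t)
    if len(t) > 1:
        dt[:-1] = np.diff(t)
    return dt


def extract_behavioral_features(
    log: VRSessionLog,
    stationary_speed: float | None = None,
) -> BehavioralFeatures:
    """Compute the six behavioral features from a session log.

    ``fixation_proportion`` uses sample-wise AOI dwell time: every gaze
    sample contributes its dwell duration to its labeled area of interest,
    and the feature is 100 × target-item time / all-menu-item time.

    ``hand_speed`` defaults to hand_distance / time_to_completion; pass
    ``stationary_speed`` (m/s) to instead divide by active movement time
    only (samples moving faster than the cutoff).
    """
    if log.gaze.empty or log.hand.empty or log.events.empty:
        raise ValueError("session log has an empty stream")
    completions = log.events[(log.events["step"].astype(int) == 6)
                             & (~log.events["is_error"].astype(bool))]
    if completions.empty:
        raise ValueError("session has no step-6 completion event")

    session_start = min(
        float(log.gaze["t"].iloc[0]),
        float(log.hand["t"].iloc[0]),
        float(log.events["t"].iloc[0]),
    )
    time_to_completion = float(completions["t"].iloc[-1]) - session_start
    if time_to_completion <= 0:
        raise ValueError("non-positive session duration")

    scanpath = _path_length(log.gaze)

    gaze = log.gaze
    valid = ~gaze[["x", "y", "z"]].isna().any(axis=1).to_numpy()
    dt = _dwell_times(gaze["t"].to_numpy(dtype=float))[valid]
    aoi = gaze["aoi"].to_numpy()[valid]
    target_time = dt[aoi == "target"].sum()
    menu_time = dt[(aoi == "target") | (aoi == "nontarget")].sum()
    fixation = 100.0 * target_time / menu_time if menu_time > 0 else 0.0

    hand_distance = _path_length(log.hand)
    if stationary_speed is None:
        active_time = time_to_completion
    else:
        ht = log.hand["t"].to_numpy(dtype=float)
        hxyz = log.hand[["x", "y", "z"]].to_numpy(dtype=float)
        seg_d = np.linalg.norm(np.diff(hxyz, axis=0), axis=1)
        seg_t = np.diff(ht)
        moving = seg_d / np.maximum(seg_t, 1e-12) > stationary_speed
        active_time = float(seg_t[moving].sum())
        if active_time <= 0:
            raise ValueError("no active hand movement above the stationary cutoff")
    hand_speed = hand_distance / active_time

    n_errors = int(log.events["is_error"].astype(bool).sum())

    return BehavioralFeatures(
        scanpath_length=scanpath,
        fixation_proportion=float(fixation),
        hand_distance=hand_distance,
        hand_speed=float(hand_speed),
        time_to_completion=time_to_completion,
        n_errors=n_errors,
    )
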