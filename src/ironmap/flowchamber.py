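"""Flow-chamber binding analysis by the dwell-time rule.

A tracked particle is deemed bound to the platelet monolayer when it stays
stationary for at least ``min_dwell`` seconds (10 s by default) within the
observation window (60 s).  "Stationary" is operationalized as: every
position of an interval lies within ``stationary_radius`` (2 um by default)
of the interval's first position.  The dwell of a track is the longest such
anchored interval; tracks still stationary when the window closes count
their observed dwell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import TrackTable
from .territory import compare_groups

DEFAULT_MIN_DWELL_S = 10.0
DEFAULT_STATIONARY_RADIUS_UM = 2.0
DEFAULT_OBSERVATION_WINDOW_S = 60.0

__all__ = [
    "DEFAULT_MIN_DWELL_S",
    "DEFAULT_STATIONARY_RADIUS_UM",
    "DEFAULT_OBSERVATION_WINDOW_S",
    "TrackClassification",
    "BindingResult",
    "classify_tracks",
    "binding_rate",
]


@dataclass(frozen=True)
class TrackClassification:
    track_id: int
    bound: bool
    dwell_s: float
    max_stationary_displacement_um: float


@dataclass
class BindingResult:
    """Per-track dwell classification plus the field-level bound count."""

    tracks: list[TrackClassification]
    bound_count: int
    min_dwell_s: float
    stationary_radius_um: float
    observation_window_s: float

    def labels(self) -> dict[int, bool]:
        return {t.track_id: t.bound for t in self.tracks}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "track_id": t.track_id,
                    "bound": t.bound,
                    "dwell_s": t.dwell_s,
                    "max_stationary_displacement_um":
                        t.max_stationary_displacement_um,
                }
                for t in self.tracks
            ]
        )

    def to_dict(self) -> dict:
        return {
            "bound_count": self.bound_count,
            "n_tracks": len(self.tracks),
            "min_dwell_s": self.min_dwell_s,
            "stationary_radius_um": self.stationary_radius_um,
            "observation_window_s": self.observation_window_s,
            "tracks": [
                {"track_id": t.track_id, "bound": t.bound, "dwell_s": t.dwell_s}
                for t in self.tracks
            ],
        }


def _longest_anchored_dwell(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, radius: float
) -> tuple[float, float]:
    """Longest interval during which all points stay within ``radius`` of
    the interval's first position.  Returns (dwell seconds, the maximum
    displacement from the anchor within that best interval)."""
    n = t.size
    best_dwell = 0.0
    best_disp = 0.0
    for i in range(n):
        dx = x[i:] - x[i]
        dy = y[i:] - y[i]
        d = np.hypot(dx, dy)
        inside = d <= radius
        # first departure from the anchor's disk ends the interval
        out = np.flatnonzero(~inside)
        j_end = out[0] - 1 if out.size else n - 1 - i
        if j_end < 0:
            continue
        dwell = t[i + j_end] - t[i]
        if dwell > best_dwell:
            best_dwell = float(dwell)
            best_disp = float(d[: j_end + 1].max())
    return best_dwell, best_disp


def classify_tracks(
    tracks: TrackTable,
    min_dwell_s: float = DEFAULT_MIN_DWELL_S,
    stationary_radius_um: float = DEFAULT_STATIONARY_RADIUS_UM,
    observation_window_s: float = DEFAULT_OBSERVATION_WINDOW_S,
) -> BindingResult:
    """Classify every track as bound/unbound by the dwell-time rule.

    Only observations within the observation window (measured from the
    earliest timestamp of the whole table, so the result is invariant to a
    constant time shift) are considered.  A track is bound when its longest
    anchored-stationary dwell is >= ``min_dwell_s``.
    """
    if stationary_radius_um <= 0:
        raise ValueError("stationary_radius_um must be > 0")
    df = tracks.frame
    results: list[TrackClassification] = []
    if len(df) == 0:
        return BindingResult([], 0, min_dwell_s, stationary_radius_um,
                             observation_window_s)
    t0 = float(df["t_s"].min())
    for tid, g in df.groupby("track_id", sort=True):
        t = g["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"track {tid}: timestamps not strictly increasing")
        in_window = t - t0 <= observation_window_s
        t_w = t[in_window]
        if t_w.size == 0:
            results.append(TrackClassification(int(tid), False, 0.0, 0.0))
            continue
        x = g["x_um"].to_numpy(dtype=float)[in_window]
        y = g["y_um"].to_numpy(dtype=float)[in_window]
        dwell, disp = _longest_anchored_dwell(t_w, x, y, stationary_radius_um)
        bound = dwell >= min_dwell_s
        results.append(TrackClassification(int(tid), bool(bound), dwell, disp))
    return BindingResult(
        tracks=results,
        bound_count=sum(t.bound for t in results),
        min_dwell_s=float(min_dwell_s),
        stationary_radius_um=float(stationary_radius_um),
        observation_window_s=float(observation_window_s),
    )


def binding_rate(
    field_counts: dict[str, list[int]],
    test: str = "mannwhitney",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize bound counts per field per group and compare the groups.

    ``field_counts`` maps group name -> bound count per observed field.
    Returns (per-group summary DataFrame, comparison table from
    :func:`ironmap.territory.compare_groups`).
    """
    for name, counts in field_counts.items():
        if len(counts) == 0:
            raise ValueError(f"group {name!r} has no fields")
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n_fields": len(counts),
                "median_bound": float(np.median(counts)),
                "mean_bound": float(np.mean(counts)),
            }
            for name, counts in field_counts.items()
        ]
    )
    comparison = compare_groups(field_counts, test=test)
    return summary, comparison
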