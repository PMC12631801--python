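"""Particle-track summary statistics from 2D time-lapse point tracks.

Inputs are point tracks (x, y in μm per frame, default 5 s frame interval),
as produced by spot-tracking tools; detection and linking are upstream and
out of scope.  Per track:

* displacement — straight-line distance from the first to the last point;
* total distance — sum of consecutive step lengths;
* rolling statistics over 10-frame windows (stride 1): the window's median
  step speed, SD of step speeds, and tortuosity (window path length /
  window net displacement; 1 for a straight path, undefined for a window
  with zero net displacement).  Windows are aggregated across the track by
  the median.  Tracks shorter than the window fall back to a single
  whole-track window and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .screen import mwu_screen


@dataclass(frozen=True)
class Track:
    """One particle track: ordered (x, y) μm points with frame indices."""

    points: np.ndarray  # (n, 2) in μm
    frames: np.ndarray  # (n,), strictly increasing
    frame_interval: float = 5.0  # s
    track_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        frames = np.asarray(self.frames)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"points must be (n, 2), got {pts.shape}")
        if len(pts) < 2:
            raise ValidationError("a track needs at least 2 points")
        if len(frames) != len(pts):
            raise ValidationError("frames and points must have equal length")
        if np.any(np.diff(frames) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValidationError("frame interval must be positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "frames", frames)


@dataclass(frozen=True)
class TrackSummary:
    """Per-track dynamics metrics, μm and μm/s."""

    track_id: str
    displacement: float
    total_distance: float
    median_speed: float
    sd_speed: float
    tortuosity: float  # ≥ 1 when defined, NaN otherwise
    whole_track_fallback: bool  # track shorter than the rolling window

    def as_dict(self) -> dict[str, float]:
        return {
            "displacement": self.displacement,
            "total_distance": self.total_distance,
            "median_speed": self.median_speed,
            "sd_speed": self.sd_speed,
            "tortuosity": self.tortuosity,
        }


def _window_stats(pts: np.ndarray, dt_steps: np.ndarray) -> tuple[float, float, float]:
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    speeds = steps / dt_steps
    net = float(np.linalg.norm(pts[-1] - pts[0]))
    path = float(steps.sum())
    tort = path / net if net > 0 else float("nan")
    sd = float(speeds.std(ddof=1)) if len(speeds) > 1 else float("nan")
    return float(np.median(speeds)), sd, tort


def summarize_track(track: Track, window: int = 10) -> TrackSummary:
    """Displacement, distance, and rolling-window speed/tortuosity statistics."""
    pts = track.points
    dt = np.diff(track.frames) * track.frame_interval
    displacement = float(np.linalg.norm(pts[-1] - pts[0]))
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(steps.sum())

    n = len(pts)
    fallback = n < window
    if fallback:
        starts = [0]
        window = n
    else:
        starts = list(range(0, n - window + 1))
    med_speeds, sd_speeds, torts = [], [], []
    for s in starts:
        m, sd, t = _window_stats(pts[s : s + window], dt[s : s + window - 1])
        med_speeds.append(m)
        sd_speeds.append(sd)
        torts.append(t)
    torts_def = [t for t in torts if np.isfinite(t)]
    sd_def = [s for s in sd_speeds if np.isfinite(s)]
    return TrackSummary(
        track_id=track.track_id,
        displacement=displacement,
        total_distance=total,
        median_speed=float(np.median(med_speeds)),
        sd_speed=float(np.median(sd_def)) if sd_def else float("nan"),
        tortuosity=float(np.median(torts_def)) if torts_def else float("nan"),
        whole_track_fallback=fallback,
    )


def summaries_frame(summaries: list[TrackSummary], group: str | None = None) -> pd.DataFrame:
    """Track summaries as a table, optionally labeled with a group."""
    df = pd.DataFrame([{"track_id": s.track_id, **s.as_dict()} for s in summaries])
    if group is not None:
        df.insert(1, "group", group)
    return df


def compare_groups(
    summaries_a: list[TrackSummary],
    summaries_b: list[TrackSummary],
    label_a: str = "A",
    label_b: str = "B",
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Per-metric Mann-Whitney U screen between two track populations."""
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        raise ValidationError("each group needs at least 2 tracks")
    table = pd.concat(
        [summaries_frame(summaries_a, label_a), summaries_frame(summaries_b, label_b)],
        ignore_index=True,
    )
    return mwu_screen(
        table, label_a, label_b, fdr=fdr,
        metric_cols=[c for c in table.columns if c not in ("track_id", "group")],
    )


def read_tracks(path, frame_interval: float = 5.0) -> list[Track]:
    """Read tracks from a CSV with columns ``track_id, frame, x, y`` (μm)."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"track table missing column(s): {sorted(missing)}")
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        out.append(
            Track(
                points=sub[["x", "y"]].to_numpy(),
                frames=sub["frame"].to_numpy(),
                frame_interval=frame_interval,
                track_id=str(tid),
            )
        )
    return out


__all__ = [
    "Track",
    "TrackSummary",
    "summarize_track",
    "summaries_frame",
    "compare_groups",
    "read_tracks",
]
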