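"""Base-point motion analysis for growth-cone tracks.

A growth cone (GC) is tracked by the position of its base — the point where
the GC joins its neurite — at regular intervals over a time-lapse movie.
This module quantifies that motion: path length, velocity, per-step turning
angle alpha, per-track mean angle, and a three-way turning classification
(horizontal / diagonal / vertical).

Angle convention (image coordinates, y increasing downward): alpha is the
signed angle of the most recent displacement vector, in degrees in
(-180, +180].  0 deg points right (+x), +90 deg points down (+y), -90 deg
points up, and +180 deg (== -180 deg) points left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackSummary",
    "orient_track",
    "resample_track",
    "step_angles",
    "track_summary",
    "classify_turning",
    "read_track_csv",
    "write_summary_csv",
]

#: Half-width (degrees) of the sectors around the named turning headings.
SECTOR_HALF_WIDTH = 22.5


@dataclass(frozen=True)
class Track:
    """Time-ordered base-point positions of one growth cone.

    Parameters
    ----------
    t : array of float
        Times in seconds, strictly increasing.
    x, y : array of float
        Positions in micrometres, image convention (y increases downward).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.t.size

    @property
    def length(self) -> float:
        """Total path length (sum of Euclidean step distances), micrometres."""
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


@dataclass(frozen=True)
class TrackSummary:
    length: float  # micrometres
    velocity: float  # micrometres / second
    mean_angle: float  # degrees in (-180, 180]
    n_steps: int = 0
    n_zero_steps: int = 0
    turning_class: str = field(default="")


def orient_track(track: Track, rotation: float) -> Track:
    """Rigidly rotate a track about its first point and move that point to the origin.

    ``rotation`` (degrees) is added to every step angle: rotating by +45 deg
    turns each displacement vector by +45 deg in the image (y-down) frame.
    Distances are preserved.
    """
    if not math.isfinite(rotation):
        raise ValueError("rotation must be finite")
    if len(track) == 0:
        return track
    theta = math.radians(rotation)
    c, s = math.cos(theta), math.sin(theta)
    dx = track.x - track.x[0]
    dy = track.y - track.y[0]
    # R(theta) in the y-down frame adds theta to atan2(y, x) headings.
    xr = c * dx - s * dy
    yr = s * dx + c * dy
    return Track(track.t.copy(), xr, yr)


def resample_track(track: Track, interval: float = 300.0) -> Track:
    """Keep only points at multiples of ``interval`` seconds from the start.

    The last point is kept regardless, so the full elapsed time survives.
    A 5-minute interval (the default) smooths out frame-to-frame jitter in
    manual tracking.  ``interval`` must be a positive multiple of the native
    spacing.
    """
    if len(track) < 2:
        return track
    native = float(np.min(np.diff(track.t)))
    if interval <= 0 or interval < native - 1e-9:
        raise ValueError(
            f"interval ({interval} s) must be a positive multiple of the "
            f"native spacing ({native} s)"
        )
    ratio = interval / native
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            f"interval ({interval} s) is not a multiple of the native spacing "
            f"({native} s)"
        )
    rel = track.t - track.t[0]
    keep = np.isclose(np.mod(rel, interval), 0.0, atol=1e-6) | np.isclose(
        np.mod(rel, interval), interval, atol=1e-6
    )
    keep[-1] = True
    return Track(track.t[keep], track.x[keep], track.y[keep])


def step_angles(track: Track, *, return_flags: bool = False):
    """Per-step turning angles alpha in degrees, range (-180, +180].

    alpha = atan2(dy, dx) in the y-down image frame, so +90 deg points
    downward.  Zero-length steps emit no angle; with ``return_flags=True`` a
    boolean array over steps marks which steps were zero-length.
    """
    if len(track) < 2:
        raise ValueError("step angles need at least 2 points")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    zero = (dx == 0) & (dy == 0)
    ang = np.degrees(np.arctan2(dy[~zero], dx[~zero]))
    # atan2 returns [-180, 180]; fold -180 onto +180 (same direction).
    ang[ang <= -180.0] = 180.0
    if return_flags:
        return ang, zero
    return ang


def _wrap_angle(a: float) -> float:
    """Map any angle in degrees to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def track_summary(
    track: Track, *, circular_mean: bool = False, classify: bool = True
) -> TrackSummary:
    """Length, velocity and mean turning angle of one (resampled) track.

    length   = sum of Euclidean step distances (micrometres)
    velocity = length / elapsed time (micrometres / second)
    mean_angle = arithmetic mean of the per-step signed angles alpha.  The
    arithmetic mean matches the reference tracker's per-track "average alpha";
    it is pathological when steps straddle the +-180 deg cut — pass
    ``circular_mean=True`` for the circular (vector) mean instead.
    """
    if len(track) < 2:
        raise ValueError("track summary needs at least 2 points")
    length = track.length
    elapsed = float(track.t[-1] - track.t[0])
    velocity = length / elapsed
    ang, zero = step_angles(track, return_flags=True)
    if ang.size == 0:
        mean_angle = math.nan
    elif circular_mean:
        rad = np.radians(ang)
        mean_angle = _wrap_angle(
            math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean()))
        )
    else:
        mean_angle = float(ang.mean())
    cls = classify_turning(mean_angle) if classify and not math.isnan(mean_angle) else ""
    return TrackSummary(
        length=length,
        velocity=velocity,
        mean_angle=mean_angle,
        n_steps=int(len(track) - 1),
        n_zero_steps=int(zero.sum()),
        turning_class=cls,
    )


def classify_turning(mean_angle: float) -> str:
    """Classify a mean turning angle into horizontal, diagonal or vertical.

    45-degree sectors centred on the named headings: horizontal around
    0 and +-180 deg, vertical around +-90 deg, diagonal around +-45 and
    +-135 deg.  Boundary ties go to the lower-|alpha| class, so |alpha| =
    22.5 is horizontal and |alpha| = 112.5 is vertical.
    """
    a = abs(_wrap_angle(float(mean_angle)))
    if a <= SECTOR_HALF_WIDTH or a >= 180.0 - SECTOR_HALF_WIDTH:
        return "horizontal"
    if 90.0 - SECTOR_HALF_WIDTH <= a <= 90.0 + SECTOR_HALF_WIDTH:
        return "vertical"
    return "diagonal"


# ---------------------------------------------------------------------------
# CSV interfaces


def read_track_csv(path, pixel_size: float | None = None) -> Track:
    """Read a track table with columns frame, t_s, x, y (or x_px, y_px).

    If the coordinates are in pixels, pass ``pixel_size`` (micrometres per
    pixel) to convert.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    t = df[cols["t_s"]].to_numpy(float)
    if "x_px" in cols:
        if pixel_size is None:
            raise ValueError("pixel coordinates require pixel_size")
        x = df[cols["x_px"]].to_numpy(float) * pixel_size
        y = df[cols["y_px"]].to_numpy(float) * pixel_size
    else:
        x = df[cols["x"]].to_numpy(float)
        y = df[cols["y"]].to_numpy(float)
        if pixel_size is not None:
            x = x * pixel_size
            y = y * pixel_size
    return Track(t, x, y)


def write_summary_csv(path, summaries: dict[str, TrackSummary]) -> None:
    """Write per-track summaries keyed by track id."""
    rows = [
        {
            "id": k,
            "length_um": s.length,
            "velocity_um_s": s.velocity,
            "mean_angle_deg": s.mean_angle,
            "turning_class": s.turning_class,
        }
        for k, s in summaries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
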