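"""Synthetic growth-cone movies and axon-field images with known ground truth.

No public time-lapse data accompany the growth-cone dynamics study this
package implements, so every downstream stage (segmentation, morphometry,
tracking, shape PCA, tensor decomposition, degeneration index) is exercised
on synthetic data with exact ground truth:

* **GC movies** — a motile dark blob (lamellipodium) with thin filopodial
  spikes and a trailing neurite, on a light background with additive
  Gaussian noise.  The blob's base performs a biased random walk whose step
  headings are von Mises distributed around a preferred direction; speed and
  heading concentration are the condition knobs.  Two presets mirror the
  direction of the published group differences: control-like growth cones
  move faster with a strong vertical bias, frataxin-deficient-like (FRDA)
  ones move slower with a weak horizontal bias.
* **Axon fields** — curvilinear intact strands (low circularity) plus round
  fragments (high circularity) with exact fragmented/total pixel areas, the
  ground truth for the degeneration index.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .track import Track

__all__ = [
    "MotilityParams",
    "FrameStack",
    "GroundTruth",
    "control_like",
    "frda_like",
    "simulate_track",
    "render_movie",
    "simulate_axon_field",
    "write_movie_tiff",
    "write_ground_truth",
]

# Rendering intensities: dark foreground on a light background, emulating
# phase-contrast imaging of growth cones.
BACKGROUND_LEVEL = 0.9
FOREGROUND_LEVEL = 0.25

_MAX_PLACEMENT_ATTEMPTS = 10


@dataclass(frozen=True)
class MotilityParams:
    """Condition parameters for one synthetic growth-cone movie.

    Defaults emulate a 1-h acquisition at 30-s intervals with a 40x
    objective (0.25 um/px, 512 x 512 frames).
    """

    mean_speed: float = 0.010  # um/s
    heading_pref: float = -90.0  # degrees in (-180, 180]; -90 = up (image y-down)
    heading_concentration: float = 4.0  # von Mises kappa, >= 0
    step_interval: float = 30.0  # s
    duration: float = 3600.0  # s
    blob_radius_mean: float = 5.0  # um
    n_filopodia: int = 6
    pixel_size: float = 0.25  # um/px
    frame_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    noise_sd: float = 0.05  # intensity units on a [0, 1] scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.heading_concentration < 0:
            raise ValueError("heading_concentration (kappa) must be >= 0")
        if self.step_interval <= 0 or self.duration <= 0:
            raise ValueError("step_interval and duration must be positive")
        n = self.duration / self.step_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer number of step intervals")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.step_interval))

    @property
    def blob_radius_px(self) -> float:
        return self.blob_radius_mean / self.pixel_size


def control_like(**overrides) -> MotilityParams:
    """Preset emulating control growth cones: faster, strong vertical bias."""
    return MotilityParams(
        mean_speed=0.010, heading_pref=-90.0, heading_concentration=4.0, **overrides
    )


def frda_like(**overrides) -> MotilityParams:
    """Preset emulating frataxin-deficient growth cones: slower, weak horizontal bias."""
    return MotilityParams(
        mean_speed=0.008, heading_pref=0.0, heading_concentration=1.5, **overrides
    )


@dataclass
class FrameStack:
    """Ordered grayscale frames with physical calibration."""

    frames: np.ndarray  # (n_frames, rows, cols), float in [0, 1]
    pixel_size: float  # um/px
    frame_interval: float  # s

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class GroundTruth:
    """Exact ground truth accompanying a synthetic render."""

    track: Track | None = None
    masks: list[np.ndarray] = field(default_factory=list)  # bool, one per frame
    per_frame_shape_metrics: list[dict] = field(default_factory=list)
    fragmented_area_px: int | None = None  # axon fields only
    total_area_px: int | None = None
    fragment_mask: np.ndarray | None = None

    @property
    def degeneration_index(self) -> float | None:
        if self.fragmented_area_px is None or not self.total_area_px:
            return None
        return self.fragmented_area_px / self.total_area_px


# ---------------------------------------------------------------------------
# Track simulation


def _draw_steps(rng: np.random.Generator, params: MotilityParams) -> tuple[np.ndarray, np.ndarray]:
    """Step lengths (um) and headings (radians) for one track."""
    n = params.n_steps
    mean_step = params.mean_speed * params.step_interval
    if mean_step == 0:
        lengths = np.zeros(n)
    else:
        # Gamma(shape=4) keeps lengths positive with moderate spread (CV = 0.5)
        # while matching the required mean exactly.
        lengths = rng.gamma(shape=4.0, scale=mean_step / 4.0, size=n)
    mu = math.radians(params.heading_pref)
    if params.heading_concentration == 0:
        headings = rng.uniform(-math.pi, math.pi, size=n)
    else:
        headings = rng.vonmises(mu, params.heading_concentration, size=n)
    return lengths, headings


def simulate_track(params: MotilityParams) -> Track:
    """Simulate one base-point track as a biased random walk.

    Steps are drawn at ``step_interval`` spacing; step lengths have mean
    ``mean_speed * step_interval`` and headings are von Mises around
    ``heading_pref`` with concentration kappa.  The walk is positioned so
    that its bounding box (plus a blob-radius margin) fits inside the frame;
    if a draw cannot fit, it is redrawn up to 10 times before failing.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.frame_shape
    height_um = rows * params.pixel_size
    width_um = cols * params.pixel_size
    # filopodia reach up to ~2.6 blob radii from the base
    margin = 3.0 * params.blob_radius_mean + 2 * params.pixel_size

    last_extent = (math.nan, math.nan)
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        lengths, headings = _draw_steps(rng, params)
        dx = lengths * np.cos(headings)
        dy = lengths * np.sin(headings)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        ext_x = x.max() - x.min()
        ext_y = y.max() - y.min()
        last_extent = (ext_x, ext_y)
        if ext_x + 2 * margin > width_um or ext_y + 2 * margin > height_um:
            continue  # re-draw and re-centre
        # Start the track at the bottom-centre of the frame (the published
        # movies are oriented this way), shifting minimally so the whole
        # bounding box stays inside the frame with the margin.
        sx = width_um / 2.0
        sx = min(max(sx, margin - x.min()), width_um - margin - x.max())
        sy = height_um - margin
        sy = min(max(sy, margin - y.min()), height_um - margin - y.max())
        t = np.arange(params.n_steps + 1) * params.step_interval
        return Track(t, x + sx, y + sy)
    raise RuntimeError(
        f"track does not fit frame after {_MAX_PLACEMENT_ATTEMPTS} attempts: "
        f"extent {last_extent[0]:.1f} x {last_extent[1]:.1f} um plus margin "
        f"{margin:.1f} um exceeds frame {width_um:.1f} x {height_um:.1f} um"
    )


# ---------------------------------------------------------------------------
# Movie rendering


def _stamp_disk(mask: np.ndarray, cy: float, cx: float, radius: float) -> None:
    rows, cols = mask.shape
    r0 = max(int(math.floor(cy - radius)) - 1, 0)
    r1 = min(int(math.ceil(cy + radius)) + 2, rows)
    c0 = max(int(math.floor(cx - radius)) - 1, 0)
    c1 = min(int(math.ceil(cx + radius)) + 2, cols)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _stamp_segment(
    mask: np.ndarray, p0: tuple[float, float], p1: tuple[float, float], half_width: float
) -> None:
    """Stamp all pixels within half_width of the segment p0-p1 (y, x in px)."""
    rows, cols = mask.shape
    y0, x0 = p0
    y1, x1 = p1
    r0 = max(int(math.floor(min(y0, y1) - half_width)) - 1, 0)
    r1 = min(int(math.ceil(max(y0, y1) + half_width)) + 2, rows)
    c0 = max(int(math.floor(min(x0, x1) - half_width)) - 1, 0)
    c1 = min(int(math.ceil(max(x0, x1) + half_width)) + 2, cols)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    vy, vx = y1 - y0, x1 - x0
    den = vy * vy + vx * vx
    if den == 0:
        d2 = (yy - y0) ** 2 + (xx - x0) ** 2
    else:
        tt = np.clip(((yy - y0) * vy + (xx - x0) * vx) / den, 0.0, 1.0)
        d2 = (yy - (y0 + tt * vy)) ** 2 + (xx - (x0 + tt * vx)) ** 2
    mask[r0:r1, c0:c1] |= d2 <= half_width**2


def render_movie(
    track: Track,
    params: MotilityParams,
    *,
    include_neurite: bool = True,
    include_filopodia: bool = True,
) -> tuple[FrameStack, GroundTruth]:
    """Render a grayscale movie of a growth cone moving along ``track``.

    Each frame shows a filled blob centred on the current base point, thin
    filopodial spikes fanned around the current heading, and (optionally)
    a trailing neurite along the past track.  The grayscale frame is the
    dark foreground on a light background plus Gaussian noise; ground-truth
    masks are the noise-free binary renders.
    """
    r_px = params.blob_radius_px
    if r_px < 2.0:
        raise ValueError(
            f"blob radius {r_px:.2f} px (< 2 px) is unresolvable at "
            f"pixel_size {params.pixel_size} um/px"
        )
    rows, cols = params.frame_shape
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n_frames = len(track)
    x_px = track.x / params.pixel_size
    y_px = track.y / params.pixel_size
    if (
        x_px.min() < r_px
        or y_px.min() < r_px
        or x_px.max() > cols - 1 - r_px
        or y_px.max() > rows - 1 - r_px
    ):
        raise ValueError("track (plus blob radius) leaves the frame bounds")

    # Per-frame heading: direction of recent displacement, exponentially
    # smoothed (unit-vector EMA) — a growth cone reorients its filopodial
    # fan over minutes, not within a single 30-s step.
    headings = np.full(n_frames, math.radians(params.heading_pref))
    dx = np.diff(x_px)
    dy = np.diff(y_px)
    alpha = 0.25
    ux, uy = math.cos(headings[0]), math.sin(headings[0])
    for i in range(1, n_frames):
        step = math.hypot(dx[i - 1], dy[i - 1])
        if step > 0:
            ux = (1 - alpha) * ux + alpha * dx[i - 1] / step
            uy = (1 - alpha) * uy + alpha * dy[i - 1] / step
        if ux != 0 or uy != 0:
            headings[i] = math.atan2(uy, ux)
        else:
            headings[i] = headings[i - 1]
    headings[0] = headings[1] if n_frames > 1 else headings[0]

    # fixed filopodium geometry per movie (deterministic given seed)
    filo_offsets = (
        rng.uniform(-math.pi / 3, math.pi / 3, size=params.n_filopodia)
        if params.n_filopodia
        else np.empty(0)
    )
    filo_lengths = rng.uniform(0.8 * r_px, 1.6 * r_px, size=params.n_filopodia)

    frames = np.empty((n_frames, rows, cols), dtype=np.float32)
    masks: list[np.ndarray] = []
    metrics: list[dict] = []
    neurite_hw = max(r_px / 3.0, 1.0)

    for i in range(n_frames):
        mask = np.zeros((rows, cols), dtype=bool)
        cy, cx = y_px[i], x_px[i]
        _stamp_disk(mask, cy, cx, r_px)
        if include_filopodia and params.n_filopodia:
            for off, flen in zip(filo_offsets, filo_lengths):
                ang = headings[i] + off
                tip = (cy + (r_px + flen) * math.sin(ang), cx + (r_px + flen) * math.cos(ang))
                _stamp_segment(mask, (cy, cx), tip, 0.8)
        if include_neurite and i > 0:
            # The neurite shaft is the *consolidated* past path: growth-cone
            # consolidation smooths out step-scale jinks, so the shaft is
            # drawn through ~5-min waypoints of the track, not every step.
            stride = max(int(round(300.0 / params.step_interval)), 1)
            idx = list(range(0, i, stride)) + [i]
            for j0, j1 in zip(idx[:-1], idx[1:]):
                _stamp_segment(
                    mask,
                    (y_px[j0], x_px[j0]),
                    (y_px[j1], x_px[j1]),
                    neurite_hw,
                )
        frame = np.full((rows, cols), BACKGROUND_LEVEL, dtype=np.float32)
        frame[mask] = FOREGROUND_LEVEL
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape).astype(
                np.float32
            )
        frames[i] = np.clip(frame, 0.0, 1.0)
        masks.append(mask)
        metrics.append(
            {
                "blob_area_um2": math.pi * params.blob_radius_mean**2,
                "centroid_x_um": float(track.x[i]),
                "centroid_y_um": float(track.y[i]),
            }
        )

    stack = FrameStack(frames, params.pixel_size, params.step_interval)
    gt = GroundTruth(track=track, masks=masks, per_frame_shape_metrics=metrics)
    return stack, gt


# ---------------------------------------------------------------------------
# Axon fields


def _rasterize_strand(mask: np.ndarray, rng: np.random.Generator) -> None:
    """One smooth curvilinear strand crossing the field (low circularity)."""
    rows, cols = mask.shape
    side = rng.integers(0, 4)
    if side == 0:
        y, x, heading = 0.0, rng.uniform(0, cols - 1), math.pi / 2
    elif side == 1:
        y, x, heading = rows - 1.0, rng.uniform(0, cols - 1), -math.pi / 2
    elif side == 2:
        y, x, heading = rng.uniform(0, rows - 1), 0.0, 0.0
    else:
        y, x, heading = rng.uniform(0, rows - 1), cols - 1.0, math.pi
    heading += rng.uniform(-0.5, 0.5)
    half_width = rng.uniform(1.0, 1.8)
    step = 4.0
    for _ in range(int(3 * max(rows, cols) / step)):
        ny = y + step * math.sin(heading)
        nx = x + step * math.cos(heading)
        _stamp_segment(mask, (y, x), (ny, nx), half_width)
        y, x = ny, nx
        heading += rng.normal(0.0, 0.12)
        if not (-step <= y <= rows - 1 + step and -step <= x <= cols - 1 + step):
            break


def simulate_axon_field(
    n_strands: int,
    n_fragments: int,
    fragment_area_range: tuple[float, float] = (50.0, 500.0),
    params: MotilityParams | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Synthetic axon-field image: intact strands plus round fragments.

    Strands are smooth curvilinear thick paths (circularity well below 0.5);
    fragments are ellipses with areas drawn from ``fragment_area_range``
    (px^2) and axis ratios >= 0.6, placed disjoint from everything else and
    away from the image border.  Ground truth (``fragmented_area_px``,
    ``total_area_px``) is recomputed from the final raster, never from
    intent, so merged or clipped shapes cannot bias it.

    Returns the grayscale image (dark foreground, light background, noise
    per ``params.noise_sd``) and the ground truth.
    """
    if n_strands < 0 or n_fragments < 0:
        raise ValueError("counts must be >= 0")
    params = params or MotilityParams()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    rows, cols = params.frame_shape

    strand_mask = np.zeros((rows, cols), dtype=bool)
    for _ in range(n_strands):
        _rasterize_strand(strand_mask, rng)

    frag_mask = np.zeros((rows, cols), dtype=bool)
    edge_margin = 3
    placed = 0
    attempts = 0
    while placed < n_fragments and attempts < 200 * max(n_fragments, 1):
        attempts += 1
        area = rng.uniform(*fragment_area_range)
        ratio = rng.uniform(0.6, 1.0)
        a = math.sqrt(area / (math.pi * ratio))  # semi-major (px)
        b = a * ratio
        theta = rng.uniform(0, math.pi)
        cy = rng.uniform(a + edge_margin, rows - 1 - a - edge_margin)
        cx = rng.uniform(a + edge_margin, cols - 1 - a - edge_margin)
        cand = np.zeros((rows, cols), dtype=bool)
        _stamp_ellipse(cand, cy, cx, a, b, theta)
        # keep fragments disjoint from strands and from each other (2 px gap)
        from scipy.ndimage import binary_dilation

        if (binary_dilation(cand, iterations=2) & (strand_mask | frag_mask)).any():
            continue
        frag_mask |= cand
        placed += 1

    final = strand_mask | frag_mask
    gt = GroundTruth(
        fragmented_area_px=int(frag_mask.sum()),
        total_area_px=int(final.sum()),
        fragment_mask=frag_mask,
        masks=[final],
    )
    image = np.full((rows, cols), BACKGROUND_LEVEL, dtype=np.float32)
    image[final] = FOREGROUND_LEVEL
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape).astype(
            np.float32
        )
    return np.clip(image, 0.0, 1.0), gt


def _stamp_ellipse(
    mask: np.ndarray, cy: float, cx: float, a: float, b: float, theta: float
) -> None:
    rows, cols = mask.shape
    r = max(a, b)
    r0 = max(int(cy - r) - 1, 0)
    r1 = min(int(cy + r) + 2, rows)
    c0 = max(int(cx - r) - 1, 0)
    c1 = min(int(cx + r) + 2, cols)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    mask[r0:r1, c0:c1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# Disk output


def write_movie_tiff(stack: FrameStack, path) -> None:
    """Write a multipage 8-bit TIFF of the movie."""
    data = (np.clip(stack.frames, 0, 1) * 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_ground_truth(gt: GroundTruth, out_dir, pixel_size: float = 1.0) -> None:
    """Write ground truth: JSON summary + CSV track table (frame, t_s, x_px, y_px).

    ``pixel_size`` (um/px) converts the track's micrometre coordinates to
    the pixel coordinates of the CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "n_frames": len(gt.masks),
        "fragmented_area_px": gt.fragmented_area_px,
        "total_area_px": gt.total_area_px,
        "per_frame_shape_metrics": gt.per_frame_shape_metrics,
    }
    (out / "ground_truth.json").write_text(json.dumps(summary, indent=1))
    if gt.track is not None:
        tr = gt.track
        pd.DataFrame(
            {
                "frame": np.arange(len(tr)),
                "t_s": tr.t,
                "x_px": tr.x / pixel_size,
                "y_px": tr.y / pixel_size,
            }
        ).to_csv(out / "track.csv", index=False)
    if gt.masks:
        data = np.stack([m.astype(np.uint8) * 255 for m in gt.masks])
        tifffile.imwrite(out / "masks.tif", data, photometric="minisblack")
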