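"""Growth-cone morphometry: the four shape descriptors from a binary mask.

* area (um^2) — foreground pixel count scaled by the pixel area;
* Feret's diameter (um) — the longest distance between any two points of
  the boundary (maximum caliper), a size measure;
* circularity = 4*pi*area / perimeter^2 — 1 for a perfect disk, approaching
  0 for elongated shapes; capped at 1.0 (the rasterized estimator can
  slightly exceed 1 on small shapes);
* solidity = area / convex area — how much the growth cone fills its
  filopodial spread.

The perimeter estimator is the length of the marching-squares boundary
polygon after light smoothing (1-px resampling + 5-point circular moving
average).  The raw crack/contour length overestimates smooth boundaries by
~5% (a rasterized disk would score circularity ~0.91); smoothing removes
the half-pixel staircase so a disk scores ~1.00 and a square ~0.80, both
within the tolerances the descriptors are used at.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import ConvexHull
from skimage.measure import find_contours, label
from skimage.morphology import convex_hull_image

logger = logging.getLogger(__name__)

__all__ = ["ShapeMetrics", "shape_metrics", "area_cdf", "mask_perimeter"]


def mask_perimeter(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Perimeter (px) of a mask's outer boundary via a smoothed contour polygon.

    The marching-squares contour is resampled to ~1-px spacing and smoothed
    with a circular moving average before measuring its length, removing
    the half-pixel staircase that inflates raw contour length by ~5% on
    smooth shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    contour = max(find_contours(padded.astype(float), 0.5), key=len)
    closed = contour if np.allclose(contour[0], contour[-1]) else np.vstack(
        [contour, contour[:1]]
    )
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return 0.0
    n = max(int(round(total)), 8)
    t = total * np.arange(n) / n
    pts = np.column_stack([np.interp(t, s, closed[:, i]) for i in range(2)])
    w = min(smooth_window, n)
    kernel = np.ones(w) / w
    sm = np.empty_like(pts)
    for i in range(2):
        ext = np.concatenate([pts[-(w // 2):, i], pts[:, i], pts[: w - w // 2, i]])
        sm[:, i] = np.convolve(ext, kernel, mode="valid")[:n]
    d = np.diff(np.vstack([sm, sm[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class ShapeMetrics:
    area: float  # um^2
    perimeter: float  # um
    feret: float  # um
    circularity: float  # dimensionless, capped at 1.0
    convex_area: float  # um^2
    solidity: float  # dimensionless in (0, 1]


def _boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corners (row, col) of the boundary pixels — the shape's outer extent."""
    boundary = mask & ~binary_erosion(mask, border_value=0)
    rr, cc = np.nonzero(boundary)
    pts = np.empty((rr.size * 4, 2), dtype=float)
    for i, (dr, dc) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        pts[i * rr.size : (i + 1) * rr.size, 0] = rr + dr
        pts[i * rr.size : (i + 1) * rr.size, 1] = cc + dc
    return pts


def shape_metrics(mask: np.ndarray, pixel_size: float = 1.0) -> ShapeMetrics:
    """Compute the shape descriptors of a single-component binary mask.

    The Feret diameter is the maximum caliper over the convex hull of the
    boundary-pixel corners, so a filled axis-aligned n x n square measures
    n*sqrt(2).  The convex area counts the pixels of the rasterized convex
    hull; the mask is always contained in it, so solidity <= 1 and a convex
    mask scores exactly 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = int(label(mask, connectivity=2).max())
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} components; extract a single growth cone first"
        )

    area_px = float(mask.sum())
    perim_px = mask_perimeter(mask)
    area = area_px * pixel_size**2
    perim = perim_px * pixel_size

    circ_raw = 4.0 * math.pi * area / perim**2 if perim > 0 else 0.0
    if circ_raw > 1.0:
        logger.debug(
            "circularity %.4f > 1 (perimeter-estimator tolerance); capping", circ_raw
        )
    circularity = min(circ_raw, 1.0)

    pts = _boundary_corner_points(mask)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    # max pairwise distance over hull vertices (hulls here are small)
    d2 = np.sum((verts[:, None, :] - verts[None, :, :]) ** 2, axis=-1)
    feret = math.sqrt(float(d2.max())) * pixel_size
    # convex area from the rasterized hull so that a convex mask (already
    # equal to its own hull raster) scores solidity 1 at any size
    convex_area = (
        float(convex_hull_image(mask, offset_coordinates=False).sum()) * pixel_size**2
    )

    return ShapeMetrics(
        area=area,
        perimeter=perim,
        feret=feret,
        circularity=circularity,
        convex_area=convex_area,
        solidity=area / convex_area,
    )


def area_cdf(areas, bin_width: float) -> pd.DataFrame:
    """Cumulative distribution of growth-cone areas on a fixed bin grid.

    Returns a table of (upper_bound, cumulative_fraction): the fraction of
    areas <= k * bin_width for k = 1 .. ceil(max/bin_width).  Fractions are
    monotone nondecreasing and end at 1.0.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("areas must be nonempty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if (areas < 0).any():
        raise ValueError("areas must be nonnegative")
    n_bins = max(int(math.ceil(areas.max() / bin_width)), 1)
    ubs = bin_width * np.arange(1, n_bins + 1)
    frac = np.array([(areas <= ub).mean() for ub in ubs])
    return pd.DataFrame({"upper_bound": ubs, "cumulative_fraction": frac})
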