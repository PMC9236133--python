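"""Shape-outline PCA of a growth-cone movie.

Each frame's growth-cone mask is reduced to its outer boundary, resampled
to 250 points equally spaced by arc length, and flattened to a
500-dimensional shape vector, so the whole movie becomes a frames x 500
matrix.  PCA of that matrix yields the principal shape-motion patterns; the
(PC1, PC2) biplot traces the growth cone's trajectory through shape space
over the hour, and the summed length of that trajectory is a scalar
dynamics readout (motile growth cones trace long, directed trajectories;
sluggish ones stay near the origin).

Outline correspondence across frames requires a canonical start point and
traversal direction; here the start is the boundary point nearest the image
bottom-centre (the oriented base of the growth cone) and traversal is
counterclockwise on screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import find_contours, label

__all__ = [
    "OutlineVector",
    "PCAModel",
    "extract_outline",
    "build_matrix",
    "pca_fit",
    "trajectory_length",
    "trajectory_extent",
]


def _smooth_closed(closed: np.ndarray, window: int = 5) -> np.ndarray:
    """Resample a closed polyline to ~1-px spacing and apply a circular
    moving average, removing the marching-squares staircase so outline
    length and point positions are stable under re-sampling density."""
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return closed
    n = max(int(round(total)), 8)
    t = total * np.arange(n) / n
    pts = np.column_stack([np.interp(t, s, closed[:, i]) for i in range(2)])
    w = min(window, n)
    kernel = np.ones(w) / w
    sm = np.empty_like(pts)
    for i in range(2):
        ext = np.concatenate([pts[-(w // 2):, i], pts[:, i], pts[: w - w // 2, i]])
        sm[:, i] = np.convolve(ext, kernel, mode="valid")[:n]
    return np.vstack([sm, sm[:1]])


@dataclass(frozen=True)
class OutlineVector:
    """A closed growth-cone boundary resampled to a fixed number of points."""

    points: np.ndarray  # (n_points, 2) of (x, y) in micrometres
    frame_index: int = 0

    @property
    def vector(self) -> np.ndarray:
        """Flattened [x0, y0, x1, y1, ...] shape vector (2 * n_points)."""
        return self.points.reshape(-1)


@dataclass(frozen=True)
class PCAModel:
    components: np.ndarray  # (k, d), orthonormal rows
    scores: np.ndarray  # (n, k)
    explained_variance_fraction: np.ndarray  # (k,)
    mean: np.ndarray  # (d,) column means used for centering

    def biplot_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.scores.shape[0]),
                "pc1": self.scores[:, 0],
                "pc2": self.scores[:, 1] if self.scores.shape[1] > 1 else 0.0,
            }
        )


def extract_outline(
    mask: np.ndarray, n_points: int = 250, pixel_size: float = 1.0, frame_index: int = 0
) -> OutlineVector:
    """Trace and resample the outer boundary of a single-component mask.

    The boundary is traced at subpixel resolution, oriented counterclockwise
    (on screen, y down), started at the point nearest the image
    bottom-centre, and resampled to ``n_points`` equally spaced by arc
    length.  A mask touching the image border yields a truncated outline and
    a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if label(mask, connectivity=2).max() != 1:
        raise ValueError("mask must contain exactly one connected component")
    if (
        mask[0, :].any()
        or mask[-1, :].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
    ):
        warnings.warn("mask touches image border; outline is truncated", stacklevel=2)
        padded = np.pad(mask, 1)
        contours = find_contours(padded.astype(float), 0.5)
        contour = max(contours, key=len) - 1.0
    else:
        contours = find_contours(mask.astype(float), 0.5)
        contour = max(contours, key=len)

    rc = contour  # (m, 2) of (row, col)
    if not np.allclose(rc[0], rc[-1]):
        rc = np.vstack([rc, rc[0]])
    xy = _smooth_closed(rc[:, ::-1].astype(float))  # (x=col, y=row)

    # counterclockwise on screen (y down) <=> negative shoelace signed area
    x, y = xy[:, 0], xy[:, 1]
    signed_area = 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
    if signed_area > 0:
        xy = xy[::-1]

    # start at the boundary point nearest the image bottom-centre
    rows, cols = mask.shape
    anchor = np.array([(cols - 1) / 2.0, rows - 1.0])
    open_xy = xy[:-1]
    start = int(np.argmin(np.sum((open_xy - anchor) ** 2, axis=1)))
    open_xy = np.roll(open_xy, -start, axis=0)
    closed = np.vstack([open_xy, open_xy[0]])

    # equal-arc-length resampling of the closed polyline
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        pts = np.repeat(closed[:1], n_points, axis=0)
    else:
        targets = total * np.arange(n_points) / n_points
        pts = np.column_stack(
            [np.interp(targets, s, closed[:, i]) for i in range(2)]
        )
    return OutlineVector(points=pts * pixel_size, frame_index=frame_index)


def build_matrix(outlines) -> np.ndarray:
    """Stack outline vectors into a (frames x d) data matrix, frame order."""
    vecs = [o.vector for o in outlines]
    if not vecs:
        raise ValueError("no outlines")
    d = vecs[0].size
    if any(v.size != d for v in vecs):
        raise ValueError("outline vectors have mismatched lengths")
    return np.vstack(vecs)


def pca_fit(matrix: np.ndarray, center: bool = True, n_components: int | None = None) -> PCAModel:
    """PCA via singular value decomposition of the (column-centred) matrix.

    Components are sorted by decreasing variance; each component's sign is
    fixed so its largest-magnitude loading is positive, making runs
    reproducible.  Zero-variance data yield zero scores and zero explained
    fractions rather than an error.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    k_max = min(X.shape)
    k = k_max if n_components is None else min(n_components, k_max)

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / (X.shape[0] - 1)
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)

    components = Vt[:k]
    scores = U[:, :k] * S[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    if total == 0:
        scores = np.zeros_like(scores)
    return PCAModel(
        components=components,
        scores=scores,
        explained_variance_fraction=frac[:k],
        mean=mean,
    )


def _scores2(model: PCAModel) -> np.ndarray:
    s = model.scores[:, :2]
    if s.shape[1] < 2:
        s = np.column_stack([s[:, 0], np.zeros(s.shape[0])])
    return s


def trajectory_length(model: PCAModel) -> float:
    """Summed path length of the (PC1, PC2) score trajectory across frames.

    Note this accumulates every frame-to-frame move, so a growth cone that
    wanders back and forth can score a *longer* path than one advancing
    steadily; for the "long directed trajectories" phenotype use
    :func:`trajectory_extent`.
    """
    s = _scores2(model)
    return float(np.hypot(*np.diff(s, axis=0).T).sum())


def trajectory_extent(model: PCAModel) -> float:
    """Diagonal extent of the (PC1, PC2) trajectory's bounding box.

    Measures how far the shape trajectory travels through the biplot
    overall — large for a growth cone tracing a long directed path, small
    for one jittering in place regardless of how much per-frame movement
    the jitter accumulates.
    """
    s = _scores2(model)
    span = s.max(axis=0) - s.min(axis=0)
    return float(np.hypot(span[0], span[1]))
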