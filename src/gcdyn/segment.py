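"""Segmentation: grayscale frames -> binary masks.

The preprocessing recipe follows the published axon-chamber pipeline:
median despeckle, rolling-ball background subtraction (light background,
paraboloid-style kernel), contrast enhancement (0.3% saturated pixels,
normalize, equalize histogram), then Otsu thresholding on a 256-bin
histogram with the foreground taken as the pixels *darker* than the
threshold when the background is light.

For growth-cone movies the default configuration disables background
subtraction and histogram equalization: the 5-px rolling ball is sized for
thin axon strands and flattens the interior of a lamellipodial blob tens of
pixels across, destroying the object it is meant to isolate.  See
docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage import exposure, restoration
from skimage.filters import threshold_otsu
from skimage.measure import label

from .synthgc import FrameStack

__all__ = [
    "PreprocessConfig",
    "axon_config",
    "gc_movie_config",
    "preprocess_frame",
    "binarize",
    "extract_gc_mask",
    "segment_movie",
    "load_config",
    "save_config",
]

# 3x3 plus-shaped (4-neighbour) median footprint: the smallest nontrivial
# despeckle kernel, standing in for the degenerate "0.2 px" radius.
_PLUS_FOOTPRINT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing options applied in order: median -> background -> contrast."""

    median_radius: float = 0.2  # px; sub-pixel radii use the 3x3 plus kernel
    rollball_radius: float | None = 5.0  # px; None disables background subtraction
    light_background: bool = True
    sliding_paraboloid: bool = True
    saturated_fraction: float = 0.3  # % of pixels clipped (split between tails)
    normalize: bool = True
    equalize: bool = True

    def __post_init__(self) -> None:
        if self.rollball_radius is not None and self.rollball_radius <= 0:
            raise ValueError("rollball_radius must be positive (or None)")
        if not (0 <= self.saturated_fraction < 100):
            raise ValueError("saturated_fraction must be in [0, 100)")
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")


def axon_config() -> PreprocessConfig:
    """The published axon-field recipe (all steps on)."""
    return PreprocessConfig()


def gc_movie_config() -> PreprocessConfig:
    """Default recipe for growth-cone movies: despeckle + contrast stretch only."""
    return PreprocessConfig(
        rollball_radius=None, sliding_paraboloid=False, equalize=False
    )


def _median_footprint(radius: float) -> np.ndarray:
    if radius < 1.0:
        return _PLUS_FOOTPRINT
    r = int(round(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy**2 + xx**2 <= radius**2


def preprocess_frame(frame: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Apply median -> background subtraction -> contrast enhancement.

    Returns a float image rescaled to [0, 1] (same shape), preserving the
    light-background orientation.  A constant image is a fixed point.
    """
    cfg = cfg or axon_config()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if img.max() == img.min():
        return img.copy()

    if cfg.median_radius > 0:
        img = ndi.median_filter(img, footprint=_median_footprint(cfg.median_radius))

    if cfg.rollball_radius is not None:
        work = img.max() - img if cfg.light_background else img
        if cfg.sliding_paraboloid:
            # paraboloid-style kernel: ellipsoid of the stated radius
            r = cfg.rollball_radius
            kernel = restoration.ellipsoid_kernel((2 * r + 1, 2 * r + 1), r)
            background = restoration.rolling_ball(work, kernel=kernel)
        else:
            background = restoration.rolling_ball(work, radius=cfg.rollball_radius)
        work = work - background
        img = work.max() - work if cfg.light_background else work

    if img.max() > img.min():
        if cfg.saturated_fraction > 0:
            half = cfg.saturated_fraction / 2.0
            lo, hi = np.percentile(img, [half, 100.0 - half])
            if hi > lo:
                img = np.clip(img, lo, hi)
        if cfg.normalize and img.max() > img.min():
            img = (img - img.min()) / (img.max() - img.min())
        if cfg.equalize and img.max() > img.min():
            img = exposure.equalize_hist(img)
    # contrast steps are no-ops on a constant residue (no divide-by-zero)
    if img.max() > img.min():
        img = (img - img.min()) / (img.max() - img.min())
    return img


def binarize(frame: np.ndarray, light_background: bool = True) -> np.ndarray:
    """Otsu threshold (256-bin histogram) -> boolean foreground mask.

    With a light background the foreground is the pixels *darker* than the
    threshold; otherwise the brighter ones.  A constant image has no
    foreground.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(img, nbins=256)
    return img < thr if light_background else img > thr


def extract_gc_mask(mask: np.ndarray, anchor: tuple[int, int]) -> np.ndarray:
    """Select the connected component at (or nearest to) ``anchor``, holes filled.

    ``anchor`` is (row, col).  8-connectivity; the anchored component wins
    over larger ones.  Raises if the mask has no foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    r, c = int(round(anchor[0])), int(round(anchor[1]))
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise ValueError("anchor outside frame")
    if not mask.any():
        raise ValueError("segmentation failed: empty mask")
    labels = label(mask, connectivity=2)
    lab = labels[r, c]
    if lab == 0:
        # nearest foreground pixel decides
        _, (ir, ic) = ndi.distance_transform_edt(~mask, return_indices=True)
        lab = labels[ir[r, c], ic[r, c]]
    comp = labels == lab
    return ndi.binary_fill_holes(comp)


def segment_movie(
    stack: FrameStack | np.ndarray,
    cfg: PreprocessConfig | None = None,
    anchors=None,
) -> list[np.ndarray]:
    """Segment every frame of a movie into one growth-cone mask each.

    ``anchors`` may be a per-frame sequence of (row, col); if omitted, the
    first frame anchors on the largest component and each later frame on the
    centroid of the previous frame's mask (the growth cone moves little
    between frames).
    """
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    cfg = cfg or gc_movie_config()
    masks: list[np.ndarray] = []
    prev_centroid: tuple[int, int] | None = None
    for i, frame in enumerate(frames):
        pre = preprocess_frame(frame, cfg)
        binary = binarize(pre, cfg.light_background)
        if anchors is not None:
            anchor = anchors[i]
        elif prev_centroid is not None:
            anchor = prev_centroid
        else:
            labels = label(binary, connectivity=2)
            if labels.max() == 0:
                raise ValueError(f"segmentation failed: empty mask at frame {i}")
            largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
            rr, cc = np.nonzero(labels == largest)
            anchor = (int(rr.mean()), int(cc.mean()))
        gc = extract_gc_mask(binary, anchor)
        rr, cc = np.nonzero(gc)
        prev_centroid = (int(rr.mean()), int(cc.mean()))
        masks.append(gc)
    return masks


def load_config(path) -> PreprocessConfig:
    """Read a YAML file whose keys mirror PreprocessConfig field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PreprocessConfig(**data)


def save_config(cfg: PreprocessConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
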