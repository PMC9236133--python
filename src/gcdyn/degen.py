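"""Axonal degeneration index from binary axon-field images.

Degenerating axons break into rounded fragments; intact axons are long,
thin, low-circularity strands.  The degeneration index (DI) is the fraction
of the axonal network's area occupied by fragments:

    DI = fragmented_area / total_area

where *fragmented area* sums the connected particles passing the published
filters — area 20-10000 px^2, circularity 0.5-1.0, not touching the image
edge — and *total area* is the full foreground pixel count (the RawIntDen
of a 0/255 mask divided by 255).  Fields are sampled as 5-10 disjoint
700 x 700 px quadrants avoiding operator-marked exclusion zones (regions
where axons stack).

Particle circularity uses the same capped 4*pi*A/P^2 estimator as the
growth-cone morphometry module — one definition repo-wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .morpho import mask_perimeter

__all__ = [
    "Particle",
    "DegenResult",
    "extract_quadrants",
    "detect_particles",
    "degeneration_index",
]

SIZE_RANGE = (20.0, 10000.0)  # px^2, published particle-size filter
CIRC_RANGE = (0.5, 1.0)  # published circularity filter


@dataclass(frozen=True)
class Particle:
    area: float  # px^2
    perimeter: float  # px
    circularity: float  # capped at 1.0
    touches_edge: bool
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass(frozen=True)
class DegenResult:
    fragmented_area: float  # px^2
    total_area: float  # px (foreground count)
    degeneration_index: float  # in [0, 1]


def extract_quadrants(
    image: np.ndarray,
    size: int = 700,
    n_min: int = 5,
    n_max: int = 10,
    exclusion_mask: np.ndarray | None = None,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Place n in [n_min, n_max] disjoint size x size regions, avoiding exclusions.

    Returns the top-left (row, col) corner of each placed quadrant.
    Admissible aligned tile positions (a size-aligned grid, which packs the
    image densely) are tried first; if exclusions leave too few, a greedy
    pass over a finer grid of candidate corners fills in.  The candidate
    order is drawn from a seeded generator, so the same seed reproduces the
    same regions.  Raises (reporting the achievable count) if fewer than
    ``n_min`` regions fit.
    """
    rows, cols = image.shape[:2]
    if rows < size or cols < size:
        raise ValueError(f"image {rows}x{cols} smaller than quadrant size {size}")
    rng = np.random.default_rng(seed)
    excl = None if exclusion_mask is None else np.asarray(exclusion_mask, dtype=bool)

    def admissible(r: int, c: int, occupied: np.ndarray) -> bool:
        if occupied[r : r + size, c : c + size].any():
            return False
        return excl is None or not excl[r : r + size, c : c + size].any()

    def greedy(corners) -> list[tuple[int, int]]:
        occupied = np.zeros((rows, cols), dtype=bool)
        placed: list[tuple[int, int]] = []
        for r, c in corners:
            if len(placed) == n_max:
                break
            if admissible(r, c, occupied):
                occupied[r : r + size, c : c + size] = True
                placed.append((r, c))
        return placed

    tiles = [
        (r, c)
        for r in range(0, rows - size + 1, size)
        for c in range(0, cols - size + 1, size)
    ]
    order = [tiles[i] for i in rng.permutation(len(tiles))]
    placed = greedy(order)
    if len(placed) < min(n_min, n_max):
        stride = max(size // 7, 1)
        fine = [
            (r, c)
            for r in range(0, rows - size + 1, stride)
            for c in range(0, cols - size + 1, stride)
        ]
        fine_order = [fine[i] for i in rng.permutation(len(fine))]
        placed = greedy(placed + fine_order)
    if len(placed) < n_min:
        raise ValueError(
            f"could only place {len(placed)} quadrants (need at least {n_min})"
        )
    return placed


def _component_particle(comp_mask: np.ndarray, bbox, touches: bool) -> Particle:
    area = float(comp_mask.sum())
    perim = mask_perimeter(comp_mask)
    circ = 4.0 * math.pi * area / perim**2 if perim > 0 else 1.0
    return Particle(
        area=area,
        perimeter=perim,
        circularity=min(circ, 1.0),
        touches_edge=touches,
        bbox=tuple(bbox),
    )


def detect_particles(mask: np.ndarray) -> list[Particle]:
    """All 8-connected foreground components with shape measurements."""
    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=2)
    rows, cols = mask.shape
    out: list[Particle] = []
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == rows or c1 == cols
        comp = labels[r0:r1, c0:c1] == prop.label
        out.append(_component_particle(comp, prop.bbox, touches))
    return out


def degeneration_index(
    mask: np.ndarray,
    size_range: tuple[float, float] = SIZE_RANGE,
    circ_range: tuple[float, float] = CIRC_RANGE,
    exclude_edges: bool = True,
) -> DegenResult:
    """DI = (area of particles passing the size/circularity/edge filters) / total area."""
    mask = np.asarray(mask, dtype=bool)
    total = float(mask.sum())
    if total == 0:
        raise ValueError("empty foreground: degeneration index undefined")
    fragmented = 0.0
    for p in detect_particles(mask):
        if not (size_range[0] <= p.area <= size_range[1]):
            continue
        if not (circ_range[0] <= p.circularity <= circ_range[1]):
            continue
        if exclude_edges and p.touches_edge:
            continue
        fragmented += p.area
    return DegenResult(
        fragmented_area=fragmented,
        total_area=total,
        degeneration_index=fragmented / total,
    )
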