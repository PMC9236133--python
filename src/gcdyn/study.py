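"""End-to-end synthetic study driver: batches of movies per condition.

Runs the full pipeline — simulate, render, segment, track, outline PCA,
tensor decomposition — over a batch of synthetic movies for one condition
preset, returning a per-movie results table.  This is the harness behind
the control-like vs FRDA-like comparisons; the analysis modules do the
work, this module only wires them together.

The default study scale (160 x 160 px at 0.5 um/px, 121 frames per movie)
keeps a full two-condition batch comparison to a few minutes on one core
while preserving every behaviour the conditions differ in.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import dyn_pca, dyn_tensor, segment, synthgc
from . import track as trk

__all__ = ["run_movie", "run_batch", "STUDY_PARAMS"]

#: Reduced-resolution study conditions shared by tests and analyses.
STUDY_PARAMS = dict(frame_shape=(160, 160), pixel_size=0.5, blob_radius_mean=4.0)


def run_movie(params: synthgc.MotilityParams, ranks=(20, 20, 2)) -> dict:
    """Full pipeline on one synthetic movie; returns the per-movie readouts.

    Velocity and length are native-interval track summaries (they estimate
    the generator's speed exactly); the mean turning angle and class follow
    the 5-min resampling convention of the published tracking.
    """
    track = synthgc.simulate_track(params)
    stack, gt = synthgc.render_movie(track, params)
    masks = segment.segment_movie(stack)

    native = trk.track_summary(track)
    t5 = trk.resample_track(track, 300.0)
    five = trk.track_summary(t5)

    outlines = [
        dyn_pca.extract_outline(m, pixel_size=params.pixel_size, frame_index=i)
        for i, m in enumerate(masks)
    ]
    model = dyn_pca.pca_fit(dyn_pca.build_matrix(outlines))

    tensor = dyn_tensor.build_tensor(
        masks, pixel_size=params.pixel_size, frame_interval=params.step_interval
    )
    tmodel = dyn_tensor.hosvd(tensor, ranks)
    p2 = dyn_tensor.pattern_image(tmodel, min(2, ranks[2]))

    iou = np.mean(
        [(a & b).sum() / (a | b).sum() for a, b in zip(masks, gt.masks)]
    )
    return {
        "velocity_um_s": native.velocity,
        "length_um": native.length,
        "mean_angle_deg": five.mean_angle,
        "turning_class": five.turning_class,
        "pc12_variance_fraction": float(model.explained_variance_fraction[:2].sum()),
        "trajectory_length": dyn_pca.trajectory_length(model),
        "trajectory_extent": dyn_pca.trajectory_extent(model),
        "pattern2_orientation_deg": dyn_tensor.dominant_orientation(p2),
        "mean_iou": float(iou),
    }


def run_batch(preset, n: int, seed: int, **param_overrides) -> pd.DataFrame:
    """Run ``n`` movies of one condition preset with per-movie derived seeds."""
    overrides = {**STUDY_PARAMS, **param_overrides}
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    rows = []
    for s in seeds:
        params = preset(seed=int(s), **overrides)
        rows.append({"seed": int(s), **run_movie(params)})
    return pd.DataFrame(rows)


def axial_median_orientation(degrees) -> float:
    """Median orientation of axial (mod-180) angles, degrees in [0, 180).

    Uses the doubled-angle circular mean direction as the centre estimate,
    appropriate for orientations where 0 and 180 are the same axis.
    """
    rad = np.radians(np.asarray(list(degrees), dtype=float) * 2.0)
    mean = math.atan2(np.sin(rad).mean(), np.cos(rad).mean()) / 2.0
    return math.degrees(mean) % 180.0
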