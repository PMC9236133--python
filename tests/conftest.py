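"""Shared fixtures: rasterized shapes and one small rendered movie."""

import numpy as np
import pytest
from skimage.draw import disk as _disk

from gcdyn import synthgc


def rasterize_disk(radius: int, pad: int = 10) -> np.ndarray:
    """Filled disk of the given integer radius on a padded canvas."""
    size = 2 * radius + 2 * pad + 1
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = _disk((radius + pad, radius + pad), radius + 0.5)
    mask[rr, cc] = True
    return mask


@pytest.fixture(scope="session")
def disk50():
    return rasterize_disk(50)


@pytest.fixture(scope="session")
def small_movie():
    """One control-like synthetic movie at reduced scale, with ground truth."""
    params = synthgc.control_like(
        seed=7,
        frame_shape=(160, 160),
        pixel_size=0.5,
        blob_radius_mean=4.0,
        duration=1800.0,  # 61 frames keeps unit tests quick
    )
    track = synthgc.simulate_track(params)
    stack, gt = synthgc.render_movie(track, params)
    return params, track, stack, gt
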