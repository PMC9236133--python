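"""HOSVD against unfolding-SVD oracles; pattern images; cross-checks."""

import numpy as np
import pytest

from gcdyn.dyn_tensor import (
    build_tensor,
    dominant_orientation,
    hosvd,
    pattern_image,
    reconstruction_error,
    unfold,
)

from conftest import rasterize_disk


def _random_tensor(shape=(8, 7, 6), seed=0):
    return np.random.default_rng(seed).normal(size=shape)


def test_build_tensor_stacks_masks_in_frame_order():
    rng = np.random.default_rng(1)
    masks = [rng.random((5, 6)) > 0.5 for _ in range(4)]
    mt = build_tensor(masks)
    assert mt.shape == (5, 6, 4)
    for t, m in enumerate(masks):
        assert np.array_equal(mt.data[:, :, t], m.astype(float))
    assert mt.data.sum() == sum(m.sum() for m in masks)
    with pytest.raises(ValueError):
        build_tensor([masks[0], masks[0][:4]])


def test_full_rank_hosvd_is_exact():
    T = _random_tensor()
    model = hosvd(T, T.shape)
    assert reconstruction_error(model, T) < 1e-10
    for U in model.factors:
        assert np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10)


def test_separable_tensor_is_rank_one():
    rng = np.random.default_rng(2)
    a, b, c = rng.normal(size=8), rng.normal(size=7), rng.normal(size=6)
    T = np.einsum("i,j,k->ijk", a, b, c)
    model = hosvd(T, (1, 1, 1))
    assert reconstruction_error(model, T) < 1e-10
    # P_1 proportional to the spatial outer product a b^T
    P = pattern_image(model, 1)
    cos = abs(np.sum(P * np.outer(a, b))) / (np.linalg.norm(P) * np.linalg.norm(np.outer(a, b)))
    assert cos == pytest.approx(1.0, abs=1e-10)


def test_mode_subspaces_match_gram_eigendecomposition_oracle():
    """Factors span the leading eigenspaces of the mode-n Gram matrices,
    built independently with einsum (no unfolding code shared)."""
    T = _random_tensor(seed=3)
    model = hosvd(T, T.shape)
    grams = [
        np.einsum("ijk,ljk->il", T, T),
        np.einsum("ijk,ilk->jl", T, T),
        np.einsum("ijk,ijl->kl", T, T),
    ]
    for U, G in zip(model.factors, grams):
        _, V = np.linalg.eigh(G)
        V = V[:, ::-1]
        # subspace match: |U^T V| is the identity when spectra are distinct
        M = np.abs(U.T @ V[:, : U.shape[1]])
        assert np.allclose(M, np.eye(U.shape[1]), atol=1e-8)


def test_mode_singular_values_match_unfolding_svd_oracle():
    T = _random_tensor(seed=4)
    for mode, perm in enumerate([(0, 1, 2), (1, 0, 2), (2, 0, 1)]):
        M = np.transpose(T, perm).reshape(T.shape[mode], -1)  # explicit unfolding
        s_oracle = np.linalg.svd(M, compute_uv=False)
        s_impl = np.linalg.svd(unfold(T, mode), compute_uv=False)
        assert np.allclose(s_impl, s_oracle, atol=1e-8)


def test_reconstruction_error_monotone_in_rank():
    T = _random_tensor(seed=5)
    errs = [reconstruction_error(hosvd(T, (r, r, r)), T) for r in (1, 2, 3, 4, 5, 6)]
    assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs, errs[1:]))
    # sweep one mode with the others fixed
    errs1 = [reconstruction_error(hosvd(T, (r, 4, 4)), T) for r in (1, 2, 4, 8)]
    assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs1, errs1[1:]))


def test_core_energy_bounded_by_tensor_energy():
    T = _random_tensor(seed=6)
    full = hosvd(T, T.shape)
    assert np.linalg.norm(full.core) == pytest.approx(np.linalg.norm(T), rel=1e-12)
    trunc = hosvd(T, (3, 3, 2))
    assert np.linalg.norm(trunc.core) <= np.linalg.norm(T) + 1e-12


def test_static_movie_pattern_is_the_common_frame():
    frame = rasterize_disk(6, pad=4).astype(float)
    T = np.repeat(frame[:, :, None], 10, axis=2)
    model = hosvd(T, (5, 5, 1))
    P = pattern_image(model, 1)
    cos = abs(np.sum(P * frame)) / (np.linalg.norm(P) * np.linalg.norm(frame))
    assert cos >= 0.99


def test_hooi_refinement_never_worse_than_hosvd():
    T = _random_tensor(seed=7)
    ranks = (3, 3, 2)
    e_hosvd = reconstruction_error(hosvd(T, ranks), T)
    e_hooi = reconstruction_error(hosvd(T, ranks, hooi=True), T)
    assert e_hooi <= e_hosvd + 1e-10


def test_motion_direction_reflected_in_pattern_orientation():
    """A vertically travelling blob vs a horizontally travelling one give
    second-pattern images whose dominant orientations differ by ~90 deg."""

    def moving_movie(axis):
        frames = []
        for i in range(24):
            m = np.zeros((64, 64), dtype=bool)
            pos = 10 + 2 * i
            r0, c0 = (pos, 32) if axis == 0 else (32, pos)
            m[r0 - 4 : r0 + 4, c0 - 4 : c0 + 4] = True
            frames.append(m)
        return build_tensor(frames)

    ori_v = dominant_orientation(pattern_image(hosvd(moving_movie(0), (16, 16, 2)), 2))
    ori_h = dominant_orientation(pattern_image(hosvd(moving_movie(1), (16, 16, 2)), 2))
    diff = abs(ori_v - ori_h) % 180
    diff = min(diff, 180 - diff)
    assert abs(diff - 90.0) < 15.0


def test_temporal_factor_matches_frame_matrix_svd():
    """Mode-3 factor equals (up to sign) the left singular vectors of the
    frames x pixels matrix — the bridge between tensor and vectorized PCA."""
    rng = np.random.default_rng(8)
    masks = [rng.random((9, 8)) for _ in range(7)]
    mt = build_tensor(masks)
    model = hosvd(mt, (9, 8, 7))
    X = np.stack([m.reshape(-1) for m in masks])  # frames x pixels
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    M = np.abs(model.factors[2].T @ U)
    assert np.allclose(M, np.eye(7), atol=1e-8)


def test_errors_on_bad_ranks_and_zero_tensor():
    T = _random_tensor()
    with pytest.raises(ValueError):
        hosvd(T, (9, 1, 1))
    model = hosvd(T, (2, 2, 2))
    with pytest.raises(ValueError):
        pattern_image(model, 3)
    with pytest.raises(ValueError):
        reconstruction_error(model, np.zeros_like(T))
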