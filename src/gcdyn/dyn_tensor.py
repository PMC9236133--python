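"""Multilinear (HOSVD / MPCA) decomposition of growth-cone movie tensors.

A segmented time-lapse movie is a third-order tensor T (rows x cols x
frames): two spatial modes and one temporal mode.  Unlike outline PCA,
which vectorizes each frame and discards the 2-D spatial structure, the
higher-order SVD keeps it: for each mode n the tensor is unfolded into a
matrix whose rows index that mode, the leading left singular vectors give
an orthonormal factor U_n, and the core G = T x_1 U1^T x_2 U2^T x_3 U3^T
holds the interactions.  Truncating the factor ranks (r1, r2, r3) gives the
multilinear principal component analysis (MPCA) of the movie.

The *pattern image* of temporal component k,

    P_k = U1 @ G[:, :, k] @ U2^T,

is the spatial image of the movement pattern associated with the k-th
temporal factor: a movie whose growth cone drifts vertically produces
vertically elongated structures in P_2, a horizontal drift produces
horizontal ones.

The decomposition is the plain truncated HOSVD (mode-wise SVDs plus one
core contraction): deterministic up to the sign convention that the
largest-magnitude entry of every factor column is positive.  Higher-order
orthogonal iteration (HOOI) is available behind a flag for optimal
truncated fits; at movie scale the difference is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "MovieTensor",
    "TensorModel",
    "build_tensor",
    "unfold",
    "hosvd",
    "pattern_image",
    "reconstruction_error",
    "dominant_orientation",
]


@dataclass
class MovieTensor:
    """rows x cols x frames array of {0,1} mask intensities with calibration."""

    data: np.ndarray
    pixel_size: float = 1.0  # um/px
    frame_interval: float = 30.0  # s

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TensorModel:
    """Core tensor + per-mode orthonormal factor matrices."""

    core: np.ndarray  # (r1, r2, r3)
    factors: tuple[np.ndarray, np.ndarray, np.ndarray]  # (rows x r1, cols x r2, frames x r3)

    @property
    def ranks(self) -> tuple[int, int, int]:
        return self.core.shape


def build_tensor(
    masks, pixel_size: float = 1.0, frame_interval: float = 30.0
) -> MovieTensor:
    """Stack per-frame masks into a rows x cols x frames tensor, frame order."""
    masks = [np.asarray(m) for m in masks]
    if not masks:
        raise ValueError("no masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks must share a common shape")
    data = np.stack([m.astype(float) for m in masks], axis=-1)
    return MovieTensor(data, pixel_size, frame_interval)


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: rows index mode ``mode``, columns the rest."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def _left_singular_basis(M: np.ndarray) -> np.ndarray:
    """Left singular vectors of M, descending singular value order.

    For very wide unfoldings (movie tensors unfold to rows x rows*frames)
    the eigendecomposition of the small Gram matrix M @ M.T is much cheaper
    than a direct SVD and spans the same basis.
    """
    rows, cols = M.shape
    if cols > 4 * rows:
        w, V = np.linalg.eigh(M @ M.T)
        return V[:, ::-1]
    U, _, _ = np.linalg.svd(M, full_matrices=False)
    return U


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Largest-|entry| of each column made positive (deterministic output)."""
    j = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[j, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def _multi_mode_product(tensor: np.ndarray, matrices, transpose: bool = False) -> np.ndarray:
    out = tensor
    for mode, M in enumerate(matrices):
        out = np.moveaxis(
            np.tensordot(M.T if transpose else M, out, axes=(1, mode)), 0, mode
        )
    return out


def hosvd(
    tensor: MovieTensor | np.ndarray,
    ranks: tuple[int, int, int],
    hooi: bool = False,
    hooi_iters: int = 10,
) -> TensorModel:
    """Truncated higher-order SVD of a 3-mode tensor.

    Factor n holds the leading ``ranks[n]`` left singular vectors of the
    mode-n unfolding; the core is the tensor contracted with the factor
    transposes.  With ``hooi=True`` the factors are refined by higher-order
    orthogonal iteration starting from the HOSVD initialisation.
    """
    T = tensor.data if isinstance(tensor, MovieTensor) else np.asarray(tensor, float)
    if T.ndim != 3:
        raise ValueError("expected a 3-mode tensor")
    for n, r in enumerate(ranks):
        if not (1 <= r <= T.shape[n]):
            raise ValueError(
                f"rank {r} out of range for mode {n} with extent {T.shape[n]}"
            )
    factors = []
    for n, r in enumerate(ranks):
        U = _left_singular_basis(unfold(T, n))
        factors.append(_fix_signs(U[:, :r]))
    if hooi:
        for _ in range(hooi_iters):
            for n in range(3):
                others = [
                    factors[m] for m in range(3) if m != n
                ]
                modes = [m for m in range(3) if m != n]
                proj = T
                for m, U in zip(modes, others):
                    proj = np.moveaxis(
                        np.tensordot(U.T, proj, axes=(1, m)), 0, m
                    )
                U = _left_singular_basis(unfold(proj, n))
                factors[n] = _fix_signs(U[:, : ranks[n]])
    core = _multi_mode_product(T, factors, transpose=True)
    return TensorModel(core=core, factors=tuple(factors))


def reconstruct(model: TensorModel) -> np.ndarray:
    """T_hat = core x_1 U1 x_2 U2 x_3 U3."""
    return _multi_mode_product(model.core, model.factors)


def reconstruction_error(model: TensorModel, tensor: MovieTensor | np.ndarray) -> float:
    """Relative Frobenius error ||T - T_hat||_F / ||T||_F."""
    T = tensor.data if isinstance(tensor, MovieTensor) else np.asarray(tensor, float)
    norm = np.linalg.norm(T)
    if norm == 0:
        raise ValueError("zero tensor: relative error undefined")
    return float(np.linalg.norm(T - reconstruct(model)) / norm)


def pattern_image(model: TensorModel, k: int, rescale: bool = False) -> np.ndarray:
    """Spatial image of temporal component ``k`` (1-based): U1 @ G[:,:,k] @ U2^T.

    With ``rescale=True`` the image is min-max rescaled to [0, 1] for
    export; the raw image preserves proportionality to the underlying
    pattern and is what analyses should use.
    """
    r3 = model.core.shape[2]
    if not (1 <= k <= r3):
        raise ValueError(f"component {k} out of range (1..{r3})")
    U1, U2, _ = model.factors
    G = model.core[:, :, k - 1]
    img = U1 @ G @ U2.T
    if rescale:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img


def dominant_orientation(image: np.ndarray, sigma: float = 2.0) -> float:
    """Dominant structure orientation of an image, degrees in [0, 180).

    Eigen-analysis of the smoothed, image-summed structure tensor: the
    eigenvector of the *smaller* eigenvalue points along the elongated
    structures (edges vary fastest across themselves).  0 deg = horizontal
    structures, 90 deg = vertical.
    """
    img = np.asarray(image, dtype=float)
    gy = ndi.gaussian_filter(img, sigma, order=(1, 0))
    gx = ndi.gaussian_filter(img, sigma, order=(0, 1))
    jxx = float((gx * gx).sum())
    jxy = float((gx * gy).sum())
    jyy = float((gy * gy).sum())
    # orientation of the gradient-dominant axis; structures run perpendicular
    theta_grad = 0.5 * math.atan2(2 * jxy, jxx - jyy)
    theta = math.degrees(theta_grad) + 90.0
    return theta % 180.0
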