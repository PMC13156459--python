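"""Forward operator of nonlinear inversion and its Sobolev preconditioning.

NLINV models the measured multi-coil k-space as F(rho, c) = P FFT(c * rho) and
penalizes a Sobolev norm of the coils.  The solver works in preconditioned
variables c~ with c = W c~, where W acts per coil as multiplication of the
k-space representation with the radial low-pass weight

    w(k) = (1 + a * |k|^2)^(-b),   k in [-0.5, 0.5]^2 (FoV-normalized),

so the quadratic penalty alpha * ||c~||^2 equals the Sobolev norm of c.  The
regularized pseudoinverse W+ (division by w capped at high frequencies by
``eps``) maps natural-domain coils back to c~; it is needed by the pole
correction, which multiplies the natural-domain coils by a non-smooth unit
field before returning to c~.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .datamodel import (
    NATURAL,
    PRECONDITIONED,
    CoilSet,
    ComplexImage,
    Grid2D,
    KSpaceData,
    SamplingPattern,
    fft2c,
    ifft2c,
)

__all__ = [
    "SobolevWeights",
    "apply_weighting",
    "apply_weighting_pinv",
    "forward_model",
    "derivative",
    "adjoint",
]


@dataclass
class SobolevWeights:
    """Radial k-space weights implementing the coil smoothness prior.

    Parameters
    ----------
    grid : Grid2D
    a, b : weight-shape parameters; defaults (220, 16) follow the NLINV
        convention.  w(0) = 1 is the maximum; larger b damps high frequencies
        harder (b -> 0 makes the weighting the identity).
    eps : Tikhonov floor of the pseudoinverse; caps the worst-case
        amplification of W+ at 1/(2 sqrt(eps)).
    """

    grid: Grid2D
    a: float = 220.0
    b: float = 16.0
    eps: float = 1e-6

    def __post_init__(self) -> None:
        kx = (np.arange(self.grid.nx) - self.grid.nx // 2) / self.grid.nx
        ky = (np.arange(self.grid.ny) - self.grid.ny // 2) / self.grid.ny
        k2 = kx[:, None] ** 2 + ky[None, :] ** 2
        self.w = (1.0 + self.a * k2) ** (-self.b)

    def pinv_w(self) -> np.ndarray:
        return self.w / (self.w**2 + self.eps)


def _check_grid(obj_grid: Grid2D, weights: SobolevWeights) -> None:
    if obj_grid != weights.grid:
        raise ValueError("grid mismatch between coils and Sobolev weights")


def apply_weighting(ctilde: CoilSet, weights: SobolevWeights) -> CoilSet:
    """Smoothing map c = W c~ = IFFT(w * FFT(c~)); preconditioned -> natural."""
    ctilde.require_domain(PRECONDITIONED)
    _check_grid(ctilde.grid, weights)
    c = ifft2c(weights.w[None] * fft2c(ctilde.values))
    return CoilSet(ctilde.grid, c, NATURAL)


def apply_weighting_pinv(c: CoilSet, weights: SobolevWeights) -> CoilSet:
    """Regularized pseudoinverse c~ = W+ c; natural -> preconditioned.

    Exact division by w for frequencies where w >> sqrt(eps); attenuated
    (instead of amplified without bound) where w falls below the floor.
    """
    c.require_domain(NATURAL)
    _check_grid(c.grid, weights)
    ct = ifft2c(weights.pinv_w()[None] * fft2c(c.values))
    return CoilSet(c.grid, ct, PRECONDITIONED)


def forward_model(
    rho: ComplexImage,
    ctilde: CoilSet,
    pattern: SamplingPattern,
    weights: SobolevWeights,
) -> KSpaceData:
    """Preconditioned forward operator F~(rho, c~) = P FFT((W c~) * rho)."""
    ctilde.require_domain(PRECONDITIONED)
    if rho.grid != ctilde.grid or rho.grid != pattern.grid:
        raise ValueError("grid mismatch in forward model")
    c = apply_weighting(ctilde, weights)
    y = fft2c(c.values * rho.values[None]) * pattern.mask[None]
    return KSpaceData(rho.grid, y, pattern)


def derivative(
    x: Tuple[ComplexImage, CoilSet],
    dx: Tuple[ComplexImage, CoilSet],
    pattern: SamplingPattern,
    weights: SobolevWeights,
) -> KSpaceData:
    """Directional derivative DF~(x)[dx] = P FFT(c * drho + (W dc~) * rho)."""
    rho, ctilde = x
    drho, dctilde = dx
    ctilde.require_domain(PRECONDITIONED)
    dctilde.require_domain(PRECONDITIONED)
    if drho.grid != rho.grid or dctilde.grid != ctilde.grid:
        raise ValueError("perturbation grids must match the base point")
    c = apply_weighting(ctilde, weights).values
    dc = apply_weighting(dctilde, weights).values
    dy = fft2c(c * drho.values[None] + dc * rho.values[None]) * pattern.mask[None]
    return KSpaceData(rho.grid, dy, pattern)


def adjoint(
    x: Tuple[ComplexImage, CoilSet],
    dy: KSpaceData,
    pattern: SamplingPattern,
    weights: SobolevWeights,
) -> Tuple[ComplexImage, CoilSet]:
    """Adjoint of the derivative under the canonical complex inner product.

    With z_i = IFFT(P dy_i):  the image part is sum_i conj(c_i) z_i and the
    coil part is W(conj(rho) z_i) per coil (W is self-adjoint since w is real).
    """
    rho, ctilde = x
    ctilde.require_domain(PRECONDITIONED)
    if dy.grid != rho.grid:
        raise ValueError("data grid mismatch in adjoint")
    c = apply_weighting(ctilde, weights).values
    z = ifft2c(dy.values * pattern.mask[None])
    drho = np.sum(np.conj(c) * z, axis=0)
    dct = ifft2c(weights.w[None] * fft2c(np.conj(rho.values)[None] * z))
    return (
        ComplexImage(rho.grid, drho),
        CoilSet(ctilde.grid, dct, PRECONDITIONED),
    )
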