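"""Synthetic multi-coil Cartesian k-space simulator.

Provides piecewise-constant ellipse phantoms with a smooth polynomial phase,
two coil-map families (smooth ``gaussian_ring`` lobes with no singularities,
and ``dipole`` maps whose transverse point-dipole field carries exactly one
in-plane phase singularity per coil), a routine to plant an artificial
pole/conjugate-pole pair without changing the data, regular undersampling
patterns with an auto-calibration block, and the noisy forward simulation
``y = P[F(c * rho) + n]``.

The amplitude of any analytic field at its own singular pixel is set to its
limit 0 with phase 0; the winding-number code treats exact zeros specially, so
the arbitrary phase there is never used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    NATURAL,
    CoilSet,
    ComplexImage,
    Grid2D,
    KSpaceData,
    SamplingPattern,
    fft2c,
)
from .polefix import phase_vortex

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "CoilLayout",
    "default_phantom_spec",
    "make_phantom",
    "make_coils",
    "plant_artificial_pole",
    "make_pattern",
    "sample_kspace",
]


@dataclass(frozen=True)
class Ellipse:
    """One phantom ellipse: center and semi-axes in FoV units."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    rotation: float = 0.0
    amplitude: complex = 1.0


@dataclass
class PhantomSpec:
    """Ellipse list plus low-order polynomial coefficients for the phase.

    ``phase_poly`` holds (c00, c10, c01, c20, c11, c02) of
    phi(x, y) = c00 + c10 x + c01 y + c20 x^2 + c11 x y + c02 y^2 (radians).
    """

    ellipses: List[Ellipse]
    phase_poly: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.ellipses:
            raise ValueError("phantom needs at least one ellipse")
        area = sum(np.pi * e.semi_axes[0] * e.semi_axes[1] for e in self.ellipses)
        if area < 0.10:
            raise ValueError("ellipse supports must cover at least 10% of the FoV")


def default_phantom_spec() -> PhantomSpec:
    """A simple head-like phantom: one large ellipse with two inner features."""
    return PhantomSpec(
        ellipses=[
            Ellipse((0.0, 0.0), (0.36, 0.30), rotation=0.2, amplitude=1.0),
            Ellipse((0.10, 0.05), (0.08, 0.05), rotation=-0.4, amplitude=0.5),
            Ellipse((-0.12, -0.08), (0.06, 0.09), rotation=0.7, amplitude=0.3),
        ],
        phase_poly=(0.3, 1.2, -0.8, 2.0, 1.5, -1.0),
    )


def _poly2(coeffs: Sequence[float], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    c00, c10, c01, c20, c11, c02 = coeffs
    return c00 + c10 * x + c01 * y + c20 * x * x + c11 * x * y + c02 * y * y


def make_phantom(grid: Grid2D, spec: PhantomSpec) -> ComplexImage:
    """Rasterize a phantom: summed ellipse indicators times a smooth phase."""
    x, y = grid.position_grids()
    amp = np.zeros(grid.shape, dtype=np.complex128)
    for e in spec.ellipses:
        dx, dy = x - e.center[0], y - e.center[1]
        ct, st = np.cos(e.rotation), np.sin(e.rotation)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        inside = (u / e.semi_axes[0]) ** 2 + (v / e.semi_axes[1]) ** 2 <= 1.0
        amp[inside] += e.amplitude
    phase = _poly2(spec.phase_poly, x, y)
    return ComplexImage(grid, amp * np.exp(1j * phase))


@dataclass
class CoilLayout:
    """Coil-array geometry for the simulator.

    ``gaussian_ring`` places nc Gaussian magnitude lobes on a ring around the
    FoV with a smooth per-coil polynomial phase (no singularities anywhere).
    ``dipole`` evaluates the transverse field of a point magnetic dipole
    m = m e_z at plane offset ``dipole_z``, c ~ (B_x - i B_y): each coil has
    exactly one in-plane phase singularity with vanishing amplitude.
    """

    nc: int
    style: str = "gaussian_ring"
    ring_radius: float = 0.5
    lobe_width: float = 0.5
    dipole_radius: float = 0.30
    dipole_z: float = 0.15

    def __post_init__(self) -> None:
        if self.nc < 2:
            raise ValueError("need at least 2 coils")
        if self.style not in ("gaussian_ring", "dipole"):
            raise ValueError(f"unknown coil style {self.style!r}")
        if self.style == "dipole" and self.dipole_z == 0:
            raise ValueError("dipole plane offset must be nonzero")


def make_coils(grid: Grid2D, layout: CoilLayout) -> CoilSet:
    """Generate natural-domain coil sensitivity maps for the given layout."""
    x, y = grid.position_grids()
    maps = np.empty((layout.nc, *grid.shape), dtype=np.complex128)
    angles = 2 * np.pi * np.arange(layout.nc) / layout.nc
    if layout.style == "gaussian_ring":
        for i, th in enumerate(angles):
            cx, cy = layout.ring_radius * np.cos(th), layout.ring_radius * np.sin(th)
            mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * layout.lobe_width**2))
            # sensitivity varies on the coil-distance scale, so the phase is
            # close to linear across the FoV; offsets decorrelate the coils
            phase = _poly2((0.2 * i, np.cos(th), np.sin(th), 0.0, 0.0, 0.0), x, y)
            maps[i] = mag * np.exp(1j * phase)
    else:  # dipole
        for i, th in enumerate(angles):
            px, py = layout.dipole_radius * np.cos(th), layout.dipole_radius * np.sin(th)
            dx, dy, dz = x - px, y - py, layout.dipole_z
            r2 = dx * dx + dy * dy + dz * dz
            # transverse dipole field: B_x - i B_y = 3 m dz (dx - i dy) / |r|^5
            c = 3.0 * dz * (dx - 1j * dy) / r2**2.5
            c /= np.abs(c).max()
            maps[i] = c
    return CoilSet(grid, maps, NATURAL)


def plant_artificial_pole(
    rho: ComplexImage, coils: CoilSet, r0: Tuple[float, float], sign: int
) -> Tuple[ComplexImage, CoilSet]:
    """Plant a pole in the image and its conjugate in every coil map.

    Multiplies the image by the unit-magnitude phase vortex of the given sign
    at ``r0`` and every coil by the opposite vortex, so all pointwise products
    c_i * rho — and hence the simulated k-space — are unchanged exactly.
    """
    coils.require_domain(NATURAL)
    if not (-0.5 <= r0[0] <= 0.5 and -0.5 <= r0[1] <= 0.5):
        raise ValueError(f"pole position {r0} lies outside the FoV")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    theta = phase_vortex(rho.grid, r0, sign).values
    rho_out = ComplexImage(rho.grid, rho.values * theta)
    coils_out = CoilSet(coils.grid, coils.values * np.conj(theta), NATURAL)
    return rho_out, coils_out


def make_pattern(grid: Grid2D, rx: int, ry: int, ac_size: int = 0) -> SamplingPattern:
    """Regular rx x ry undersampling lattice through the k-space center,
    plus a fully sampled central ``ac_size`` x ``ac_size`` block."""
    if rx < 1 or ry < 1:
        raise ValueError("acceleration factors must be >= 1")
    if ac_size > min(grid.nx, grid.ny):
        raise ValueError("AC block larger than the grid")
    ix = np.arange(grid.nx)[:, None]
    iy = np.arange(grid.ny)[None, :]
    cx, cy = grid.nx // 2, grid.ny // 2
    mask = ((ix - cx) % rx == 0) & ((iy - cy) % ry == 0)
    if ac_size > 0:
        mask[cx - ac_size // 2 : cx - ac_size // 2 + ac_size,
             cy - ac_size // 2 : cy - ac_size // 2 + ac_size] = True
    return SamplingPattern(grid, mask, ac_size)


def sample_kspace(
    rho: ComplexImage,
    coils: CoilSet,
    pattern: SamplingPattern,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpaceData:
    """Simulate y = P[FFT(c_i * rho) + n] with iid complex Gaussian noise.

    ``noise_sigma`` is the standard deviation per real/imaginary component
    (pre-whitened, iid across coils).  Masked-out entries are exactly zero.
    """
    coils.require_domain(NATURAL)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if coils.grid != rho.grid or pattern.grid != rho.grid:
        raise ValueError("grid mismatch between image, coils and pattern")
    y = fft2c(coils.values * rho.values[None])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        y = y + noise_sigma * noise
    y = y * pattern.mask[None]
    return KSpaceData(rho.grid, y, pattern)
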