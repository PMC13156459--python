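"""Phase-pole detection and correction on coil sensitivity maps.

Joint estimation of an image and coil sensitivities is only determined up to a
complex scaling field: a phase vortex in the image compensated by the
conjugate vortex in every coil is data-consistent, and smooth-coil
regularization then forces a zero ("black hole") into the reconstruction at
the vortex.  This module detects such spurious poles and removes them.

Detection works on the coil maps, not the image, because the smooth coils are
noise-free while low-signal image regions produce spurious windings:

1. per coil, the winding number S_i(r) of the map around a small circle of
   diameter d (default 0.05 FoV) is computed at every pixel;
2. the per-pixel weighted average S(r) = sum_i w_i S_i / sum_i w_i with
   w_i = |c_i|^2 suppresses genuine single-coil singularities (their own
   amplitude vanishes there) while a pole shared by all coils survives;
3. |S| is thresholded at t (default 1/2), nearby components are merged by a
   morphological closing with a disk of diameter d_closing (default d),
   and each remaining connected component yields one pole: its location is
   the component centroid, its sign the sign of the mean of S over it.

Correction multiplies the image by the product of unit-magnitude phase
vortices built from the detected poles (one per pole, with the coil-side
winding sign so that the conjugate applied to the coils cancels their
vortices), fixes the global phase so the image phase changes as little as
possible in high-signal regions, and maps the coils back to the
preconditioned domain through the regularized pseudoinverse W+.

An external mode handles coil maps estimated by other calibrations (e.g.
ESPIRiT), where poles sit at identical pixels in all coils: winding numbers
use the 4-neighbour one-pixel loop and the closing step is skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .datamodel import (
    NATURAL,
    PRECONDITIONED,
    CoilSet,
    ComplexImage,
    Grid2D,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DetectConfig",
    "PoleMap",
    "PoleSet",
    "CorrectionField",
    "CircleCurve",
    "phase_vortex",
    "circle_curve",
    "winding_number",
    "coil_winding_maps",
    "detect_poles",
    "global_phase",
    "build_correction",
    "apply_correction",
    "correct_external_coils",
]


@dataclass
class DetectConfig:
    """Parameters of the pole detector.

    circle_diameter and closing_diameter are FoV fractions; they convert to
    pixels at use sites by multiplying with the grid size.  ``external_mode``
    selects one-pixel (4-neighbour) loops and skips the closing, for coil
    stacks whose poles coincide exactly across coils.
    """

    circle_diameter: float = 0.05
    threshold: float = 0.5
    closing_diameter: Optional[float] = None
    connectivity: int = 8
    external_mode: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.circle_diameter <= 0:
            raise ValueError("circle diameter must be positive")
        if self.closing_diameter is None:
            self.closing_diameter = self.circle_diameter
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class PoleMap:
    """Per-coil winding maps, weights and their weighted average."""

    grid: Grid2D
    s_maps: np.ndarray  # (nc, nx, ny) integer winding numbers
    weight_maps: np.ndarray  # (nc, nx, ny) |c_i|^2
    s_avg: np.ndarray  # (nx, ny) weighted average, 0 where total weight is 0
    mask: Optional[np.ndarray] = None  # binary detection mask (after closing)


@dataclass
class PoleSet:
    """Detected pole locations (continuous FoV positions) and winding signs.

    Signs are the windings observed in the coil maps; the compensated image
    pole has the opposite winding.
    """

    locations: np.ndarray  # (M, 2)
    signs: np.ndarray  # (M,) in {+1, -1}

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        if self.locations.size == 0:
            self.locations = self.locations.reshape(0, 2)
        self.signs = np.asarray(self.signs, dtype=int).reshape(-1)
        if np.any(self.signs == 0):
            raise ValueError("pole signs must be nonzero")
        if self.locations.shape != (self.signs.size, 2):
            raise ValueError("locations and signs disagree in length")

    @property
    def count(self) -> int:
        return self.signs.size


@dataclass
class CorrectionField:
    """A unit-magnitude complex field theta(r) used as multiplicative correction."""

    grid: Grid2D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError("correction field shape does not match grid")
        if np.max(np.abs(np.abs(self.values) - 1.0)) > 1e-12:
            raise ValueError("correction field must have unit magnitude everywhere")


def phase_vortex(grid: Grid2D, r0: Tuple[float, float], sign: int) -> CorrectionField:
    """Unit-magnitude field with azimuthal phase of winding ``sign`` about r0.

    theta(r) = ((r - r0)_x + i sign (r - r0)_y) / |r - r0|; at a pixel whose
    center coincides with r0 (distance < 1e-12) the value is set to 1.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    x, y = grid.position_grids()
    dx, dy = x - r0[0], y - r0[1]
    dist = np.hypot(dx, dy)
    at_pole = dist < 1e-12
    safe = np.where(at_pole, 1.0, dist)
    theta = (dx + 1j * sign * dy) / safe
    theta[at_pole] = 1.0
    return CorrectionField(grid, theta)


@dataclass
class CircleCurve:
    """Closed discrete loop of pixel indices (closure r_N = r_0 implicit)."""

    points: np.ndarray  # (N, 2) int pixel indices
    clipped: bool = False  # touched the grid boundary -> winding defined as 0


def _circle_offsets(diameter_px: float) -> np.ndarray:
    """Integer pixel offsets approximating a circle of the given diameter.

    Diameters below 2 px degenerate under rounding, so they yield the
    4-neighbour one-pixel loop (the square of adjacent pixels) used by the
    external/ESPIRiT mode.
    """
    if diameter_px < 2.0:
        return np.array([[1, 0], [0, 1], [-1, 0], [0, -1]])
    n = max(8, int(np.ceil(np.pi * diameter_px)))
    ang = 2 * np.pi * np.arange(n) / n
    pts = np.rint(np.column_stack([diameter_px / 2 * np.cos(ang),
                                   diameter_px / 2 * np.sin(ang)])).astype(int)
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)  # drop consecutive dups
    return pts[keep]


def circle_curve(
    center_pixel: Tuple[int, int], diameter_px: float, grid: Grid2D
) -> CircleCurve:
    """Discrete circle of pixel indices around ``center_pixel``.

    Curves that would leave the grid are flagged ``clipped``; the winding
    number is reported as 0 there (poles within half a diameter of the FoV
    edge are a known blind zone).
    """
    if diameter_px < 1:
        raise ValueError("diameter must be at least 1 pixel")
    offs = _circle_offsets(diameter_px)
    pts = np.asarray(center_pixel, dtype=int) + offs
    clipped = bool(
        np.any(pts < 0) or np.any(pts[:, 0] >= grid.nx) or np.any(pts[:, 1] >= grid.ny)
    )
    if clipped:
        pts = np.clip(pts, 0, [grid.nx - 1, grid.ny - 1])
    return CircleCurve(pts, clipped)


def winding_number(field: ComplexImage, curve: CircleCurve | np.ndarray) -> int:
    """Winding number of a complex field along a closed pixel loop.

    Sums the principal-value phase increments Arg in (-pi, pi] along the loop
    and divides by 2 pi, rounding to the nearest integer.  If the field is
    exactly zero at any curve point, the phase there is undefined and the
    winding number is defined as 0; clipped curves also give 0.
    """
    if isinstance(curve, CircleCurve):
        if curve.clipped:
            return 0
        pts = curve.points
    else:
        pts = np.asarray(curve, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("curve must be an (N, 2) list of pixel indices, N >= 3")
    v = field.values[pts[:, 0], pts[:, 1]]
    if np.any(v == 0):
        return 0
    dphi = np.angle(np.roll(v, -1) * np.conj(v))
    return int(np.rint(dphi.sum() / (2 * np.pi)))


def _winding_map(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Vectorized per-pixel winding map of one complex map.

    Equivalent to evaluating ``winding_number`` on the translated loop at every
    pixel: shifted copies of the map realize the loop samples simultaneously.
    Pixels whose loop would leave the grid, or touches an exact zero, get 0.
    """
    nx, ny = values.shape
    shifted = np.empty((len(offsets), nx, ny), dtype=np.complex128)
    for j, (ox, oy) in enumerate(offsets):
        shifted[j] = np.roll(values, (-ox, -oy), axis=(0, 1))
    dphi = np.angle(shifted[np.r_[1:len(offsets), 0]] * np.conj(shifted))
    s = np.rint(dphi.sum(axis=0) / (2 * np.pi)).astype(int)
    s[np.any(shifted == 0, axis=0)] = 0
    # invalidate the boundary band where np.roll wraps around
    xmax, ymax = offsets[:, 0].max(), offsets[:, 1].max()
    xmin, ymin = offsets[:, 0].min(), offsets[:, 1].min()
    if xmin < 0:
        s[:-xmin, :] = 0
    if xmax > 0:
        s[nx - xmax :, :] = 0
    if ymin < 0:
        s[:, :-ymin] = 0
    if ymax > 0:
        s[:, ny - ymax :] = 0
    return s


def coil_winding_maps(coils: CoilSet, cfg: DetectConfig) -> PoleMap:
    """Per-coil winding maps, |c_i|^2 weights and their weighted average."""
    coils.require_domain(NATURAL)
    if coils.nc < 2:
        raise ValueError("pole detection needs at least 2 coils")
    grid = coils.grid
    d_px = 1.0 if cfg.external_mode else cfg.circle_diameter * grid.nx
    offsets = _circle_offsets(d_px)
    s_maps = np.stack([_winding_map(coils.values[i], offsets) for i in range(coils.nc)])
    w = np.abs(coils.values) ** 2
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_avg = np.where(wsum > 0, (w * s_maps).sum(axis=0) / np.where(wsum > 0, wsum, 1), 0.0)
    return PoleMap(grid, s_maps, w, s_avg)


def _disk_footprint(diameter_px: float) -> np.ndarray:
    """Binary disk structuring element of the given diameter in pixels."""
    r = diameter_px / 2.0
    n = int(np.ceil(r))
    ox, oy = np.mgrid[-n : n + 1, -n : n + 1]
    return (ox * ox + oy * oy) <= r * r


def detect_poles(pm: PoleMap, cfg: DetectConfig) -> PoleSet:
    """Threshold, close and label the weighted winding map into a pole list.

    Components of |S| > t merged by a morphological closing (skipped in
    external mode) become poles: location = unweighted centroid of the
    component converted to a FoV position, sign = sign of the mean of S over
    the component.
    """
    mask = np.abs(pm.s_avg) > cfg.threshold
    if mask.any() and not cfg.external_mode:
        fp = _disk_footprint(cfg.closing_diameter * pm.grid.nx)
        mask = ndimage.binary_closing(mask, structure=fp)
    pm.mask = mask
    if not mask.any():
        return PoleSet(np.empty((0, 2)), np.empty(0, dtype=int))
    structure = np.ones((3, 3), dtype=int) if cfg.connectivity == 8 else None
    labels, m = ndimage.label(mask, structure=structure)
    locs, signs = [], []
    for j in range(1, m + 1):
        comp = labels == j
        mean_s = pm.s_avg[comp].mean()
        if mean_s == 0:
            logger.warning("component %d has zero mean winding; skipped", j)
            continue
        cx, cy = ndimage.center_of_mass(comp)
        locs.append(pm.grid.pixel_to_pos(cx, cy))
        signs.append(1 if mean_s > 0 else -1)
    if not signs:
        return PoleSet(np.empty((0, 2)), np.empty(0, dtype=int))
    return PoleSet(np.asarray(locs), np.asarray(signs))


def global_phase(theta: CorrectionField, rho: ComplexImage) -> CorrectionField:
    """Fix the global phase of theta so it perturbs the image phase least.

    Multiplies theta by the unit number that makes <rho, theta * rho> real and
    positive (inner product conjugate-linear in its second argument), i.e. the
    normalized image-power-weighted average of conj(theta).  A zero inner
    product leaves theta unchanged with a warning.
    """
    z = np.sum(np.abs(rho.values) ** 2 * np.conj(theta.values))
    if z == 0:
        warnings.warn("global phase undefined (zero inner product); theta unchanged")
        return theta
    return CorrectionField(theta.grid, theta.values * (z / np.abs(z)))


def build_correction(
    poles: PoleSet, grid: Grid2D, rho: ComplexImage
) -> CorrectionField:
    """Product of phase vortices for all detected poles, with global phase.

    The vortex signs are the coil-side windings, so multiplying the returned
    field onto the image (and its conjugate onto the coils) cancels the
    compensated pole pair.  With no poles the identity field is returned.
    """
    theta = np.ones(grid.shape, dtype=np.complex128)
    if poles.count == 0:
        return CorrectionField(grid, theta)
    for loc, s in zip(poles.locations, poles.signs):
        theta = theta * phase_vortex(grid, tuple(loc), int(s)).values
    theta /= np.abs(theta)  # re-normalize accumulated rounding
    return global_phase(CorrectionField(grid, theta), rho)


def apply_correction(
    rho: ComplexImage,
    ctilde: CoilSet,
    theta: CorrectionField,
    weights,
) -> Tuple[ComplexImage, CoilSet]:
    """Apply a pole correction inside the solver.

    rho' = theta * rho; the preconditioned coils pass through the natural
    domain: c~' = W+ (conj(theta) * (W c~)).  The products c' * rho' equal
    c * rho up to the bounded W+ regularization error.
    """
    from .forward import apply_weighting, apply_weighting_pinv

    ctilde.require_domain(PRECONDITIONED)
    if theta.grid != rho.grid or ctilde.grid != rho.grid:
        raise ValueError("grid mismatch in apply_correction")
    rho_out = ComplexImage(rho.grid, rho.values * theta.values)
    c = apply_weighting(ctilde, weights)
    c_corr = CoilSet(c.grid, c.values * np.conj(theta.values)[None], NATURAL)
    return rho_out, apply_weighting_pinv(c_corr, weights)


def correct_external_coils(
    coils: CoilSet,
    combined: Optional[ComplexImage],
    cfg: Optional[DetectConfig] = None,
) -> Tuple[CoilSet, Optional[ComplexImage], PoleSet]:
    """Post-hoc pole removal on externally estimated coil maps.

    Poles in such stacks (e.g. ESPIRiT maps with the first coil as phase
    reference) sit at identical pixels in every coil, so detection uses the
    one-pixel 4-neighbour loop and no closing.  Coils are multiplied by the
    conjugate vortex product and the combined image (if given) by the vortex
    product with the global phase fixed; the pointwise products
    coil * combined are preserved exactly (no W+ involved here).
    """
    coils.require_domain(NATURAL)
    if cfg is None:
        cfg = DetectConfig(external_mode=True)
    elif not cfg.external_mode:
        raise ValueError("correct_external_coils requires external_mode detection")
    pm = coil_winding_maps(coils, cfg)
    poles = detect_poles(pm, cfg)
    if poles.count == 0:
        return coils, combined, poles
    theta = np.ones(coils.grid.shape, dtype=np.complex128)
    for loc, s in zip(poles.locations, poles.signs):
        theta = theta * phase_vortex(coils.grid, tuple(loc), int(s)).values
    theta /= np.abs(theta)
    field = CorrectionField(coils.grid, theta)
    if combined is not None:
        field = global_phase(field, combined)
        combined = ComplexImage(combined.grid, combined.values * field.values)
    coils_out = CoilSet(coils.grid, coils.values * np.conj(field.values)[None], NATURAL)
    return coils_out, combined, poles
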