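"""Core grid/array containers, coordinate conventions, FFT helpers and CFL I/O.

Conventions used throughout the package:

* The field of view (FoV) is the unit square.  Pixel ``(ix, iy)`` of an
  ``nx x ny`` grid sits at the continuous position
  ``r = ((ix + 0.5)/nx - 0.5, (iy + 0.5)/ny - 0.5)``, so distances expressed
  as FoV fractions convert to pixels by multiplying with ``nx`` (resp. ``ny``).
* k-space is stored centered: the zero-frequency sample lives at index
  ``(nx // 2, ny // 2)`` and the FFT used everywhere is the unitary, centered
  discrete Fourier transform (shift - FFT - shift).
* Arrays are complex128; image arrays have shape ``(nx, ny)`` and multi-coil
  stacks ``(nc, nx, ny)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "Grid2D",
    "ComplexImage",
    "CoilSet",
    "SamplingPattern",
    "KSpaceData",
    "ReconConfig",
    "CFLFormatError",
    "read_cfl",
    "write_cfl",
    "fft2c",
    "ifft2c",
]

_SPATIAL_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered, unitary 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_SPATIAL_AXES), axes=_SPATIAL_AXES, norm="ortho"),
        axes=_SPATIAL_AXES,
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Centered, unitary 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_SPATIAL_AXES), axes=_SPATIAL_AXES, norm="ortho"),
        axes=_SPATIAL_AXES,
    )


@dataclass(frozen=True)
class Grid2D:
    """A 2D pixel grid over the unit-square field of view."""

    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError(f"grid must be at least 8x8, got {self.nx}x{self.ny}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.nx, self.ny)

    def pixel_to_pos(self, ix, iy):
        """Continuous FoV position of pixel centers (vectorized)."""
        x = (np.asarray(ix) + 0.5) / self.nx - 0.5
        y = (np.asarray(iy) + 0.5) / self.ny - 0.5
        return x, y

    def pos_to_pixel(self, x, y):
        """Nearest pixel index of a FoV position; inverse of pixel_to_pos."""
        ix = np.rint((np.asarray(x) + 0.5) * self.nx - 0.5).astype(int)
        iy = np.rint((np.asarray(y) + 0.5) * self.ny - 0.5).astype(int)
        return ix, iy

    def position_grids(self) -> Tuple[np.ndarray, np.ndarray]:
        """Meshgrids X, Y of shape (nx, ny) with pixel-center positions."""
        x = (np.arange(self.nx) + 0.5) / self.nx - 0.5
        y = (np.arange(self.ny) + 0.5) / self.ny - 0.5
        return np.meshgrid(x, y, indexing="ij")


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class ComplexImage:
    """A complex scalar field rho(r) on a 2D grid.

    Magnitude and phase are implicit: ``abs(values)`` and ``angle(values)``.
    """

    grid: Grid2D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"image shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        _check_finite(self.values, "ComplexImage")

    def copy(self) -> "ComplexImage":
        return ComplexImage(self.grid, self.values.copy())


NATURAL = "natural"
PRECONDITIONED = "preconditioned"


@dataclass
class CoilSet:
    """A stack of complex coil sensitivity maps.

    ``domain_tag`` records whether the maps are natural-domain sensitivities c
    or the preconditioned variables c~ (c = W c~ with W the Sobolev smoothing
    operator); operations check the tag so the two are never silently mixed.
    """

    grid: Grid2D
    values: np.ndarray
    domain_tag: str = NATURAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"coil stack shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.domain_tag not in (NATURAL, PRECONDITIONED):
            raise ValueError(f"unknown domain_tag {self.domain_tag!r}")
        _check_finite(self.values, "CoilSet")

    @property
    def nc(self) -> int:
        return self.values.shape[0]

    def require_domain(self, tag: str) -> None:
        if self.domain_tag != tag:
            raise ValueError(
                f"expected {tag}-domain coils, got {self.domain_tag}-domain"
            )

    def copy(self) -> "CoilSet":
        return CoilSet(self.grid, self.values.copy(), self.domain_tag)


@dataclass
class SamplingPattern:
    """Binary Cartesian k-space sampling mask with an optional AC block.

    ``ac_size`` is the side length of the fully sampled central
    auto-calibration block (0 if none).  The block is anchored so that the
    zero-frequency index (nx//2, ny//2) is inside it.
    """

    grid: Grid2D
    mask: np.ndarray
    ac_size: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("sampling mask is all-zero")
        if self.ac_size > 0:
            sl = self.ac_slices()
            if not self.mask[sl].all():
                raise ValueError("central AC block is not fully sampled")

    def ac_slices(self) -> Tuple[slice, slice]:
        s = self.ac_size
        cx, cy = self.grid.nx // 2, self.grid.ny // 2
        return (slice(cx - s // 2, cx - s // 2 + s), slice(cy - s // 2, cy - s // 2 + s))

    @property
    def is_full(self) -> bool:
        return bool(self.mask.all())


@dataclass
class KSpaceData:
    """Measured or simulated multi-coil Cartesian k-space (centered)."""

    grid: Grid2D
    values: np.ndarray
    pattern: SamplingPattern

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise ValueError("k-space stack shape does not match grid")
        _check_finite(self.values, "KSpaceData")
        if np.any(self.values[:, ~self.pattern.mask] != 0):
            raise ValueError("k-space values must be zero where the mask is zero")

    @property
    def nc(self) -> int:
        return self.values.shape[0]


@dataclass
class ReconConfig:
    """Configuration of the iteratively regularized Gauss-Newton solver."""

    newton_steps: int = 12
    alpha_min: float = 0.001
    alpha_decay: float = 0.5
    cg_iters: int = 50
    cg_tol: float = 1e-6
    data_norm_target: float = 100.0
    pole_correction: bool = False
    detect_step: int = 8
    detect_params: "object" = None  # DetectConfig; resolved lazily to avoid a cycle
    detect_every: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha_min < 1):
            raise ValueError("alpha_min must lie in (0, 1)")
        if not (0 < self.alpha_decay < 1):
            raise ValueError("alpha_decay must lie in (0, 1)")
        if self.detect_step >= self.newton_steps:
            raise ValueError("detect_step must be smaller than newton_steps")
        if self.detect_params is None:
            from .polefix import DetectConfig

            self.detect_params = DetectConfig()


class CFLFormatError(RuntimeError):
    """Raised when a CFL header/payload pair is malformed or inconsistent."""


def read_cfl(path_stem: str | os.PathLike) -> Tuple[list, np.ndarray]:
    """Read a BART-style CFL pair ``<stem>.hdr`` / ``<stem>.cfl``.

    Returns the dimension list from the header and the complex array
    (column-major layout, little-endian float32 interleaved pairs).
    """
    stem = os.fspath(path_stem)
    hdr_path, cfl_path = stem + ".hdr", stem + ".cfl"
    if not os.path.exists(hdr_path):
        raise FileNotFoundError(hdr_path)
    if not os.path.exists(cfl_path):
        raise FileNotFoundError(cfl_path)

    with open(hdr_path, "r") as fh:
        lines = fh.read().splitlines()
    dims = None
    for i, line in enumerate(lines):
        if line.startswith("# Dimensions"):
            if i + 1 >= len(lines):
                raise CFLFormatError(f"{hdr_path}: missing dimension line")
            try:
                dims = [int(tok) for tok in lines[i + 1].split()]
            except ValueError as exc:
                raise CFLFormatError(f"{hdr_path}: unparsable dimensions") from exc
            break
    if not dims:
        raise CFLFormatError(f"{hdr_path}: no '# Dimensions' entry")

    n = int(np.prod(dims))
    raw = np.fromfile(cfl_path, dtype="<f4")
    if raw.size != 2 * n:
        raise CFLFormatError(
            f"{cfl_path}: expected {2 * n} float32 entries for dims {dims}, found {raw.size}"
        )
    values = raw[0::2] + 1j * raw[1::2]
    return dims, values.reshape(dims, order="F")


def write_cfl(path_stem: str | os.PathLike, values: np.ndarray) -> None:
    """Write ``values`` as a BART-style CFL pair (dims padded to >= 5 with 1s)."""
    values = np.asarray(values)
    _check_finite(values, "CFL payload")
    stem = os.fspath(path_stem)
    dims = list(values.shape) if values.ndim else [1]
    dims = dims + [1] * max(0, 5 - len(dims))
    with open(stem + ".hdr", "w") as fh:
        fh.write("# Dimensions\n")
        fh.write(" ".join(str(d) for d in dims) + "\n")
    flat = np.ravel(values.astype(np.complex64), order="F")
    out = np.empty(2 * flat.size, dtype="<f4")
    out[0::2] = flat.real
    out[1::2] = flat.imag
    out.tofile(stem + ".cfl")
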