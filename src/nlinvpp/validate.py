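"""Quantitative quality measures: the coil projection test and pole recovery.

The projection test asks whether measured coil images m_i(r) lie in the
pointwise one-dimensional subspace spanned by the estimated sensitivities:
P_c(r) = c(r) c(r)^H / ||c(r)||^2 applied across the coil axis.  For well
calibrated coils the residual m - P_c m is only measurement noise and carries
no image structure; a compensated phase pole leaves a localized residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .datamodel import NATURAL, CoilSet, ComplexImage, KSpaceData, ifft2c
from .polefix import PoleSet

__all__ = [
    "ProjectionReport",
    "projection_residual",
    "coil_image",
    "support_mask",
    "pole_recovery_score",
]


@dataclass
class ProjectionReport:
    """Residuals of the pointwise projection of coil images onto span(c)."""

    residuals: np.ndarray  # (nc, nx, ny)
    rss: np.ndarray  # (nx, ny) root-sum-of-squares residual

    def mean_rss(self, mask: Optional[np.ndarray] = None) -> float:
        """Mean RSS residual, optionally restricted to a support mask."""
        return float(self.rss[mask].mean() if mask is not None else self.rss.mean())


def projection_residual(m: CoilSet, coils: CoilSet) -> ProjectionReport:
    """Residual m - P_c m of the pointwise rank-one projection onto the coils.

    Where ||c(r)|| = 0 the projector is the zero map (the continuous limit),
    so the residual there equals m.
    """
    m.require_domain(NATURAL)
    coils.require_domain(NATURAL)
    if m.grid != coils.grid or m.nc != coils.nc:
        raise ValueError("coil images and sensitivities must share grid and coil count")
    c = coils.values
    norm2 = np.sum(np.abs(c) ** 2, axis=0)
    inner = np.sum(np.conj(c) * m.values, axis=0)  # c^H m pointwise
    coef = np.where(norm2 > 0, inner / np.where(norm2 > 0, norm2, 1), 0)
    resid = m.values - c * coef[None]
    rss = np.sqrt(np.sum(np.abs(resid) ** 2, axis=0))
    return ProjectionReport(resid, rss)


def coil_image(y: KSpaceData) -> CoilSet:
    """Coil images m = IFFT(y) (centered, unitary, per coil).

    Intended for fully sampled data; on undersampled input the zero-filled
    transform is returned with a warning.
    """
    if not y.pattern.is_full:
        warnings.warn("coil images from undersampled k-space are zero-filled")
    return CoilSet(y.grid, ifft2c(y.values), NATURAL)


def support_mask(
    reference: ComplexImage | CoilSet, threshold: float = 0.1
) -> np.ndarray:
    """Support mask: |rho| > 0 for a ground-truth image, or RSS(coil images)
    above ``threshold`` times its maximum for measured data."""
    if isinstance(reference, ComplexImage):
        return np.abs(reference.values) > 0
    rss = np.sqrt(np.sum(np.abs(reference.values) ** 2, axis=0))
    return rss > threshold * rss.max()


def pole_recovery_score(
    truth: PoleSet, detected: PoleSet, tol: float
) -> Tuple[int, int, int, float]:
    """Greedy nearest matching of detected poles to ground truth.

    A detection matches a truth pole if it lies within ``tol`` (FoV units) and
    has the same sign; each truth pole is consumed at most once.  Returns
    (matches, misses, false_positives, mean location error of the matches).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    remaining = list(range(truth.count))
    matches, errors = 0, []
    for loc, s in sorted(
        zip(detected.locations.tolist(), detected.signs.tolist()), key=tuple
    ):
        best, best_d = None, tol
        for idx in remaining:
            if truth.signs[idx] != s:
                continue
            d = float(np.hypot(loc[0] - truth.locations[idx, 0], loc[1] - truth.locations[idx, 1]))
            if d <= best_d:
                best, best_d = idx, d
        if best is not None:
            remaining.remove(best)
            matches += 1
            errors.append(best_d)
    misses = len(remaining)
    false_positives = detected.count - matches
    mean_err = float(np.mean(errors)) if errors else 0.0
    return matches, misses, false_positives, mean_err
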