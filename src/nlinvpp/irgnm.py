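"""Iteratively regularized Gauss-Newton solver (NLINV) with pole correction.

Solves

    min_{rho, c~}  || y - F~(rho, c~) ||^2 + alpha ||rho||^2 + alpha ||c~||^2

by linearizing F~ around the current iterate and solving each inner ridge
problem with conjugate gradients.  The regularization weight alpha decays
exponentially from 1 to ``alpha_min`` and the full new iterate is regularized
(the update solves (DF^H DF + alpha I) dx = DF^H (y - F(x)) - alpha x), so
early iterations shrink toward the initialization rho = 1, c~ = 0, which
favors real-valued images.  The data is normalized to ||y|| = 100 beforehand
(an empirically good operating point for 2D imaging) and un-scaled at the end.

If pole correction is enabled, after ``detect_step`` Gauss-Newton steps the
natural-domain coils are scanned for a consensus phase pole; if one is found
the image/coil pair is multiplied by the compensating vortex pair and the
remaining steps refine the corrected iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .datamodel import (
    NATURAL,
    PRECONDITIONED,
    CoilSet,
    ComplexImage,
    Grid2D,
    KSpaceData,
    ReconConfig,
)
from .forward import SobolevWeights, adjoint, apply_weighting, derivative, forward_model
from . import polefix

__all__ = [
    "ReconState",
    "normalize_data",
    "alpha_schedule",
    "gauss_newton_step",
    "rss_rescale",
    "nlinv",
]


@dataclass
class ReconState:
    """State of the Gauss-Newton iteration.

    ``rho_ref``/``ctilde_ref`` hold the reference point x0 toward which the
    alpha-penalty shrinks (the IRGNM penalty is alpha * ||x + dx - x0||^2);
    ``None`` means a zero reference for that component.
    """

    k: int
    rho: ComplexImage
    ctilde: CoilSet
    alpha: float
    residual: float = np.inf
    log: List[dict] = dc_field(default_factory=list)
    rho_ref: Optional[ComplexImage] = None
    ctilde_ref: Optional[CoilSet] = None


def normalize_data(y: KSpaceData, target: float = 100.0) -> Tuple[KSpaceData, float]:
    """Scale k-space so its l2 norm equals ``target``; returns (data, scale)."""
    norm = float(np.linalg.norm(y.values))
    if norm == 0:
        raise ValueError("cannot normalize all-zero k-space data")
    scale = target / norm
    return KSpaceData(y.grid, y.values * scale, y.pattern), scale


def alpha_schedule(k: int, cfg: ReconConfig) -> float:
    """alpha(k) = max(alpha_min, q^k): exponential decay from 1 to alpha_min."""
    if k < 0:
        raise ValueError("iteration index must be >= 0")
    return max(cfg.alpha_min, cfg.alpha_decay**k)


def _pack(rho: np.ndarray, ct: np.ndarray) -> np.ndarray:
    return np.concatenate([rho.ravel(), ct.ravel()])


def _unpack(v: np.ndarray, grid: Grid2D, nc: int) -> Tuple[np.ndarray, np.ndarray]:
    n = grid.nx * grid.ny
    return v[:n].reshape(grid.shape), v[n:].reshape((nc, *grid.shape))


def gauss_newton_step(
    state: ReconState,
    y: KSpaceData,
    pattern,
    weights: SobolevWeights,
    cfg: ReconConfig,
) -> ReconState:
    """One Gauss-Newton update: CG solve of the regularized normal equations.

    The update solves (DF^H DF + alpha I) dx = DF^H (y - F(x)) + alpha (x0 - x),
    i.e. it minimizes the linearized data term plus alpha * ||x + dx - x0||^2
    with x0 the initialization, so early (large-alpha) steps shrink toward x0
    rather than toward zero — shrinking the bilinear pair toward zero would
    alternately annihilate image and coils and stall.  The system is Hermitian
    positive definite; CG stops at relative residual ``cfg.cg_tol`` or after
    ``cfg.cg_iters`` iterations.  The step is the exact minimizer of the
    linearized objective, which therefore cannot increase.
    """
    grid, nc = state.rho.grid, state.ctilde.nc
    alpha = state.alpha
    x = (state.rho, state.ctilde)

    r = y.values - forward_model(state.rho, state.ctilde, pattern, weights).values
    g_rho, g_ct = adjoint(x, KSpaceData(grid, r * pattern.mask[None], pattern), pattern, weights)
    ref = _pack(
        state.rho_ref.values if state.rho_ref is not None else np.zeros(grid.shape),
        state.ctilde_ref.values
        if state.ctilde_ref is not None
        else np.zeros((nc, *grid.shape)),
    )
    rhs = _pack(g_rho.values, g_ct.values) + alpha * (
        ref - _pack(state.rho.values, state.ctilde.values)
    )

    def matvec(v: np.ndarray) -> np.ndarray:
        drho, dct = _unpack(v, grid, nc)
        dx = (ComplexImage(grid, drho), CoilSet(grid, dct, PRECONDITIONED))
        dy = derivative(x, dx, pattern, weights)
        arho, act = adjoint(x, dy, pattern, weights)
        return _pack(arho.values, act.values) + alpha * v

    n = rhs.size
    op = LinearOperator((n, n), matvec=matvec, dtype=np.complex128)
    dx_vec, info = cg(op, rhs, rtol=cfg.cg_tol, maxiter=cfg.cg_iters)
    if not np.all(np.isfinite(dx_vec)):
        raise RuntimeError(f"CG produced non-finite values at step {state.k}")

    drho, dct = _unpack(dx_vec, grid, nc)
    rho_new = ComplexImage(grid, state.rho.values + drho)
    ct_new = CoilSet(grid, state.ctilde.values + dct, PRECONDITIONED)
    res = float(
        np.linalg.norm(y.values - forward_model(rho_new, ct_new, pattern, weights).values)
    )
    log = state.log + [
        {"event": "gn_step", "k": state.k, "alpha": alpha, "residual": res, "cg_info": int(info)}
    ]
    return ReconState(
        state.k + 1, rho_new, ct_new, alpha, res, log, state.rho_ref, state.ctilde_ref
    )


def rss_rescale(rho: ComplexImage, coils: CoilSet) -> Tuple[ComplexImage, CoilSet]:
    """Move the coil magnitude into the image: rho * RSS(c), c / RSS(c).

    After rescaling the coils have root-sum-of-squares 1 wherever the RSS was
    nonzero (the ESPIRiT normalization) and the products c_i * rho are
    unchanged.  Where RSS = 0 both outputs are 0.
    """
    coils.require_domain(NATURAL)
    rss = np.sqrt(np.sum(np.abs(coils.values) ** 2, axis=0))
    nz = rss > 0
    rho_out = np.where(nz, rho.values * rss, 0)
    c_out = np.where(nz[None], coils.values / np.where(nz, rss, 1)[None], 0)
    return ComplexImage(rho.grid, rho_out), CoilSet(coils.grid, c_out, NATURAL)


def nlinv(
    y: KSpaceData,
    cfg: Optional[ReconConfig] = None,
    weights: Optional[SobolevWeights] = None,
    init: Optional[Tuple[ComplexImage, CoilSet]] = None,
    rss_normalize: bool = True,
) -> Tuple[ComplexImage, CoilSet, List[dict]]:
    """Joint image/coil reconstruction by regularized nonlinear inversion.

    Parameters
    ----------
    y : measured k-space with its sampling pattern.
    cfg : solver configuration; ``cfg.pole_correction`` enables detection and
        correction after ``cfg.detect_step`` Gauss-Newton steps (repeated every
        later step if ``cfg.detect_every``).
    weights : Sobolev weights; defaults to ``SobolevWeights(y.grid)``.
    init : optional (rho0, ctilde0) starting point; defaults to the standard
        initialization rho = 1, c~ = 0.  The supplied init also serves as the
        reference of the alpha-penalty, as in the standard IRGNM.
    rss_normalize : apply the final RSS rescaling (coils normalized to unit
        root-sum-of-squares, magnitude moved into the image).  Disable to
        inspect the raw coil magnitudes, e.g. for black-hole diagnostics.

    Returns
    -------
    (rho, coils, log): RSS-rescaled image on the original data scale,
    natural-domain coils with unit RSS on the support, and the event log.
    """
    cfg = cfg or ReconConfig()
    weights = weights or SobolevWeights(y.grid)
    grid, nc = y.grid, y.nc
    y_n, scale = normalize_data(y, cfg.data_norm_target)

    if init is not None:
        rho0, ct0 = init
        ct0.require_domain(PRECONDITIONED)
    else:
        rho0 = ComplexImage(grid, np.ones(grid.shape, dtype=np.complex128))
        ct0 = CoilSet(grid, np.zeros((nc, *grid.shape), dtype=np.complex128), PRECONDITIONED)
    state = ReconState(
        0, rho0.copy(), ct0.copy(), 1.0, rho_ref=rho0.copy(), ctilde_ref=ct0.copy()
    )

    for k in range(cfg.newton_steps):
        state.alpha = alpha_schedule(k, cfg)
        state = gauss_newton_step(state, y_n, y.pattern, weights, cfg)
        run_detect = cfg.pole_correction and (
            (k + 1) == cfg.detect_step or (cfg.detect_every and (k + 1) > cfg.detect_step)
        )
        if run_detect:
            c_nat = apply_weighting(state.ctilde, weights)
            pm = polefix.coil_winding_maps(c_nat, cfg.detect_params)
            poles = polefix.detect_poles(pm, cfg.detect_params)
            state.log.append(
                {"event": "pole_detection", "k": k + 1, "count": poles.count,
                 "locations": poles.locations.tolist(), "signs": poles.signs.tolist()}
            )
            if poles.count > 0:
                theta = polefix.build_correction(poles, grid, state.rho)
                state.rho, state.ctilde = polefix.apply_correction(
                    state.rho, state.ctilde, theta, weights
                )
                # the correction is a gauge change; transport the penalty
                # reference through it, or the alpha-term would pull the
                # refinement steps back into the just-removed pole gauge
                if state.rho_ref is not None or state.ctilde_ref is not None:
                    rref = state.rho_ref or ComplexImage(grid, np.zeros(grid.shape))
                    cref = state.ctilde_ref or CoilSet(
                        grid, np.zeros((nc, *grid.shape)), PRECONDITIONED
                    )
                    state.rho_ref, state.ctilde_ref = polefix.apply_correction(
                        rref, cref, theta, weights
                    )
                state.log.append({"event": "pole_correction", "k": k + 1, "count": poles.count})

    coils = apply_weighting(state.ctilde, weights)
    if rss_normalize:
        rho, coils = rss_rescale(state.rho, coils)
        rho = ComplexImage(grid, rho.values / scale)  # coils are scale-free after RSS
    else:
        rho = ComplexImage(grid, state.rho.values / scale)
    return rho, coils, state.log
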