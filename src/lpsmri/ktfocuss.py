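"""k-t FOCUSS baseline reconstruction.

Iteratively reweighted least squares in the spatio-temporal-frequency
(x-f) domain: starting from a baseline x-f image rho_0 built from the
fully sampled low-frequency (center) k-space lines, each outer
iteration solves the weighted, Tikhonov-regularized data-fit problem

    min_q  || E(rho_0 + W q) - y ||_2^2 + lambda ||q||_2^2

by conjugate gradients on the normal equations, sets
rho = rho_0 + W q, and updates the weights to W = |rho|^p. With a
single outer iteration and uniform weights this reduces to the
covariance-regularized least-squares solution that the training-based
k-t linear methods compute. E maps x-f to sampled (k,t)-space:
E = mask o F_xy o F_t^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DynamicImage
from .kspace import KTData, fft2c, ifft2c

__all__ = ["KTFocussConfig", "ktfocuss_reconstruct"]


@dataclass
class KTFocussConfig:
    inner_iterations: int = 40
    outer_iterations: int = 2
    power: float = 0.5  # weighting matrix power factor p
    n_low_freq: int | None = None  # defaults to mask.n_center
    lam: float = 1e-6  # relative Lagrangian multiplier (scaled by mean |W|^2)
    weight_floor: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 < self.power <= 1):
            raise ValueError("power factor must be in (0, 1]")
        if self.inner_iterations < 1 or self.outer_iterations < 1:
            raise ValueError("iteration counts must be >= 1")


def _xf(image: np.ndarray) -> np.ndarray:
    return np.fft.fft(image, axis=-1, norm="ortho")


def _ixf(rho: np.ndarray) -> np.ndarray:
    return np.fft.ifft(rho, axis=-1, norm="ortho")


def _e_forward(rho: np.ndarray, lines: np.ndarray) -> np.ndarray:
    return fft2c(_ixf(rho)) * lines[None, :, :]


def _e_adjoint(y: np.ndarray, lines: np.ndarray) -> np.ndarray:
    return _xf(ifft2c(y * lines[None, :, :]))


def ktfocuss_reconstruct(
    y: KTData, config: KTFocussConfig | None = None, initial_weights: np.ndarray | None = None
) -> DynamicImage:
    """Reconstruct an x-y-t image series from undersampled (k,t)-space data.

    ``initial_weights`` overrides the |rho_0|^p initialization (uniform
    weights reproduce the non-iterated, training-data-regularized
    solution exactly).
    """
    cfg = config or KTFocussConfig()
    lines = y.mask.lines
    data = y.samples
    nx, ny, nt = data.shape

    scale = float(np.abs(data).max())
    if scale == 0:
        return DynamicImage(np.zeros((nx, ny, nt), dtype=np.complex128))
    data = data / scale

    # baseline: x-f transform of the center-line (low-frequency) recon
    n_low = cfg.n_low_freq if cfg.n_low_freq is not None else y.mask.n_center
    center = np.zeros(ny, dtype=bool)
    c = ny // 2
    center[c - n_low // 2 : c - n_low // 2 + n_low] = True
    low_lines = lines & center[:, None]
    rho0 = _xf(ifft2c(data * low_lines[None, :, :]))

    resid = data - _e_forward(rho0, lines)
    if initial_weights is not None:
        w = np.asarray(initial_weights, dtype=float)
    else:
        w = np.abs(rho0) ** cfg.power
    rho = rho0.copy()
    drho = np.zeros_like(rho0)

    for _ in range(cfg.outer_iterations):
        w = np.maximum(w, cfg.weight_floor)
        lam = cfg.lam * float(np.mean(w**2))

        def normal_op(q: np.ndarray) -> np.ndarray:
            return w * _e_adjoint(_e_forward(w * q, lines), lines) + lam * q

        rhs = w * _e_adjoint(resid, lines)
        # warm start from the previous outer solution so reweighting can
        # only refine it (a cold restart with support-locked weights
        # cannot re-create corrections where the estimate is zero)
        q = drho / w
        r = rhs - normal_op(q)
        p = r.copy()
        rs_old = np.vdot(r, r).real
        for _ in range(cfg.inner_iterations):
            if rs_old <= 1e-30:
                break
            ap = normal_op(p)
            alpha = rs_old / np.vdot(p, ap).real
            q = q + alpha * p
            r = r - alpha * ap
            rs_new = np.vdot(r, r).real
            p = r + (rs_new / rs_old) * p
            rs_old = rs_new
        drho = w * q
        rho = rho0 + drho
        if not np.all(np.isfinite(rho.real)):
            raise FloatingPointError("k-t FOCUSS iterate diverged")
        w = np.abs(rho) ** cfg.power

    return DynamicImage(_ixf(rho) * scale)
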