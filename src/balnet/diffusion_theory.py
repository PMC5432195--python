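"""Semi-analytic diffusion along the attractor from single-network noise.

Near its balanced fixed point a single balanced subnetwork behaves as a
linear stochastic system

    d(dm)/dt = B1 dm + B2 dE + xi,

with B1 the 2x2 response to mean-activity perturbations, B2 the response to
feedforward-input perturbations, and xi an effective (chaotic) noise with
stationary covariance C_xi(dt).  C_xi is not known analytically; it is
inferred from the measured activity covariance C_m of the single network by
inverting the linear relation between the two.  Writing the coupled
four-population dynamics as dX/dt = lambda X + v0.xi along the slow
direction then yields the autocovariance of X,

    C_X(t) = -(1/2 lambda) int e^(lambda |t'|) v0^T C~_xi(t - t') v0 dt',

with C~_xi the block-diagonal 4x4 extension of C_xi, and finally

    G_theory(dt) = 2 (C_X(0) - C_X(dt)),

a zero-fitting-parameter prediction of the measured diffusion curve.

All rates here are physical (1/ms) and lags are in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .params import NetworkParams
from .meanfield import (
    FixedPointError,
    SaturationError,
    _newton,
    _phi,
    gaussian_tail,
    _CLIP,
)

__all__ = [
    "NoiseModel",
    "TheoryG",
    "single_fixed_point",
    "single_network_linearization",
    "noise_correlation_from_cm",
    "extend_block_diagonal",
    "theory_cx",
]


# ---------------------------------------------------------------------------
# Single-subnetwork mean field

def _single_stats(m2, params: NetworkParams, E_in: float, K: float):
    """Mean inputs and variances of an isolated (E, I) balanced network."""
    mE, mI = m2
    sqrtK = math.sqrt(K)
    u = np.array([
        sqrtK * (mE - params.J_E * mI + E_in) - params.T[0],
        sqrtK * (mE - params.J_I * mI) - params.T[1],
    ])
    alpha = np.array([mE + params.J_E**2 * mI, mE + params.J_I**2 * mI])
    return u, alpha


def _single_f(m2, params, E_in, K):
    """2x2 partials f_ij = dH(-u_i/sqrt(alpha_i))/dm_j."""
    u, alpha = _single_stats(m2, params, E_in, K)
    z = -u / np.sqrt(alpha)
    CU = np.array([[1.0, -params.J_E], [1.0, -params.J_I]])
    CA = np.array([[1.0, params.J_E**2], [1.0, params.J_I**2]])
    sqrtK = math.sqrt(K)
    dz = (-sqrtK * CU) / np.sqrt(alpha)[:, None] + (u / (2 * alpha**1.5))[:, None] * CA
    return -_phi(z)[:, None] * dz


def single_fixed_point(params: NetworkParams, E_in: float,
                       K: Optional[float] = None) -> np.ndarray:
    """Balanced fixed point (m_E, m_I) of one subnetwork at drive E_in."""
    K = params.K if K is None else K

    def residual(m2):
        u, alpha = _single_stats(m2, params, E_in, K)
        return m2 - gaussian_tail(-u / np.sqrt(alpha))

    def jac(m2):
        return np.eye(2) - _single_f(m2, params, E_in, K)

    # balance-limit seed: mE = JI*Ein/(JE-JI), mI = Ein/(JE-JI)
    dJ = params.J_E - params.J_I
    guess = np.clip(np.array([params.J_I * E_in / dJ, E_in / dJ]), 1e-4, 1 - 1e-4)
    m2, _ = _newton(residual, jac, guess)
    if np.any(m2 <= 10 * _CLIP) or np.any(m2 >= 1 - 10 * _CLIP):
        raise SaturationError(f"single-network fixed point saturates: {m2}")
    return m2


def single_network_linearization(
    params: NetworkParams, E_in: float, K: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Response matrices (B1, B2) of one subnetwork at its fixed point.

    B1 (1/ms) is the Jacobian of the single-network mean-field dynamics;
    B2 (1/ms) holds the partials with respect to perturbations of the
    feedforward input channel of each population (the inhibitory channel
    carries no external drive in the model but its response is defined the
    same way).  Also returns the fixed point itself.
    """
    K = params.K if K is None else K
    m2 = single_fixed_point(params, E_in, K)
    f = _single_f(m2, params, E_in, K)
    tau = np.array([params.tau_E, params.tau_I])
    B1 = (f - np.eye(2)) / tau[:, None]
    u, alpha = _single_stats(m2, params, E_in, K)
    z = -u / np.sqrt(alpha)
    # dH(-u/sqrt(alpha))/dE_ch = phi(z) sqrt(K)/sqrt(alpha) on the diagonal
    gain = _phi(z) * math.sqrt(K) / np.sqrt(alpha)
    B2 = np.diag(gain / tau)
    return B1, B2, m2


# ---------------------------------------------------------------------------
# Noise covariance from the measured activity covariance

@dataclass
class NoiseModel:
    """Effective-noise covariance of the linearized single network."""

    lags: np.ndarray             # ms, uniform, symmetric about 0
    C_xi: np.ndarray             # (nlag, 2, 2)
    B1: np.ndarray
    B2: Optional[np.ndarray] = None


def noise_correlation_from_cm(
    lags: np.ndarray,
    Cm: np.ndarray,
    B1: np.ndarray,
    params: Optional[NetworkParams] = None,
    smooth_ms: Optional[float] = None,
) -> NoiseModel:
    """Invert the linear-response relation to obtain C_xi from C_m.

    For d(dm)/dt = B1 dm + xi with C_m(t) = <dm(s+t) dm(s)^T>,

        C_xi(t) = -C_m'' - C_m' B1^T + B1 C_m' + B1 C_m B1^T.

    ``lags`` must be a uniform grid (spacing <= tau_E/5) covering negative
    and positive lags; the curve is smoothed with a Gaussian kernel
    (width tau_E/5 by default) before the central finite differences,
    because second derivatives of empirical covariances are otherwise
    dominated by sampling noise.  Pass ``smooth_ms=0`` to disable.
    """
    lags = np.asarray(lags, float)
    Cm = np.asarray(Cm, float)
    h = lags[1] - lags[0]
    if not np.allclose(np.diff(lags), h, rtol=1e-6):
        raise ValueError("lag grid must be uniform")
    tau_ref = params.tau_E if params is not None else 10.0
    if h > tau_ref / 5 + 1e-9:
        raise ValueError(f"lag spacing {h} ms too coarse (need <= tau_E/5)")
    if smooth_ms is None:
        smooth_ms = tau_ref / 5.0
    C = Cm.copy()
    if smooth_ms > 0:
        C = gaussian_filter1d(C, sigma=smooth_ms / h, axis=0, mode="nearest")
    d1 = np.gradient(C, h, axis=0)
    d2 = np.gradient(d1, h, axis=0)
    B1T = B1.T
    C_xi = -d2 - d1 @ B1T + np.einsum("ab,tbc->tac", B1, d1) \
        + np.einsum("ab,tbc,cd->tad", B1, C, B1T)
    return NoiseModel(lags=lags, C_xi=C_xi, B1=B1)


def extend_block_diagonal(C_xi: np.ndarray) -> np.ndarray:
    """Block-diagonal 4x4 extension of the 2x2 noise covariance.

    The two subnetworks' chaotic noises are independent; each block is the
    single-network C_xi.
    """
    n = C_xi.shape[0]
    out = np.zeros((n, 4, 4))
    out[:, :2, :2] = C_xi
    out[:, 2:, 2:] = C_xi
    return out


# ---------------------------------------------------------------------------
# Autocovariance of X and the predicted diffusion curve

@dataclass
class TheoryG:
    """Theoretical autocovariance of X and diffusion curve."""

    lags: np.ndarray             # ms (nonnegative output grid)
    C_X: np.ndarray
    G: np.ndarray

    @property
    def G_inf(self) -> float:
        return 2.0 * self.C_X[0]


def theory_cx(
    lags: np.ndarray,
    C_xi_4: np.ndarray,
    v0: np.ndarray,
    lam_per_ms: float,
    out_lags: Optional[np.ndarray] = None,
) -> TheoryG:
    """Convolve the noise covariance with the slow mode's Green function.

    C_X(t) = -(1/2 lambda) int e^(lambda |t'|) c(t - t') dt' with
    c(s) = v0^T C~_xi(s) v0, evaluated by trapezoidal quadrature on the
    measured support (c taken as zero beyond it); then
    G(dt) = 2 (C_X(0) - C_X(dt)).  Requires lambda < 0.
    """
    if lam_per_ms >= 0:
        raise ValueError("the slow eigenvalue must be negative (stable mode)")
    lags = np.asarray(lags, float)
    v0 = np.asarray(v0, float)
    c = np.einsum("i,tij,j->t", v0, np.asarray(C_xi_4, float), v0)
    h = lags[1] - lags[0]
    if out_lags is None:
        out_lags = lags[lags >= 0]
    out_lags = np.asarray(out_lags, float)
    lam = lam_per_ms
    C_X = np.empty(len(out_lags))
    for k, t in enumerate(out_lags):
        kern = np.exp(lam * np.abs(t - lags))   # e^(lam |t'|) at t' = t - lags
        C_X[k] = -np.trapezoid(kern * c, dx=h) / (2.0 * lam)
    # C_X(0) for the G curve
    kern0 = np.exp(lam * np.abs(0.0 - lags))
    C_X0 = -np.trapezoid(kern0 * c, dx=h) / (2.0 * lam)
    G = 2.0 * (C_X0 - C_X)
    return TheoryG(lags=out_lags, C_X=C_X, G=G)
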