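"""Mean-field theory of the coupled balanced networks.

In the limit N -> infinity the four population-averaged activities m_i obey

    tau_i dm_i/dt = -m_i + H(-u_i / sqrt(alpha_i)),

where H is the Gaussian tail function, u_i the population-mean input and
alpha_i its variance across neurons.  Steady states satisfy
m_i = H(-u_i/sqrt(alpha_i)); for K -> infinity the steady-state equations
become linear and, when the cross-inhibition is tuned to J~ = J_E - J_I,
singular -- yielding a line of balanced states.  At finite K the line is
only approximate: tuning J~ places a zero eigenvalue of the Jacobian at the
symmetric fixed point, and the eigenvalue closest to zero (lambda) sets the
memory decay time.

Time is nondimensionalized by tau_E in the Jacobian; physical rates are
obtained by dividing by tau_E (ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from .params import NetworkParams

__all__ = [
    "MeanFieldPoint",
    "JacobianInfo",
    "ProjectionBasis",
    "gaussian_tail",
    "gaussian_tail_inv",
    "coupling_matrix",
    "variance_matrix",
    "input_stats",
    "mf_rhs",
    "line_kinf",
    "solve_fixed_point",
    "jacobian",
    "eigenvalues_closed_form",
    "dm1_dm3",
    "f14_singular",
    "tune_jtilde",
    "lambda_vs_jtilde",
    "tune_to_rate",
    "projection_basis",
    "integrate_mf",
    "nullcline",
]

_CLIP = 1e-12  # activities clamped to [_CLIP, 1-_CLIP] before H^-1


# ---------------------------------------------------------------------------
# Gaussian tail function

def gaussian_tail(x):
    """Gaussian tail H(x) = int_x^inf exp(-z^2/2)/sqrt(2 pi) dz."""
    return ndtr(-np.asarray(x, dtype=float))


def gaussian_tail_inv(p):
    """Functional inverse of :func:`gaussian_tail`; requires p in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("gaussian_tail_inv requires arguments strictly inside (0, 1)")
    return -ndtri(p)


def _phi(x):
    """Standard normal density."""
    return np.exp(-0.5 * np.asarray(x, dtype=float) ** 2) / math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Structure matrices

def coupling_matrix(params: NetworkParams, J_tilde: Optional[float] = None) -> np.ndarray:
    """Coefficient matrix of the balance brackets u_i/sqrt(K) + T_i/sqrt(K) - E0_i.

    Row i gives the linear combination of m entering the mean input of
    population i; this is also the coefficient matrix of the K -> infinity
    steady-state system.
    """
    jt = params.J_tilde if J_tilde is None else J_tilde
    JE, JI = params.J_E, params.J_I
    return np.array(
        [
            [1.0, -JE, 0.0, -jt],
            [1.0, -JI, 0.0, 0.0],
            [0.0, -jt, 1.0, -JE],
            [0.0, 0.0, 1.0, -JI],
        ]
    )


def variance_matrix(params: NetworkParams, cross_mode: Optional[str] = None) -> np.ndarray:
    """Coefficients of the input variances alpha_i as functions of m.

    In all-to-all cross mode the weak cross synapses contribute only at
    higher order in K/N and are absent; in sparse cross mode the strong
    random cross synapses add J~^2 times the opposing inhibitory activity
    to the excitatory rows.
    """
    mode = params.cross_mode if cross_mode is None else cross_mode
    JE2, JI2 = params.J_E**2, params.J_I**2
    jt2 = params.J_tilde**2
    if mode == "all_to_all":
        return np.array(
            [
                [1.0, JE2, 0.0, 0.0],
                [1.0, JI2, 0.0, 0.0],
                [0.0, 0.0, 1.0, JE2],
                [0.0, 0.0, 1.0, JI2],
            ]
        )
    if mode == "sparse":
        return np.array(
            [
                [1.0, JE2, 0.0, jt2],
                [1.0, JI2, 0.0, 0.0],
                [0.0, jt2, 1.0, JE2],
                [0.0, 0.0, 1.0, JI2],
            ]
        )
    raise ValueError(f"unknown cross_mode {mode!r}")


def input_stats(
    m,
    params: NetworkParams,
    K: Optional[float] = None,
    cross_mode: Optional[str] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Population-mean inputs u and input variances alpha at activities m.

    ``u_i = sqrt(K) * (sum_j C_ij m_j + E0_i) - T_i`` with C the coupling
    matrix; ``alpha_i`` is linear in m with coefficients from
    :func:`variance_matrix`.
    """
    m = np.asarray(m, dtype=float)
    K = params.K if K is None else K
    if not np.isfinite(K):
        raise ValueError("input_stats requires finite K (u diverges as sqrt(K))")
    bracket = coupling_matrix(params) @ m + np.asarray(params.E0_pop)
    u = math.sqrt(K) * bracket - np.asarray(params.T, dtype=float)
    alpha = variance_matrix(params, cross_mode) @ m
    return u, alpha


# ---------------------------------------------------------------------------
# Mean-field dynamics

@dataclass(frozen=True)
class MeanFieldPoint:
    """Mean activities with their input means and variances."""

    m: np.ndarray
    u: np.ndarray
    alpha: np.ndarray
    residual: float = 0.0
    K: float = np.inf


def _transfer(m, params, K, cross_mode=None):
    """H(-u_i/sqrt(alpha_i)) evaluated at activities m."""
    u, alpha = input_stats(m, params, K, cross_mode)
    if np.any(alpha <= 0.0):
        if np.any((alpha <= 0.0) & (u == 0.0)):
            raise FloatingPointError("degenerate input: alpha = 0 with u = 0")
        # alpha -> 0 with u != 0: the transfer saturates at a step
        return np.where(u > 0, 1.0, 0.0), u, np.maximum(alpha, 0.0)
    return gaussian_tail(-u / np.sqrt(alpha)), u, alpha


def mf_rhs(m, params: NetworkParams, K: Optional[float] = None) -> np.ndarray:
    """Right-hand side dm/dt (1/ms) of the population dynamics."""
    h, _, _ = _transfer(np.asarray(m, float), params, params.K if K is None else K)
    return (h - np.asarray(m, float)) / np.asarray(params.tau_pop)


def line_kinf(x, params: NetworkParams) -> np.ndarray:
    """Point on the K -> infinity line of balanced states at position x.

    Requires the singular tuning J~ = J_E - J_I; valid for
    0 < x < J_I*E0/(J_E - J_I).
    """
    if not math.isclose(params.J_tilde, params.J_E - params.J_I, rel_tol=1e-12, abs_tol=1e-12):
        raise ValueError("the K->infinity line exists only for J~ = J_E - J_I")
    if not (0.0 < x < params.x_max):
        raise ValueError(f"x={x} outside the open validity interval (0, {params.x_max})")
    JI, E0, dJ = params.J_I, params.E0, params.J_E - params.J_I
    return np.array([x, x / JI, -x + JI * E0 / dJ, -x / JI + E0 / dJ])


# ---------------------------------------------------------------------------
# f-matrix and Jacobian

def f_matrix(m, params: NetworkParams, K: Optional[float] = None) -> np.ndarray:
    """Partial derivatives f_ij = d H(-u_i/sqrt(alpha_i)) / d m_j."""
    m = np.asarray(m, dtype=float)
    K = params.K if K is None else K
    u, alpha = input_stats(m, params, K)
    if np.any(alpha <= 0.0):
        raise FloatingPointError("derivative blow-up: alpha <= 0 (activities on the boundary)")
    z = -u / np.sqrt(alpha)
    CU = coupling_matrix(params)
    CA = variance_matrix(params)
    sqrtK = math.sqrt(K)
    # dz_i/dm_j = -sqrtK*CU_ij/sqrt(alpha_i) + u_i*CA_ij/(2 alpha_i^{3/2})
    dz = (-sqrtK * CU) / np.sqrt(alpha)[:, None] + (u / (2.0 * alpha**1.5))[:, None] * CA
    return -_phi(z)[:, None] * dz


@dataclass(frozen=True)
class JacobianInfo:
    """f-matrix, Jacobian (time in units of tau_E) and its spectrum."""

    f: np.ndarray
    A: np.ndarray
    eigenvalues: np.ndarray   # all four, numerically computed
    lambda0: complex          # eigenvalue with smallest |real part|
    tau: float                # tau_I / tau_E


def _assemble_A(f: np.ndarray, tau: float) -> np.ndarray:
    A = f - np.eye(4)
    A[1, :] /= tau
    A[3, :] /= tau
    return A


def _sorted_by_slowness(eigs: np.ndarray) -> np.ndarray:
    """Sort eigenvalues by |real part| (ties broken by |imag|)."""
    order = np.lexsort((np.abs(eigs.imag), np.abs(eigs.real)))
    return eigs[order]


def jacobian(point, params: NetworkParams, K: Optional[float] = None) -> JacobianInfo:
    """Jacobian of the mean-field dynamics at the given point.

    ``point`` may be a :class:`MeanFieldPoint` or a bare 4-vector of
    activities.  Time is measured in units of tau_E: the inhibitory rows
    are divided by tau = tau_I/tau_E.
    """
    m = point.m if isinstance(point, MeanFieldPoint) else np.asarray(point, float)
    K = params.K if K is None else K
    f = f_matrix(m, params, K)
    A = _assemble_A(f, params.tau)
    eigs = _sorted_by_slowness(np.linalg.eigvals(A))
    return JacobianInfo(f=f, A=A, eigenvalues=eigs, lambda0=eigs[0], tau=params.tau)


# physical-rate helper is defined as a free function so JacobianInfo stays a
# plain container
def lambda_per_ms(info: JacobianInfo, params: NetworkParams) -> complex:
    """Convert the slow eigenvalue from 1/tau_E units to 1/ms."""
    return info.lambda0 / params.tau_E


def eigenvalues_closed_form(f: np.ndarray, tau: float) -> np.ndarray:
    """Closed-form eigenvalues at a symmetric fixed point.

    Valid when f obeys the symmetric-point identities (f11=f33 etc.); the
    four sign combinations (s1, s2) of the nested +/- are enumerated in the
    order (+,+), (+,-), (-,+), (-,-).  Complex results are kept complex.
    """
    a = f[0, 0] - 1.0
    b = (f[1, 1] - 1.0) / tau
    f12, f21, f14 = f[0, 1], f[1, 0], f[0, 3]
    out = []
    for s1 in (+1.0, -1.0):
        for s2 in (+1.0, -1.0):
            rad = (a - b) ** 2 + (4.0 / tau) * f12 * f21 + s2 * (4.0 / tau) * f14 * f21
            out.append(0.5 * (a + b) + s1 * 0.5 * np.sqrt(complex(rad)))
    return np.array(out)


def dm1_dm3(f: np.ndarray) -> float:
    """Slope of the m1-nullcline, dm1/dm3 at the symmetric point.

    Obtained by slaving m2 and m4 to their steady states in the linearized
    equations; equals -1 exactly when the Jacobian has a zero eigenvalue.
    """
    f11, f12, f21, f22, f14 = f[0, 0], f[0, 1], f[1, 0], f[1, 1], f[0, 3]
    return f14 * f21 / (f11 * f22 - f12 * f21 + 1.0 - (f11 + f22))


def f14_singular(f: np.ndarray) -> float:
    """Value of f14 that forces the slope -1 (hence a zero eigenvalue)."""
    f11, f12, f21, f22 = f[0, 0], f[0, 1], f[1, 0], f[1, 1]
    return (f12 * f21 - 1.0 + f11 + f22 - f11 * f22) / f21


# ---------------------------------------------------------------------------
# Fixed points

class FixedPointError(RuntimeError):
    pass


class SaturationError(FixedPointError):
    pass


def _newton(res_fun, jac_fun, x0, tol=1e-13, maxiter=200):
    """Damped Newton iteration keeping iterates strictly inside (0, 1)."""
    x = np.array(x0, dtype=float)
    for _ in range(maxiter):
        r = res_fun(x)
        if np.max(np.abs(r)) < tol:
            return x, float(np.max(np.abs(r)))
        try:
            step = np.linalg.solve(jac_fun(x), -r)
        except np.linalg.LinAlgError:
            raise FixedPointError("singular Newton Jacobian")
        lam = 1.0
        r0 = np.max(np.abs(r))
        while lam > 1e-8:
            xn = x + lam * step
            if np.all(xn > _CLIP) and np.all(xn < 1.0 - _CLIP):
                rn = res_fun(xn)
                if np.max(np.abs(rn)) < r0 or lam <= 2e-8:
                    x = xn
                    break
            lam *= 0.5
        else:
            raise FixedPointError("Newton damping failed")
    r = res_fun(x)
    if np.max(np.abs(r)) < 1e-9:
        return x, float(np.max(np.abs(r)))
    raise FixedPointError(f"no convergence; residual {np.max(np.abs(r)):.3e}")


def solve_fixed_point(
    params: NetworkParams,
    K: Optional[float] = None,
    guess=None,
    symmetric: bool = True,
) -> MeanFieldPoint:
    """Solve the finite-K steady-state equations m_i = H(-u_i/sqrt(alpha_i)).

    The symmetric solution (m1=m3, m2=m4), which always exists, is found in
    the reduced two-variable subspace by default; pass ``symmetric=False``
    to run the full four-dimensional Newton iteration from ``guess``.
    """
    K = params.K if K is None else K
    if not np.isfinite(K):
        raise ValueError("solve_fixed_point requires finite K; use line_kinf for the limit")

    def residual4(m):
        h, _, _ = _transfer(m, params, K)
        return m - h

    def jac4(m):
        return np.eye(4) - f_matrix(m, params, K)

    if guess is None:
        x = params.x_symmetric
        guess = np.array([x, x / params.J_I, x, x / params.J_I])
    else:
        guess = np.asarray(guess, dtype=float)

    if symmetric:
        def residual2(ab):
            m = np.array([ab[0], ab[1], ab[0], ab[1]])
            return residual4(m)[:2]

        def jac2(ab):
            m = np.array([ab[0], ab[1], ab[0], ab[1]])
            f = f_matrix(m, params, K)
            J = np.eye(4) - f
            # collapse columns: dm3 = dm1, dm4 = dm2
            return np.array(
                [
                    [J[0, 0] + J[0, 2], J[0, 1] + J[0, 3]],
                    [J[1, 0] + J[1, 2], J[1, 1] + J[1, 3]],
                ]
            )

        ab, _ = _newton(residual2, jac2, guess[:2])
        m = np.array([ab[0], ab[1], ab[0], ab[1]])
    else:
        m, _ = _newton(residual4, jac4, guess)

    res = float(np.max(np.abs(residual4(m))))
    if np.any(m <= 10 * _CLIP) or np.any(m >= 1.0 - 10 * _CLIP):
        raise SaturationError(f"fixed point saturates at the boundary: m={m}")
    u, alpha = input_stats(m, params, K)
    return MeanFieldPoint(m=m, u=u, alpha=alpha, residual=res, K=K)


# ---------------------------------------------------------------------------
# Tuning

class TuningError(RuntimeError):
    pass


def _lambda_at(params: NetworkParams, K: float, J_tilde: float) -> float:
    p = params.with_(J_tilde=float(J_tilde))
    fp = solve_fixed_point(p, K)
    info = jacobian(fp, p, K)
    return float(info.lambda0.real)


def tune_jtilde(params: NetworkParams, K: Optional[float] = None,
                bracket: Optional[Tuple[float, float]] = None) -> float:
    """Cross-inhibition J~* at which the slow eigenvalue vanishes.

    For K = infinity this is exactly J_E - J_I (the singular tuning of the
    linear steady-state system).  For finite K the zero of
    Re(lambda)(J~) at the symmetric fixed point is bracketed in
    [J_E - J_I, J_E - J_I + 1] and found with Brent's method.
    """
    K = params.K if K is None else K
    dJ = params.J_E - params.J_I
    if not np.isfinite(K):
        return dJ
    lo, hi = bracket if bracket is not None else (dJ, dJ + 1.0)
    flo, fhi = _lambda_at(params, K, lo), _lambda_at(params, K, hi)
    if flo * fhi > 0:
        raise TuningError(
            f"no sign change of lambda on J~ in [{lo}, {hi}]: "
            f"lambda({lo})={flo:.3e}, lambda({hi})={fhi:.3e}"
        )
    return float(optimize.brentq(lambda j: _lambda_at(params, K, j), lo, hi, xtol=1e-12))


def lambda_vs_jtilde(params: NetworkParams, K: Optional[float], grid: Sequence[float]):
    """Slow eigenvalue (and next-slowest real part) along a grid of J~.

    Returns arrays (J~, lambda0_real, lambda_next_real) in 1/tau_E units.
    """
    K = params.K if K is None else K
    lam0, lam1 = [], []
    for jt in grid:
        p = params.with_(J_tilde=float(jt))
        fp = solve_fixed_point(p, K)
        info = jacobian(fp, p, K)
        lam0.append(info.eigenvalues[0].real)
        lam1.append(info.eigenvalues[1].real)
    return np.asarray(grid, float), np.array(lam0), np.array(lam1)


def tune_to_rate(params: NetworkParams, K: Optional[float], lambda_target_per_ms: float) -> float:
    """J~ giving a prescribed (negative) slow rate lambda (1/ms).

    Used to set a finite memory decay time deliberately, e.g. for
    simulations where the Ornstein-Uhlenbeck regime must be reachable.
    """
    if lambda_target_per_ms >= 0:
        raise ValueError("the target rate must be negative (stable slow mode)")
    K = params.K if K is None else K
    target = lambda_target_per_ms * params.tau_E  # 1/tau_E units
    jstar = tune_jtilde(params, K)
    lo = params.J_E - params.J_I

    def g(j):
        return _lambda_at(params, K, j) - target

    if g(lo) > 0:
        raise TuningError("target rate unreachable: lambda at J~=J_E-J_I is above target")
    return float(optimize.brentq(g, lo, jstar, xtol=1e-12))


# ---------------------------------------------------------------------------
# Projection basis

@dataclass(frozen=True)
class ProjectionBasis:
    """Slow-mode basis for the scalar attractor coordinate X = v0.(m - m0)."""

    m0: np.ndarray
    v0: np.ndarray
    r0: np.ndarray
    lam: float            # slow eigenvalue, 1/tau_E units
    tau_E: float
    left_rest: Optional[np.ndarray] = None   # remaining left eigenvectors (rows)

    @property
    def lam_per_ms(self) -> float:
        return self.lam / self.tau_E


def projection_basis(params: NetworkParams, K: Optional[float] = None) -> ProjectionBasis:
    """Left/right slow eigenvectors normalized to the line parametrization.

    The right eigenvector is rescaled so its first component is 1 (the
    K -> infinity null direction is (1, 1/J_I, -1, -1/J_I)); the left
    eigenvector is scaled so v0 . r0 = 1, which makes X along the exact
    line equal to the line parameter offset x - x_sym.
    """
    K = params.K if K is None else K
    if not np.isfinite(K):
        return _projection_basis_kinf(params)
    fp = solve_fixed_point(params, K)
    info = jacobian(fp, params, K)
    eigs, R = np.linalg.eig(info.A)
    order = np.lexsort((np.abs(eigs.imag), np.abs(eigs.real)))
    i0 = order[0]
    if np.abs(eigs[i0].imag) > 1e-8:
        raise FloatingPointError("slow eigenvalue is part of a complex pair; no real basis")
    r0 = R[:, i0].real
    r0 = r0 / r0[0]
    # left eigenvectors: rows of inv(R); guard against degeneracy via solve
    L = np.linalg.inv(R)
    v0 = L[i0, :].real
    v0 = v0 / (v0 @ r0)
    left_rest = np.delete(L, i0, axis=0).real
    return ProjectionBasis(
        m0=fp.m, v0=v0, r0=r0, lam=float(eigs[i0].real), tau_E=params.tau_E,
        left_rest=left_rest,
    )


def _projection_basis_kinf(params: NetworkParams) -> ProjectionBasis:
    """K -> infinity basis from the singular linear steady-state system.

    The right null direction follows from the coupling matrix; the left
    eigenvector is the left null vector of the coupling matrix, reweighted
    by the asymptotic gain tau_i * sqrt(alpha_i)/phi_i of each population
    (from the dominant sqrt(K) part of the Jacobian).
    """
    if not math.isclose(params.J_tilde, params.J_E - params.J_I, rel_tol=1e-12):
        raise ValueError("the K->infinity basis requires the singular tuning J~ = J_E - J_I")
    JI = params.J_I
    r0 = np.array([1.0, 1.0 / JI, -1.0, -1.0 / JI])
    m0 = line_kinf(params.x_symmetric, params)
    CU = coupling_matrix(params)
    # left null vector of the coupling matrix
    _, _, Vh = np.linalg.svd(CU.T)
    w = Vh[-1]
    z = gaussian_tail_inv(m0)            # -u_i/sqrt(alpha_i) at the limit point
    alpha = variance_matrix(params) @ m0
    tau_rel = np.asarray(params.tau_pop) / params.tau_E
    v0 = w * tau_rel * np.sqrt(alpha) / _phi(z)
    v0 = v0 / (v0 @ r0)
    return ProjectionBasis(m0=m0, v0=v0, r0=r0, lam=0.0, tau_E=params.tau_E)


# ---------------------------------------------------------------------------
# Noisy mean-field integrator

class IntegrationError(RuntimeError):
    pass


def integrate_mf(
    m_init,
    params: NetworkParams,
    duration: float,
    dt: float = 0.1,
    noise_sigma: float = 0.0,
    K: Optional[float] = None,
    seed: int = 0,
    record_every: int = 1,
):
    """Euler-Maruyama integration of the population dynamics.

    Independent white noise xi_i with <xi_i(t) xi_j(t')> =
    noise_sigma^2 delta_ij delta(t-t') is added to each population equation
    (tau_i dm_i = (...) dt + dW scaled accordingly); with noise_sigma = 0
    the integration is deterministic.  States are clipped to [0, 1]; if a
    state leaves [-0.1, 1.1] before clipping the step size is deemed
    unstable and an error is raised.

    Returns (times, m) with m of shape (n_rec, 4).
    """
    K = params.K if K is None else K
    m = np.asarray(m_init, dtype=float).copy()
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("m_init must lie in [0, 1]^4")
    rng = np.random.default_rng(seed)
    tau = np.asarray(params.tau_pop)
    n_steps = int(round(duration / dt))
    times = [0.0]
    rec = [m.copy()]
    amp = noise_sigma * math.sqrt(dt) / tau
    for step in range(1, n_steps + 1):
        mc = np.clip(m, _CLIP, 1.0 - _CLIP)
        h, _, _ = _transfer(mc, params, K)
        m = m + dt * (h - mc) / tau
        if noise_sigma > 0.0:
            m = m + amp * rng.standard_normal(4)
        if np.any(m < -0.1) or np.any(m > 1.1):
            raise IntegrationError(f"integration unstable at t={step*dt}: m={m}")
        m = np.clip(m, 0.0, 1.0)
        if step % record_every == 0:
            times.append(step * dt)
            rec.append(m.copy())
    return np.asarray(times), np.asarray(rec)


# ---------------------------------------------------------------------------
# Nullclines

def nullcline(params: NetworkParams, K: Optional[float], grid, which: int = 1):
    """Projection of the dm1/dt = 0 (or dm3/dt = 0) manifold on the m1-m3 plane.

    For ``which=1``: for each m1 on the grid, solve the steady-state
    equations of populations {1, 2, 4} for (m2, m3, m4) and report m3 (the
    m2 and m4 equations slave the inhibitory activities).  For ``which=3``
    the roles of m1 and m3 are exchanged.  Failed grid points are reported
    as NaN rather than raising.

    Returns (grid, partner) where partner[i] is the complementary
    excitatory activity.
    """
    K = params.K if K is None else K
    if not np.isfinite(K):
        raise ValueError("nullclines are defined for finite K")
    if which not in (1, 3):
        raise ValueError("which must be 1 or 3")
    fixed_idx = 0 if which == 1 else 2
    free_idx = [i for i in range(4) if i != fixed_idx]
    # steady-state residuals of all populations except the complementary
    # excitatory one (index 2 for which=1, index 0 for which=3)
    eq_idx = [i for i in range(4) if i != (2 if which == 1 else 0)]
    partner_idx = 2 if which == 1 else 0

    fp = solve_fixed_point(params, K)
    start = fp.m.copy()

    grid = np.asarray(grid, dtype=float)
    out = np.full(grid.shape, np.nan)
    prev = start[free_idx]
    for i, val in enumerate(grid):
        def residual(free):
            m = np.empty(4)
            m[fixed_idx] = val
            m[free_idx] = free
            mc = np.clip(m, _CLIP, 1.0 - _CLIP)
            h, _, _ = _transfer(mc, params, K)
            return (m - h)[eq_idx]

        sol = optimize.root(residual, prev, method="hybr", tol=1e-13)
        if sol.success and np.max(np.abs(sol.fun)) < 1e-9:
            m = np.empty(4)
            m[fixed_idx] = val
            m[free_idx] = sol.x
            out[i] = m[partner_idx]
            prev = sol.x
    return grid, out
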