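"""Mean-field theory: fixed points, Jacobian spectrum, tuning, projections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from balnet import NetworkParams
from balnet import meanfield as mf

FIG2 = dict(J_E=4.0, J_I=2.5, E0=0.3, tau_E=10.0, tau_I=8.0)


@pytest.fixture
def params():
    return NetworkParams(N=100_000, K=1000, **FIG2)


# ---------------------------------------------------------------------------
# Gaussian tail

def test_gaussian_tail_basics():
    assert mf.gaussian_tail(0.0) == pytest.approx(0.5)
    assert mf.gaussian_tail(-40.0) == pytest.approx(1.0)
    assert mf.gaussian_tail(40.0) == pytest.approx(0.0, abs=1e-300)
    assert abs(mf.gaussian_tail_inv(mf.gaussian_tail(1.2345)) - 1.2345) < 1e-10
    for bad in (0.0, 1.0, -0.1):
        with pytest.raises(ValueError):
            mf.gaussian_tail_inv(bad)


@settings(derandomize=True, max_examples=50)
@given(st.floats(-6.0, 6.0))
def test_gaussian_tail_roundtrip_and_monotone(x):
    p = mf.gaussian_tail(x)
    assert 0.0 < p < 1.0
    assert abs(mf.gaussian_tail_inv(p) - x) < 1e-9
    assert mf.gaussian_tail(x + 0.1) < p


# ---------------------------------------------------------------------------
# Input statistics and the line

def test_input_stats_symmetric_line_point(params):
    m = [0.25, 0.1, 0.25, 0.1]
    u, alpha = mf.input_stats(m, params, 100)
    # the balance bracket vanishes exactly at the line point, so u = -T
    assert np.allclose(u, -np.asarray(params.T))
    assert alpha[0] == pytest.approx(0.25 + 16 * 0.1)       # 1.85
    assert alpha[1] == pytest.approx(0.25 + 6.25 * 0.1)     # 0.875
    _, alpha_s = mf.input_stats(m, params, 100, cross_mode="sparse")
    assert alpha_s[0] == pytest.approx(1.85 + 1.5**2 * 0.1)  # 2.075


def test_line_kinf_parametrization(params):
    m = mf.line_kinf(0.25, params)
    assert np.allclose(m, [0.25, 0.1, 0.25, 0.1])
    assert params.x_max == pytest.approx(0.5)
    m_edge = mf.line_kinf(1e-9, params)
    assert np.allclose(m_edge, [0.0, 0.0, 0.5, 0.2], atol=1e-8)
    for x in (0.0, 0.5, -0.1, 0.7):
        with pytest.raises(ValueError):
            mf.line_kinf(x, params)
    # every line point solves the K->infinity linear system exactly
    C = mf.coupling_matrix(params)
    for x in (0.05, 0.2, 0.45):
        m = mf.line_kinf(x, params)
        assert np.allclose(C @ m + np.asarray(params.E0_pop), 0.0, atol=1e-14)


def test_kinf_system_singular_iff_tuned(params):
    C = mf.coupling_matrix(params)  # J~ = 1.5 = J_E - J_I
    r0 = np.array([1.0, 1 / 2.5, -1.0, -1 / 2.5])
    assert np.allclose(C @ r0, 0.0, atol=1e-14)
    assert abs(np.linalg.det(mf.coupling_matrix(params, J_tilde=1.6))) > 1e-3


# ---------------------------------------------------------------------------
# Fixed points

def _bisection_symmetric_fp(params, K):
    """Independent oracle: nested bisection on the symmetric subspace."""
    sqrtK = np.sqrt(K)

    def res_b(a, b):
        alpha = a + params.J_I**2 * b
        u = sqrtK * (a - params.J_I * b) - params.T[1]
        return b - mf.gaussian_tail(-u / np.sqrt(alpha))

    def res_a(a):
        b = brentq(lambda bb: res_b(a, bb), 1e-9, 1 - 1e-9, xtol=1e-15)
        alpha = a + params.J_E**2 * b
        u = sqrtK * (a - params.J_E * b - params.J_tilde * b + params.E0) \
            - params.T[0]
        return a - mf.gaussian_tail(-u / np.sqrt(alpha))

    # bracket from the valid line range: the symmetric point sits near
    # x = J_I E0 / (2 (J_E - J_I)) = 0.25, far from the unstable corners
    a = brentq(res_a, 0.1, 0.45, xtol=1e-15)
    b = brentq(lambda bb: res_b(a, bb), 1e-9, 1 - 1e-9, xtol=1e-15)
    return np.array([a, b, a, b])


def test_fixed_point_residual_and_bisection_oracle(params):
    fp = mf.solve_fixed_point(params, 1000)
    assert fp.residual < 1e-12
    oracle = _bisection_symmetric_fp(params, 1000)
    assert np.allclose(fp.m, oracle, atol=1e-10)
    assert np.allclose(fp.m, mf.gaussian_tail(-fp.u / np.sqrt(fp.alpha)))


def test_fixed_point_from_remote_guess(params):
    fp = mf.solve_fixed_point(params, 1000)
    try:
        fp2 = mf.solve_fixed_point(params, 1000, guess=[0.99] * 4,
                                   symmetric=False)
        assert np.allclose(fp2.m, fp.m, atol=1e-8)
    except mf.FixedPointError:
        pass  # explicit basin-failure report is acceptable


def test_mf_rhs_zero_at_fixed_point_and_drive_from_silence(params):
    fp = mf.solve_fixed_point(params, 1000)
    assert np.max(np.abs(mf.mf_rhs(fp.m, params, 1000))) < 1e-12
    rhs = mf.mf_rhs([0.0, 0.0, 0.0, 0.0], params, 1000)
    assert rhs[0] > 0  # sqrt(K) E0 > T drives the silent network up


# ---------------------------------------------------------------------------
# Jacobian and eigenstructure

def test_f_matrix_against_finite_differences(params):
    fp = mf.solve_fixed_point(params, 1000)
    f = mf.f_matrix(fp.m, params, 1000)
    h = 1e-7
    for j in range(4):
        mp, mm = fp.m.copy(), fp.m.copy()
        mp[j] += h
        mm[j] -= h
        hp, _, _ = mf._transfer(mp, params, 1000)
        hm, _, _ = mf._transfer(mm, params, 1000)
        fd = (hp - hm) / (2 * h)
        assert np.max(np.abs(f[:, j] - fd) / np.maximum(np.abs(fd), 1.0)) < 1e-6


def test_closed_form_eigenvalues_match_numeric(params):
    jt = mf.tune_jtilde(params, 1000)
    p = params.with_(J_tilde=jt)
    fp = mf.solve_fixed_point(p, 1000)
    info = mf.jacobian(fp, p, 1000)
    closed = mf.eigenvalues_closed_form(info.f, p.tau)
    a = np.sort_complex(np.round(closed, 12))
    b = np.sort_complex(np.round(info.eigenvalues, 12))
    assert np.max(np.abs(a - b)) < 1e-10


@settings(derandomize=True, max_examples=100)
@given(st.floats(0.05, 0.9), st.floats(-0.9, -0.05), st.floats(0.1, 0.9),
       st.floats(0.05, 0.9), st.floats(0.5, 1.5))
def test_singular_f14_forces_zero_eigenvalue(f11, f12, f21, f22, tau):
    """The slope-(-1) condition chain: Eq-42 slope -> f14 -> lambda-- = 0."""
    f = np.zeros((4, 4))
    f[0, 0] = f[2, 2] = f11
    f[0, 1] = f[2, 3] = f12
    f[1, 0] = f[3, 2] = f21
    f[1, 1] = f[3, 3] = f22
    f14 = mf.f14_singular(f)
    f[0, 3] = f[2, 1] = f14
    assert mf.dm1_dm3(f) == pytest.approx(-1.0, abs=1e-12)
    eigs = mf.eigenvalues_closed_form(f, tau)
    assert min(abs(e) for e in eigs) < 1e-12
    A = mf._assemble_A(f.copy(), tau)
    assert min(abs(e) for e in np.linalg.eigvals(A)) < 1e-10


# ---------------------------------------------------------------------------
# Tuning

def test_tuning_kinf_and_k1000(params):
    assert mf.tune_jtilde(params, np.inf) == 1.5
    jstar = mf.tune_jtilde(params, 1000)
    assert round(jstar, 1) == 1.7
    assert abs(mf._lambda_at(params, 1000, jstar)) < 1e-9


def test_tuned_jtilde_decreases_toward_kinf_limit(params):
    js = [mf.tune_jtilde(params, K) for K in (100, 500, 1000, 5000)]
    assert all(a > b for a, b in zip(js, js[1:]))
    assert all(j > 1.5 for j in js)


def test_lambda_locally_linear_in_jtilde(params):
    jstar = mf.tune_jtilde(params, 1000)
    d = 0.005 * jstar  # +-0.5%
    grid = np.array([jstar - d, jstar, jstar + d])
    _, lam, lam_next = mf.lambda_vs_jtilde(params, 1000, grid)
    assert abs(lam[1]) < 1e-9
    curvature = abs(lam[2] + lam[0] - 2 * lam[1])
    span = abs(lam[2] - lam[0])
    assert curvature / span < 0.05
    assert np.all(lam_next < 0)


def test_tuning_slope_grows_as_sqrt_K(params):
    def slope(K):
        jstar = mf.tune_jtilde(params, K)
        h = 1e-4
        return (mf._lambda_at(params, K, jstar + h)
                - mf._lambda_at(params, K, jstar - h)) / (2 * h)

    ratio = slope(400) / slope(100)
    assert ratio == pytest.approx(2.0, rel=0.1)


def test_tune_to_rate_hits_target(params):
    target = -1.0 / 80.0  # 1/ms
    jt = mf.tune_to_rate(params, 1000, target)
    lam = mf._lambda_at(params, 1000, jt) / params.tau_E
    assert lam == pytest.approx(target, rel=1e-6)


# ---------------------------------------------------------------------------
# Projection basis

def test_projection_basis_kinf(params):
    b = mf.projection_basis(params, np.inf)
    assert np.allclose(b.r0, [1.0, 0.4, -1.0, -0.4])
    assert b.v0 @ b.r0 == pytest.approx(1.0)
    # X along the exact line equals the line-parameter offset
    for x in (0.1, 0.3, 0.4):
        m = mf.line_kinf(x, params)
        X = b.v0 @ (m - b.m0)
        assert X == pytest.approx(x - params.x_symmetric, abs=1e-12)


def test_projection_basis_finite_K(params):
    p = params.with_(J_tilde=mf.tune_jtilde(params, 1000))
    b = mf.projection_basis(p, 1000)
    assert b.v0 @ b.r0 == pytest.approx(1.0)
    assert b.r0[0] == pytest.approx(1.0)
    assert abs(b.lam) < 1e-9
    # r0 approaches the K->infinity pattern
    assert np.allclose(b.r0, [1.0, 0.4, -1.0, -0.4], atol=0.05)
    # v0 is a left eigenvector: v0 A = lam v0
    fp = mf.solve_fixed_point(p, 1000)
    A = mf.jacobian(fp, p, 1000).A
    assert np.allclose(b.v0 @ A, b.lam * b.v0, atol=1e-8)


# ---------------------------------------------------------------------------
# Integrator

def test_integrator_stays_at_fixed_point(params):
    fp = mf.solve_fixed_point(params, 1000)
    _, m = mf.integrate_mf(fp.m, params, 200.0, dt=0.05, K=1000)
    assert np.max(np.abs(m[-1] - fp.m)) < 1e-10


def test_integrator_decay_rate_matches_lambda(params):
    # untuned J~ = 1.5 at K = 1000: a start displaced along r0 decays at |lambda|
    fp = mf.solve_fixed_point(params, 1000)
    info = mf.jacobian(fp, params, 1000)
    b = mf.projection_basis(params.with_(J_tilde=mf.tune_jtilde(params, 1000)),
                            1000)
    m0 = fp.m + 0.02 * b.r0
    times, m = mf.integrate_mf(m0, params, 60.0, dt=0.01, K=1000)
    X = (m - fp.m) @ b.v0
    sel = (times > 10) & (times < 50) & (np.abs(X) > 1e-6)
    rate = np.polyfit(times[sel], np.log(np.abs(X[sel])), 1)[0]
    lam_ms = info.lambda0.real / params.tau_E
    assert rate == pytest.approx(lam_ms, rel=0.10)


def test_integrator_consistency_with_rhs(params):
    fp = mf.solve_fixed_point(params, 1000)
    m0 = np.clip(fp.m + [0.01, -0.005, 0.008, 0.002], 0, 1)
    dt = 0.01
    times, m = mf.integrate_mf(m0, params, 1.0, dt=dt, K=1000)
    mid = 40
    fd = (m[mid + 1] - m[mid - 1]) / (2 * dt)
    rhs = mf.mf_rhs(m[mid], params, 1000)
    assert np.max(np.abs(fd - rhs)) < 50 * dt**2 + 1e-8


def test_noisy_integration_diffuses_along_line(params):
    p = params.with_(J_tilde=mf.tune_jtilde(params, 1000))
    fp = mf.solve_fixed_point(p, 1000)
    b = mf.projection_basis(p, 1000)
    sigma = 1e-2 * np.sqrt(10.0)
    _, m = mf.integrate_mf(fp.m, p, 20_000.0, dt=0.5, noise_sigma=sigma,
                           K=1000, seed=4, record_every=4)
    dm = m - fp.m
    X = dm @ b.v0
    perp = dm @ (b.left_rest / np.linalg.norm(b.left_rest, axis=1,
                                              keepdims=True)).T

    def msd_ratio(sig, short=5, long=250):  # lags in samples (2 ms each)
        msd = lambda L: np.mean((sig[L:] - sig[:-L]) ** 2)
        return msd(long) / msd(short)

    # X keeps diffusing (MSD grows with lag); perpendicular modes saturate
    assert msd_ratio(X) > 3.0
    assert all(msd_ratio(perp[:, k]) < 1.5 for k in range(perp.shape[1]))
    # the cloud is elongated along the m1-m3 anti-diagonal
    anti = (dm[:, 0] - dm[:, 2]) / np.sqrt(2)
    diag = (dm[:, 0] + dm[:, 2]) / np.sqrt(2)
    assert anti.std() > 2.5 * diag.std()


def test_integrator_instability_detected(params):
    with pytest.raises(mf.IntegrationError):
        mf.integrate_mf([0.5, 0.5, 0.5, 0.5], params, 10.0, dt=0.1,
                        noise_sigma=5.0, K=1000, seed=1)


# ---------------------------------------------------------------------------
# Nullclines

def test_nullclines_intersect_at_symmetric_point(params):
    fp = mf.solve_fixed_point(params, 1000)
    g1, m3 = mf.nullcline(params, 1000, [fp.m[0]], which=1)
    g3, m1 = mf.nullcline(params, 1000, [fp.m[2]], which=3)
    assert m3[0] == pytest.approx(fp.m[2], abs=1e-9)
    assert m1[0] == pytest.approx(fp.m[0], abs=1e-9)


def test_nullcline_slope_minus_one_at_tuned_point(params):
    p = params.with_(J_tilde=mf.tune_jtilde(params, 1000))
    fp = mf.solve_fixed_point(p, 1000)
    h = 1e-5
    _, m3 = mf.nullcline(p, 1000, [fp.m[0] - h, fp.m[0] + h], which=1)
    slope = (m3[1] - m3[0]) / (2 * h)
    assert abs(slope + 1.0) < 1e-6
    # closed-form slope agrees with the numerical one
    f = mf.f_matrix(fp.m, p, 1000)
    assert mf.dm1_dm3(f) == pytest.approx(slope, abs=1e-4)


def test_nullcline_slope_from_f_at_untuned_point(params):
    fp = mf.solve_fixed_point(params, 1000)
    h = 1e-5
    _, m3 = mf.nullcline(params, 1000, [fp.m[0] - h, fp.m[0] + h], which=1)
    slope = (m3[1] - m3[0]) / (2 * h)   # dm3/dm1 along the dm1/dt=0 manifold
    f = mf.f_matrix(fp.m, params, 1000)
    assert mf.dm1_dm3(f) == pytest.approx(1.0 / slope, abs=1e-4)


def test_eigenvalues_negative_along_attractor(params):
    """Stability along the approximate line: all modes decay except the
    near-zero one (evaluated at points of the dm1/dt = 0 manifold)."""
    from scipy.optimize import root

    p = params.with_(J_tilde=mf.tune_jtilde(params, 1000))
    fp = mf.solve_fixed_point(p, 1000)
    for m1 in np.linspace(0.19, 0.29, 5):
        def residual(rest):
            m = np.array([m1, rest[0], rest[1], rest[2]])
            h, _, _ = mf._transfer(np.clip(m, 1e-12, 1 - 1e-12), p, 1000)
            return (m - h)[[0, 1, 3]]

        sol = root(residual, [fp.m[1], fp.m[2], fp.m[3]], tol=1e-12)
        assert sol.success
        m = np.array([m1, sol.x[0], sol.x[1], sol.x[2]])
        eigs = mf.jacobian(m, p, 1000).eigenvalues
        assert eigs[0].real < 0.05
        assert all(e.real < -0.1 for e in eigs[1:])
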