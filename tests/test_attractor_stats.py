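"""Trajectory statistics validated against exact OU ground truth and
hand-computed covariance oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from balnet import NetworkParams
from balnet import meanfield as mf
from balnet import attractor_stats as stats
from balnet.ou import simulate_ou, ou_g, ou_variance

LAM, D = 0.01, 1e-5   # OU ground truth used throughout (1/ms, X^2/ms)


@pytest.fixture(scope="module")
def ou_paths():
    # 200 stationary paths of length 100/lam
    return simulate_ou(LAM, D, dt=1.0, n_steps=10_000, n_paths=200,
                       stationary_start=True, seed=12)


@pytest.fixture(scope="module")
def basis_kinf():
    p = NetworkParams(N=10_000, K=1000)
    return p, mf.projection_basis(p, np.inf)


# ---------------------------------------------------------------------------
# Projection

def test_project_constant_trace_is_zero(basis_kinf):
    _, b = basis_kinf
    m = np.tile(b.m0, (50, 1))
    assert np.allclose(stats.project(m, b), 0.0)


def test_project_line_points_recover_position(basis_kinf):
    p, b = basis_kinf
    xs = np.array([0.1, 0.2, 0.3, 0.4])
    m = np.stack([mf.line_kinf(x, p) for x in xs])
    X = stats.project(m, b)
    assert np.allclose(X, xs - p.x_symmetric, atol=1e-12)


def test_project_mirrored_trajectory_is_zero(basis_kinf):
    """A symmetric trajectory (m1=m3, m2=m4) has X = 0 even while m moves."""
    p, b = basis_kinf
    rng = np.random.default_rng(0)
    a = 0.25 + 0.05 * rng.standard_normal(100)
    c = 0.1 + 0.02 * rng.standard_normal(100)
    m = np.stack([a, c, a, c], axis=1)
    assert np.max(np.abs(stats.project(m, b))) < 1e-12


# ---------------------------------------------------------------------------
# Conditional moments on exact OU paths

def test_drift_moment_recovers_minus_lambda_x(ou_paths):
    Xg = np.array([-0.04, -0.02, 0.0, 0.02, 0.04])
    est = stats.drift_diffusion(list(ou_paths), 1.0, Xg, [1.0, 2.0],
                                delta=1e-3)
    for il, L in enumerate([1.0, 2.0]):
        expect = Xg * (np.exp(-LAM * L) - 1.0)   # exact OU conditional mean
        ok = np.isfinite(est.F[:, il])
        assert np.all(np.abs(est.F[ok, il] - expect[ok])
                      <= 2 * est.se_F[ok, il] + 1e-6)


def test_diffusion_moment_recovers_2d(ou_paths):
    est = stats.drift_diffusion(list(ou_paths), 1.0, [0.0], [1.0, 2.0, 4.0],
                                delta=1e-3)
    for il, L in enumerate([1.0, 2.0, 4.0]):
        expect = ou_g(LAM, D, L)
        assert est.G[0, il] == pytest.approx(expect, rel=0.05)
    assert abs(est.G[0, 0] / 1.0 - 2 * D) / (2 * D) < 0.05


def test_constant_trace_gives_zero_moments():
    x = np.full(5000, 0.017)
    est = stats.drift_diffusion([x], 1.0, [0.017], [1.0, 5.0], delta=1e-3)
    assert np.allclose(est.F[0], 0.0)
    assert np.allclose(est.G[0], 0.0)


def test_empty_cells_are_nan_not_zero(ou_paths):
    est = stats.drift_diffusion(list(ou_paths[:2]), 1.0, [5.0], [1.0],
                                delta=1e-3)  # X=5 is ~150 sigma out
    assert np.isnan(est.F[0, 0]) and np.isnan(est.G[0, 0])
    assert est.counts[0, 0] == 0


def test_estimator_invariant_to_time_shift(ou_paths):
    x = ou_paths[0]
    a = stats.drift_diffusion([x], 1.0, [0.0], [2.0], delta=2e-3)
    b = stats.drift_diffusion([np.roll(x, 500)[500:]], 1.0, [0.0], [2.0],
                              delta=2e-3)
    # same path content, shifted start: estimates agree closely
    assert a.G[0, 0] == pytest.approx(b.G[0, 0], rel=0.2)


def test_lag_validation():
    with pytest.raises(ValueError):
        stats.drift_diffusion([np.zeros(100)], 1.0, [0.0], [0.5], delta=1e-3)


# ---------------------------------------------------------------------------
# OU fits

def test_fit_ou_exact_curve_roundtrip():
    lags = np.linspace(1, 600, 40)
    fit = stats.fit_ou(lags, ou_g(LAM, D, lags))
    assert fit.lam == pytest.approx(LAM, abs=1e-8)
    assert fit.D == pytest.approx(D, rel=1e-6)


def test_fit_ou_variance_exact_roundtrip():
    t = np.linspace(5, 800, 60)
    fit = stats.fit_ou_variance(t, ou_variance(LAM, D, t))
    assert fit.lam == pytest.approx(LAM, abs=1e-8)
    assert fit.D == pytest.approx(D, rel=1e-6)


def test_fit_ou_recovery_from_simulated_paths(ou_paths):
    lags = np.unique(np.round(np.geomspace(1, 900, 25))).astype(float)
    est = stats.drift_diffusion(list(ou_paths), 1.0, [0.0], lags, delta=2e-3)
    fit = stats.fit_ou(lags, est.G[0], se=est.se_G[0])
    assert fit.lam == pytest.approx(LAM, rel=0.10)
    assert fit.D == pytest.approx(D, rel=0.10)


def test_fit_ou_window_excludes_sub_tau_lags():
    lags = np.concatenate([np.arange(1, 10), np.linspace(10, 600, 30)])
    fit = stats.fit_ou(lags, ou_g(LAM, D, lags), tau=10.0)
    assert fit.window[0] >= 10.0
    assert fit.lam == pytest.approx(LAM, rel=1e-4)


def test_fit_ou_errors():
    with pytest.raises(stats.OUFitError):
        stats.fit_ou([1, 2, 3], [1e-6, 2e-6, 3e-6])   # too few points


# ---------------------------------------------------------------------------
# Ensemble variance

def test_ensemble_variance_identical_replicas():
    X = np.tile(np.linspace(0, 1, 50), (10, 1))
    var, se = stats.ensemble_variance(X)
    assert np.allclose(var, 0.0)
    with pytest.raises(ValueError):
        stats.ensemble_variance(X[:1])


def test_ensemble_variance_matches_ou_growth():
    X = simulate_ou(LAM, D, dt=1.0, n_steps=600, n_paths=1200, x0=0.0, seed=3)
    var, se = stats.ensemble_variance(X, seed=5)
    t = np.arange(601.0)
    expect = ou_variance(LAM, D, t)
    sel = [50, 150, 300, 600]
    for i in sel:
        assert abs(var[i] - expect[i]) < 2.5 * se[i]


# ---------------------------------------------------------------------------
# Single-neuron autocorrelation

def test_q_frozen_states_and_zero_lag():
    rng = np.random.default_rng(7)
    row = (rng.random(300) < 0.3).astype(np.int8)
    S = np.tile(row, (400, 1))   # no updates applied
    q = stats.autocorrelation_q(S, 1.0, max_lag_ms=20.0)
    assert np.allclose(q.q, q.q[0])
    assert q.q[0] == pytest.approx(row.mean())   # binary idempotence


def test_q_bernoulli_refresh_surrogate():
    """Neurons refreshed at Poisson rate 1/tau to Bernoulli(p):
    q(dt) = p^2 + p(1-p) e^(-dt/tau), initial slope -p(1-p)/tau."""
    rng = np.random.default_rng(11)
    tau, pon = 10.0, 0.3
    nt, n, dt = 40_000, 400, 1.0
    S = np.empty((nt, n), dtype=np.int8)
    S[0] = rng.random(n) < pon
    for t in range(1, nt):
        refresh = rng.random(n) < dt / tau   # Poisson refresh per step
        new = rng.random(n) < pon
        S[t] = np.where(refresh, new, S[t - 1])
    q = stats.autocorrelation_q(S, dt, max_lag_ms=40.0, slope_window_ms=10.0)
    lags = q.lags
    expect = pon**2 + pon * (1 - pon) * np.exp(-lags / tau)
    assert np.max(np.abs(q.q - expect)) < 0.01
    # discrete-step refresh realizes rate ln(1/(1-dt/tau)) ~ 1/tau + O(dt)
    assert q.slope0 == pytest.approx(-pon * (1 - pon) / tau, rel=0.12)


def test_short_time_g_scalings():
    v0 = np.array([0.7, -0.4, -0.7, 0.4])
    slopes = np.array([-0.01, -0.005, -0.01, -0.005])
    g1 = stats.short_time_G(slopes, v0, 10_000)
    g2 = stats.short_time_G(slopes, v0, 20_000)
    assert g1 == pytest.approx(2 * g2)          # explicit 1/N factor
    assert stats.short_time_G([0, 0, 0, 0], v0, 10_000) == 0.0
    assert g1 > 0


# ---------------------------------------------------------------------------
# Covariance estimators

def _eq19_by_hand(a, b, m):
    """Single-pair unbiased covariance, written out term by term."""
    M = len(a)
    acc = 0.0
    for t in range(M - abs(m)):
        acc += a[t + m] * b[t]
    acc /= (M - abs(m))
    return acc - (sum(a) / M) * (sum(b) / M)


def test_pair_covariance_hand_oracle():
    a = np.array([1, 0, 1, 1, 0, 1], dtype=float)
    b = np.array([0, 1, 1, 0, 1, 0], dtype=float)
    expect = _eq19_by_hand(a, b, 1)
    cs = stats.pair_cross_covariance(a[:, None], b[:, None], [1], dt=66.0)
    assert cs.C[0] == pytest.approx(expect, abs=1e-14)
    assert expect == pytest.approx(3 / 5 - (4 / 6) * (3 / 6), abs=1e-14)


def test_pair_covariance_constant_sequences_zero():
    a = np.ones((30, 4))
    cs = stats.pair_cross_covariance(a, None, [-2, 0, 2], dt=1.0)
    assert np.allclose(cs.C, 0.0)


def test_pair_covariance_excludes_self_pairs():
    rng = np.random.default_rng(2)
    A = (rng.random((500, 6)) < 0.4).astype(float)
    cs = stats.pair_cross_covariance(A, None, [0], dt=1.0)
    # self-pairs would contribute the (large) variance ~p(1-p); distinct
    # independent columns give ~0
    assert abs(cs.C[0]) < 0.01
    assert cs.n_pairs == 15


def test_population_covariance_symmetry():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(4000)
    y = 0.5 * x + rng.standard_normal(4000)
    lags = np.arange(-5, 6)
    cxy = stats.population_cross_covariance(x, y, lags, dt=1.0)
    cyx = stats.population_cross_covariance(y, x, lags, dt=1.0)
    assert np.allclose(cxy.C, cyx.C[::-1], atol=1e-10)


def test_cm_matrix_transpose_relation():
    rng = np.random.default_rng(4)
    m = rng.standard_normal((3000, 2))
    m[:, 1] += 0.3 * np.roll(m[:, 0], 2)
    lags = np.arange(-6, 7)
    cm = stats.cm_matrix(m, lags, dt=1.0)
    for k, L in enumerate(lags):
        krev = np.nonzero(lags == -L)[0][0]
        assert np.allclose(cm[k], cm[krev].T, atol=1e-10)


@settings(derandomize=True, max_examples=20)
@given(st.integers(0, 400))
def test_population_covariance_time_shift_invariance(shift):
    rng = np.random.default_rng(9)
    x = np.sin(np.arange(2000) / 7.0) + 0.1 * rng.standard_normal(2000)
    base = stats.population_cross_covariance(x[:1200], x[:1200], [0, 3], 1.0)
    shifted = stats.population_cross_covariance(x[shift:shift + 1200],
                                                x[shift:shift + 1200],
                                                [0, 3], 1.0)
    assert np.allclose(base.C, shifted.C, atol=0.05 * abs(base.C[0]) + 1e-3)


def test_pair_estimator_noise_falls_with_n_and_time():
    """Sampling noise of the pair-averaged estimator shrinks with the number
    of neurons and with the recording length (independent-neuron surrogate)."""
    rng = np.random.default_rng(6)

    def spread(n, M, reps=40):
        vals = []
        for _ in range(reps):
            A = (rng.random((M, n)) < 0.3).astype(float)
            vals.append(stats.pair_cross_covariance(A, None, [1], 1.0).C[0])
        return np.std(vals)

    s_small, s_large = spread(6, 300), spread(24, 300)
    assert s_large < s_small / 2.0          # ~1/n scaling (factor 4 nominal)
    s_short, s_long = spread(8, 200), spread(8, 3200)
    assert s_long < s_short / 2.0           # ~1/sqrt(M)... at least halves


def test_moments_along_attractor_from_simulation(coupled_suite):
    """On simulated resting trajectories the drift rate is linear in X with
    negative slope, and the diffusion rate is approximately uniform in X
    (max/min < 1.5 over the central +-1.5 sigma range)."""
    Xs = coupled_suite[8000]["X"]
    sd = np.concatenate(Xs).std()
    Xg = np.linspace(-1.5 * sd, 1.5 * sd, 7)
    est = stats.drift_diffusion(Xs, 1.0, Xg, [3.0, 10.0], delta=1.5e-3)
    slope = np.polyfit(Xg, est.F[:, 1] / 10.0, 1)[0]
    assert slope < 0
    g = est.G[:, 0]
    assert np.nanmax(g) / np.nanmin(g) < 1.5
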