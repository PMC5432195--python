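"""Trajectory statistics along the approximate attractor.

The scalar coordinate X(t) = v0 . (m(t) - m0) tracks the position along the
slow direction.  Its dynamics are summarized by the conditional moments

    F(X, dt) = < X(t+dt) - X(t)   | X(t) = X >      (systematic drift)
    G(X, dt) = < [X(t+dt)-X(t)]^2 | X(t) = X >      (random diffusion)

estimated by conditioning on |X(t) - X| < delta, and compactly described by
an Ornstein-Uhlenbeck fit (lambda, D) over lags between the single-neuron
time scale tau and the memory decay time 1/lambda.  Short lags are governed
by single-neuron statistics instead: G(X, dt)/dt = (2/N) sum_j (v0_j)^2
(-dq_j/dt|_0) with q_j the population-averaged binary autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .meanfield import ProjectionBasis
from .simulator import PopulationTrace
from .ou import ou_g, ou_variance

__all__ = [
    "DriftDiffusionEstimate",
    "OUFit",
    "CorrelationSet",
    "AutocorrelationTrace",
    "project",
    "drift_diffusion",
    "fit_ou",
    "fit_ou_variance",
    "ensemble_variance",
    "autocorrelation_q",
    "short_time_G",
    "pair_cross_covariance",
    "population_cross_covariance",
    "cm_matrix",
]


# ---------------------------------------------------------------------------
# Projection

def project(trace, basis: ProjectionBasis, perpendicular: bool = False):
    """Attractor coordinate X(t) = v0 . (m(t) - m0) of a trace.

    ``trace`` may be a :class:`PopulationTrace` or a bare (n, 4) array.
    With ``perpendicular=True`` also returns the projections on the
    remaining left eigenvectors (shape (n, 3)).
    """
    m = trace.m if isinstance(trace, PopulationTrace) else np.asarray(trace, float)
    dm = m - basis.m0
    X = dm @ basis.v0
    if perpendicular:
        if basis.left_rest is None:
            raise ValueError("basis carries no perpendicular directions")
        return X, dm @ basis.left_rest.T
    return X


# ---------------------------------------------------------------------------
# Conditional drift / diffusion moments

@dataclass
class DriftDiffusionEstimate:
    """Conditional moments F and G on an (X, lag) grid.

    Cells with fewer than ``min_count`` qualifying samples are NaN.
    Standard errors are trial-based when at least three traces contribute
    to a cell, otherwise pooled per-sample errors (which ignore temporal
    correlation and are therefore optimistic).
    """

    X_grid: np.ndarray
    lags: np.ndarray             # ms
    F: np.ndarray                # (nX, nlag)
    G: np.ndarray
    counts: np.ndarray           # int
    se_F: np.ndarray
    se_G: np.ndarray
    delta: float


def drift_diffusion(
    traces: Sequence[np.ndarray],
    dt: float,
    X_grid,
    lags_ms,
    delta: float = 1e-3,
    min_count: int = 50,
) -> DriftDiffusionEstimate:
    """Estimate F(X, dt) and G(X, dt) from X trajectories.

    For every X on the grid, all time points with |X(t) - X| < delta
    qualify; displacements over each lag are averaged over qualifying times
    and over traces.  ``lags_ms`` must be (near) multiples of the sampling
    interval ``dt``.
    """
    X_grid = np.atleast_1d(np.asarray(X_grid, float))
    lags_ms = np.atleast_1d(np.asarray(lags_ms, float))
    lag_steps = np.round(lags_ms / dt).astype(int)
    if np.any(np.abs(lag_steps * dt - lags_ms) > 1e-6 * dt) or np.any(lag_steps < 1):
        raise ValueError("lags must be positive multiples of the sampling interval")

    nX, nL, nT = len(X_grid), len(lag_steps), len(traces)
    sum1 = np.zeros((nT, nX, nL))
    sum2 = np.zeros((nT, nX, nL))
    cnt = np.zeros((nT, nX, nL), dtype=np.int64)
    sum4 = np.zeros((nX, nL))  # pooled squares of squared displacements

    for it, x in enumerate(traces):
        x = np.asarray(x, float)
        for ix, xc in enumerate(X_grid):
            idx = np.nonzero(np.abs(x - xc) < delta)[0]
            if len(idx) == 0:
                continue
            for il, L in enumerate(lag_steps):
                ok = idx[idx + L < len(x)]
                if len(ok) == 0:
                    continue
                d = x[ok + L] - x[ok]
                sum1[it, ix, il] += d.sum()
                sum2[it, ix, il] += (d * d).sum()
                sum4[ix, il] += (d ** 4).sum()
                cnt[it, ix, il] += len(ok)

    tot = cnt.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = sum1.sum(axis=0) / tot
        G = sum2.sum(axis=0) / tot
        varF = sum2.sum(axis=0) / tot - F**2
        varG = sum4 / tot - G**2
        se_F = np.sqrt(np.maximum(varF, 0.0) / tot)
        se_G = np.sqrt(np.maximum(varG, 0.0) / tot)
        # trial-based errors where enough traces contribute
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perF = sum1 / cnt
            perG = sum2 / cnt
        for ix in range(nX):
            for il in range(nL):
                good = cnt[:, ix, il] > 0
                n = int(good.sum())
                if n >= 3:
                    se_F[ix, il] = np.nanstd(perF[good, ix, il], ddof=1) / np.sqrt(n)
                    se_G[ix, il] = np.nanstd(perG[good, ix, il], ddof=1) / np.sqrt(n)
    bad = tot < min_count
    for arr in (F, G, se_F, se_G):
        arr[bad] = np.nan
    return DriftDiffusionEstimate(X_grid=X_grid, lags=lags_ms, F=F, G=G,
                                  counts=tot, se_F=se_F, se_G=se_G, delta=delta)


# ---------------------------------------------------------------------------
# OU fits

@dataclass
class OUFit:
    """Fitted OU parameters, with Var(t|X0) = (D/lam)(1 - e^(-2 lam t))."""

    lam: float                   # 1/ms
    D: float                     # X^2/ms
    cov: np.ndarray              # 2x2 covariance of (lam, D)
    window: Tuple[float, float]  # fitted lag range, ms

    @property
    def D_per_10ms(self) -> float:
        return self.D * 10.0

    @property
    def se(self) -> Tuple[float, float]:
        return tuple(np.sqrt(np.diag(self.cov)))


class OUFitError(RuntimeError):
    pass


def _do_fit(model, t, y, p0, sigma):
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=([1e-12, 1e-30], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise OUFitError(f"OU fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)) or np.any(popt <= 0):
        raise OUFitError(f"nonpositive OU parameter estimates {popt}")
    return popt, pcov


def fit_ou(lags_ms, G0, se=None, lam_init: Optional[float] = None,
           tau: Optional[float] = None) -> OUFit:
    """Least-squares fit of G(0, dt) to (2D/lam)(1 - exp(-lam dt)).

    ``lam_init`` seeds the decay rate (1/ms); by default it is taken from
    the span of the lag window.  At least 5 lag points are required.
    When ``tau`` is given, lags below tau are excluded (they are governed
    by single-neuron statistics rather than the slow OU regime) and the
    window is iterated once to dt <= 4/lambda_hat after a first estimate.
    """
    t = np.asarray(lags_ms, float)
    y = np.asarray(G0, float)
    good = np.isfinite(y)
    se_all = None if se is None else np.asarray(se, float)
    if tau is not None:
        good &= t >= tau - 1e-9
    t1, y1 = t[good], y[good]
    se1 = None if se_all is None else se_all[good]
    if len(t1) < 5:
        raise OUFitError("need at least 5 lag points for an OU fit")
    lam0 = lam_init if lam_init is not None else 1.0 / (0.5 * t1.max())
    D0 = 0.5 * np.interp(min(1.0 / lam0, t1.max()), t1, y1) * lam0
    popt, pcov = _do_fit(lambda tt, lam, D: ou_g(lam, D, tt), t1, y1,
                         [lam0, max(D0, 1e-12)], se1)
    if tau is not None:
        hi = 4.0 / popt[0]
        good2 = good & (t <= hi)
        if good2.sum() >= 5 and good2.sum() < good.sum():
            t2, y2 = t[good2], y[good2]
            se2 = None if se_all is None else se_all[good2]
            popt, pcov = _do_fit(lambda tt, lam, D: ou_g(lam, D, tt), t2, y2,
                                 list(popt), se2)
            return OUFit(lam=popt[0], D=popt[1], cov=pcov,
                         window=(t2.min(), t2.max()))
    return OUFit(lam=popt[0], D=popt[1], cov=pcov, window=(t1.min(), t1.max()))


def fit_ou_variance(times_ms, var, se=None, lam_init: Optional[float] = None) -> OUFit:
    """Fit an ensemble variance curve to (D/lam)(1 - exp(-2 lam t))."""
    t = np.asarray(times_ms, float)
    y = np.asarray(var, float)
    good = np.isfinite(y) & (t > 0)
    t, y = t[good], y[good]
    se = None if se is None else np.asarray(se, float)[good]
    if len(t) < 5:
        raise OUFitError("need at least 5 time points for an OU fit")
    lam0 = lam_init if lam_init is not None else 1.0 / (0.5 * t.max())
    D0 = max(np.interp(min(1.0 / lam0, t.max()), t, y) * lam0, 1e-12)
    popt, pcov = _do_fit(lambda tt, lam, D: ou_variance(lam, D, tt), t, y,
                         [lam0, D0], se)
    return OUFit(lam=popt[0], D=popt[1], cov=pcov, window=(t.min(), t.max()))


def ensemble_variance(X: np.ndarray, n_boot: int = 200, seed: int = 0):
    """Across-replica variance of X at each sample time.

    ``X`` has shape (n_replicas, n_times); replicas share the update
    schedule and differ in their initial perturbation.  Returns
    (var, se) with bootstrap standard errors over replicas.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 replicas")
    var = X.var(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = X[idx].var(axis=0, ddof=1)
    return var, boots.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Single-neuron autocorrelation and the short-lag G prediction

@dataclass
class AutocorrelationTrace:
    """Population-averaged single-neuron autocorrelation q(dt)."""

    lags: np.ndarray             # ms
    q: np.ndarray                # per lag
    slope0: float                # estimated -dq/dt|_0 has sign: this is dq/dt
    n_neurons: int


def autocorrelation_q(states: np.ndarray, dt: float, max_lag_ms: float,
                      slope_window_ms: Optional[float] = None,
                      slope_method: str = "exp") -> AutocorrelationTrace:
    """q(dt) = (1/n) sum_k <sigma_k(t+dt) sigma_k(t)> from state samples.

    ``states`` has shape (n_times, n_neurons) with entries in {0, 1};
    samples must cover a stationary stretch at spacing <= tau/10.  The
    initial slope dq/dt|_0 is estimated over lags up to ``slope_window_ms``
    (default: a third of ``max_lag_ms``) either by fitting
    a + b exp(-t/tau_q) and differentiating at 0 (``slope_method="exp"``,
    default -- unbiased for the near-exponential decay of binary-state
    autocorrelations) or by a straight linear fit (``"linear"``, which
    underestimates |dq/dt| by the secant bias).  A trend in the population
    mean larger than 3 standard errors triggers a nonstationarity warning.
    """
    S = np.asarray(states)
    nt, n = S.shape
    max_lag = int(round(max_lag_ms / dt))
    if max_lag >= nt:
        raise ValueError("max_lag exceeds the record length")
    # stationarity check on the population mean
    mbar = S.mean(axis=1)
    half = nt // 2
    d = mbar[half:].mean() - mbar[:half].mean()
    se = np.sqrt(mbar[:half].var() / half + mbar[half:].var() / (nt - half))
    if se > 0 and abs(d) > 3 * se * np.sqrt(max(1.0, nt / (2 * max_lag))):
        warnings.warn("population mean shows a trend; q assumes stationarity")

    Sf = S.astype(np.float64)
    q = np.empty(max_lag + 1)
    for L in range(max_lag + 1):
        q[L] = np.mean(Sf[L:] * Sf[:nt - L])
    lags = np.arange(max_lag + 1) * dt
    win = slope_window_ms if slope_window_ms is not None else max_lag_ms / 3.0
    sel = lags <= win + 1e-9
    if slope_method == "linear":
        slope = np.polyfit(lags[sel], q[sel], 1)[0]
    elif slope_method == "exp":
        slope = _exp_slope(lags[sel], q[sel])
    else:
        raise ValueError(f"unknown slope_method {slope_method!r}")
    return AutocorrelationTrace(lags=lags, q=q, slope0=slope, n_neurons=n)


def _exp_slope(t, y):
    """Initial derivative of y ~ a + b exp(-t/tau_q); falls back to linear."""
    b0 = y[0] - y[-1]
    if abs(b0) < 1e-15:
        return 0.0
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, b, tq: a + b * np.exp(-tt / tq), t, y,
            p0=[y[-1], b0, max(t[-1] / 2.0, t[1])],
            bounds=([-np.inf, -np.inf, t[1] / 10.0], [np.inf, np.inf, np.inf]),
            maxfev=10000)
        return float(-popt[1] / popt[2])
    except RuntimeError:
        return float(np.polyfit(t, y, 1)[0])


def short_time_G(q_slopes, v0, N: int) -> float:
    """Short-lag diffusion rate G(X, dt)/dt = (2/N) sum_j v0_j^2 (-dq_j/dt|0).

    ``q_slopes`` are the initial slopes dq_j/dt (negative for decaying
    autocorrelations); no fitting parameters enter.
    """
    q_slopes = np.asarray(q_slopes, float)
    v0 = np.asarray(v0, float)
    return float(2.0 / N * np.sum(v0**2 * (-q_slopes)))


# ---------------------------------------------------------------------------
# Cross-covariance estimators

@dataclass
class CorrelationSet:
    """Lagged covariance curve with metadata."""

    lags: np.ndarray             # in sampling steps times dt
    C: np.ndarray
    dt: float                    # sampling interval, ms
    n_pairs: int = 0


def _lagged_products(A: np.ndarray, B: np.ndarray, m: int) -> np.ndarray:
    """Matrix of (1/(M-|m|)) sum_a A[a+m, i] B[a, j] over valid a."""
    M = A.shape[0]
    if abs(m) >= M:
        raise ValueError("lag exceeds record length")
    if m >= 0:
        return A[m:].T @ B[:M - m] / (M - m)
    return A[:M + m].T @ B[-m:] / (M + m)


def pair_cross_covariance(samples_a: np.ndarray, samples_b: Optional[np.ndarray],
                          lags: Sequence[int], dt: float) -> CorrelationSet:
    """Pairwise-averaged unbiased cross covariance of sampled neuron states.

    ``samples_a`` (and ``samples_b`` for a cross-population estimate) have
    shape (M, n): M equally spaced time samples of n neurons.  For each
    pair the single-pair estimate subtracts the product of the two full
    means from the lagged product normalized by M - |lag|; the average runs
    over distinct unordered pairs within one population (self-pairs
    excluded) or over all pairs across two populations.
    """
    A = np.asarray(samples_a, np.float64)
    same = samples_b is None
    B = A if same else np.asarray(samples_b, np.float64)
    M, n_a = A.shape
    n_b = B.shape[1]
    if same and n_a < 2:
        raise ValueError("need at least 2 neurons for within-population pairs")
    if B.shape[0] != M:
        raise ValueError("sample blocks must share the time grid")
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    outer = np.outer(mean_a, mean_b)
    lags = np.asarray(lags, int)
    C = np.empty(len(lags))
    if same:
        iu = np.triu_indices(n_a, k=1)
        n_pairs = len(iu[0])
    else:
        n_pairs = n_a * n_b
    for k, m in enumerate(lags):
        P = _lagged_products(A, B, int(m)) - outer
        C[k] = P[iu].mean() if same else P.mean()
    return CorrelationSet(lags=lags * dt, C=C, dt=dt, n_pairs=n_pairs)


def population_cross_covariance(series_k: np.ndarray, series_l: np.ndarray,
                                lags: Sequence[int], dt: float) -> CorrelationSet:
    """Unbiased lagged covariance of two population-activity series.

    C(m) = (1/(M-|m|)) sum_a x_k(t_{a+m}) x_l(t_a) - mean_k * mean_l.
    Unlike the pairwise estimator this includes the auto-covariance terms,
    whose relative contribution is O(1/N).
    """
    x = np.asarray(series_k, float)[:, None]
    y = np.asarray(series_l, float)[:, None]
    lags = np.asarray(lags, int)
    C = np.empty(len(lags))
    mx, my = x.mean(), y.mean()
    for k, m in enumerate(lags):
        C[k] = _lagged_products(x, y, int(m))[0, 0] - mx * my
    return CorrelationSet(lags=lags * dt, C=C, dt=dt, n_pairs=1)


def cm_matrix(m_series: np.ndarray, lags: Sequence[int], dt: float) -> np.ndarray:
    """Population covariance matrix C^m on a lag grid.

    ``m_series`` has shape (M, P); returns (nlag, P, P) with
    out[k, i, j] = C^m_ij(lag_k) following the t+dt-leads-i convention, so
    that out[k].T equals the value at the opposite lag.
    """
    X = np.asarray(m_series, float)
    mu = X.mean(axis=0)
    lags = np.asarray(lags, int)
    out = np.empty((len(lags), X.shape[1], X.shape[1]))
    for k, m in enumerate(lags):
        out[k] = _lagged_products(X, X, int(m)) - np.outer(mu, mu)
    return out
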