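"""Ornstein-Uhlenbeck process: exact sampling and closed-form statistics.

Convention: dX = -lambda X dt + sqrt(2 D) dW, so that

* stationary variance        Var_inf = D / lambda,
* variance from a point      Var(t | X0) = (D/lambda) (1 - exp(-2 lambda t)),
* conditional mean square    G(0, dt) = Var(dt | 0)
                                      = (D/lambda) (1 - exp(-2 lambda dt)),

hence G grows as 2 D dt for dt << 1/lambda.  Note that conditioning on the
starting value makes G(0, dt) saturate at the stationary variance D/lambda,
half the unconditioned mean squared displacement 2 Var_inf (1 - e^(-lam dt)).
These are the reference statistics against which the drift/diffusion
estimators are validated and to which measured attractor trajectories are
fitted.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_ou", "ou_g", "ou_variance", "ou_mean"]


def simulate_ou(lam: float, D: float, dt: float, n_steps: int, n_paths: int = 1,
                x0=0.0, stationary_start: bool = False, seed: int = 0) -> np.ndarray:
    """Exactly sampled OU paths, shape (n_paths, n_steps + 1).

    Uses the exact transition density X(t+dt) | X(t) ~ Normal(X mu,
    (D/lam)(1 - mu^2)) with mu = exp(-lam dt); no discretization error.
    """
    if lam <= 0 or D <= 0 or dt <= 0:
        raise ValueError("lam, D and dt must be positive")
    rng = np.random.default_rng(seed)
    mu = np.exp(-lam * dt)
    sd = np.sqrt(D / lam * (1.0 - mu * mu))
    x = np.empty((n_paths, n_steps + 1))
    if stationary_start:
        x[:, 0] = rng.normal(0.0, np.sqrt(D / lam), size=n_paths)
    else:
        x[:, 0] = x0
    z = rng.standard_normal((n_paths, n_steps))
    for k in range(n_steps):
        x[:, k + 1] = x[:, k] * mu + sd * z[:, k]
    return x


def ou_mean(lam: float, t, x0: float) -> np.ndarray:
    """Conditional mean from X(0) = x0."""
    return x0 * np.exp(-lam * np.asarray(t, float))


def ou_variance(lam: float, D: float, t) -> np.ndarray:
    """Variance at time t of paths started from a common point."""
    return D / lam * (1.0 - np.exp(-2.0 * lam * np.asarray(t, float)))


def ou_g(lam: float, D: float, dt) -> np.ndarray:
    """Conditional mean-square displacement G(0, dt) = Var(dt | X=0)."""
    return D / lam * (1.0 - np.exp(-2.0 * lam * np.asarray(dt, float)))
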