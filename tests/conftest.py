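"""Shared fixtures.

The heavy session fixtures run the coupled and single balanced networks at
desk scale once and are shared by the simulator, statistics and acceptance
tests.  All randomness is seeded; reruns are deterministic.
"""

import numpy as np
import pytest

from balnet import NetworkParams, build_connectivity, init_state, run
from balnet import meanfield as mf
from balnet import attractor_stats as stats
from balnet.diffusion_theory import single_fixed_point

K_DESK = 100
#: mean-field slow-rate setting of the weakly tuned coupling used by the
#: stochastic suites; the realized (finite-N) rate is slower than -1/tau
#: but faster than the mean-field value (see docs/methods.md)
LAMBDA_MF = -1.0 / 50.0
N_LIST = (4000, 8000, 16000)
TRIALS = 6
DURATION = 8_000.0  # ms per trial


@pytest.fixture(scope="session")
def weak_tuning():
    """Coupling J~ set for a mean-field slow rate of -1/50 ms at K=100."""
    p = NetworkParams(N=8000, K=K_DESK)
    jt = mf.tune_to_rate(p, K_DESK, LAMBDA_MF)
    p = p.with_(J_tilde=jt)
    basis = mf.projection_basis(p, K_DESK)
    return p, basis


def _coupled_trial(p, tr, duration, dt_rec, **kw):
    pt = p.with_(connectivity_seed=11 + tr, schedule_seed=211 + tr,
                 init_seed=311 + tr)
    conn = build_connectivity(pt)
    state = init_state(conn, pt, mode="attractor")
    _, _, state = run(state, conn, pt, 500.0, dt_rec=500.0)
    return run(state, conn, pt, duration, dt_rec=dt_rec, **kw)


@pytest.fixture(scope="session")
def coupled_suite(weak_tuning):
    """Resting-state runs of the weakly tuned coupled network, three sizes.

    For each N: TRIALS independent realizations (fresh connectivity,
    schedule and initial state), population activities at 1 ms resolution,
    and the projections X on the slow direction.
    """
    p0, basis = weak_tuning
    out = {}
    for N in N_LIST:
        p = p0.with_(N=N)
        traces_m, traces_X = [], []
        for tr in range(TRIALS):
            trace, _, _ = _coupled_trial(p, tr, DURATION, 1.0)
            traces_m.append(trace.m)
            traces_X.append(stats.project(trace, basis))
        out[N] = dict(params=p, m=traces_m, X=traces_X, dt=1.0)
    return out


@pytest.fixture(scope="session")
def fine_run(weak_tuning):
    """One finely sampled run (dt = tau_E/40) with neuron states and spikes.

    Used for the single-neuron autocorrelation, the short-lag diffusion
    prediction, and ISI statistics.
    """
    p0, basis = weak_tuning
    p = p0.with_(N=8000)
    trace, spikes, _ = _coupled_trial(p, 0, 4_000.0, 0.25,
                                      record_neurons=800, record_spikes=60)
    return dict(params=p, basis=basis, trace=trace, spikes=spikes)


@pytest.fixture(scope="session")
def isi_run(weak_tuning):
    """A 16 s resting run recording 400 spike trains per population.

    Long enough that low-rate neurons accumulate the spikes needed for
    per-neuron inter-spike-interval statistics (shorter records select the
    high-rate neurons, biasing the CV downward).
    """
    p0, _ = weak_tuning
    p = p0.with_(N=8000)
    _, spikes, _ = _coupled_trial(p, 0, 16_000.0, 1000.0, record_spikes=400)
    return dict(params=p, spikes=spikes, n_recorded=400)


@pytest.fixture(scope="session")
def single_suite(weak_tuning):
    """Single balanced networks (J~ = 0) at the coupled network's drive.

    The drive equals the mean input each subnetwork receives at the
    coupled symmetric fixed point, E_in = E0 - J~ m_I.  With J~ = 0 the two
    subnetworks decouple, so each run yields two independent single-network
    realizations (populations (1,2) and (3,4)).
    """
    p0, _ = weak_tuning
    fp = mf.solve_fixed_point(p0, K_DESK)
    E_in = p0.E0 - p0.J_tilde * fp.m[3]
    out = {"E_in": E_in, "coupled_fp": fp}
    for N in (4000, 8000):
        p = p0.with_(N=N, J_tilde=0.0, E0=E_in, connectivity_seed=21,
                     schedule_seed=22, init_seed=23)
        m2 = single_fixed_point(p, E_in, K_DESK)
        conn = build_connectivity(p)
        state = init_state(conn, p, mode="random",
                           m_target=[m2[0], m2[1], m2[0], m2[1]])
        _, _, state = run(state, conn, p, 500.0, dt_rec=500.0)
        trace, _, _ = run(state, conn, p, 30_000.0, dt_rec=1.0)
        out[N] = dict(params=p, m=trace.m, dt=1.0, mf_point=m2)
    return out


@pytest.fixture(scope="session")
def small_net():
    """A small coupled network for fast mechanistic checks."""
    p = NetworkParams(N=1000, K=50, connectivity_seed=5, schedule_seed=6,
                      init_seed=7)
    conn = build_connectivity(p)
    return p, conn
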