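"""Event-driven asynchronous simulation of the binary-neuron dynamics.

Neurons are updated at Poisson times (mean interval tau_E for excitatory,
tau_I for inhibitory neurons); at each update sigma = Theta(u) with u the
total weighted input

    u = sum over synapses + sqrt(K)*E0 - T   (+ cross inhibition + noise),

where the all-to-all cross inhibition -J~*sqrt(K)*m_opp is evaluated
exactly from the opposing population count and the optional shared input
noise is an Ornstein-Uhlenbeck process propagated exactly between events.
The tie-break Theta(0) = 0 is fixed by convention.

Cached per-neuron inputs hold the recurrent-plus-constant part of u; the
population-count cross term and the noise are added at evaluation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .params import NetworkParams
from .connectivity import Connectivity
from ._kernels import run_kernel

__all__ = [
    "NetworkState",
    "PopulationTrace",
    "SpikeRecord",
    "init_state",
    "run",
    "step_event",
    "flip_neuron",
    "recompute_inputs_bruteforce",
    "cached_input_error",
    "isi_statistics",
]


@dataclass
class NetworkState:
    """Binary states, cached inputs and simulation clock."""

    sigma: np.ndarray           # int8, 4N
    u: np.ndarray               # float64, 4N: recurrent + sqrt(K)E0 - T
    counts: np.ndarray          # int64, 4
    t: float = 0.0
    xi: np.ndarray = field(default_factory=lambda: np.zeros(2))
    run_count: int = 0

    def m(self) -> np.ndarray:
        """Population mean activities."""
        N = self.sigma.shape[0] // 4
        return self.counts / N

    def copy(self) -> "NetworkState":
        return NetworkState(self.sigma.copy(), self.u.copy(), self.counts.copy(),
                            self.t, self.xi.copy(), self.run_count)


@dataclass
class PopulationTrace:
    """Population activities sampled on a uniform grid.

    ``neuron_gids``/``neuron_states`` optionally carry binary-state samples
    of a recorded neuron subset on the same grid.
    """

    times: np.ndarray            # ms
    m: np.ndarray                # (n_samples, 4)
    neuron_gids: Optional[np.ndarray] = None
    neuron_states: Optional[np.ndarray] = None   # int8 (n_samples, n_rec)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else math.nan

    def states_of_population(self, population: int, N: int) -> np.ndarray:
        """Recorded state samples restricted to one population."""
        if self.neuron_gids is None:
            raise ValueError("no neuron states were recorded")
        sel = (self.neuron_gids // N) == population
        return self.neuron_states[:, sel]


@dataclass
class SpikeRecord:
    """0 -> 1 transitions as (time, population, neuron index) triples."""

    times: np.ndarray
    populations: np.ndarray
    indices: np.ndarray
    overflow: bool = False

    def __len__(self) -> int:
        return len(self.times)

    def of_neuron(self, population: int, index: int) -> np.ndarray:
        sel = (self.populations == population) & (self.indices == index)
        return self.times[sel]


# ---------------------------------------------------------------------------

def _base_input(params: NetworkParams) -> np.ndarray:
    """Constant part sqrt(K)*E0_p - T_p per neuron."""
    N = params.N
    base = np.empty(4 * N)
    for p in range(4):
        base[p * N:(p + 1) * N] = params.sqrtK * params.E0_pop[p] - params.T[p]
    return base


def _line_activities(x: float, params: NetworkParams) -> np.ndarray:
    """Line-parametrization activities used for initialization (valid for
    0 < x < J_I*E0/(J_E-J_I), independent of the actual J~)."""
    if not (0.0 < x < params.x_max):
        raise ValueError(f"x={x} outside the valid line range (0, {params.x_max})")
    JI, E0, dJ = params.J_I, params.E0, params.J_E - params.J_I
    return np.array([x, x / JI, -x + JI * E0 / dJ, -x / JI + E0 / dJ])


def init_state(
    conn: Connectivity,
    params: NetworkParams,
    mode: str = "attractor",
    m_target=None,
    x: Optional[float] = None,
    seed: Optional[int] = None,
    mirror: bool = False,
) -> NetworkState:
    """Draw an initial state with target population activities.

    ``mode="random"`` draws each sigma Bernoulli with probability
    ``m_target[p]``; ``mode="attractor"`` targets the line activities at
    position ``x`` (default: the symmetric point).  With ``mirror=True``
    subnetwork 2 starts as an exact copy of subnetwork 1 (requires a
    symmetric target), so that with mirrored connectivity and a mirrored
    schedule the subnetwork symmetry is exact for all time.  Cached inputs
    are computed by brute force.  Deterministic given ``init_seed``.
    """
    N = params.N
    if mode == "attractor":
        xx = params.x_symmetric if x is None else float(x)
        m_target = _line_activities(xx, params)
    elif mode == "random":
        if m_target is None:
            raise ValueError("random mode requires m_target")
        m_target = np.asarray(m_target, dtype=float)
        if np.any(m_target < 0) or np.any(m_target > 1):
            raise ValueError("m_target must lie in [0, 1]^4")
    else:
        raise ValueError(f"unknown init mode {mode!r}")

    rng = np.random.default_rng(params.init_seed if seed is None else seed)
    sigma = np.empty(4 * N, dtype=np.int8)
    if mirror:
        if not (np.isclose(m_target[0], m_target[2])
                and np.isclose(m_target[1], m_target[3])):
            raise ValueError("mirror init requires a symmetric target")
        for p in range(2):
            sigma[p * N:(p + 1) * N] = rng.random(N) < m_target[p]
        sigma[2 * N:4 * N] = sigma[0:2 * N]
    else:
        for p in range(4):
            sigma[p * N:(p + 1) * N] = rng.random(N) < m_target[p]
    counts = np.array([int(sigma[p * N:(p + 1) * N].sum()) for p in range(4)],
                      dtype=np.int64)
    W = conn.to_sparse()
    u = np.asarray(W.T @ sigma.astype(np.float64)) + _base_input(params)
    return NetworkState(sigma=sigma, u=u, counts=counts, t=0.0)


def run(
    state: NetworkState,
    conn: Connectivity,
    params: NetworkParams,
    duration: float,
    dt_rec: float = 1.0,
    record_neurons: int = 0,
    record_spikes: int = 0,
    mirrored_schedule: bool = False,
    schedule_seed: Optional[int] = None,
    refresh_every: int = 1_000_000,
) -> Tuple[PopulationTrace, SpikeRecord, NetworkState]:
    """Advance the network by ``duration`` ms.

    Population activities are sampled every ``dt_rec`` ms (value at the most
    recent event before each sample time).  ``record_neurons`` binary states
    and ``record_spikes`` spike trains are recorded for the first so-many
    neurons of every population.  The update schedule is deterministic given
    the schedule seed; consecutive calls on the same state continue with
    fresh, reproducible schedule segments.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    N = params.N
    st = state.copy()
    n_samples = int(math.floor(duration / dt_rec + 1e-9)) + 1
    rec_m = np.empty((n_samples, 4))
    if record_neurons > 0:
        gids = np.concatenate([p * N + np.arange(min(record_neurons, N))
                               for p in range(4)]).astype(np.int64)
    else:
        gids = np.empty(0, dtype=np.int64)
    rec_states = np.empty((n_samples, len(gids)), dtype=np.int8)

    tau_min = min(params.tau_E, params.tau_I)
    spk_cap = int(4 * record_spikes * duration / tau_min * 1.2) + 1024 \
        if record_spikes > 0 else 0
    spk_t = np.empty(spk_cap)
    spk_p = np.empty(spk_cap, dtype=np.int8)
    spk_i = np.empty(spk_cap, dtype=np.int32)

    base_seed = params.schedule_seed if schedule_seed is None else schedule_seed
    seed = int((base_seed + 40503 * st.run_count) % (2**32))

    cross_coef = params.J_tilde * params.sqrtK / N \
        if params.cross_mode == "all_to_all" else 0.0
    noise_on = params.noise_enabled

    t_end, n_written, n_spk, n_ev, overflow = run_kernel(
        st.sigma, st.u, st.counts, conn.indptr, conn.targets, conn.weights,
        N, params.tau_E, params.tau_I, params.sqrtK, cross_coef,
        st.t, float(duration),
        float(dt_rec), rec_m,
        gids, rec_states,
        record_spikes, spk_t, spk_p, spk_i,
        mirrored_schedule,
        noise_on, params.noise_shared,
        params.tau_noise if noise_on else 1.0,
        params.sigma_noise, st.xi,
        refresh_every, _base_input(params), seed,
    )
    st.t = t_end
    st.run_count += 1

    times = state.t + np.arange(n_written) * dt_rec
    trace = PopulationTrace(
        times=times, m=rec_m[:n_written],
        neuron_gids=gids if record_neurons > 0 else None,
        neuron_states=rec_states[:n_written] if record_neurons > 0 else None,
    )
    spikes = SpikeRecord(times=spk_t[:n_spk].copy(), populations=spk_p[:n_spk].copy(),
                         indices=spk_i[:n_spk].copy(), overflow=bool(overflow))
    return trace, spikes, st


# ---------------------------------------------------------------------------
# Reference single-event step (pure Python, used for small-scale testing)

def step_event(
    state: NetworkState,
    conn: Connectivity,
    params: NetworkParams,
    rng: np.random.Generator,
) -> Optional[Tuple[float, int, int]]:
    """Advance the clock by one exponential waiting time and update one neuron.

    Mirrors the compiled event loop's mechanics (global clock with total
    rate 2N/tau_E + 2N/tau_I, categorical population choice, strict
    threshold Theta(0) = 0).  Returns (time, population, index) if the
    update produced a spike (0 -> 1 flip), else None.  Mutates ``state``.
    """
    N = params.N
    rate_E, rate_I = 2 * N / params.tau_E, 2 * N / params.tau_I
    total = rate_E + rate_I
    state.t += rng.exponential(1.0 / total)
    ptype = 0 if rng.random() * total < rate_E else 1
    i = int(rng.integers(N))
    p = ptype + 2 * (1 if rng.random() < 0.5 else 0)

    g = p * N + i
    ue = state.u[g]
    if params.cross_mode == "all_to_all":
        cc = params.J_tilde * params.sqrtK / N
        if p == 0:
            ue -= cc * state.counts[3]
        elif p == 2:
            ue -= cc * state.counts[1]
    new = 1 if ue > 0.0 else 0
    if new != state.sigma[g]:
        _apply_flip(state, conn, p, i, new)
        if new == 1:
            return (state.t, p, i)
    return None


def _apply_flip(state: NetworkState, conn: Connectivity, p: int, i: int, new: int):
    N = state.sigma.shape[0] // 4
    g = p * N + i
    delta = 1.0 if new == 1 else -1.0
    state.sigma[g] = new
    state.counts[p] += 1 if new == 1 else -1
    tgt, w = conn.synapses_of(p, i)
    state.u[tgt] += delta * w


def flip_neuron(state: NetworkState, conn: Connectivity, population: int, index: int
                ) -> NetworkState:
    """Toggle one neuron's state, propagating to cached inputs and counts.

    Used to build perturbed-replica ensembles that share an update schedule.
    Returns a new state; the input is not modified.
    """
    N = state.sigma.shape[0] // 4
    if not (0 <= population < 4 and 0 <= index < N):
        raise IndexError(f"neuron ({population}, {index}) out of range")
    st = state.copy()
    g = population * N + index
    _apply_flip(st, conn, population, index, 1 - int(st.sigma[g]))
    return st


# ---------------------------------------------------------------------------
# Brute-force oracles

def recompute_inputs_bruteforce(
    state: NetworkState, conn: Connectivity, params: NetworkParams,
) -> np.ndarray:
    """Total input per neuron by direct summation over all synapses.

    Includes the constant drive sqrt(K)*E0 - T and, in all-to-all cross
    mode, the exact implicit term -J~*sqrt(K)*m_opp for excitatory neurons
    (input noise is not part of the deterministic input sum).
    """
    N = params.N
    W = conn.to_sparse()
    u = np.asarray(W.T @ state.sigma.astype(np.float64)) + _base_input(params)
    if params.cross_mode == "all_to_all":
        cc = params.J_tilde * params.sqrtK / N
        u[0:N] -= cc * state.counts[3]
        u[2 * N:3 * N] -= cc * state.counts[1]
    return u


def cached_input_error(state: NetworkState, conn: Connectivity, params: NetworkParams
                       ) -> float:
    """Max abs deviation of the cached inputs from the brute-force sum."""
    N = params.N
    u_ref = recompute_inputs_bruteforce(state, conn, params)
    u = state.u.copy()
    if params.cross_mode == "all_to_all":
        cc = params.J_tilde * params.sqrtK / N
        u[0:N] -= cc * state.counts[3]
        u[2 * N:3 * N] -= cc * state.counts[1]
    return float(np.max(np.abs(u - u_ref)))


def isi_statistics(spikes: SpikeRecord, population: int, n_neurons: int,
                   min_spikes: int = 20):
    """Per-neuron inter-spike-interval mean and CV for recorded neurons.

    Returns (means, cvs) over neurons with at least ``min_spikes`` spikes.
    """
    means, cvs = [], []
    for i in range(n_neurons):
        t = spikes.of_neuron(population, i)
        if len(t) >= min_spikes:
            isi = np.diff(t)
            means.append(isi.mean())
            cvs.append(isi.std(ddof=1) / isi.mean())
    return np.array(means), np.array(cvs)
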