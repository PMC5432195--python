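"""Compiled event loop for the asynchronous binary-neuron dynamics.

One global exponential clock with total rate sum_p N/tau_p drives the
updates (Gillespie-style): each event picks a population proportionally to
its rate and a neuron uniformly within it, then sets sigma = Theta(u) with
the strict convention Theta(0) = 0.  On a flip, the change is propagated
additively to the cached inputs of all postsynaptic neurons; a full
brute-force refresh of the cache every ``refresh_every`` events caps the
accumulated floating-point drift.

In mirrored-schedule mode each event applies the sampled (population
parity, neuron index) to both subnetworks at the same time, which together
with mirrored connectivity makes the subnetwork symmetry exact.
"""

import numpy as np
from numba import njit

__all__ = ["run_kernel"]


@njit(cache=True)
def _refresh_inputs(sigma, u, indptr, targets, weights, base):
    for g in range(u.shape[0]):
        u[g] = base[g]
    for g in range(sigma.shape[0]):
        if sigma[g] == 1:
            for k in range(indptr[g], indptr[g + 1]):
                u[targets[k]] += weights[k]


@njit(cache=True)
def _eval_input(u, g, p, counts, cross_coef, sqrtK, noise_on, noise_shared, xi):
    ue = u[g]
    if cross_coef != 0.0:
        if p == 0:
            ue -= cross_coef * counts[3]
        elif p == 2:
            ue -= cross_coef * counts[1]
    if noise_on and (p == 0 or p == 2):
        if noise_shared or p == 0:
            ue += sqrtK * xi[0]
        else:
            ue += sqrtK * xi[1]
    return ue


@njit(cache=True)
def _update_neuron(sigma, u, counts, indptr, targets, weights, N, p, i,
                   cross_coef, sqrtK, noise_on, noise_shared, xi):
    """Apply one asynchronous update; returns +1 on a 0->1 flip (a spike),
    -1 on a 1->0 flip, 0 if the state is unchanged."""
    g = p * N + i
    ue = _eval_input(u, g, p, counts, cross_coef, sqrtK, noise_on, noise_shared, xi)
    new = 1 if ue > 0.0 else 0      # Theta(0) = 0
    old = sigma[g]
    if new == old:
        return 0
    delta = 1.0 if new == 1 else -1.0
    sigma[g] = new
    counts[p] += new - old
    for k in range(indptr[g], indptr[g + 1]):
        u[targets[k]] += delta * weights[k]
    return 1 if new == 1 else -1


@njit(cache=True)
def run_kernel(sigma, u, counts, indptr, targets, weights,
               N, tau_E, tau_I, sqrtK, cross_coef,
               t_start, duration,
               dt_rec, rec_m,                      # (n_samples, 4)
               rec_gids, rec_states,               # (n_rec,), (n_samples, n_rec)
               n_spike_per_pop, spk_t, spk_p, spk_i,
               mirrored_sched,
               noise_on, noise_shared, tau_noise, sig_noise, xi,
               refresh_every, base, seed):
    """Run the event loop for ``duration`` ms.  Returns
    (t_end, n_samples_written, n_spikes, n_events, overflow_flag)."""
    np.random.seed(seed)
    if mirrored_sched:
        rate_E = N / tau_E
        rate_I = N / tau_I
    else:
        rate_E = 2.0 * N / tau_E
        rate_I = 2.0 * N / tau_I
    total = rate_E + rate_I
    scale = 1.0 / total

    n_samples = rec_m.shape[0]
    n_rec = rec_gids.shape[0]
    spk_cap = spk_t.shape[0]
    t_end = t_start + duration

    t = t_start
    isamp = 0
    n_spk = 0
    n_ev = 0
    overflow = 0

    # note: assigning a loop-carried variable right before `break` inside a
    # `while True` miscompiles on some numba versions; the loop below only
    # ever advances t via `t = tn`
    while True:
        dt = np.random.exponential(scale)
        tn = t + dt
        if tn > t_end:
            # flush remaining samples (state is constant past the last event)
            while isamp < n_samples and t_start + isamp * dt_rec <= t_end:
                for p in range(4):
                    rec_m[isamp, p] = counts[p] / N
                for k in range(n_rec):
                    rec_states[isamp, k] = sigma[rec_gids[k]]
                isamp += 1
            break
        if noise_on:
            mu = np.exp(-dt / tau_noise)
            sd = sig_noise / np.sqrt(2.0 * tau_noise) * np.sqrt(1.0 - mu * mu)
            xi[0] = xi[0] * mu + sd * np.random.standard_normal()
            if noise_shared:
                xi[1] = xi[0]
            else:
                xi[1] = xi[1] * mu + sd * np.random.standard_normal()
        # emit samples falling strictly before the next event
        while isamp < n_samples and t_start + isamp * dt_rec <= tn:
            for p in range(4):
                rec_m[isamp, p] = counts[p] / N
            for k in range(n_rec):
                rec_states[isamp, k] = sigma[rec_gids[k]]
            isamp += 1
        t = tn

        r = np.random.random() * total
        ptype = 0 if r < rate_E else 1
        i = np.random.randint(0, N)
        if mirrored_sched:
            for p in (ptype, ptype + 2):
                res = _update_neuron(sigma, u, counts, indptr, targets, weights,
                                     N, p, i, cross_coef, sqrtK,
                                     noise_on, noise_shared, xi)
                if res == 1 and i < n_spike_per_pop:
                    if n_spk < spk_cap:
                        spk_t[n_spk] = t
                        spk_p[n_spk] = p
                        spk_i[n_spk] = i
                        n_spk += 1
                    else:
                        overflow = 1
        else:
            # second fair coin chooses the subnetwork
            p = ptype + 2 * (1 if np.random.random() < 0.5 else 0)
            res = _update_neuron(sigma, u, counts, indptr, targets, weights,
                                 N, p, i, cross_coef, sqrtK,
                                 noise_on, noise_shared, xi)
            if res == 1 and i < n_spike_per_pop:
                if n_spk < spk_cap:
                    spk_t[n_spk] = t
                    spk_p[n_spk] = p
                    spk_i[n_spk] = i
                    n_spk += 1
                else:
                    overflow = 1

        n_ev += 1
        if refresh_every > 0 and n_ev % refresh_every == 0:
            _refresh_inputs(sigma, u, indptr, targets, weights, base)

    return t_end, isamp, n_spk, n_ev, overflow
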