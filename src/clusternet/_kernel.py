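"""Numba event loop for the asynchronous binary-network simulation.

Continuous-time scheduling: the total update rate is
``Lambda = N_E/tau_E + N_I/tau_I``; waiting times between updates are
``Exp(1/Lambda)``, the population of the updated unit is drawn proportional
to ``N_a/tau_a`` and the unit uniformly within it.  Each unit's own update
times then form a Poisson process of rate ``1/tau_a`` (exponential
inter-update intervals with mean ``tau_a``), and the population update-
probability ratio is ``P_UE/P_UI = tau_I/tau_E``.

On an update the unit's state becomes ``Theta(h_i - theta_a + J_aX m_X)``
where ``h_i`` is its recurrent input, maintained incrementally: when unit j
flips, ``h`` is adjusted along j's outgoing synapses (CSC columns).
"""

import numpy as np
from numba import njit

__all__ = ["run_events"]


@njit(cache=False)
def run_events(indptr, indices, data, n_exc, N, tau_E, tau_I, T,
               theta_E, theta_I, ext_E, ext_I, init_up_prob, seed,
               record_updates):
    """Simulate for ``T`` ms; return initial state and the flip-event log.

    Returns
    -------
    sigma0 : (N,) int8 initial states
    ev_t, ev_unit, ev_state : flip events (time ms, unit id, new state)
    up_t, up_unit : all update events (empty unless ``record_updates``)
    """
    np.random.seed(seed)
    sigma = np.empty(N, dtype=np.int8)
    for i in range(N):
        sigma[i] = 1 if np.random.random() < init_up_prob else 0
    sigma0 = sigma.copy()
    h = np.zeros(N)
    for j in range(N):
        if sigma[j] == 1:
            for k in range(indptr[j], indptr[j + 1]):
                h[indices[k]] += data[k]

    lam_E = n_exc / tau_E
    lam_I = (N - n_exc) / tau_I
    lam = lam_E + lam_I
    p_E = lam_E / lam

    cap = int(lam * T) + 16
    ev_t = np.empty(cap)
    ev_unit = np.empty(cap, dtype=np.int32)
    ev_state = np.empty(cap, dtype=np.int8)
    n_ev = 0
    if record_updates:
        up_t = np.empty(cap)
        up_unit = np.empty(cap, dtype=np.int32)
    else:
        up_t = np.empty(0)
        up_unit = np.empty(0, dtype=np.int32)
    n_up = 0

    t = 0.0
    while True:
        t += np.random.exponential(1.0 / lam)
        if t >= T or n_ev >= cap:
            break
        if np.random.random() < p_E:
            i = np.random.randint(0, n_exc)
            inp = h[i] - theta_E + ext_E
        else:
            i = n_exc + np.random.randint(0, N - n_exc)
            inp = h[i] - theta_I + ext_I
        if record_updates and n_up < cap:
            up_t[n_up] = t
            up_unit[n_up] = i
            n_up += 1
        if not np.isfinite(inp):
            raise FloatingPointError("non-finite input encountered")
        new = 1 if inp > 0.0 else 0
        if new != sigma[i]:
            sigma[i] = new
            ev_t[n_ev] = t
            ev_unit[n_ev] = i
            ev_state[n_ev] = new
            n_ev += 1
            d = 1.0 if new == 1 else -1.0
            for k in range(indptr[i], indptr[i + 1]):
                h[indices[k]] += d * data[k]
    return (sigma0, ev_t[:n_ev], ev_unit[:n_ev], ev_state[:n_ev],
            up_t[:n_up], up_unit[:n_up])
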