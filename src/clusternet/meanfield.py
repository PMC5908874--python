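"""Population-level (mean-field) reduction and rate dynamics.

Any architecture is represented as ``P`` homogeneous populations.  The mean
input to population ``a`` at rates ``m`` is

    mu_a = sum_b Jbar_ab m_b + J_aX m_X - theta_a,
    Jbar_ab = j_ab p_ab n_b sqrt(N) (cluster multipliers folded in)

and, neglecting input correlations, the input variance is carried by the
Bernoulli variance of the realised weights,

    s2_a = sum_b Jbar2_ab m_b,
    Jbar2_ab = p_ab (1 - p_ab) j_ab^2 n_b (squared multipliers folded in).

The rates evolve as

    tau_a dm_a/dt = -m_a + H(-mu_a / s_a)

with ``H`` the upper tail of the standard normal; fixed points satisfy
``m_a = H(-mu_a/s_a)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

from .balance import BalanceWeights, NetworkSpec, derive_weights
from .connectivity import ClusterSpec, probability_clustering

__all__ = [
    "PopulationSystem",
    "RateState",
    "InputMoments",
    "Trajectory",
    "gain_H",
    "input_moments",
    "rate_derivative",
    "integrate_rates",
    "reduce_network",
]


def gain_H(z):
    """Upper tail of the standard normal, ``H(z) = P(X > z)``.

    Strictly decreasing, numerically stable over the whole double range
    (no catastrophic cancellation for large ``|z|``); accepts +-inf.
    """
    z = np.asarray(z, dtype=float)
    if np.any(np.isnan(z)):
        raise ValueError("gain_H received NaN input")
    out = special.ndtr(-z)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RateState:
    """Population rates ``m`` in [0,1]^P at time ``t`` (ms)."""

    m: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "m", m)
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class InputMoments:
    mu: np.ndarray
    s2: np.ndarray


@dataclass
class PopulationSystem:
    """Mean-field reduction: mean weights, weight variances, drives, clocks.

    ``labels`` identify populations, e.g. ``['E0', ..., 'E19', 'I']`` for an
    E-clustered system or ``['E0', ..., 'I0', ...]`` in EI mode; ``'Ebg'``
    marks an unstructured excitatory background.
    """

    sizes: np.ndarray          # per-population unit counts
    Jbar: np.ndarray           # (P, P) mean weights
    Jbar2: np.ndarray          # (P, P) weight variances, >= 0
    theta: np.ndarray          # per-population thresholds
    Jx: np.ndarray             # per-population external weights
    m_X: float                 # external drive rate
    tau: np.ndarray            # per-population time constants (ms)
    labels: list

    @property
    def P(self) -> int:
        return len(self.labels)

    @property
    def e_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l.startswith("E")])

    @property
    def i_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l.startswith("I")])

    @property
    def cluster_e_indices(self) -> np.ndarray:
        """Excitatory cluster populations (excludes a background population)."""
        return np.array(
            [i for i, l in enumerate(self.labels) if l.startswith("E") and l != "Ebg"]
        )

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes.tolist(),
            "Jbar": self.Jbar.tolist(),
            "Jbar2": self.Jbar2.tolist(),
            "theta": self.theta.tolist(),
            "Jx": self.Jx.tolist(),
            "m_X": self.m_X,
            "tau": self.tau.tolist(),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSystem":
        return cls(
            sizes=np.asarray(d["sizes"], dtype=float),
            Jbar=np.asarray(d["Jbar"], dtype=float),
            Jbar2=np.asarray(d["Jbar2"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            Jx=np.asarray(d["Jx"], dtype=float),
            m_X=float(d["m_X"]),
            tau=np.asarray(d["tau"], dtype=float),
            labels=list(d["labels"]),
        )


def _rates(state) -> np.ndarray:
    return state.m if isinstance(state, RateState) else np.asarray(state, dtype=float)


def input_moments(sys: PopulationSystem, state) -> InputMoments:
    """Mean and variance of the input to each population at rates ``m``."""
    m = _rates(state)
    if m.shape != (sys.P,):
        raise ValueError(f"rate vector has shape {m.shape}, expected ({sys.P},)")
    mu = sys.Jbar @ m + sys.Jx * sys.m_X - sys.theta
    s2 = sys.Jbar2 @ m
    return InputMoments(mu=mu, s2=s2)


def _gain_target(mu: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """H(-mu/s) with the degenerate s2=0 limit resolved as a step in mu."""
    out = np.empty_like(mu)
    zero = s2 <= 0.0
    if np.any(zero):
        out[zero] = np.where(mu[zero] > 0, 1.0, np.where(mu[zero] < 0, 0.0, 0.5))
    nz = ~zero
    out[nz] = gain_H(-mu[nz] / np.sqrt(s2[nz]))
    return out


def rate_derivative(sys: PopulationSystem, state) -> np.ndarray:
    """``dm/dt`` (per ms) of the population rate dynamics."""
    m = _rates(state)
    mom = input_moments(sys, m)
    return (-m + _gain_target(mom.mu, mom.s2)) / sys.tau


def fixed_point_residual(sys: PopulationSystem, state) -> np.ndarray:
    """``-m + H(-mu/s)``: zero at a steady state."""
    m = _rates(state)
    mom = input_moments(sys, m)
    return -m + _gain_target(mom.mu, mom.s2)


@dataclass
class Trajectory:
    t: np.ndarray              # (n,) times, ms
    m: np.ndarray              # (n, P) rates
    residual: float            # max |dm/dt * tau| at final state

    @property
    def final(self) -> RateState:
        return RateState(m=self.m[-1], t=float(self.t[-1]))

    def to_dataframe(self, labels=None):
        import pandas as pd
        cols = labels or [f"m_{i + 1}" for i in range(self.m.shape[1])]
        df = pd.DataFrame(self.m, columns=cols)
        df.insert(0, "t", self.t)
        return df


def integrate_rates(sys: PopulationSystem, state0, T: float,
                    dt: Optional[float] = None) -> Trajectory:
    """Explicit Euler integration of the rate dynamics for duration ``T`` ms.

    ``dt`` defaults to ``0.05 * min(tau)`` and must not exceed
    ``0.1 * min(tau)``.  The dynamics are self-limiting, so trajectories stay
    in [0,1]^P (a defensive clip guards rounding).
    """
    m = _rates(state0).copy()
    t0 = state0.t if isinstance(state0, RateState) else 0.0
    if dt is None:
        dt = 0.05 * float(np.min(sys.tau))
    if dt > 0.1 * float(np.min(sys.tau)) + 1e-15:
        raise ValueError("dt must be <= 0.1 * min(tau) for stable integration")
    n = max(int(round(T / dt)), 0)
    traj = np.empty((n + 1, sys.P))
    times = t0 + dt * np.arange(n + 1)
    traj[0] = m
    for k in range(n):
        m = m + dt * rate_derivative(sys, m)
        if not np.all(np.isfinite(m)):
            raise FloatingPointError(
                f"non-finite rates during integration at step {k}"
            )
        np.clip(m, 0.0, 1.0, out=m)
        traj[k + 1] = m
    res = float(np.max(np.abs(fixed_point_residual(sys, m))))
    return Trajectory(t=times, m=traj, residual=res)


def reduce_network(spec: NetworkSpec, weights: Optional[BalanceWeights] = None,
                   cluster: Optional[ClusterSpec] = None) -> PopulationSystem:
    """Fold an architecture into its population-level system.

    Population counts: 2 (``none``), ``Q+1`` (E-clustered or
    probability-clustered), ``Q+2`` (background variant), ``2Q``
    (EI-clustered).  The cluster multipliers enter ``Jbar`` linearly and
    ``Jbar2`` squared; for probability clustering the within/across
    probabilities replace ``p_EE`` blockwise.
    """
    if weights is None:
        weights = derive_weights(spec)
    if cluster is None:
        cluster = ClusterSpec.from_spec(spec)
    mode = cluster.mode
    Q = cluster.Q
    N = spec.N

    if mode == "none":
        labels = ["E", "I"]
        sizes = np.array([spec.N_E, spec.N_I], dtype=float)
    elif mode in ("E_weights", "E_probability"):
        labels = [f"E{q}" for q in range(Q)] + ["I"]
        sizes = np.array([spec.N_E / Q] * Q + [spec.N_I], dtype=float)
    elif mode == "E_weights_background":
        n_bg = int(round(cluster.background_fraction * spec.N_E))
        labels = [f"E{q}" for q in range(Q)] + ["Ebg", "I"]
        sizes = np.array([(spec.N_E - n_bg) / Q] * Q + [n_bg, spec.N_I], dtype=float)
    elif mode == "EI_weights":
        labels = [f"E{q}" for q in range(Q)] + [f"I{q}" for q in range(Q)]
        sizes = np.array([spec.N_E / Q] * Q + [spec.N_I / Q] * Q, dtype=float)
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")

    P = len(labels)
    kind = ["E" if l.startswith("E") else "I" for l in labels]
    # cluster id per population; -1 for unclustered/background/global pools
    cid = []
    for l in labels:
        if l in ("E", "I", "Ebg"):
            cid.append(-1)
        else:
            cid.append(int(l[1:]))
    cid = np.array(cid)

    jmat = np.empty((P, P))
    pmat = np.empty((P, P))
    mult = np.ones((P, P))
    if mode == "E_probability":
        p_in, p_out = probability_clustering(Q, spec.p_EE, cluster.R_EE)
    for a in range(P):
        for b in range(P):
            ka, kb = kind[a], kind[b]
            jmat[a, b] = weights.j(ka, kb)
            pmat[a, b] = getattr(spec, f"p_{ka}{kb}")
            same = cid[a] >= 0 and cid[a] == cid[b]
            both_cluster = cid[a] >= 0 and cid[b] >= 0
            if ka == "E" and kb == "E":
                if mode == "E_probability" and both_cluster:
                    pmat[a, b] = p_in if same else p_out
                    if same:
                        mult[a, b] = cluster.prob_weight_factor
                elif mode in ("E_weights", "EI_weights", "E_weights_background"):
                    if both_cluster:
                        mult[a, b] = cluster.J_Eplus if same else cluster.J_Eminus
            elif mode == "EI_weights":
                mult[a, b] = cluster.J_Iplus if same else cluster.J_Iminus
    nb = sizes / N
    Jbar = mult * jmat * pmat * nb[None, :] * np.sqrt(N)
    Jbar2 = mult**2 * pmat * (1.0 - pmat) * jmat**2 * nb[None, :]
    theta = np.array([spec.theta_E if k == "E" else spec.theta_I for k in kind])
    Jx = np.array([spec.J_EX if k == "E" else spec.J_IX for k in kind])
    tau = np.array([spec.tau_E if k == "E" else spec.tau_I for k in kind])
    return PopulationSystem(sizes=sizes, Jbar=Jbar, Jbar2=Jbar2, theta=theta,
                            Jx=Jx, m_X=spec.m_X, tau=tau, labels=labels)
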