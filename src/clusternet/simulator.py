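"""Asynchronous binary-network simulation and rate statistics.

A unit's state sigma in {0, 1} is updated at random, exponentially
distributed times (mean interval ``tau_a``) to
``Theta(sum_j J_ij sigma_j - theta_i + J_aX m_X)``; the external drive is a
constant, not a spike source.  A *spike* is a 0 -> 1 transition.

Rate statistics: per-cluster mean activity rates are estimated per time bin
(default: time-averaged occupancy within the bin; optionally the state
sampled at the bin end), and the winnerless-competition statistic
``sigma^2_m`` is the variance of each cluster's rate over time after a
transient discard, averaged over clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._kernel import run_events
from .balance import NetworkSpec
from .connectivity import ClusterSpec, WeightMatrix, build_matrix

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "ClusterRateSeries",
    "simulate",
    "cluster_rates",
    "population_rates",
    "sigma2_m",
    "variance_sweep",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Run-length, binning and trial bookkeeping for simulations."""

    duration_ms: float = 1000.0
    bin_ms: float = 10.0
    discard_ms: float = 100.0
    init_up_prob: float = 0.5
    seed: int = 0
    n_trials: int = 1
    n_realizations: int = 1
    record_updates: bool = False  # log every update (for interval statistics)

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if not 0.0 <= self.init_up_prob <= 1.0:
            raise ValueError("init_up_prob must lie in [0, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SimulationResult:
    """Initial state plus the flip-event log of one trial.

    ``events_*`` hold state *changes* only; ``spike_times``/``spike_units``
    are the 0 -> 1 subset.  ``update_*`` hold every update event when
    ``record_updates`` was set.
    """

    initial_state: np.ndarray
    events_t: np.ndarray
    events_unit: np.ndarray
    events_state: np.ndarray
    duration_ms: float
    n_exc: int
    spec: NetworkSpec
    config: SimulationConfig
    cluster: Optional[ClusterSpec] = None
    update_t: Optional[np.ndarray] = None
    update_unit: Optional[np.ndarray] = None

    @property
    def N(self) -> int:
        return self.initial_state.size

    @property
    def spike_times(self) -> np.ndarray:
        return self.events_t[self.events_state == 1]

    @property
    def spike_units(self) -> np.ndarray:
        return self.events_unit[self.events_state == 1]

    def assignment(self, include_inhibitory: bool = False) -> np.ndarray:
        """Unit -> cluster map (-1 = not pooled) from the build-time geometry."""
        a = np.full(self.N, -1, dtype=np.int64)
        if self.cluster is not None and self.cluster.assignment_E is not None:
            a[: self.n_exc] = self.cluster.assignment_E
            if include_inhibitory and self.cluster.assignment_I is not None:
                Qe = int(self.cluster.assignment_E.max()) + 1
                a[self.n_exc:] = self.cluster.assignment_I + Qe
        return a


def simulate(matrix: WeightMatrix, spec: Optional[NetworkSpec] = None,
             config: SimulationConfig = SimulationConfig()) -> SimulationResult:
    """Run one trial on a realised weight matrix; reproducible given the seed."""
    spec = matrix.spec if spec is None else spec
    if matrix.N != spec.N or matrix.n_exc != spec.N_E:
        raise ValueError("matrix dimensions do not match the network spec")
    csc = matrix.to_csc()
    out = run_events(
        csc.indptr.astype(np.int64), csc.indices.astype(np.int32),
        csc.data.astype(np.float64),
        matrix.n_exc, matrix.N, float(spec.tau_E), float(spec.tau_I),
        float(config.duration_ms), float(spec.theta_E), float(spec.theta_I),
        float(spec.J_EX * spec.m_X), float(spec.J_IX * spec.m_X),
        float(config.init_up_prob), int(config.seed) % (2**31 - 1),
        config.record_updates,
    )
    sigma0, ev_t, ev_unit, ev_state, up_t, up_unit = out
    return SimulationResult(
        initial_state=sigma0, events_t=ev_t, events_unit=ev_unit,
        events_state=ev_state, duration_ms=config.duration_ms,
        n_exc=matrix.n_exc, spec=spec, config=config, cluster=matrix.cluster,
        update_t=up_t if config.record_updates else None,
        update_unit=up_unit if config.record_updates else None,
    )


@dataclass
class ClusterRateSeries:
    """Per-cluster mean activity rate per time bin; rows = bins."""

    t: np.ndarray              # bin end times (ms)
    rates: np.ndarray          # (n_bins, n_clusters)
    bin_ms: float
    sizes: np.ndarray          # units per cluster

    @property
    def n_clusters(self) -> int:
        return self.rates.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates,
                          columns=[f"cluster_{c}" for c in range(self.n_clusters)])
        df.insert(0, "t_ms", self.t)
        return df


def cluster_rates(result: SimulationResult, assignment=None,
                  bin_ms: Optional[float] = None,
                  method: str = "mean") -> ClusterRateSeries:
    """Pool unit states per cluster into binned mean activity rates.

    ``assignment`` maps unit index -> cluster id (-1 excludes a unit); by
    default the excitatory build-time assignment is used.  ``method="mean"``
    averages the instantaneous up-fraction over each bin (time-weighted
    occupancy); ``method="endpoint"`` samples the state at the bin end,
    i.e. the plain fraction of up units at that instant.
    """
    if assignment is None:
        assignment = result.assignment()
    assignment = np.asarray(assignment)
    if bin_ms is None:
        bin_ms = result.config.bin_ms
    n_clusters = int(assignment.max()) + 1
    if n_clusters < 1:
        raise ValueError("assignment defines no clusters")
    sizes = np.bincount(assignment[assignment >= 0], minlength=n_clusters)
    if np.any(sizes == 0):
        raise ValueError("assignment contains an empty cluster")
    n_bins = int(round(result.duration_ms / bin_ms))
    edges = bin_ms * np.arange(n_bins + 1)

    rates = np.empty((n_bins, n_clusters))
    for c in range(n_clusters):
        members = assignment == c
        up0 = int(result.initial_state[members].sum())
        in_c = members[result.events_unit]
        tk = result.events_t[in_c]
        dk = np.where(result.events_state[in_c] == 1, 1, -1)
        counts = up0 + np.concatenate([[0], np.cumsum(dk)])
        if method == "endpoint":
            idx = np.searchsorted(tk, edges[1:], side="right")
            rates[:, c] = counts[idx] / sizes[c]
        elif method == "mean":
            # cumulative integral of the up-count step function
            t_nodes = np.concatenate([[0.0], tk, [result.duration_ms]])
            I_nodes = np.concatenate(
                [[0.0], np.cumsum(counts[:-1] * np.diff(t_nodes[:-1]))])
            I_nodes = np.append(
                I_nodes, I_nodes[-1] + counts[-1] * (t_nodes[-1] - t_nodes[-2]))
            idx = np.searchsorted(tk, edges, side="right")
            I_edges = I_nodes[idx] + counts[idx] * (edges - t_nodes[idx])
            rates[:, c] = np.diff(I_edges) / (bin_ms * sizes[c])
        else:
            raise ValueError(f"unknown method {method!r}")
    return ClusterRateSeries(t=edges[1:], rates=rates, bin_ms=bin_ms,
                             sizes=sizes)


def population_rates(result: SimulationResult,
                     discard_ms: Optional[float] = None) -> tuple[float, float]:
    """Time-averaged activity rates ``(m_E, m_I)`` after the transient."""
    if discard_ms is None:
        discard_ms = result.config.discard_ms
    a = np.zeros(result.N, dtype=np.int64)
    a[result.n_exc:] = 1
    series = cluster_rates(result, a, bin_ms=result.config.bin_ms,
                           method="mean")
    keep = series.t > discard_ms
    mE, mI = series.rates[keep].mean(axis=0)
    return float(mE), float(mI)


def sigma2_m(series: ClusterRateSeries, discard_ms: float = 100.0) -> float:
    """Variance over time of each cluster's rate, averaged over clusters."""
    keep = series.t > discard_ms
    if not np.any(keep):
        raise ValueError("discard window leaves no bins")
    return float(series.rates[keep].var(axis=0).mean())


def variance_sweep(spec: NetworkSpec, mode: str = "E_weights",
                   R_J: float = 0.0, grid=None,
                   config: SimulationConfig = SimulationConfig(
                       n_trials=5, n_realizations=5)) -> pd.DataFrame:
    """Mean and sd of ``sigma^2_m`` versus clustering strength.

    For each grid value, ``n_realizations`` connectivity draws are simulated
    for ``n_trials`` trials each; seeds derive deterministically from
    ``config.seed``.
    """
    if grid is None:
        grid = np.arange(1.0, spec.Q + 0.05, 0.1)
    rows = []
    for v in np.asarray(grid, dtype=float):
        s = spec.replace(clustering_mode=mode, R_J=R_J, J_Eplus=float(v))
        vals = []
        for rz in range(config.n_realizations):
            mat = build_matrix(s, seed=config.seed + 1000 * rz + int(1e6 * v) % 997)
            for tr in range(config.n_trials):
                res = simulate(mat, s, config.replace(
                    seed=config.seed + 7919 * rz + tr + int(1e6 * v) % 65521))
                vals.append(sigma2_m(cluster_rates(res),
                                     discard_ms=config.discard_ms))
        rows.append({"sweep_value": v, "sigma2_m_mean": float(np.mean(vals)),
                     "sigma2_m_sd": float(np.std(vals, ddof=1)) if len(vals) > 1
                     else 0.0, "n": len(vals)})
    return pd.DataFrame(rows)
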