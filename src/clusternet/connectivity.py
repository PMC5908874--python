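"""Realised unit-level weight matrices for clustered balanced networks.

Connectivity is independent Bernoulli per ordered pair: the synapse from unit
``j`` (presynaptic, population ``b``) to unit ``i`` (population ``a``) equals
``J_ab`` with probability ``p_ab`` and 0 otherwise.  Clustering multiplies
within-cluster weights by ``J_+`` and across-cluster weights by

    J_- = (Q - J_+) / (Q - 1)

so that the expected row sum of each block is unchanged ("balance of
weights").  Supported architectures:

``none``
    Homogeneous two-population network.
``E_weights``
    The excitatory population is split into Q equal clusters; only E->E
    weights are modulated.
``EI_weights``
    Both populations are split into Q clusters; E->E weights use ``J_E+``
    while all blocks involving inhibition (E->I, I->E, I->I) share a single
    parameter ``J_I+ = 1 + R_J (J_E+ - 1)``, paired cluster-to-cluster.
``E_weights_background``
    A fraction of E units forms an unstructured background connecting with
    unmodified weights; the weight renormalisation applies among the
    clustered units only.
``E_probability``
    Clustering by connection probability: within-cluster probability
    ``p_in = R_EE * p_out`` with the block mean preserved, optionally with a
    within-cluster weight factor.

Self-connections are excluded (diagonal forced to zero); matrices are dense
below ``DENSE_LIMIT`` units and CSR-sparse above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .balance import BalanceWeights, NetworkSpec, derive_weights

__all__ = [
    "ClusterSpec",
    "WeightMatrix",
    "cluster_scaling",
    "probability_clustering",
    "build_matrix",
    "build_probability_clustered",
    "build_background_variant",
    "DENSE_LIMIT",
]

DENSE_LIMIT = 6_000

#: within-cluster weight factor used alongside probability clustering
#: (value taken from the construction this variant emulates; it does not
#: enter any quantitative acceptance surface)
PROBABILITY_WEIGHT_FACTOR = 1.9


def cluster_scaling(Q: int, J_plus: float) -> float:
    """Across-cluster multiplier ``J_- = (Q - J_+)/(Q - 1)``.

    ``J_+ = 1`` gives homogeneous connectivity (``J_- = 1``); ``J_+ = Q``
    decouples the clusters (``J_- = 0``).  Values above Q are computed but
    produce negative across-cluster weights (warned).
    """
    if Q < 2:
        raise ValueError(f"cluster scaling requires Q >= 2, got Q={Q}")
    if J_plus > Q:
        warnings.warn(
            f"J_plus={J_plus} exceeds Q={Q}: across-cluster weights become negative",
            stacklevel=2,
        )
    return (Q - J_plus) / (Q - 1)


def probability_clustering(Q: int, p_mean: float, R_EE: float) -> tuple[float, float]:
    """Within/across probabilities ``(p_in, p_out)`` with ``p_in = R_EE * p_out``
    and the block mean ``(p_in + (Q-1) p_out)/Q = p_mean`` preserved."""
    p_out = Q * p_mean / (R_EE + Q - 1.0)
    p_in = R_EE * p_out
    if p_in > 1.0:
        raise ValueError(
            f"probability clustering with R_EE={R_EE} gives p_in={p_in:.3f} > 1"
        )
    return p_in, p_out


@dataclass(frozen=True)
class ClusterSpec:
    """Cluster geometry and block multipliers of one architecture."""

    mode: str
    Q: int
    J_Eplus: float = 1.0
    J_Eminus: float = 1.0
    J_Iplus: float = 1.0
    J_Iminus: float = 1.0
    R_J: float = 0.0
    R_EE: float = 1.0
    prob_weight_factor: float = 1.0
    background_fraction: float = 0.0
    assignment_E: Optional[np.ndarray] = None  # unit -> cluster id, -1 background
    assignment_I: Optional[np.ndarray] = None

    @classmethod
    def from_spec(cls, spec: NetworkSpec) -> "ClusterSpec":
        mode = spec.clustering_mode
        Q = spec.Q
        if mode == "none":
            return cls(mode=mode, Q=1,
                       assignment_E=np.zeros(spec.N_E, dtype=np.int64),
                       assignment_I=np.zeros(spec.N_I, dtype=np.int64))
        JEp = spec.J_Eplus
        JEm = cluster_scaling(Q, JEp)
        if mode == "EI_weights":
            if spec.N_E % Q or spec.N_I % Q:
                raise ValueError(
                    f"N_E={spec.N_E} and N_I={spec.N_I} must both be divisible by Q={Q}"
                )
            JIp = 1.0 + spec.R_J * (JEp - 1.0)
            return cls(
                mode=mode, Q=Q, J_Eplus=JEp, J_Eminus=JEm,
                J_Iplus=JIp, J_Iminus=cluster_scaling(Q, JIp), R_J=spec.R_J,
                assignment_E=np.repeat(np.arange(Q), spec.N_E // Q),
                assignment_I=np.repeat(np.arange(Q), spec.N_I // Q),
            )
        if mode == "E_weights_background":
            n_bg = int(round(spec.background_fraction * spec.N_E))
            n_cl = spec.N_E - n_bg
            if n_cl % Q:
                raise ValueError(
                    f"clustered unit count {n_cl} not divisible by Q={Q}"
                )
            assignment = np.concatenate(
                [np.repeat(np.arange(Q), n_cl // Q), np.full(n_bg, -1)]
            )
            return cls(
                mode=mode, Q=Q, J_Eplus=JEp, J_Eminus=JEm,
                background_fraction=spec.background_fraction,
                assignment_E=assignment,
                assignment_I=np.zeros(spec.N_I, dtype=np.int64),
            )
        if mode in ("E_weights", "E_probability"):
            if spec.N_E % Q:
                raise ValueError(f"N_E={spec.N_E} must be divisible by Q={Q}")
            kw: dict = {}
            if mode == "E_probability":
                kw = dict(R_EE=spec.R_EE,
                          prob_weight_factor=PROBABILITY_WEIGHT_FACTOR,
                          J_Eplus=1.0, J_Eminus=1.0)
            else:
                kw = dict(J_Eplus=JEp, J_Eminus=JEm)
            return cls(
                mode=mode, Q=Q,
                assignment_E=np.repeat(np.arange(Q), spec.N_E // Q),
                assignment_I=np.zeros(spec.N_I, dtype=np.int64),
                **kw,
            )
        raise ValueError(f"unknown clustering mode {mode!r}")


@dataclass
class WeightMatrix:
    """Realised per-synapse weights, row = postsynaptic, column = presynaptic.

    Units ``0 .. n_exc-1`` are excitatory, the remainder inhibitory.
    """

    matrix: "np.ndarray | sp.spmatrix"
    n_exc: int
    cluster: ClusterSpec
    seed: int
    spec: NetworkSpec

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.matrix)

    def block(self, alpha: str, beta: str) -> np.ndarray:
        """Dense copy of the (post=alpha, pre=beta) block."""
        sl = {"E": slice(0, self.n_exc), "I": slice(self.n_exc, self.N)}
        blk = self.matrix[sl[alpha], sl[beta]]
        return blk.toarray() if sp.issparse(blk) else np.asarray(blk)

    def to_csc(self) -> sp.csc_matrix:
        """Column-compressed form (outgoing adjacency per presynaptic unit)."""
        return sp.csc_matrix(self.matrix)


def _pair_multiplier(cl_post, cl_pre, plus, minus):
    """Multiplier matrix for a block given cluster assignments (-1 = background)."""
    m = np.where(cl_post[:, None] == cl_pre[None, :], plus, minus)
    bg = (cl_post[:, None] < 0) | (cl_pre[None, :] < 0)
    return np.where(bg, 1.0, m)


def _block_profiles(spec: NetworkSpec, weights: BalanceWeights, cluster: ClusterSpec):
    """Per-block (probability matrix fn, weight matrix fn) descriptors.

    Returns dict keyed by (alpha, beta) of tuples (p_fn, w_fn) mapping
    (cl_post, cl_pre) -> arrays.  Keeps dense and sparse builders consistent.
    """
    J = {(a, b): weights.J(a, b) for a in "EI" for b in "EI"}
    p = {(a, b): getattr(spec, f"p_{a}{b}") for a in "EI" for b in "EI"}
    mode = cluster.mode

    def const(x):
        return lambda cp, cq: np.full((len(cp), len(cq)), x)

    prof = {}
    for a in "EI":
        for b in "EI":
            prof[(a, b)] = (const(p[(a, b)]), const(J[(a, b)]))

    if mode in ("E_weights", "E_weights_background"):
        prof[("E", "E")] = (
            const(p[("E", "E")]),
            lambda cp, cq: J[("E", "E")]
            * _pair_multiplier(cp, cq, cluster.J_Eplus, cluster.J_Eminus),
        )
    elif mode == "EI_weights":
        prof[("E", "E")] = (
            const(p[("E", "E")]),
            lambda cp, cq: J[("E", "E")]
            * _pair_multiplier(cp, cq, cluster.J_Eplus, cluster.J_Eminus),
        )
        for ab in (("E", "I"), ("I", "E"), ("I", "I")):
            Jab = J[ab]
            prof[ab] = (
                const(p[ab]),
                lambda cp, cq, Jab=Jab: Jab
                * _pair_multiplier(cp, cq, cluster.J_Iplus, cluster.J_Iminus),
            )
    elif mode == "E_probability":
        p_in, p_out = probability_clustering(cluster.Q, p[("E", "E")], cluster.R_EE)
        wf = cluster.prob_weight_factor
        prof[("E", "E")] = (
            lambda cp, cq: _pair_multiplier(cp, cq, p_in, p_out),
            lambda cp, cq: J[("E", "E")] * _pair_multiplier(cp, cq, wf, 1.0),
        )
    elif mode != "none":
        raise ValueError(f"unknown clustering mode {mode!r}")
    return prof


def _build(spec: NetworkSpec, weights: BalanceWeights, cluster: ClusterSpec,
           seed: int, storage: str = "auto") -> WeightMatrix:
    N_E, N_I, N = spec.N_E, spec.N_I, spec.N
    prof = _block_profiles(spec, weights, cluster)
    cl = {"E": cluster.assignment_E, "I": cluster.assignment_I}
    sl = {"E": (0, N_E), "I": (N_E, N)}
    rng = np.random.default_rng(seed)

    if storage == "auto":
        storage = "dense" if N <= DENSE_LIMIT else "sparse"

    if storage == "dense":
        W = np.zeros((N, N))
        for a in "EI":
            for b in "EI":
                p_fn, w_fn = prof[(a, b)]
                P = p_fn(cl[a], cl[b])
                Wab = w_fn(cl[a], cl[b])
                a0, a1 = sl[a]
                b0, b1 = sl[b]
                W[a0:a1, b0:b1] = (rng.random((a1 - a0, b1 - b0)) < P) * Wab
        np.fill_diagonal(W, 0.0)
        return WeightMatrix(W, N_E, cluster, seed, spec)

    # sparse: build CSC in chunks of columns sharing one (population, cluster)
    # profile; cluster assignments are contiguous so chunks are ranges.
    chunk_cols = 512
    indptr = np.zeros(N + 1, dtype=np.int64)
    idx_chunks, dat_chunks = [], []
    j = 0
    while j < N:
        b = "E" if j < N_E else "I"
        b0, b1 = sl[b]
        cj_val = cl[b][j - b0]
        # extend chunk while same population and cluster id
        j_end = j
        while (j_end < b1 and j_end - j < chunk_cols
               and cl[b][j_end - b0] == cj_val):
            j_end += 1
        nc = j_end - j
        cj = np.array([cj_val])
        col_p = np.empty(N)
        col_w = np.empty(N)
        for a in "EI":
            p_fn, w_fn = prof[(a, b)]
            a0, a1 = sl[a]
            col_p[a0:a1] = p_fn(cl[a], cj)[:, 0]
            col_w[a0:a1] = w_fn(cl[a], cj)[:, 0]
        mask = rng.random((N, nc)) < col_p[:, None]
        mask[np.arange(j, j_end), np.arange(nc)] = False  # no self-connections
        rows, cols = np.nonzero(mask.T)  # rows here = local column index
        order = np.argsort(rows, kind="stable")
        rows, cols = rows[order], cols[order]
        counts = np.bincount(rows, minlength=nc)
        indptr[j + 1 : j_end + 1] = indptr[j] + np.cumsum(counts)
        idx_chunks.append(cols.astype(np.int32))
        dat_chunks.append(col_w[cols])
        j = j_end
    M = sp.csc_matrix(
        (np.concatenate(dat_chunks), np.concatenate(idx_chunks), indptr),
        shape=(N, N),
    ).tocsr()
    return WeightMatrix(M, N_E, cluster, seed, spec)


def build_matrix(spec: NetworkSpec, weights: Optional[BalanceWeights] = None,
                 cluster: Optional[ClusterSpec] = None, seed: Optional[int] = None,
                 storage: str = "auto") -> WeightMatrix:
    """Build a realised weight matrix for ``spec.clustering_mode``.

    Reproducible given ``seed`` (defaults to ``spec.seed``).
    """
    if weights is None:
        weights = derive_weights(spec)
    if cluster is None:
        cluster = ClusterSpec.from_spec(spec)
    return _build(spec, weights, cluster, spec.seed if seed is None else seed,
                  storage)


def build_probability_clustered(spec: NetworkSpec,
                                weights: Optional[BalanceWeights] = None,
                                R_EE: Optional[float] = None,
                                seed: Optional[int] = None,
                                storage: str = "auto") -> WeightMatrix:
    """Probability-clustered variant: ``p_in = R_EE * p_out``, mean preserved."""
    spec = spec.replace(clustering_mode="E_probability",
                        R_EE=spec.R_EE if R_EE is None else R_EE)
    return build_matrix(spec, weights, None, seed, storage)


def build_background_variant(spec: NetworkSpec,
                             weights: Optional[BalanceWeights] = None,
                             cluster: Optional[ClusterSpec] = None,
                             background_fraction: Optional[float] = None,
                             seed: Optional[int] = None,
                             storage: str = "auto") -> WeightMatrix:
    """Weight-clustered variant with an unstructured background population.

    Background units connect everywhere with unmodified ``J_EE``; the
    ``J_-`` renormalisation applies among the clustered units only, so every
    row keeps expected total E input ``N_E * p_EE * J_EE``.
    """
    if background_fraction is None:
        background_fraction = spec.background_fraction
    spec = spec.replace(clustering_mode="E_weights_background",
                        background_fraction=background_fraction)
    return build_matrix(spec, weights, cluster, seed, storage)
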