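"""Balanced-state parameterisation of binary excitatory-inhibitory networks.

A network of ``N_E`` excitatory and ``N_I`` inhibitory binary units is in the
balanced state when the O(sqrt(N)) excitatory and inhibitory inputs to every
unit cancel on average, leaving firing driven by input fluctuations.  This
module derives the synaptic weight constants that realise that cancellation
for given sizes, connection probabilities and thresholds, evaluates the
closed-form large-N population rates, and checks the admissibility conditions
on the relative inhibition strength ``g`` and the external drive.

Conventions
-----------
Per-synapse weights scale as ``J_ab = j_ab / sqrt(N)`` with ``N = N_E + N_I``,
and ``n_a = N_a / N`` denotes a population *fraction*.  With these definitions
the weight constants

    j_EE =  theta_E / sqrt(p_EE * n_E)
    j_EI = -g * j_EE * p_EE * n_E / (p_EI * n_I)
    j_IE =  theta_I / sqrt(p_IE * n_E)
    j_II = -j_IE * p_IE * n_E / (p_II * n_I)

satisfy exactly the threshold normalisation ``sqrt(p_aE * N_E) * J_aE =
theta_a`` and the row-wise balance of total excitation against total
inhibition.  (Some presentations write ``n_E = N / N_E``; that convention is
inconsistent with the threshold normalisation and is presumed a typo -- see
``docs/methods.md``.)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "CLUSTERING_MODES",
    "NetworkSpec",
    "BalanceWeights",
    "BalanceReport",
    "derive_weights",
    "check_balance_conditions",
    "balanced_rates",
]

CLUSTERING_MODES = (
    "none",
    "E_weights",
    "EI_weights",
    "E_weights_background",
    "E_probability",
)


@dataclass(frozen=True)
class NetworkSpec:
    """All scalar parameters of a network.

    Defaults reproduce the reference parameter set used throughout:
    ``N_E = 4 N_I``, ``theta = 1``, ``tau_I = 0.5 tau_E``, ``p_EE = 0.2``,
    ``p_EI = p_IE = p_II = 0.5``, ``g = 1.2``, ``J_EX = sqrt(p_EE N_E)``,
    ``J_IX = 0.8 J_EX`` and external drive ``m_X = 0.03``.

    ``J_EX``/``J_IX`` may be given explicitly; when left ``None`` they are
    resolved from ``J_EX_factor``/``J_IX_factor`` times ``sqrt(p_EE * N_E)``.
    """

    N_E: int = 4000
    N_I: int = 1000
    Q: int = 20
    p_EE: float = 0.2
    p_EI: float = 0.5
    p_IE: float = 0.5
    p_II: float = 0.5
    g: float = 1.2
    theta_E: float = 1.0
    theta_I: float = 1.0
    J_EX: Optional[float] = None
    J_IX: Optional[float] = None
    J_EX_factor: float = 1.0
    J_IX_factor: float = 0.8
    m_X: float = 0.03
    tau_E: float = 10.0  # ms
    tau_I: Optional[float] = None  # ms; default 0.5 * tau_E
    clustering_mode: str = "none"
    J_Eplus: float = 1.0
    R_J: float = 0.0
    background_fraction: float = 0.1
    R_EE: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_E <= 0 or self.N_I <= 0:
            raise ValueError("population sizes N_E and N_I must be positive")
        if self.Q <= 0:
            raise ValueError("cluster count Q must be positive")
        for name in ("p_EE", "p_EI", "p_IE", "p_II"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {name}={p} outside [0, 1]")
        if self.g <= 0:
            raise ValueError("relative inhibition strength g must be positive")
        if not 0.0 <= self.m_X <= 1.0:
            raise ValueError("external drive m_X must lie in [0, 1]")
        if self.tau_E <= 0:
            raise ValueError("tau_E must be positive")
        if self.clustering_mode not in CLUSTERING_MODES:
            raise ValueError(
                f"unknown clustering_mode {self.clustering_mode!r}; "
                f"expected one of {CLUSTERING_MODES}"
            )
        if self.J_Eplus < 1.0:
            raise ValueError("J_Eplus must be >= 1")
        if not 0.0 <= self.R_J <= 1.0:
            raise ValueError("R_J must lie in [0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.R_EE < 1.0:
            raise ValueError("R_EE must be >= 1")
        if self.tau_I is None:
            object.__setattr__(self, "tau_I", 0.5 * self.tau_E)
        if self.tau_I <= 0:
            raise ValueError("tau_I must be positive")
        if self.J_EX is None:
            object.__setattr__(
                self, "J_EX", self.J_EX_factor * np.sqrt(self.p_EE * self.N_E)
            )
        if self.J_IX is None:
            object.__setattr__(
                self, "J_IX", self.J_IX_factor * np.sqrt(self.p_EE * self.N_E)
            )
        # keep plain python scalars (serialisation-friendly)
        for name in ("J_EX", "J_IX", "tau_I"):
            object.__setattr__(self, name, float(getattr(self, name)))

    # ------------------------------------------------------------------ sizes
    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def n_E(self) -> float:
        """Excitatory population fraction N_E / N."""
        return self.N_E / self.N

    @property
    def n_I(self) -> float:
        return self.N_I / self.N

    def K(self, alpha: str, beta: str) -> float:
        """Mean in-degree ``K_ab = p_ab * N_b`` of a unit in ``alpha`` from ``beta``."""
        p = getattr(self, f"p_{alpha}{beta}")
        n = self.N_E if beta == "E" else self.N_I
        return p * n

    def replace(self, **kwargs) -> "NetworkSpec":
        """Copy with fields changed.

        External weights that were derived from ``J_*X_factor`` (rather than
        given explicitly) are re-derived, so that e.g. changing ``N_E`` keeps
        ``J_EX = J_EX_factor * sqrt(p_EE * N_E)``.
        """
        d = dataclasses.asdict(self)
        base = np.sqrt(self.p_EE * self.N_E)
        for key, fac in (("J_EX", "J_EX_factor"), ("J_IX", "J_IX_factor")):
            if key not in kwargs and d[key] == getattr(self, fac) * base:
                d[key] = None
        d.update(kwargs)
        return type(self)(**d)

    # -------------------------------------------------------------- serialise
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        # flat-config aliases
        if "theta" in d:
            theta = d.pop("theta")
            d.setdefault("theta_E", theta)
            d.setdefault("theta_I", theta)
        if "tau_I_over_tau_E" in d:
            ratio = d.pop("tau_I_over_tau_E")
            d["tau_I"] = ratio * d.get("tau_E", cls.tau_E)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown NetworkSpec keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class BalanceWeights:
    """Size-scaled weight constants ``j_ab`` and per-synapse weights ``J_ab = j_ab/sqrt(N)``."""

    j_EE: float
    j_EI: float
    j_IE: float
    j_II: float
    J_EE: float
    J_EI: float
    J_IE: float
    J_II: float
    n_E: float
    n_I: float

    def j(self, alpha: str, beta: str) -> float:
        return getattr(self, f"j_{alpha}{beta}")

    def J(self, alpha: str, beta: str) -> float:
        return getattr(self, f"J_{alpha}{beta}")


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of the balanced-state admissibility check.

    ``branch`` identifies which inequality chain holds: ``"g<1"`` (weak
    inhibition with weak relative external drive to E) or ``"g>1"`` (dominant
    inhibition with strong relative drive).  ``applicable`` is False when
    ``theta_E != theta_I``, for which the conditions are not stated.
    """

    applicable: bool
    satisfied: bool
    branch: Optional[str]
    g: float
    drive_ratio: float  # J_EX / J_IX
    probability_ratio: float  # g * sqrt(p_EE / p_IE)


def derive_weights(spec: NetworkSpec) -> BalanceWeights:
    """Derive the balanced-state weight constants from network parameters.

    Raises
    ------
    ValueError
        If any connection probability entering the formulas is zero, naming
        the offending parameter.
    """
    for name in ("p_EE", "p_EI", "p_IE", "p_II"):
        if getattr(spec, name) == 0.0:
            raise ValueError(f"cannot derive balanced weights: {name} is zero")
    n_E, n_I = spec.n_E, spec.n_I
    j_EE = spec.theta_E / np.sqrt(spec.p_EE * n_E)
    j_EI = -spec.g * j_EE * (spec.p_EE * n_E) / (spec.p_EI * n_I)
    j_IE = spec.theta_I / np.sqrt(spec.p_IE * n_E)
    j_II = -j_IE * (spec.p_IE * n_E) / (spec.p_II * n_I)
    sqrtN = np.sqrt(spec.N)
    return BalanceWeights(
        j_EE=j_EE, j_EI=j_EI, j_IE=j_IE, j_II=j_II,
        J_EE=j_EE / sqrtN, J_EI=j_EI / sqrtN,
        J_IE=j_IE / sqrtN, J_II=j_II / sqrtN,
        n_E=n_E, n_I=n_I,
    )


def check_balance_conditions(spec: NetworkSpec) -> BalanceReport:
    """Check which admissibility branch (if any) the parameters satisfy.

    With equal thresholds, positive finite balanced rates require either
    ``g < 1`` together with ``J_EX/J_IX < g*sqrt(p_EE/p_IE)`` or ``g > 1``
    together with the reversed inequality.  Exactly one branch can hold.
    """
    drive_ratio = spec.J_EX / spec.J_IX
    prob_ratio = spec.g * np.sqrt(spec.p_EE / spec.p_IE)
    if spec.theta_E != spec.theta_I:
        return BalanceReport(False, False, None, spec.g, drive_ratio, prob_ratio)
    if spec.g < 1 and drive_ratio < prob_ratio:
        return BalanceReport(True, True, "g<1", spec.g, drive_ratio, prob_ratio)
    if spec.g > 1 and drive_ratio > prob_ratio:
        return BalanceReport(True, True, "g>1", spec.g, drive_ratio, prob_ratio)
    return BalanceReport(True, False, None, spec.g, drive_ratio, prob_ratio)


def balanced_rates(spec: NetworkSpec) -> tuple[float, float]:
    """Closed-form large-N balanced rates ``(m_E, m_I)``.

    These are the rates at which the O(sqrt(N)) recurrent and external inputs
    cancel exactly,

        m_E = m_X / (sqrt(N_E) (g-1)) * (J_EX/(theta_E sqrt(p_EE))
                                         - g J_IX/(theta_I sqrt(p_IE)))
        m_I = m_X / (sqrt(N_E) (g-1)) * (J_EX/(theta_E sqrt(p_EE))
                                         - J_IX/(theta_I sqrt(p_IE)))

    Equivalently the solution of the 2x2 linear balance system
    ``Jbar_aE m_E + Jbar_aI m_I + J_aX m_X = 0``.

    Raises
    ------
    ZeroDivisionError
        If ``g == 1`` (the rates diverge).
    """
    if spec.g == 1.0:
        raise ZeroDivisionError("balanced rates are singular at g = 1")
    pref = spec.m_X / (np.sqrt(spec.N_E) * (spec.g - 1.0))
    a = spec.J_EX / (spec.theta_E * np.sqrt(spec.p_EE))
    b = spec.J_IX / (spec.theta_I * np.sqrt(spec.p_IE))
    return pref * (a - spec.g * b), pref * (a - b)
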