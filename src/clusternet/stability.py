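"""Linear stability of mean-field fixed points.

The Jacobian of the rate dynamics at a point ``m0`` has entries

    d(dm_a/dt)/dm_b = -(1/tau_a) * ( delta_ab
        + H'(-mu_a/s_a) * (Jbar_ab s_a - mu_a Jbar2_ab / (2 s_a)) / s_a^2 )

with ``H'(x) = -exp(-x^2/2)/sqrt(2 pi)``: the second term combines the
direct mean-input path and the variance path (``s`` depends on the rates).

For the two-population system, stability depends on the time constants only
through the ratio ``r = tau_I / tau_E``.  Writing ``f'_ab`` for the
tau-scaled partial derivatives (in units of ``tau_E``), the trace and
determinant of the stability matrix are ``T_S = f'_EE + f'_II / r`` and
``delta_S = (f'_EE f'_II - f'_EI f'_IE) / r``, and the eigenvalue structure
changes at three critical ratios

    r1 = A - sqrt(A^2 - B^2),   r2 = -B,   r3 = A + sqrt(A^2 - B^2)

with ``A = (f'_EE f'_II - 2 f'_EI f'_IE) / f'_EE^2`` and
``B = f'_II / f'_EE``: below ``r1`` the fixed point is a stable node, between
``r1`` and ``r2`` a stable spiral (damped oscillations), and above ``r2`` it
is unstable (large-amplitude limit cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .meanfield import PopulationSystem, input_moments, _rates

__all__ = [
    "DegenerateGainError",
    "StabilityReport",
    "jacobian",
    "classify",
    "critical_ratios",
    "MARGINAL_TOL",
]

MARGINAL_TOL = 1e-8


class DegenerateGainError(ValueError):
    """Raised when the input variance vanishes at the evaluation point.

    The Gaussian-input gain is a step function there and has no derivative;
    evaluate the Jacobian at a point with all rates (hence variances)
    strictly positive.
    """


@dataclass
class StabilityReport:
    """Eigenvalues and classification of a fixed point.

    ``eigenvalues`` are those of the Jacobian expressed in units of
    ``1/tau_E`` (dimensionless growth rates per excitatory time constant);
    the sign structure is independent of that scaling.  For two-population
    systems the closed-form quantities (trace, determinant, tau-scaled
    partials, A, B and the critical ratios r1-r3) are filled in; ``r1``/``r3``
    are None when complex (A^2 < B^2).
    """

    eigenvalues: np.ndarray
    stable: bool
    classification: str  # stable node | stable spiral | unstable | marginal
    T_S: Optional[float] = None
    delta_S: Optional[float] = None
    fprime_EE: Optional[float] = None
    fprime_EI: Optional[float] = None
    fprime_IE: Optional[float] = None
    fprime_II: Optional[float] = None
    A: Optional[float] = None
    B: Optional[float] = None
    r1: Optional[float] = None
    r2: Optional[float] = None
    r3: Optional[float] = None

    @property
    def max_real(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def to_dict(self) -> dict:
        d = {
            "eigenvalues_re": self.eigenvalues.real.tolist(),
            "eigenvalues_im": self.eigenvalues.imag.tolist(),
            "stable": self.stable,
            "classification": self.classification,
        }
        for k in ("T_S", "delta_S", "fprime_EE", "fprime_EI", "fprime_IE",
                  "fprime_II", "A", "B", "r1", "r2", "r3"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def jacobian(sys: PopulationSystem, m0) -> np.ndarray:
    """Jacobian of the rate dynamics at ``m0`` (entries per ms).

    Raises :class:`DegenerateGainError` if any population has zero input
    variance at ``m0``.
    """
    m = _rates(m0)
    mom = input_moments(sys, m)
    if np.any(mom.s2 <= 0.0):
        bad = [sys.labels[i] for i in np.nonzero(mom.s2 <= 0.0)[0]]
        raise DegenerateGainError(
            f"zero input variance for population(s) {bad}: the gain is a step "
            "function there; evaluate at strictly positive rates"
        )
    s = np.sqrt(mom.s2)
    z = -mom.mu / s
    phi = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)  # = -H'(z)
    inner = (sys.Jbar * s[:, None] - 0.5 * mom.mu[:, None] * sys.Jbar2 / s[:, None])
    J = (-np.eye(sys.P) + phi[:, None] * inner / mom.s2[:, None]) / sys.tau[:, None]
    return J


def _tau_E(sys: PopulationSystem) -> float:
    e = sys.e_indices
    return float(sys.tau[e[0]]) if e.size else float(np.max(sys.tau))


def classify(sys: PopulationSystem, m0) -> StabilityReport:
    """Classify a fixed point from the eigenvalues of its Jacobian.

    Stable node: all eigenvalues real and negative.  Stable spiral: complex
    pairs, all real parts negative.  Marginal: some ``|Re(lambda)|`` below
    ``MARGINAL_TOL``.  Unstable otherwise.
    """
    J = jacobian(sys, m0)
    tauE = _tau_E(sys)
    eig = np.linalg.eigvals(J) * tauE
    re = eig.real
    complex_present = np.any(np.abs(eig.imag) > 1e-12)
    if np.any(np.abs(re) < MARGINAL_TOL):
        cls = "marginal"
        stable = False
    elif np.all(re < 0):
        cls = "stable spiral" if complex_present else "stable node"
        stable = True
    else:
        cls = "unstable"
        stable = False
    report = StabilityReport(eigenvalues=eig, stable=stable, classification=cls)
    if sys.P == 2:
        r = float(sys.tau[1] / sys.tau[0])  # tau_I / tau_E
        f = J * tauE  # per tau_E
        fp_EE, fp_EI = f[0, 0], f[0, 1]
        fp_IE, fp_II = f[1, 0] * r, f[1, 1] * r  # f'_ab = tau_a * f_ab
        report.fprime_EE, report.fprime_EI = float(fp_EE), float(fp_EI)
        report.fprime_IE, report.fprime_II = float(fp_IE), float(fp_II)
        report.T_S = float(fp_EE + fp_II / r)
        report.delta_S = float((fp_EE * fp_II - fp_EI * fp_IE) / r)
        r1, r2, r3, A, B = _ratios(fp_EE, fp_EI, fp_IE, fp_II)
        report.A, report.B = A, B
        report.r1, report.r2, report.r3 = r1, r2, r3
    return report


def _ratios(fEE, fEI, fIE, fII):
    if fEE == 0.0:
        raise ValueError("critical ratios undefined for fprime_EE = 0")
    A = (fEE * fII - 2.0 * fEI * fIE) / fEE**2
    B = fII / fEE
    r2 = -B
    disc = A * A - B * B
    if disc < 0:
        return None, float(r2), None, float(A), float(B)
    root = np.sqrt(disc)
    return float(A - root), float(r2), float(A + root), float(A), float(B)


def critical_ratios(fprime_EE: float, fprime_EI: float,
                    fprime_IE: float, fprime_II: float):
    """Critical time-constant ratios ``(r1, r2, r3)`` of the 2-population system.

    ``r1``/``r3`` are None when ``A^2 < B^2`` (no real node/spiral boundary).
    """
    r1, r2, r3, _, _ = _ratios(fprime_EE, fprime_EI, fprime_IE, fprime_II)
    return r1, r2, r3
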