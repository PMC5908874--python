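"""Fixed-point landscapes of clustered mean-field systems.

Multistability in clustered networks is mapped with three complementary
tools:

* **Random-restart sampling** -- rates are initialised uniformly in [0,1]^P,
  integrated for a transient, coarsened with Nelder-Mead on the squared
  steady-state residual and polished with a Newton-type root solve.  The
  pre-integration biases the search towards *stable* fixed points.
* **Constrained solving** -- by symmetry, states with ``n`` active clusters
  can be found from a reduced system in which the ``Q - n`` remaining
  clusters (and, for EI clustering, their inhibitory partners) share one
  rate; solutions are lifted back to the full system, re-verified and
  re-classified there.  This also finds unstable intermediate states.
* **Effective response functions (EFR)** -- the rate of one *focus*
  population is imposed as a parameter ``m1``; all other populations are
  relaxed to their steady state ``m'(m1)``, and the output rate
  ``Phi_eff(m1) = H(-mu_1(m1, m'(m1)) / s_1)`` is read off.  Diagonal
  crossings ``Phi_eff(m) = m`` are fixed points of the full system; a
  crossing with slope > 1 is unstable on the curve.  Full-system stability
  is evaluated separately (a curve-stable point need not be globally
  stable).

All reported fixed points satisfy the steady-state equations with maximum
residual below ``RESIDUAL_TOL`` and carry a stability report and a
permutation-invariant signature (sorted, rounded excitatory cluster rates
plus the number of active clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .balance import NetworkSpec
from .meanfield import (PopulationSystem, fixed_point_residual, integrate_rates,
                        input_moments, _gain_target, reduce_network)
from .stability import StabilityReport, classify

__all__ = [
    "FixedPoint",
    "EFRCrossing",
    "EFRCurve",
    "AttractorLandscape",
    "sample_fixed_points",
    "solve_constrained",
    "effective_response",
    "critical_clustering_strength",
    "homogeneous_fixed_point",
    "landscape_sweep",
    "RESIDUAL_TOL",
]

logger = logging.getLogger(__name__)

RESIDUAL_TOL = 1e-9
SIGNATURE_DECIMALS = 4
#: minimum input variance for a state to count as fluctuation-driven
S2_FLOOR = 1e-9


# --------------------------------------------------------------------------
# fixed-point container and signature


@dataclass
class FixedPoint:
    """A verified steady state of a population system."""

    m: np.ndarray
    residual: float
    report: StabilityReport
    signature: tuple          # sorted-descending rounded E-cluster rates
    n_active: int
    m_up: float               # largest excitatory rate

    @property
    def stable(self) -> bool:
        return self.report.stable


def _signature(sys: PopulationSystem, m: np.ndarray):
    """Canonical permutation-invariant signature of the E-cluster rates.

    A cluster counts as *active* when its rate exceeds the midpoint between
    the largest and smallest excitatory cluster rates; a homogeneous state
    (spread below rounding resolution) has zero active clusters.
    """
    e = sys.cluster_e_indices
    rates = np.sort(np.round(m[e], SIGNATURE_DECIMALS))[::-1]
    lo, hi = rates[-1], rates[0]
    if hi - lo < 10.0 ** (-SIGNATURE_DECIMALS):
        n_active = 0
    else:
        n_active = int(np.sum(rates > 0.5 * (hi + lo)))
    return tuple(rates), n_active


def _make_fixed_point(sys: PopulationSystem, m: np.ndarray) -> FixedPoint:
    res = float(np.max(np.abs(fixed_point_residual(sys, m))))
    report = classify(sys, m)
    sig, n_active = _signature(sys, m)
    e = sys.e_indices
    return FixedPoint(m=m, residual=res, report=report, signature=sig,
                      n_active=n_active, m_up=float(np.max(m[e])))


# --------------------------------------------------------------------------
# core solvers


def _polish(sys: PopulationSystem, m0: np.ndarray,
            nelder_mead: bool = True) -> Optional[np.ndarray]:
    """Refine ``m0`` to a steady state; None on failure or degenerate variance."""
    m = np.clip(np.asarray(m0, dtype=float), 0.0, 1.0)

    def res_clipped(x):
        if not np.all(np.isfinite(x)):
            return np.full(len(x), 1e3)
        return fixed_point_residual(sys, np.clip(x, 0.0, 1.0))

    if nelder_mead:
        # derivative-free coarsening; the Newton polish below reaches the
        # final residual, so the simplex only needs a modest budget
        out = optimize.minimize(
            lambda x: float(np.sum(res_clipped(x) ** 2)), m,
            method="Nelder-Mead",
            options={"fatol": 1e-12, "xatol": 1e-8, "maxfev": 40 * sys.P},
        )
        m = np.clip(out.x, 0.0, 1.0)
    sol = optimize.root(res_clipped, m, method="hybr", tol=1e-13)
    m = np.clip(sol.x, 0.0, 1.0)
    if np.max(np.abs(fixed_point_residual(sys, m))) > RESIDUAL_TOL:
        return None
    if np.any(input_moments(sys, m).s2 <= S2_FLOOR):
        return None  # degenerate (all-silent) state: outside the Gaussian theory
    return m


def sample_fixed_points(sys: PopulationSystem, n_restarts: int = 200,
                        seed: Optional[int] = None,
                        keep_unstable: bool = False,
                        pre_T_factor: float = 50.0) -> list[FixedPoint]:
    """Random-restart search for (stable) fixed points.

    Each restart integrates the dynamics for ``pre_T_factor * tau_E`` from a
    uniform random initial state before the two-stage refinement; points are
    deduplicated by signature.  Unstable refinements are discarded unless
    ``keep_unstable``.  Raises if no restart converges.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    tauE = float(np.max(sys.tau))
    found: dict = {}
    n_fail = 0
    for _ in range(n_restarts):
        m0 = rng.random(sys.P)
        traj = integrate_rates(sys, m0, T=pre_T_factor * tauE)
        m = _polish(sys, traj.m[-1])
        if m is None:
            n_fail += 1
            continue
        fp = _make_fixed_point(sys, m)
        if not keep_unstable and not fp.stable:
            continue
        found.setdefault(fp.signature, fp)
    if n_fail:
        logger.info("sample_fixed_points: %d/%d restarts failed to converge",
                    n_fail, n_restarts)
    if not found:
        raise RuntimeError("no fixed point found in any restart")
    return sorted(found.values(), key=lambda f: -f.m_up)


def _groups_constrained(sys: PopulationSystem, n_active: int):
    """Index groups for the reduced constrained system.

    Groups: active E clusters, remaining E clusters, then for EI clustering
    the partner I clusters of the active set and the remaining I clusters;
    any other population (global I, background) is its own group.
    """
    e = list(sys.cluster_e_indices)
    Q = len(e)
    if not 1 <= n_active < Q:
        raise ValueError(f"n_active must be in [1, {Q - 1}]")
    groups = [e[:n_active], e[n_active:]]
    i_clusters = [i for i, l in enumerate(sys.labels)
                  if l.startswith("I") and l != "I"]
    if i_clusters:  # EI mode: pair I clusters with the same ids as the E groups
        id_of = {i: int(sys.labels[i][1:]) for i in i_clusters}
        active_ids = {int(sys.labels[i][1:]) for i in groups[0]}
        groups.append([i for i in i_clusters if id_of[i] in active_ids])
        groups.append([i for i in i_clusters if id_of[i] not in active_ids])
    for i, l in enumerate(sys.labels):
        if l == "I" or l == "Ebg":
            groups.append([i])
    return groups


def _lift(sys: PopulationSystem, groups, x) -> np.ndarray:
    m = np.empty(sys.P)
    for g, xi in zip(groups, x):
        m[g] = xi
    return m


def _grouped_residual(sys, groups):
    def f(x):
        if not np.all(np.isfinite(x)):
            return np.full(len(x), 1e3)
        r = fixed_point_residual(sys, _lift(sys, groups, np.clip(x, 0.0, 1.0)))
        return np.array([r[g[0]] for g in groups]) \
            + np.where(x < 0, -x, 0.0) + np.where(x > 1, x - 1.0, 0.0)
    return f


def solve_constrained(sys: PopulationSystem, n_active: int = 1,
                      starts: Optional[list] = None) -> list[FixedPoint]:
    """Fixed points with ``n_active`` clusters sharing one (elevated) rate.

    Solves the reduced grouped system from a grid of starting points, lifts
    solutions to the full system, re-verifies the residual and re-classifies
    there.  Returns stable *and* unstable solutions, deduplicated by
    signature; empty list if nothing converges (a valid outcome when no
    up-state exists).
    """
    groups = _groups_constrained(sys, n_active)
    f = _grouped_residual(sys, groups)
    if starts is None:
        base = homogeneous_fixed_point(sys)
        mE0 = float(np.mean(base.m[sys.cluster_e_indices]))
        mI = float(np.mean(base.m[sys.i_indices]))
        starts = [[mE0, mE0], [0.2, 0.7 * mE0], [0.4, 0.7 * mE0],
                  [0.6, 0.5 * mE0], [0.8, 0.5 * mE0], [0.95, 0.3 * mE0],
                  [0.999, 0.2 * mE0], [0.5, mE0], [0.9, mE0]]
        full_starts = []
        for mf, mo in starts:
            x = [mf, mo]
            for g in groups[2:]:
                lbl = sys.labels[g[0]]
                if lbl.startswith("I"):
                    # inhibitory partner of the focus tracks it part-way
                    x.append(min(1.0, 0.6 * mf + mI) if len(groups) > 3
                             and g is groups[2] else mI)
                else:
                    x.append(mE0)
            full_starts.append(x)
        starts = full_starts
    found: dict = {}
    for x0 in starts:
        sol = optimize.root(f, np.asarray(x0, dtype=float), method="hybr",
                            tol=1e-13)
        if not sol.success:
            continue
        x = np.clip(sol.x, 0.0, 1.0)
        m = _lift(sys, groups, x)
        if np.max(np.abs(fixed_point_residual(sys, m))) > RESIDUAL_TOL:
            continue
        if np.any(input_moments(sys, m).s2 <= S2_FLOOR):
            continue
        fp = _make_fixed_point(sys, m)
        found.setdefault(fp.signature, fp)
    return sorted(found.values(), key=lambda fp: -fp.m_up)


def homogeneous_fixed_point(sys: PopulationSystem) -> FixedPoint:
    """The steady state with all excitatory clusters at one common rate.

    Solved in a reduced system grouping all E clusters together (and all I
    clusters together in EI mode; background stays separate), lifted back
    and classified in the full system, where its stability decides the onset
    of obligatory cluster dynamics.
    """
    groups = [list(sys.cluster_e_indices)]
    i_clusters = [i for i, l in enumerate(sys.labels)
                  if l.startswith("I") and l != "I"]
    if i_clusters:
        groups.append(i_clusters)
    for i, l in enumerate(sys.labels):
        if l in ("I", "Ebg"):
            groups.append([i])
    f = _grouped_residual(sys, groups)
    # Relax the grouped dynamics first, then Newton-polish.  Fixed-point
    # locations are independent of the time constants, so the relaxation uses
    # uniform clocks (avoids the limit-cycle regime at large tau_I/tau_E,
    # where the true-clock flow never settles).  Several starting levels
    # guard against sliding into the degenerate all-silent basin.
    for x0 in (0.5, 0.2, 0.1, 0.05, 0.02, 0.8):
        x = np.full(len(groups), x0)
        for _ in range(2000):
            x = np.clip(x + 0.05 * f(x), 1e-12, 1.0)
        sol = optimize.root(f, x, method="hybr", tol=1e-13)
        m = _lift(sys, groups, np.clip(sol.x, 0.0, 1.0))
        res = float(np.max(np.abs(fixed_point_residual(sys, m))))
        if res <= RESIDUAL_TOL and np.all(input_moments(sys, m).s2 > S2_FLOOR):
            return _make_fixed_point(sys, m)
    raise RuntimeError(
        f"homogeneous fixed point did not converge (residual {res:.2e})")


# --------------------------------------------------------------------------
# effective response functions


@dataclass
class EFRCrossing:
    m_star: float             # rate where Phi_eff crosses the diagonal
    slope: float              # dPhi_eff/dm at the crossing
    stable_on_curve: bool     # slope < 1
    report: StabilityReport   # full-system stability at the lifted point
    m_full: np.ndarray        # lifted full-system state


@dataclass
class EFRCurve:
    """Effective response of one focus population.

    ``grid``/``phi`` tabulate ``Phi_eff``; ``slave`` holds the relaxed
    steady-state rates of the remaining populations at each grid point;
    ``valid`` flags grid points whose slave system converged.
    """

    focus: int
    grid: np.ndarray
    phi: np.ndarray
    slave: np.ndarray          # (n, P) full states with m[focus] = grid value
    valid: np.ndarray
    crossings: list

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)


def _relax_slave(sys: PopulationSystem, focus: int, mbar: float,
                 x0: np.ndarray, T_factor: float = 3.0):
    """Steady state of all non-focus populations with ``m[focus]`` clamped.

    Returns the full state vector (focus entry set to ``mbar``) or None.
    """
    others = [i for i in range(sys.P) if i != focus]

    def full(x):
        m = np.empty(sys.P)
        m[focus] = mbar
        m[others] = np.clip(x, 0.0, 1.0)
        return m

    def f(x):
        if not np.all(np.isfinite(x)):
            return np.full(len(x), 1e3)
        return fixed_point_residual(sys, full(x))[others] \
            + np.where(x < 0, -x, 0.0) + np.where(x > 1, x - 1.0, 0.0)

    # short relaxation then Newton polish
    x = x0.copy()
    taus = sys.tau[others]
    dt = 0.05 * float(np.min(sys.tau))
    n = int(T_factor * float(np.max(sys.tau)) / dt)
    for _ in range(n):
        x = np.clip(x + dt * f(x) / taus, 0.0, 1.0)
    sol = optimize.root(f, x, method="hybr", tol=1e-13)
    x = np.clip(sol.x, 0.0, 1.0)
    if np.max(np.abs(f(x))) > RESIDUAL_TOL:
        return None
    return full(x)


def _phi_eff(sys: PopulationSystem, focus: int, m_full: np.ndarray) -> float:
    mom = input_moments(sys, m_full)
    return float(_gain_target(mom.mu, mom.s2)[focus])


def effective_response(sys: PopulationSystem, focus: int = 0,
                       grid=None) -> EFRCurve:
    """Compute the effective response function of ``focus`` on ``grid``.

    The slave solution is continued from one grid point to the next.
    Crossings of the diagonal are located by bisection between bracketing
    grid points, their slope estimated by central differences, and the
    full-system stability evaluated at the lifted state.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 50:
        raise ValueError("EFR grid needs at least 50 points")
    others = [i for i in range(sys.P) if i != focus]
    base = homogeneous_fixed_point(sys)
    x0 = base.m[others]
    phi = np.full(grid.size, np.nan)
    slave = np.full((grid.size, sys.P), np.nan)
    valid = np.zeros(grid.size, dtype=bool)
    x_prev = x0
    for k, mbar in enumerate(grid):
        m_full = _relax_slave(sys, focus, mbar, x_prev)
        if m_full is None:
            logger.warning("EFR: slave system failed at m1=%.4f", mbar)
            continue
        slave[k] = m_full
        phi[k] = _phi_eff(sys, focus, m_full)
        valid[k] = True
        x_prev = m_full[others]
    # interpolate isolated failures so crossing detection stays usable
    if not np.all(valid) and np.any(valid):
        phi[~valid] = np.interp(grid[~valid], grid[valid], phi[valid])

    def g(mbar, x_init):
        m_full = _relax_slave(sys, focus, mbar, x_init)
        if m_full is None:
            raise RuntimeError(f"slave system failed during bisection at {mbar}")
        return _phi_eff(sys, focus, m_full) - mbar, m_full

    crossings = []
    d = phi - grid
    for k in np.nonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0]:
        a, b = grid[k], grid[k + 1]
        x_init = slave[k][others] if valid[k] else x0
        fa = d[k]
        for _ in range(60):  # bisection to ~1e-14 of the bracket
            c = 0.5 * (a + b)
            fc, m_full = g(c, x_init)
            x_init = m_full[others]
            if fa * fc <= 0:
                b = c
            else:
                a, fa = c, fc
            if b - a < 1e-12:
                break
        m_star = 0.5 * (a + b)
        h = max(1e-5, (grid[1] - grid[0]) * 1e-2)
        gp, _ = g(min(m_star + h, 1.0), x_init)
        gm, mf_lo = g(max(m_star - h, 0.0), x_init)
        slope = (gp - gm) / (min(m_star + h, 1.0) - max(m_star - h, 0.0)) + 1.0
        _, m_full = g(m_star, x_init)
        m_full[focus] = m_star
        m_polished = _polish(sys, m_full, nelder_mead=False)
        if m_polished is not None:
            m_full = m_polished
        report = classify(sys, np.clip(m_full, 1e-12, 1.0))
        crossings.append(EFRCrossing(m_star=float(m_star), slope=float(slope),
                                     stable_on_curve=bool(slope < 1.0),
                                     report=report, m_full=m_full))
    return EFRCurve(focus=focus, grid=grid, phi=phi, slave=slave,
                    valid=valid, crossings=crossings)


# --------------------------------------------------------------------------
# sweeps


def _system_for(spec: NetworkSpec, mode: str, R_J: float,
                J_plus: float) -> PopulationSystem:
    field = "R_EE" if mode == "E_probability" else "J_Eplus"
    return reduce_network(spec.replace(clustering_mode=mode, R_J=R_J,
                                       **{field: J_plus}))


def critical_clustering_strength(spec: NetworkSpec, mode: str = "E_weights",
                                 R_J: float = 0.0,
                                 criterion: str = "homogeneous_unstable",
                                 step: float = 0.1,
                                 bounds: Optional[tuple] = None,
                                 refine: bool = False) -> float:
    """Smallest clustering strength meeting ``criterion`` on a ``step`` grid.

    ``homogeneous_unstable``: first grid point where the homogeneous fixed
    point has an eigenvalue with positive real part.  ``upstate_emerges``:
    first grid point where the single-focus EFR crosses the diagonal more
    than once.  By default the grid value itself is returned (matching how
    such thresholds are read off a sweep); ``refine=True`` bisects the
    bracket down to 0.01.  Returns NaN when the criterion is never met.
    """
    if criterion not in ("homogeneous_unstable", "upstate_emerges"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if bounds is None:
        bounds = (1.0, float(spec.Q))

    def met(J_plus: float) -> bool:
        sys = _system_for(spec, mode, R_J, J_plus)
        if criterion == "homogeneous_unstable":
            return homogeneous_fixed_point(sys).report.max_real > 0.0
        return effective_response(sys).n_crossings > 1

    lo = None
    grid = np.arange(bounds[0], bounds[1] + 0.5 * step, step)
    for J_plus in grid:
        if met(float(J_plus)):
            lo = float(J_plus)
            break
    if lo is None:
        logger.warning("criterion %s never met in %s", criterion, bounds)
        return float("nan")
    if not refine or lo <= bounds[0]:
        return round(lo, 10)
    a, b = lo - step, lo
    while b - a > 0.01:
        c = 0.5 * (a + b)
        if met(c):
            b = c
        else:
            a = c
    return b


@dataclass
class AttractorLandscape:
    """Deduplicated stable fixed points along a clustering-strength sweep."""

    sweep_parameter: str
    grid: np.ndarray
    points: list              # list (per grid value) of lists of FixedPoint
    homogeneous: list         # FixedPoint of the homogeneous state per value
    n_restarts: int
    seed: Optional[int]

    def max_up_rate(self) -> float:
        return max((fp.m_up for pts in self.points for fp in pts
                    if fp.n_active > 0), default=float("nan"))

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for v, pts in zip(self.grid, self.points):
            for sig_id, fp in enumerate(pts):
                for lbl, rate in zip(_labels_of(fp), fp.m):
                    rows.append({
                        "sweep_value": v, "signature_id": sig_id,
                        "n_active": fp.n_active, "population_label": lbl,
                        "rate": rate, "stable": fp.stable,
                        "max_Re_lambda": fp.report.max_real,
                    })
        return pd.DataFrame(rows)


def _labels_of(fp: FixedPoint):
    # lengths of fp.m and the system labels coincide; carried via closure-free
    # convention: label list is attached during sweep
    return getattr(fp, "_labels", [f"p{i}" for i in range(len(fp.m))])


def landscape_sweep(spec: NetworkSpec, mode: str = "E_weights",
                    R_J: float = 0.0, grid=None, n_restarts: int = 200,
                    seed: Optional[int] = 0,
                    n_active_max: int = 2) -> AttractorLandscape:
    """Stable fixed points (sampler + constrained solver) along a sweep.

    For each grid value the random-restart sampler is merged with
    constrained solutions for ``n_active`` up to ``n_active_max``; stable
    states are kept, deduplicated by signature.  The homogeneous state is
    recorded separately with its stability flag.
    """
    if grid is None:
        grid = np.arange(1.0, spec.Q + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    points, homogeneous = [], []
    for v in grid:
        sys = _system_for(spec, mode, R_J, float(v))
        found: dict = {}
        homog = homogeneous_fixed_point(sys)
        homogeneous.append(homog)
        if homog.stable:
            found[homog.signature] = homog
        for n_active in range(1, n_active_max + 1):
            for fp in solve_constrained(sys, n_active):
                if fp.stable:
                    found.setdefault(fp.signature, fp)
        try:
            sampled = sample_fixed_points(
                sys, n_restarts=n_restarts,
                seed=int(rng.integers(2**31 - 1)))
        except RuntimeError:
            sampled = []
        for fp in sampled:
            found.setdefault(fp.signature, fp)
        pts = sorted(found.values(), key=lambda fp: -fp.m_up)
        for fp in pts:
            fp._labels = list(sys.labels)
        points.append(pts)
    return AttractorLandscape(
        sweep_parameter="R_EE" if mode == "E_probability" else "J_Eplus",
        grid=grid, points=points, homogeneous=homogeneous,
        n_restarts=n_restarts, seed=seed)
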