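"""Experiment drivers: each reproduces one analysis as data tables.

Every driver takes an :class:`ExperimentConfig`, writes CSV/JSON artifacts
plus a manifest into the output directory, and returns the written paths.
``scale`` multiplies trial/restart counts for scaled-down runs (``scale=1``
reproduces the reference protocol).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attractors, simulator
from .balance import NetworkSpec, balanced_rates, check_balance_conditions, derive_weights
from .connectivity import build_matrix
from .io import save_network_spec, write_manifest, write_tables
from .meanfield import reduce_network
from .simulator import SimulationConfig, cluster_rates, sigma2_m, simulate

EXPERIMENTS = ("balanced_demo", "variance_sweep", "landscape", "efr",
               "critical_strength", "architecture_comparison")

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]


@dataclass
class ExperimentConfig:
    name: str
    outdir: str = "out"
    seed: int = 0
    scale: float = 1.0
    spec: dict = field(default_factory=dict)      # NetworkSpec overrides
    options: dict = field(default_factory=dict)   # experiment-specific knobs

    def __post_init__(self):
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"choose from {EXPERIMENTS}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
        return cls(**d)

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec.from_dict(self.spec)

    def opt(self, key, default):
        return self.options.get(key, default)


def run_experiment(config: ExperimentConfig) -> list:
    """Dispatch and run; artifacts land in ``config.outdir``."""
    spec = config.network_spec()  # validate before writing anything
    sim_opts = {k: v for k, v in config.options.items()
                if k in ("duration_ms", "bin_ms", "discard_ms")}
    SimulationConfig(seed=config.seed, **sim_opts)  # validates durations early
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_manifest(outdir, dataclasses.asdict(config), config.seed)
    save_network_spec(spec, outdir / "network_spec.yaml")
    driver = globals()[f"_run_{config.name}"]
    return driver(config, spec, outdir)


def _scaled(n, scale, minimum=1):
    return max(minimum, int(round(n * scale)))


def _run_balanced_demo(config, spec, outdir):
    w = derive_weights(spec)
    mE, mI = balanced_rates(spec)
    rep = check_balance_conditions(spec)
    sys = reduce_network(spec.replace(clustering_mode="none"))
    fp = attractors.homogeneous_fixed_point(sys)
    mat = build_matrix(spec.replace(clustering_mode="none"), seed=config.seed)
    sim = simulate(mat, config=SimulationConfig(
        duration_ms=config.opt("duration_ms", 2000.0), seed=config.seed))
    simE, simI = simulator.population_rates(sim)
    table = pd.DataFrame([{
        "j_EE": w.j_EE, "j_EI": w.j_EI, "j_IE": w.j_IE, "j_II": w.j_II,
        "balance_branch": rep.branch, "m_E_closed_form": mE,
        "m_I_closed_form": mI, "m_E_mean_field": fp.m[0],
        "m_I_mean_field": fp.m[1], "m_E_simulation": simE,
        "m_I_simulation": simI, "classification": fp.report.classification,
    }])
    return write_tables({"balanced_rates": table}, outdir)


def _run_variance_sweep(config, spec, outdir):
    grid = np.asarray(config.opt("grid", np.arange(1.0, 3.05, 0.1)), dtype=float)
    cfg = SimulationConfig(
        duration_ms=config.opt("duration_ms", 1000.0),
        n_trials=_scaled(config.opt("n_trials", 20), config.scale),
        n_realizations=_scaled(config.opt("n_realizations", 20), config.scale),
        seed=config.seed)
    df = simulator.variance_sweep(spec, mode=config.opt("mode", "E_weights"),
                                  R_J=config.opt("R_J", spec.R_J),
                                  grid=grid, config=cfg)
    return write_tables({"variance_sweep": df}, outdir)


def _run_landscape(config, spec, outdir):
    grid = np.asarray(config.opt("grid", np.arange(1.0, spec.Q + 0.25, 0.5)),
                      dtype=float)
    land = attractors.landscape_sweep(
        spec, mode=config.opt("mode", "E_weights"),
        R_J=config.opt("R_J", spec.R_J), grid=grid,
        n_restarts=_scaled(config.opt("n_restarts", 200), config.scale),
        seed=config.seed)
    return write_tables({"landscape": land.to_dataframe()}, outdir)


def _run_efr(config, spec, outdir):
    mode = config.opt("mode", "E_weights")
    J_plus = config.opt("J_Eplus", spec.J_Eplus)
    sys = reduce_network(spec.replace(clustering_mode=mode,
                                      J_Eplus=J_plus,
                                      R_J=config.opt("R_J", spec.R_J)))
    curve = attractors.effective_response(sys)
    df = pd.DataFrame({"m_bar": curve.grid, "phi_eff": curve.phi,
                       "valid": curve.valid})
    cr = pd.DataFrame([{"m_star": c.m_star, "slope": c.slope,
                        "stable_on_curve": c.stable_on_curve,
                        "stable_full_system": c.report.stable}
                       for c in curve.crossings])
    return write_tables({"efr_curve": df, "efr_crossings": cr}, outdir)


def _run_critical_strength(config, spec, outdir):
    rows = []
    for criterion in config.opt("criteria",
                                ["homogeneous_unstable", "upstate_emerges"]):
        val = attractors.critical_clustering_strength(
            spec, mode=config.opt("mode", "E_weights"),
            R_J=config.opt("R_J", spec.R_J), criterion=criterion,
            refine=config.opt("refine", False))
        rows.append({"criterion": criterion, "J_Eplus_critical": val})
    return write_tables({"critical_strength": pd.DataFrame(rows)}, outdir)


def _run_architecture_comparison(config, spec, outdir):
    """Maximum instantaneous cluster rates: E-only versus EI clustering."""
    n_runs = _scaled(config.opt("n_runs", 100), config.scale)
    duration = config.opt("duration_ms", 1000.0)
    rows = []
    for label, mode, J_plus, R_J in (
            ("E_only", "E_weights", config.opt("J_Eplus_E", 2.9), 0.0),
            ("EI", "EI_weights", config.opt("J_Eplus_EI", 4.0),
             config.opt("R_J", 0.75))):
        s = spec.replace(clustering_mode=mode, J_Eplus=J_plus, R_J=R_J)
        for run in range(n_runs):
            mat = build_matrix(s, seed=config.seed + 5000 + run)
            res = simulate(mat, config=SimulationConfig(
                duration_ms=duration, seed=config.seed + run))
            series = cluster_rates(res)
            keep = series.t > res.config.discard_ms
            rows.append({"architecture": label, "run": run,
                         "max_cluster_rate": float(series.rates[keep].max()),
                         "sigma2_m": sigma2_m(series)})
    return write_tables({"comparison": pd.DataFrame(rows)}, outdir)
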