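"""Event-driven binary-network simulation and rate statistics."""

import numpy as np
import pytest
from scipy import stats

import clusternet as cn
from clusternet.connectivity import ClusterSpec, WeightMatrix
from conftest import grouped_rates


def _make_result(initial_state, events, duration, n_exc, spec, assignment_E):
    """Synthetic SimulationResult for estimator unit tests."""
    t, u, s = (np.array([e[i] for e in events]) for i in range(3))
    cl = ClusterSpec(mode="E_weights", Q=int(assignment_E.max()) + 1,
                     assignment_E=assignment_E,
                     assignment_I=np.zeros(spec.N_I, dtype=np.int64))
    return cn.SimulationResult(
        initial_state=np.asarray(initial_state, dtype=np.int8),
        events_t=t.astype(float), events_unit=u.astype(np.int32),
        events_state=s.astype(np.int8), duration_ms=duration, n_exc=n_exc,
        spec=spec, config=cn.SimulationConfig(duration_ms=duration),
        cluster=cl)


class TestSimulate:
    def test_isolated_suprathreshold_units_latch_up(self):
        """With no recurrence and drive above threshold, each unit turns on
        at its first update and stays: exactly one spike per unit."""
        spec = cn.NetworkSpec(N_E=1, N_I=1, Q=1, J_EX=25.0, J_IX=25.0,
                              m_X=0.05)
        wm = WeightMatrix(np.zeros((2, 2)), 1, ClusterSpec.from_spec(spec),
                          0, spec)
        res = cn.simulate(wm, config=cn.SimulationConfig(
            duration_ms=300.0, init_up_prob=0.0, seed=13))
        assert res.spike_times.size == 2
        assert set(res.spike_units) == {0, 1}
        assert res.events_t.size == 2  # no further state changes

    def test_rates_match_mean_field_prediction(self, sim_unclustered,
                                               fp_unclustered):
        """Stationary simulated rates agree with the finite-N steady state of
        the rate equations (the large-N closed form is approached only as N
        grows; see the finite-size test below)."""
        mE, mI = cn.population_rates(sim_unclustered)
        assert mE == pytest.approx(fp_unclustered.m[0], rel=0.15)
        assert mI == pytest.approx(fp_unclustered.m[1], rel=0.15)

    def test_finite_size_convergence_to_closed_form(self, table1_spec):
        """|simulated rate - closed form| shrinks as the network grows."""
        cf = cn.balanced_rates(table1_spec)[0]
        errs = []
        for scale in (1, 2, 4):
            s = table1_spec.replace(N_E=4000 * scale, N_I=1000 * scale)
            mat = cn.build_matrix(s, seed=21)
            res = cn.simulate(mat, s, cn.SimulationConfig(duration_ms=1500.0,
                                                          seed=6))
            errs.append(abs(cn.population_rates(res)[0] - cf))
        assert errs[0] > errs[1] > errs[2]

    def test_oscillatory_regime_departs_from_fixed_point(self, table1_spec,
                                                         fp_unclustered):
        """At tau_I/tau_E = 2 the balanced point is not maintained: the rates
        make a large oscillatory excursion and collapse into silence (the
        all-down state is absorbing for subthreshold drive), in contrast to
        ratio 0.5 where the simulation holds the fixed point."""
        stable = cn.population_rates(
            _ratio_sim(table1_spec, tau_I=5.0))
        assert abs(stable[0] - fp_unclustered.m[0]) < 0.5 * fp_unclustered.m[0]
        res = _ratio_sim(table1_spec, tau_I=20.0)
        a = np.full(res.N, -1)
        a[:table1_spec.N_E] = 0
        mE = cn.cluster_rates(res, a, bin_ms=5.0).rates[:, 0]
        assert mE.min() == 0.0  # extinction after the excursion
        assert mE.max() > 1.5 * fp_unclustered.m[0]

    def test_seed_determinism(self, table1_spec):
        spec = table1_spec.replace(N_E=400, N_I=100, Q=5)
        mat = cn.build_matrix(spec, seed=31)
        cfg = cn.SimulationConfig(duration_ms=500.0, seed=7)
        r1, r2 = cn.simulate(mat, spec, cfg), cn.simulate(mat, spec, cfg)
        assert np.array_equal(r1.events_t, r2.events_t)
        assert np.array_equal(r1.events_unit, r2.events_unit)
        assert np.array_equal(r1.initial_state, r2.initial_state)

    def test_inter_update_intervals_are_exponential(self):
        """Per-unit update intervals follow Exp(tau_a) for both populations."""
        spec = cn.NetworkSpec(N_E=40, N_I=10, Q=1)
        mat = cn.build_matrix(spec, seed=2)
        res = cn.simulate(mat, config=cn.SimulationConfig(
            duration_ms=4000.0, seed=5, record_updates=True))
        for lo, hi, tau in ((0, 40, spec.tau_E), (40, 50, spec.tau_I)):
            ivals = np.concatenate([
                np.diff(res.update_t[res.update_unit == u])
                for u in range(lo, hi)])
            assert ivals.mean() == pytest.approx(tau, rel=0.05)
            assert stats.kstest(ivals, "expon", args=(0, tau)).pvalue > 0.01

    def test_dimension_mismatch_rejected(self, table1_spec):
        spec_small = table1_spec.replace(N_E=400, N_I=100, Q=5)
        mat = cn.build_matrix(spec_small, seed=1)
        with pytest.raises(ValueError):
            cn.simulate(mat, table1_spec)


class TestClusterRates:
    def test_all_up_and_one_cluster_up(self):
        spec = cn.NetworkSpec(N_E=40, N_I=10, Q=2,
                              clustering_mode="E_weights", J_Eplus=1.0)
        assignment = np.repeat([0, 1], 20)
        res = _make_result(np.ones(50), [], 100.0, 40, spec, assignment)
        ser = cn.cluster_rates(res, bin_ms=10.0)
        assert np.all(ser.rates == 1.0)
        one_up = np.concatenate([np.ones(20), np.zeros(30)])
        res = _make_result(one_up, [], 100.0, 40, spec, assignment)
        ser = cn.cluster_rates(res, bin_ms=10.0)
        assert np.all(ser.rates[:, 0] == 1.0) and np.all(ser.rates[:, 1] == 0.0)

    def test_time_weighted_occupancy_exact(self):
        """A single flip mid-bin contributes its occupancy fraction."""
        spec = cn.NetworkSpec(N_E=40, N_I=10, Q=2,
                              clustering_mode="E_weights", J_Eplus=1.0)
        assignment = np.repeat([0, 1], 20)
        # unit 0 turns on at t=25: bin (20,30] gets 0.5/20, later bins 1/20
        res = _make_result(np.zeros(50), [(25.0, 0, 1)], 50.0, 40, spec,
                           assignment)
        ser = cn.cluster_rates(res, bin_ms=10.0, method="mean")
        assert np.allclose(ser.rates[:, 0], [0, 0, 0.5 / 20, 1 / 20, 1 / 20])
        end = cn.cluster_rates(res, bin_ms=10.0, method="endpoint")
        assert np.allclose(end.rates[:, 0], [0, 0, 1 / 20, 1 / 20, 1 / 20])

    def test_size_weighted_sum_equals_population_rate(self, sim_ei_clustered):
        ser = grouped_rates(sim_ei_clustered)
        a = np.full(sim_ei_clustered.N, -1)
        a[:sim_ei_clustered.n_exc] = 0
        pop = cn.cluster_rates(sim_ei_clustered, a, bin_ms=10.0)
        lhs = (ser.rates * ser.sizes).sum(axis=1) / ser.sizes.sum()
        assert np.allclose(lhs, pop.rates[:, 0], atol=1e-12)

    def test_empty_cluster_rejected(self, sim_ei_clustered):
        a = np.full(sim_ei_clustered.N, -1)
        a[0] = 1  # cluster 0 empty
        with pytest.raises(ValueError, match="empty"):
            cn.cluster_rates(sim_ei_clustered, a)


class TestSigma2m:
    def test_constant_series_is_zero(self):
        ser = cn.simulator.ClusterRateSeries(
            t=10.0 * np.arange(1, 21), rates=np.full((20, 3), 0.4),
            bin_ms=10.0, sizes=np.full(3, 10))
        assert cn.sigma2_m(ser, discard_ms=50.0) == pytest.approx(0.0, abs=1e-30)

    def test_alternating_series_quarter(self):
        rates = np.tile([[0.0], [1.0]], (10, 1))
        ser = cn.simulator.ClusterRateSeries(
            t=10.0 * np.arange(1, 21), rates=rates, bin_ms=10.0,
            sizes=np.array([10]))
        assert cn.sigma2_m(ser, discard_ms=0.0) == pytest.approx(0.25)

    def test_discard_window_validation(self):
        ser = cn.simulator.ClusterRateSeries(
            t=np.array([10.0]), rates=np.zeros((1, 2)), bin_ms=10.0,
            sizes=np.array([5, 5]))
        with pytest.raises(ValueError):
            cn.sigma2_m(ser, discard_ms=50.0)

    def test_winnerless_regime_boosts_rate_variance(self, table1_spec):
        """sigma^2_m rises by far more than 5x between J_+ = 1 and 2.2."""
        vals = {}
        for J in (1.0, 2.2):
            spec = table1_spec.replace(clustering_mode="E_weights", J_Eplus=J)
            v = []
            for rz in range(2):
                mat = cn.build_matrix(spec, seed=400 + rz)
                for tr in range(2):
                    res = cn.simulate(mat, config=cn.SimulationConfig(
                        duration_ms=1000.0, seed=40 + 10 * rz + tr))
                    v.append(cn.sigma2_m(grouped_rates(res)))
            vals[J] = np.mean(v)
        assert vals[2.2] > 5 * vals[1.0]


class TestEIClustering:
    def test_inhibitory_clusters_track_excitatory_partners(self,
                                                           sim_ei_clustered):
        """In the winnerless regime each I cluster follows its E partner."""
        ser = grouped_rates(sim_ei_clustered, include_inhibitory=True)
        r = ser.rates[ser.t > 100.0]
        cors = [np.corrcoef(r[:, q], r[:, 20 + q])[0, 1] for q in range(20)]
        assert np.mean(cors) > 0.5
        assert min(cors) > 0.0

    def test_moderate_rates_in_ei_regime(self, sim_ei_clustered):
        ser = grouped_rates(sim_ei_clustered)
        assert ser.rates[ser.t > 100.0].max() < 0.75


class TestVarianceSweep:
    def test_single_point_table(self, table1_spec):
        spec = table1_spec.replace(N_E=400, N_I=100, Q=5)
        df = cn.variance_sweep(spec, grid=[2.0],
                               config=cn.SimulationConfig(
                                   duration_ms=300.0, n_trials=2,
                                   n_realizations=1, seed=3))
        assert len(df) == 1
        assert set(df.columns) == {"sweep_value", "sigma2_m_mean",
                                   "sigma2_m_sd", "n"}
        assert df["n"].iloc[0] == 2


def _ratio_sim(spec, tau_I):
    s = spec.replace(tau_I=tau_I)
    mat = cn.build_matrix(s, seed=11)
    return cn.simulate(mat, config=cn.SimulationConfig(duration_ms=800.0,
                                                       seed=4))
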