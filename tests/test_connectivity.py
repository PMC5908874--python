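"""Realised weight matrices: block laws, balance of weights, variants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import clusternet as cn
from clusternet.connectivity import (DENSE_LIMIT, probability_clustering)


class TestClusterScaling:
    def test_endpoints_and_example(self):
        assert cn.cluster_scaling(20, 1.0) == 1.0
        assert cn.cluster_scaling(20, 20.0) == 0.0
        assert cn.cluster_scaling(20, 2.0) == pytest.approx(18 / 19)

    @given(Q=st.integers(2, 50), J=st.floats(1.0, 50.0))
    def test_weight_mean_preserved(self, Q, J):
        """J_+ + (Q-1) J_- = Q: the block-mean weight is unchanged."""
        J = min(J, Q)
        Jm = cn.cluster_scaling(Q, J)
        assert J + (Q - 1) * Jm == pytest.approx(Q, rel=1e-12)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            cn.cluster_scaling(1, 1.0)
        with pytest.warns(UserWarning, match="negative"):
            assert cn.cluster_scaling(10, 12.0) < 0


class TestProbabilityClustering:
    def test_identity_and_example(self):
        assert probability_clustering(20, 0.2, 1.0) == (
            pytest.approx(0.2), pytest.approx(0.2))
        p_in, p_out = probability_clustering(20, 0.2, 2.0)
        assert p_out == pytest.approx(0.2 * 20 / 21)
        assert p_in == pytest.approx(2 * 0.2 * 20 / 21)

    def test_invalid_p_in_rejected(self):
        with pytest.raises(ValueError, match="p_in"):
            probability_clustering(4, 0.9, 4.0)


def _density(block):
    return (block != 0).mean()


def _se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestBuildMatrix:
    def test_unclustered_block_laws(self, small_spec):
        w = cn.derive_weights(small_spec)
        wm = cn.build_matrix(small_spec, seed=1)
        EE = wm.block("E", "E")
        assert set(np.unique(EE)) <= {0.0, w.J_EE}
        for a, b, p in [("E", "E", 0.2), ("E", "I", 0.5),
                        ("I", "E", 0.5), ("I", "I", 0.5)]:
            blk = wm.block(a, b)
            assert abs(_density(blk) - p) < 5 * _se(p, blk.size)
        # sign consistency by presynaptic population
        assert (wm.block("E", "I") <= 0).all() and (wm.block("I", "I") <= 0).all()
        assert (wm.block("E", "E") >= 0).all() and (wm.block("I", "E") >= 0).all()
        assert np.all(np.diag(np.asarray(wm.matrix)) == 0)

    def test_full_decoupling_zeroes_across_cluster(self, small_spec):
        spec = small_spec.replace(clustering_mode="E_weights", J_Eplus=5.0)
        wm = cn.build_matrix(spec, seed=2)
        EE = wm.block("E", "E")
        cl = wm.cluster.assignment_E
        across = cl[:, None] != cl[None, :]
        assert np.all(EE[across] == 0.0)
        within = ~across
        w = cn.derive_weights(spec)
        nz = EE[within][EE[within] != 0]
        assert np.allclose(nz, 5.0 * w.J_EE)

    def test_ei_mode_inhibitory_multiplier(self, small_spec):
        """R_J=3/4 at J_E+=4 gives J_I+ = 3.25 on all I-involving blocks."""
        spec = small_spec.replace(clustering_mode="EI_weights", J_Eplus=4.0,
                                  R_J=0.75)
        wm = cn.build_matrix(spec, seed=3)
        assert wm.cluster.J_Iplus == pytest.approx(3.25)
        w = cn.derive_weights(spec)
        II = wm.block("I", "I")
        cl = wm.cluster.assignment_I
        same = cl[:, None] == cl[None, :]
        nz = II[same][II[same] != 0]
        assert np.allclose(nz, 3.25 * w.J_II)

    def test_row_input_balance_independent_of_clustering(self, small_spec):
        """Mean total E input per E row is invariant under J_+ (20 realisations).

        The exact expectation differs from N_E p J_EE only by the excluded
        self-connection (one within-cluster partner, weight J_+ p J_EE).
        """
        w = cn.derive_weights(small_spec)
        nominal = small_spec.N_E * small_spec.p_EE * w.J_EE
        N_c = small_spec.N_E // small_spec.Q
        for J_plus in (1.0, 2.5, 5.0):
            spec = small_spec.replace(clustering_mode="E_weights",
                                      J_Eplus=J_plus)
            J_minus = cn.cluster_scaling(spec.Q, J_plus)
            expected = spec.p_EE * w.J_EE * (
                (N_c - 1) * J_plus + (spec.N_E - N_c) * J_minus)
            assert expected == pytest.approx(
                nominal - spec.p_EE * w.J_EE * J_plus, rel=1e-12)
            sums = []
            for r in range(20):
                wm = cn.build_matrix(spec, seed=100 + r)
                sums.append(wm.block("E", "E").sum(axis=1).mean())
            se = np.std(sums, ddof=1) / np.sqrt(len(sums))
            assert abs(np.mean(sums) - expected) < 5 * se + 1e-12

    def test_permutation_symmetry_of_cluster_blocks(self, small_spec):
        """Within-cluster EE blocks share their weight law across clusters."""
        spec = small_spec.replace(clustering_mode="E_weights", J_Eplus=3.0)
        wm = cn.build_matrix(spec, seed=7)
        EE = wm.block("E", "E")
        cl = wm.cluster.assignment_E
        means, ns = [], []
        for q in range(spec.Q):
            blk = EE[np.ix_(cl == q, cl == q)]
            means.append(blk.mean())
            ns.append(blk.size)
        grand = np.mean(means)
        # binomial SE of a block-mean weight
        w = cn.derive_weights(spec)
        se = 3.0 * w.J_EE * _se(0.2, ns[0])
        assert np.all(np.abs(np.array(means) - grand) < 5 * se)

    def test_seed_determinism_and_reproducibility(self, small_spec):
        a = cn.build_matrix(small_spec, seed=9)
        b = cn.build_matrix(small_spec, seed=9)
        c = cn.build_matrix(small_spec, seed=10)
        assert np.array_equal(np.asarray(a.matrix), np.asarray(b.matrix))
        assert not np.array_equal(np.asarray(a.matrix), np.asarray(c.matrix))

    def test_sparse_storage_same_law(self, small_spec):
        wm = cn.build_matrix(small_spec, seed=4, storage="sparse")
        assert wm.is_sparse
        for a, b, p in [("E", "E", 0.2), ("I", "I", 0.5)]:
            blk = wm.block(a, b)
            assert abs(_density(blk) - p) < 5 * _se(p, blk.size)
        assert wm.matrix.diagonal().sum() == 0.0

    def test_indivisible_cluster_size_rejected(self):
        spec = cn.NetworkSpec(N_E=401, N_I=100, Q=5,
                              clustering_mode="E_weights", J_Eplus=2.0)
        with pytest.raises(ValueError, match="divisible"):
            cn.build_matrix(spec, seed=0)


class TestProbabilityClusteredBuild:
    def test_density_contrast_and_mean_preserved(self, small_spec):
        spec = small_spec.replace(clustering_mode="E_probability", R_EE=2.0)
        wm = cn.build_probability_clustered(spec, seed=5)
        EE = wm.block("E", "E")
        cl = wm.cluster.assignment_E
        same = cl[:, None] == cl[None, :]
        d_in, d_out = _density(EE[same]), _density(EE[~same])
        p_in, p_out = probability_clustering(5, 0.2, 2.0)
        assert abs(d_in - p_in) < 5 * _se(p_in, same.sum())
        assert abs(d_out - p_out) < 5 * _se(p_out, (~same).sum())
        assert abs(_density(EE) - 0.2) < 5 * _se(0.2, EE.size)

    def test_identity_ratio(self, small_spec):
        wm = cn.build_probability_clustered(small_spec, R_EE=1.0, seed=6)
        EE = wm.block("E", "E")
        assert abs(_density(EE) - 0.2) < 5 * _se(0.2, EE.size)


class TestBackgroundVariant:
    def test_partition_arithmetic(self):
        spec = cn.NetworkSpec(clustering_mode="E_weights_background",
                              background_fraction=0.1)
        cl = cn.ClusterSpec.from_spec(spec)
        assert (cl.assignment_E == -1).sum() == 400
        assert (cl.assignment_E == 0).sum() == 180

    def test_background_rows_keep_expected_input(self, small_spec):
        spec = small_spec.replace(clustering_mode="E_weights_background",
                                  background_fraction=0.1, J_Eplus=3.0)
        w = cn.derive_weights(spec)
        expected = spec.N_E * spec.p_EE * w.J_EE
        sums = []
        for r in range(20):
            wm = cn.build_background_variant(spec, seed=300 + r)
            bg = wm.cluster.assignment_E == -1
            sums.append(wm.block("E", "E")[bg].sum(axis=1).mean())
        se = np.std(sums, ddof=1) / np.sqrt(len(sums))
        assert abs(np.mean(sums) - expected) < 5 * se

    def test_zero_fraction_degenerates_to_weight_clustering(self, small_spec):
        spec = small_spec.replace(clustering_mode="E_weights_background",
                                  background_fraction=0.0, J_Eplus=2.0)
        wm = cn.build_background_variant(spec, background_fraction=0.0, seed=8)
        assert (wm.cluster.assignment_E >= 0).all()
        ref = cn.build_matrix(small_spec.replace(clustering_mode="E_weights",
                                                 J_Eplus=2.0), seed=8)
        assert np.array_equal(np.asarray(wm.matrix), np.asarray(ref.matrix))
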