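"""Feature-encoder operations against scalar-loop oracles and invariants."""

import numpy as np
import pytest

from tgfm.autodiff import Parameter, Tensor
from tgfm.featurize import (DegreeScaler, EdgeTypeModulation, FeatureEncoder,
                            FeatureFusion, GaussianBasis, SQRT_2PI, combine,
                            degree_scale, edge_scatter, fuse_features,
                            gauss_encode, modulate_distances)
from tgfm.predictor import ModelConfig

RNG = np.random.default_rng(17)


class TestGaussEncode:
    def test_value_at_mean_is_inverse_sqrt_2pi(self):
        basis = GaussianBasis(3, np.random.default_rng(0))
        basis.u.data[:] = [1.0, 2.0, 3.0]
        out = gauss_encode(np.array([2.0]), basis)
        assert out.data[0, 1] == pytest.approx(1.0 / SQRT_2PI)  # ~0.398942

    def test_monotone_decay_away_from_mean(self):
        basis = GaussianBasis(1, np.random.default_rng(0))
        basis.u.data[:] = 1.5
        d = np.array([1.5, 2.0, 2.5, 3.5, 6.0])
        vals = gauss_encode(d, basis).data[:, 0]
        assert np.all(np.diff(vals) < 0)

    def test_matches_scalar_loop_oracle(self):
        basis = GaussianBasis(4, np.random.default_rng(1))
        d = RNG.uniform(0.5, 4.0, 5)
        out = gauss_encode(d, basis).data
        sigma = np.exp(basis.log_sigma.data)
        for e in range(5):
            for i in range(4):
                expected = np.exp(-0.5 * ((d[e] - basis.u.data[i]) / sigma[i]) ** 2) / SQRT_2PI
                assert out[e, i] == pytest.approx(expected, abs=1e-12)

    def test_outputs_bounded_by_normaliser(self):
        basis = GaussianBasis(8, np.random.default_rng(2))
        out = gauss_encode(RNG.uniform(0, 5, 50), basis).data
        assert np.all(out > 0) and np.all(out <= 1.0 / SQRT_2PI + 1e-15)

    def test_sigma_normalised_option(self):
        rng = np.random.default_rng(3)
        basis = GaussianBasis(2, rng, normalize_by_sigma=True)
        basis.log_sigma.data[:] = np.log(2.0)
        basis.u.data[:] = 1.0
        out = gauss_encode(np.array([1.0]), basis)
        assert out.data[0, 0] == pytest.approx(1.0 / (2.0 * SQRT_2PI))

    def test_nonfinite_distance_fatal(self):
        basis = GaussianBasis(2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="non-finite"):
            gauss_encode(np.array([np.nan]), basis)


class TestEdgeScatter:
    def test_identical_edge_features_give_that_vector(self):
        x = np.tile([1.0, 2.0, 3.0], (4, 1))
        EI = np.array([[1, 2, 3, 1], [0, 0, 0, 2]])
        out = edge_scatter(Tensor(x), EI, 4)
        np.testing.assert_allclose(out.data[0], [1, 2, 3])

    def test_isolated_node_gets_zero_vector(self):
        out = edge_scatter(Tensor(np.ones((2, 3))), np.array([[0, 1], [1, 0]]), 4)
        np.testing.assert_array_equal(out.data[2], 0)
        np.testing.assert_array_equal(out.data[3], 0)

    def test_matches_incidence_loop_oracle(self):
        n, m, dim = 8, 14, 5
        EI = np.stack([RNG.integers(0, n, m), RNG.integers(0, n, m)])
        feats = RNG.normal(size=(m, dim))
        out = edge_scatter(Tensor(feats), EI, n).data
        for v in range(n):
            incident = np.flatnonzero(EI[1] == v)
            expected = (feats[incident].sum(axis=0) / len(incident)
                        if len(incident) else np.zeros(dim))
            np.testing.assert_allclose(out[v], expected, atol=1e-12)

    def test_invalid_endpoint_fatal(self):
        with pytest.raises(ValueError, match="out of range"):
            edge_scatter(Tensor(np.ones((1, 2))), np.array([[0], [5]]), 3)


class TestDegreeScaler:
    def test_all_ones_is_identity(self):
        scaler = DegreeScaler(4)
        Psi = Tensor(RNG.normal(size=(5, 4)))
        degrees = np.array([1, 2, 3, 4, 0])
        np.testing.assert_array_equal(degree_scale(Psi, degrees, scaler).data,
                                      Psi.data)

    def test_degree_seven_uses_degree_four_column(self):
        scaler = DegreeScaler(3)
        scaler.lam.data[:, 3] = 5.0
        Psi = Tensor(np.ones((2, 3)))
        out = degree_scale(Psi, np.array([7, 4]), scaler).data
        np.testing.assert_allclose(out[0], out[1])
        np.testing.assert_allclose(out[0], 5.0)

    def test_doubling_one_column_doubles_only_that_bucket(self):
        dim = 6
        scaler = DegreeScaler(dim)
        Psi = Tensor(RNG.normal(size=(6, dim)))
        degrees = np.array([1, 2, 2, 3, 4, 1])
        base = degree_scale(Psi, degrees, scaler).data.copy()
        scaler.lam.data[:, 1] *= 2.0           # bucket of degree-2 nodes
        out = degree_scale(Psi, degrees, scaler).data
        mask = degrees == 2
        np.testing.assert_allclose(out[mask], 2.0 * base[mask])
        np.testing.assert_allclose(out[~mask], base[~mask])

    def test_degree_zero_rows_pass_through(self):
        scaler = DegreeScaler(3)
        scaler.lam.data[:] = 7.0
        Psi = Tensor(np.ones((2, 3)))
        out = degree_scale(Psi, np.array([0, 1]), scaler).data
        np.testing.assert_allclose(out[0], 1.0)
        np.testing.assert_allclose(out[1], 7.0)


class TestCombineAndVariants:
    def test_zero_psi_gives_atom_features(self):
        A = Tensor(RNG.normal(size=(3, 4)))
        assert np.array_equal(combine(A, Tensor(np.zeros((3, 4)))).data, A.data)

    def test_commutative(self):
        A, B = Tensor(RNG.normal(size=(3, 4))), Tensor(RNG.normal(size=(3, 4)))
        np.testing.assert_array_equal(combine(A, B).data, combine(B, A).data)

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            combine(Tensor(np.zeros((2, 3))), Tensor(np.zeros((3, 2))))

    def test_gradient_flows_to_both_summands(self):
        A = Parameter(RNG.normal(size=(3, 4)))
        B = Parameter(RNG.normal(size=(3, 4)))
        (combine(A, B) * Tensor(RNG.normal(size=(3, 4)))).sum().backward()
        assert np.any(A.grad != 0) and np.any(B.grad != 0)
        np.testing.assert_array_equal(A.grad, B.grad)

    def test_modulation_identity(self):
        mod = EdgeTypeModulation(3)
        D = np.array([1.0, 2.0, 1.5])
        out = modulate_distances(D, np.array([0, 1, 2]), mod)
        np.testing.assert_array_equal(out.data, D)

    def test_modulation_same_type_same_distance_same_output(self):
        mod = EdgeTypeModulation(2)
        mod.scale.data[:] = [2.0, 3.0]
        mod.shift.data[:] = [0.1, 0.2]
        out = modulate_distances(np.array([1.5, 1.5]), np.array([1, 1]), mod)
        assert out.data[0] == out.data[1]

    def test_modulation_matches_per_edge_oracle(self):
        mod = EdgeTypeModulation(4)
        mod.scale.data[:] = RNG.normal(1, 0.2, 4)
        mod.shift.data[:] = RNG.normal(0, 0.1, 4)
        D = RNG.uniform(1, 3, 10)
        T = RNG.integers(0, 4, 10)
        out = modulate_distances(D, T, mod).data
        for e in range(10):
            assert out[e] == pytest.approx(
                mod.scale.data[T[e]] * D[e] + mod.shift.data[T[e]], abs=1e-12)

    def test_modulation_out_of_range_fatal(self):
        with pytest.raises(ValueError, match="out of range"):
            modulate_distances(np.array([1.0]), np.array([5]),
                               EdgeTypeModulation(3))

    def test_fusion_saturated_gate_selects_2d(self):
        fusion = FeatureFusion(4, np.random.default_rng(0))
        fusion.gate.weight.data[:] = 0.0
        fusion.gate.bias.data[:] = 50.0         # logistic -> 1
        F2d, F3d = Tensor(RNG.normal(size=(3, 4))), Tensor(RNG.normal(size=(3, 4)))
        np.testing.assert_allclose(fuse_features(F2d, F3d, fusion).data,
                                   F2d.data, atol=1e-12)

    def test_fusion_half_gate_with_equal_inputs(self):
        fusion = FeatureFusion(4, np.random.default_rng(0))
        fusion.gate.weight.data[:] = 0.0
        fusion.gate.bias.data[:] = 0.0          # logistic -> 0.5
        F = Tensor(RNG.normal(size=(3, 4)))
        np.testing.assert_allclose(fuse_features(F, F, fusion).data, F.data)

    def test_fusion_output_between_inputs(self):
        fusion = FeatureFusion(5, np.random.default_rng(1))
        F2d, F3d = Tensor(RNG.normal(size=(6, 5))), Tensor(RNG.normal(size=(6, 5)))
        out = fuse_features(F2d, F3d, fusion).data
        lo = np.minimum(F2d.data, F3d.data)
        hi = np.maximum(F2d.data, F3d.data)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)
        assert fusion.last_weights.shape == (6, 1)   # weights exposed


class TestEncoderInvariances:
    def _encode(self, cfg, ds):
        enc = FeatureEncoder(cfg.resolved(), np.random.default_rng(0))
        EI = ds.global_edge_index()
        return enc, enc(ds.A, EI, ds.A.shape[0], D=ds.D, EA=ds.EA, T=ds.T)

    def test_permutation_equivariance(self, small_ds, tiny_config):
        from tgfm import pack, preprocess
        rec = small_ds.molecule(3)
        perm = np.random.default_rng(4).permutation(rec.n_atoms)
        ds1, _ = preprocess(pack([rec]))
        ds2, _ = preprocess(pack([rec.permuted(perm)]))
        enc = FeatureEncoder(tiny_config.resolved(), np.random.default_rng(0))
        F1 = enc(ds1.A, ds1.global_edge_index(), ds1.A.shape[0], D=ds1.D,
                 EA=ds1.EA, T=ds1.T).data
        F2 = enc(ds2.A, ds2.global_edge_index(), ds2.A.shape[0], D=ds2.D,
                 EA=ds2.EA, T=ds2.T).data
        np.testing.assert_allclose(F2, F1[perm], atol=1e-12)

    def test_rigid_motion_invariance(self, small_records, tiny_config):
        import dataclasses
        from scipy.spatial.transform import Rotation
        from tgfm import pack, preprocess
        rec = small_records[0]
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = dataclasses.replace(rec, coords=rec.coords @ R.T + [5.0, -2.0, 1.0])
        ds1, _ = preprocess(pack([rec]))
        ds2, _ = preprocess(pack([moved]))
        enc = FeatureEncoder(tiny_config.resolved(), np.random.default_rng(0))
        F1 = enc(ds1.A, ds1.global_edge_index(), ds1.A.shape[0], D=ds1.D,
                 EA=ds1.EA, T=ds1.T).data
        F2 = enc(ds2.A, ds2.global_edge_index(), ds2.A.shape[0], D=ds2.D,
                 EA=ds2.EA, T=ds2.T).data
        np.testing.assert_allclose(F2, F1, atol=1e-9)

    def test_component_parameter_deltas(self, tiny_config):
        import dataclasses
        from tgfm import count_parameters
        N = tiny_config.embed_dim
        full = count_parameters(tiny_config)
        no_scaler = count_parameters(dataclasses.replace(
            tiny_config, use_degree_scaler=False))
        assert full - no_scaler == 4 * N
        atoms_only = count_parameters(dataclasses.replace(
            tiny_config, edge_source="none", use_edge_scatter=False,
            use_degree_scaler=False))
        assert full - atoms_only == 4 * N + 2 * N     # scaler + Gaussian basis
        with_mod = count_parameters(dataclasses.replace(
            tiny_config, variant="edge_attributes", n_edge_types=11))
        assert with_mod - full == 22
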