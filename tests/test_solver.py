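import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tlpca
from tlpca.exceptions import ConvergenceWarning, SingularSystemError, ValidationError

LEU_ROW = np.array([1.2906, 0.0, 84.5476, 0.0, 1.21, 1.30, 0.68, 166.7])


def brute_force_collapse(X, vec, axis):
    """Plain triple-loop contraction used as oracle for the einsum paths."""
    N, L, K = X.shape
    if axis == "fragment":  # weight fragments -> N x K
        out = np.zeros((N, K))
        for i in range(N):
            for k in range(K):
                for l in range(L):
                    out[i, k] += vec[l] * X[i, l, k]
    else:  # weight properties -> N x L
        out = np.zeros((N, L))
        for i in range(N):
            for l in range(L):
                for k in range(K):
                    out[i, l] += vec[k] * X[i, l, k]
    return out


class TestCollapse:
    def test_all_ones_sums_fragments(self, small_tensor):
        F = tlpca.collapse_to_property_matrix(small_tensor, np.ones(3))
        np.testing.assert_allclose(F, small_tensor.X.sum(axis=1))

    def test_zero_weights_give_zero(self, small_tensor):
        assert not tlpca.collapse_to_property_matrix(small_tensor, np.zeros(3)).any()
        assert not tlpca.collapse_to_fragment_matrix(small_tensor, np.zeros(2)).any()

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(3, 2, 2))
        B = np.array([1.0, -1.0])
        np.testing.assert_allclose(
            tlpca.collapse_to_property_matrix(X, B), brute_force_collapse(X, B, "fragment")
        )
        A = rng.normal(size=2)
        np.testing.assert_allclose(
            tlpca.collapse_to_fragment_matrix(X, A), brute_force_collapse(X, A, "property")
        )

    def test_unit_property_vector_extracts_slice(self, small_tensor):
        e0 = np.array([1.0, 0.0])
        H = tlpca.collapse_to_fragment_matrix(small_tensor, e0)
        np.testing.assert_allclose(H, small_tensor.X[:, :, 0])

    def test_leucine_fragment_contribution(self, benchmark):
        """A Leu side chain under the published property coefficients."""
        dg = float(LEU_ROW @ benchmark.reference_model.A)
        assert dg == pytest.approx(0.8214, abs=5e-4)

    def test_length_mismatch_rejected(self, small_tensor):
        with pytest.raises(ValidationError):
            tlpca.collapse_to_property_matrix(small_tensor, np.ones(4))
        with pytest.raises(ValidationError):
            tlpca.collapse_to_fragment_matrix(small_tensor, np.ones(3))


class TestSolveNormalSystem:
    def test_identity_returns_rhs(self):
        rhs = np.array([2.0, -1.0, 0.5])
        np.testing.assert_allclose(tlpca.solve_normal_system(np.eye(3), rhs), rhs)

    @given(seed=st.integers(0, 200))
    @settings(deadline=None, max_examples=40)
    def test_matches_dense_solver_on_well_conditioned_systems(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 11))
        G = rng.normal(size=(2 * p, p))
        M = G.T @ G + 0.5 * np.eye(p)
        rhs = rng.normal(size=p)
        x = tlpca.solve_normal_system(M, rhs)
        expected = np.linalg.solve(M, rhs)
        assert np.linalg.norm(x - expected) <= 1e-8 * np.linalg.norm(expected)

    def test_tiny_eigenvalue_suppressed(self):
        M = np.diag([1.0, 1e-30])
        x = tlpca.solve_normal_system(M, np.array([1.0, 1.0]))
        np.testing.assert_allclose(x, [1.0, 0.0])

    def test_all_zero_matrix_is_singular(self):
        with pytest.raises(SingularSystemError):
            tlpca.solve_normal_system(np.zeros((3, 3)), np.ones(3))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            tlpca.solve_normal_system(np.array([[1.0, 2.0], [0.0, 1.0]]), np.ones(2))

    def test_principal_energy_truncates_spectrum(self):
        # diag(8, 1, 1): leading eigenvalue is 80% of the spectrum, so a 0.75
        # cutoff keeps only it and the solution loses the other components.
        M = np.diag([8.0, 1.0, 1.0])
        cfg = tlpca.SolverConfig(principal_energy=0.75)
        x = tlpca.solve_normal_system(M, np.array([8.0, 1.0, 1.0]), cfg)
        np.testing.assert_allclose(x, [1.0, 0.0, 0.0])


class TestFit:
    def test_exact_model_recovered_noise_free(self):
        tensor, a, b = tlpca.simulate_tensor(tlpca.SyntheticSpec(n_samples=60, seed=5))
        model, trace = tlpca.fit(tensor, tlpca.SolverConfig(epsilon=1e-12))
        assert model.converged
        assert trace.r_b[-1] == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(
            tlpca.predict(model, tensor), tensor.W,
            rtol=1e-8, atol=1e-8 * float(np.std(tensor.W)),
        )

    def test_training_error_non_increasing_across_half_steps(self):
        tensor, _, _ = tlpca.simulate_tensor(
            tlpca.SyntheticSpec(n_samples=120, noise_sd=1.0, seed=11)
        )
        _, trace = tlpca.fit(tensor)
        qs = []
        for qa, qb in zip(trace.q_a, trace.q_b):
            qs.extend([qa, qb])
        diffs = np.diff(qs)
        assert np.all(diffs <= 1e-8)

    def test_missing_activities_rejected(self, small_tensor):
        with pytest.raises(ValidationError, match="activities"):
            tlpca.fit(small_tensor.without_activities())

    def test_underdetermined_fit_warns(self):
        tensor, _, _ = tlpca.simulate_tensor(
            tlpca.SyntheticSpec(n_samples=4, n_fragments=4, n_properties=3, seed=0)
        )
        with pytest.warns(UserWarning, match="under-determined|weakly"):
            tlpca.fit(tensor)

    def test_iteration_cap_flags_non_convergence(self):
        tensor, _, _ = tlpca.simulate_tensor(
            tlpca.SyntheticSpec(n_samples=80, noise_sd=2.0, seed=2)
        )
        cfg = tlpca.SolverConfig(epsilon=1e-15, max_iterations=2)
        with pytest.warns(ConvergenceWarning):
            model, trace = tlpca.fit(tensor, cfg)
        assert not model.converged
        assert model.n_iterations == 2
        assert len(trace) == 2

    def test_trace_values_within_bounds(self, benchmark_fit):
        _, trace = benchmark_fit
        frame = trace.to_frame()
        assert ((frame[["R_a", "R_b"]] >= -1) & (frame[["R_a", "R_b"]] <= 1)).all().all()
        assert (frame[["Q_a", "Q_b"]] >= 0).all().all()


class TestPredict:
    def test_scale_invariance(self, small_tensor):
        rng = np.random.default_rng(1)
        model = tlpca.CoefficientModel(
            A=rng.normal(size=2), B=rng.normal(size=3),
            property_names=small_tensor.property_names,
            fragment_labels=small_tensor.fragment_labels,
        )
        base = tlpca.predict(model, small_tensor)
        for c in (2.0, -0.5, 1e6):
            scaled = tlpca.CoefficientModel(
                A=model.A * c, B=model.B / c,
                property_names=model.property_names,
                fragment_labels=model.fragment_labels,
            )
            np.testing.assert_allclose(tlpca.predict(scaled, small_tensor), base, rtol=1e-10)

    def test_zero_tensor_predicts_zero(self, benchmark):
        model = benchmark.reference_model
        tensor = tlpca.FragmentTensor(
            ("z",), model.fragment_labels, model.property_names,
            np.zeros((1, 9, 8)),
        )
        assert tlpca.predict(model, tensor) == pytest.approx([0.0])

    def test_label_mismatch_rejected(self, benchmark, small_tensor):
        with pytest.raises(ValidationError, match="labels"):
            tlpca.predict(benchmark.reference_model, small_tensor)

    def test_normalized_model_same_predictions(self, benchmark_fit, training_tensor):
        model, _ = benchmark_fit
        normed = tlpca.normalize_model(model)
        assert np.linalg.norm(normed.B) == pytest.approx(np.sqrt(9))
        np.testing.assert_allclose(
            tlpca.predict(normed, training_tensor),
            tlpca.predict(model, training_tensor),
            rtol=1e-10,
        )


class TestMetrics:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert tlpca.pearson_r(x, x) == pytest.approx(1.0)
        assert tlpca.pearson_r(-x, x) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            tlpca.pearson_r(np.ones(5), np.arange(5.0))

    def test_pearson_matches_direct_formula_on_printed_test_set(self, benchmark):
        from tlpca.datasets import testing_frame

        frame = testing_frame()
        pred, expt = frame["predicted"].to_numpy(), frame["activity"].to_numpy()
        # direct evaluation of the product-moment formula
        dp, de = pred - pred.mean(), expt - expt.mean()
        expected = (dp * de).sum() / np.sqrt((dp**2).sum() * (de**2).sum())
        assert tlpca.pearson_r(pred, expt) == pytest.approx(expected, abs=1e-12)

    def test_q_residue_basic_values(self):
        x = np.arange(5.0)
        assert tlpca.q_residue(x, x) == 0.0
        assert tlpca.q_residue(x, x + 2.0) == pytest.approx(2.0)

    def test_q_residue_on_printed_training_differences(self):
        from tlpca.datasets import training_frame

        frame = training_frame()
        expected = float(np.sqrt(np.mean(frame["difference"].to_numpy() ** 2)))
        q = tlpca.q_residue(frame["predicted"].to_numpy(), frame["activity"].to_numpy())
        assert q == pytest.approx(expected, abs=1e-3)  # printed columns are rounded

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tlpca.q_residue(np.ones(3), np.ones(4))


class TestModelIO:
    def test_model_json_round_trip_bit_stable(self, benchmark_fit, tmp_path):
        model, _ = benchmark_fit
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        model.save(p1)
        again = tlpca.CoefficientModel.load(p1)
        np.testing.assert_array_equal(again.A, model.A)
        np.testing.assert_array_equal(again.B, model.B)
        assert again.property_names == model.property_names
        assert again.config == model.config
        again.save(p2)
        assert p1.read_text() == p2.read_text()

    def test_trace_export_round_trip(self, benchmark_fit, tmp_path):
        _, trace = benchmark_fit
        path = tmp_path / "trace.csv"
        trace.save(path)
        header = path.read_text().splitlines()[0]
        assert header == "iteration,R_a,Q_a,R_b,Q_b"
        again = tlpca.FitTrace.load(path)
        np.testing.assert_allclose(again.r_b, trace.r_b)
        np.testing.assert_allclose(again.q_a, trace.q_a)
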