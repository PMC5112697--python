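import numpy as np
import pytest

from pdmedit.dataset_io import SyntheticConfig, generate_synthetic
from pdmedit.dnne import (
    DNNEModel,
    DnneError,
    NormalSystem,
    RVFLEnsembleSpec,
    build_normal_system,
    c_constants,
    dnne_grid_search,
    dnne_predict,
    dnne_train,
    flatten_index,
    hidden_activations,
    index_map,
    solve_output_weights,
)


class TestCConstants:
    @pytest.mark.parametrize(
        "lam,M,expected",
        [
            (0.0, 2, (1.0, 0.0)),
            (0.0, 7, (1.0, 0.0)),
            (0.5, 2, (0.75, 0.25)),
            (1.0, 10, (-0.62, 0.18)),  # C1 may go negative
        ],
    )
    def test_known_values(self, lam, M, expected):
        c1, c2 = c_constants(lam, M)
        assert c1 == pytest.approx(expected[0])
        assert c2 == pytest.approx(expected[1])

    def test_conservation_identity_on_full_grid(self):
        # C1 + (M-1)*C2 = 1 for every lambda and M
        for M in range(2, 16):
            for lam in [round(0.1 * i, 1) for i in range(11)]:
                c1, c2 = c_constants(lam, M)
                assert c1 + (M - 1) * c2 == pytest.approx(1.0, abs=1e-14)

    def test_out_of_range_rejected(self):
        with pytest.raises(DnneError):
            c_constants(-0.1, 3)
        with pytest.raises(DnneError):
            c_constants(1.1, 3)
        with pytest.raises(DnneError):
            c_constants(0.5, 1)


class TestIndexMap:
    @pytest.mark.parametrize("p,L,expected", [(1, 5, (1, 1)), (7, 5, (2, 2)), (5, 5, (1, 5)), (6, 5, (2, 1))])
    def test_known_values(self, p, L, expected):
        assert index_map(p, L) == expected

    def test_round_trip_exhaustive(self):
        M, L = 3, 4
        for p in range(1, M * L + 1):
            m, n = index_map(p, L)
            assert flatten_index(m, n, L) == p

    def test_out_of_range(self):
        with pytest.raises(DnneError):
            index_map(0, 5)
        with pytest.raises(DnneError):
            flatten_index(1, 6, 5)


class TestHiddenActivations:
    def test_zero_weights_give_half(self):
        spec = RVFLEnsembleSpec(M=2, L=3, d=4, lam=0.5, seed=0)
        spec.hidden_weights[:] = 0.0
        spec.hidden_biases[:] = 0.0
        G = hidden_activations(spec, np.random.default_rng(0).normal(size=(5, 4)))
        assert np.all(G == 0.5)

    def test_entries_strictly_in_unit_interval(self):
        spec = RVFLEnsembleSpec(M=3, L=4, d=6, lam=0.2, seed=1)
        G = hidden_activations(spec, np.random.default_rng(1).normal(size=(20, 6)))
        assert G.shape == (20, 12)
        assert np.all((G > 0) & (G < 1))

    def test_column_ordering_is_network_major(self):
        spec = RVFLEnsembleSpec(M=2, L=2, d=3, lam=0.0, seed=2)
        x = np.random.default_rng(3).normal(size=(1, 3))
        G = hidden_activations(spec, x)
        from scipy.special import expit

        # column (m-1)*L + n-1 must hold neuron n of network m
        for m in range(2):
            for n in range(2):
                z = spec.hidden_weights[m, n] @ x[0] + spec.hidden_biases[m, n]
                assert G[0, m * 2 + n] == pytest.approx(expit(z))

    def test_dimension_mismatch(self):
        spec = RVFLEnsembleSpec(M=2, L=2, d=3, lam=0.0, seed=0)
        with pytest.raises(DnneError):
            hidden_activations(spec, np.zeros((2, 4)))


class TestNormalSystem:
    def test_hand_worked_two_network_fixture(self):
        # M=2, L=1, g11=[1,2], g21=[3,4], y=[1,0], lam=0.5:
        # phi(1,1,1,1)=5, phi(1,1,2,1)=11, phi(2,1,2,1)=25, (C1,C2)=(0.75,0.25)
        G = np.array([[1.0, 3.0], [2.0, 4.0]])
        y = np.array([1.0, 0.0])
        system = build_normal_system(G, y, 0.5, 2, 1)
        np.testing.assert_allclose(
            system.H_corr, [[3.75, 2.75], [2.75, 18.75]], atol=1e-12
        )
        np.testing.assert_allclose(system.T_h, [1.0, 3.0], atol=1e-12)
        B, note = solve_output_weights(system)
        np.testing.assert_allclose(
            B, [10.5 / 62.75, 8.5 / 62.75], atol=1e-12
        )

    def test_lambda_zero_is_block_diagonal(self):
        rng = np.random.default_rng(4)
        G = rng.uniform(0, 1, size=(20, 6))
        system = build_normal_system(G, rng.normal(size=20), 0.0, 3, 2)
        for i in range(3):
            for k in range(3):
                block = system.H_corr[i * 2 : (i + 1) * 2, k * 2 : (k + 1) * 2]
                if i != k:
                    assert np.all(block == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_structural_identity(self, seed):
        rng = np.random.default_rng(seed)
        M, L, N = 3, 4, 30
        G = rng.uniform(0, 1, size=(N, M * L))
        y = rng.normal(size=N)
        lam = rng.uniform(0, 1)
        system = build_normal_system(G, y, lam, M, L)
        H = system.H_corr
        assert np.allclose(H, H.T, rtol=1e-10)
        # independent construction: (C1 - C2) * blockdiag(Gi^T Gi) + C2 * G^T G
        from pdmedit.dnne import c_constants

        c1, c2 = c_constants(lam, M)
        ref = c2 * (G.T @ G)
        for i in range(M):
            Gi = G[:, i * L : (i + 1) * L]
            ref[i * L : (i + 1) * L, i * L : (i + 1) * L] += (c1 - c2) * (Gi.T @ Gi)
        np.testing.assert_allclose(H, ref, rtol=1e-10, atol=1e-12)

    def test_non_finite_rejected(self):
        G = np.ones((3, 4))
        G[0, 0] = np.nan
        with pytest.raises(DnneError):
            build_normal_system(G, np.zeros(3), 0.5, 2, 2)


class TestSolver:
    def test_identity_system(self):
        sys_ = NormalSystem(np.eye(3), np.array([1.0, -2.0, 0.5]), 3, 1, 0.0)
        B, note = solve_output_weights(sys_)
        np.testing.assert_array_equal(B, sys_.T_h)
        assert note.method == "direct"

    def test_residual_contract_on_well_conditioned_system(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(10, 10))
        H = A @ A.T + 10 * np.eye(10)
        T = rng.normal(size=10)
        B, note = solve_output_weights(NormalSystem(H, T, 5, 2, 0.3))
        assert note.method == "direct"
        assert np.abs(H @ B - T).max() <= 1e-8 * max(1.0, np.abs(T).max())

    def test_singular_system_falls_back_with_record(self):
        H = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank deficient
        T = np.array([1.0, 1.0])
        B, note = solve_output_weights(NormalSystem(H, T, 2, 1, 1.0))
        assert note.method in ("ridge", "pinv")
        assert np.all(np.isfinite(B))
        assert note.ridge_eps  # escalation was recorded

    def test_agrees_with_generic_dense_solve(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            A = rng.normal(size=(8, 8))
            H = A @ A.T + 5 * np.eye(8)
            T = rng.normal(size=8)
            B, _ = solve_output_weights(NormalSystem(H, T, 4, 2, 0.1))
            np.testing.assert_allclose(B, np.linalg.solve(H, T), atol=1e-8)


class TestTrainPredict:
    def test_bit_identical_retrain(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        m1 = dnne_train(X, y, M=3, L=5, lam=0.4, seed=11)
        m2 = dnne_train(X, y, M=3, L=5, lam=0.4, seed=11)
        np.testing.assert_array_equal(m1.B_ens, m2.B_ens)

    def test_lambda_zero_decouples_into_per_network_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, 50).astype(float)
        model = dnne_train(X, y, M=3, L=5, lam=0.0, seed=5)
        G = hidden_activations(model.spec, model.scaler.transform(X))
        for i in range(3):
            Gi = G[:, i * 5 : (i + 1) * 5]
            beta = np.linalg.solve(Gi.T @ Gi, Gi.T @ y)
            np.testing.assert_allclose(
                model.B_ens[i * 5 : (i + 1) * 5], beta, atol=1e-8
            )
        # and the ensemble score is the mean of per-network OLS predictions
        scores, _ = dnne_predict(model, X)
        per_net = np.mean(
            [
                G[:, i * 5 : (i + 1) * 5]
                @ np.linalg.solve(
                    G[:, i * 5 : (i + 1) * 5].T @ G[:, i * 5 : (i + 1) * 5],
                    G[:, i * 5 : (i + 1) * 5].T @ y,
                )
                for i in range(3)
            ],
            axis=0,
        )
        np.testing.assert_allclose(scores, per_net, atol=1e-8)

    def test_separable_data_trains_to_perfect_accuracy(self):
        ds = generate_synthetic(
            SyntheticConfig(
                subjects_per_class=5, samples_per_subject=8, d=4,
                class_separation=15.0, subject_sd=0.5, noise_sd=0.3,
                contamination=0.0, seed=3,
            )
        )
        model = dnne_train(ds.X, ds.y, M=5, L=20, lam=0.5, seed=2)
        _, labels = dnne_predict(model, ds.X)
        assert np.mean(labels == ds.y) == 1.0

    def test_zero_weights_predict_all_healthy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        model = dnne_train(X, rng.integers(0, 2, 10), M=2, L=3, lam=0.0, seed=0)
        model.B_ens = np.zeros_like(model.B_ens)
        scores, labels = dnne_predict(model, X)
        assert np.all(scores == 0.0) and np.all(labels == 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        model = dnne_train(X, rng.integers(0, 2, 20), M=2, L=4, lam=0.3, seed=1)
        perm = rng.permutation(20)
        s1, l1 = dnne_predict(model, X)
        s2, l2 = dnne_predict(model, X[perm])
        np.testing.assert_array_equal(s1[perm], s2)
        np.testing.assert_array_equal(l1[perm], l2)

    def test_single_class_rejected(self):
        with pytest.raises(DnneError):
            dnne_train(np.zeros((5, 2)), np.zeros(5), M=2, L=2, lam=0.0, seed=0)

    def test_json_round_trip_is_bit_exact(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        model = dnne_train(X, rng.integers(0, 2, 30), M=3, L=4, lam=0.6, seed=9)
        back = DNNEModel.from_json(model.to_json())
        s1, _ = dnne_predict(model, X)
        s2, _ = dnne_predict(back, X)
        np.testing.assert_array_equal(s1, s2)

    def test_bagging_mode_changes_fit_but_stays_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        m1 = dnne_train(X, y, M=3, L=4, lam=0.2, seed=1, bagging_fraction=0.6)
        m2 = dnne_train(X, y, M=3, L=4, lam=0.2, seed=1, bagging_fraction=0.6)
        full = dnne_train(X, y, M=3, L=4, lam=0.2, seed=1)
        np.testing.assert_array_equal(m1.B_ens, m2.B_ens)
        assert not np.allclose(m1.B_ens, full.B_ens)


class TestGridSearch:
    def _data(self):
        ds = generate_synthetic(
            SyntheticConfig(
                subjects_per_class=4, samples_per_subject=6, d=3,
                class_separation=15.0, subject_sd=0.5, noise_sd=0.3,
                contamination=0.0, seed=6,
            )
        )
        return ds.X, ds.y, ds.subject_ids

    def test_single_cell_returned(self):
        X, y, groups = self._data()
        best, table = dnne_grid_search(
            X, y, groups, M_grid=[3], L_grid=[5], lam_grid=[0.5], seed=0
        )
        assert best == {"M": 3, "L": 5, "lam": 0.5}
        assert len(table) == 1

    def test_tie_breaks_toward_smaller_m(self):
        X, y, groups = self._data()
        best, table = dnne_grid_search(
            X, y, groups, M_grid=[2, 3], L_grid=[5], lam_grid=[0.0], seed=0
        )
        scores = table.set_index("M")["score"]
        if scores[2] == scores[3]:
            assert best["M"] == 2

    def test_separable_winner_is_perfect(self):
        X, y, groups = self._data()
        best, table = dnne_grid_search(
            X, y, groups, M_grid=[2, 4], L_grid=[5, 10], lam_grid=[0.0, 0.5],
            seed=0,
        )
        assert table["score"].max() == 1.0

    def test_boosting_threshold_ignored_with_warning(self):
        X, y, groups = self._data()
        with pytest.warns(UserWarning, match="boosting_threshold"):
            dnne_grid_search(
                X, y, groups, M_grid=[2], L_grid=[5], lam_grid=[0.0],
                boosting_threshold=0.4, seed=0,
            )
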