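import numpy as np
import pytest

import cortconn.forward as fwd
from cortconn.inverse import (
    CLoretaSolver,
    SourceActivationSet,
    cloreta_transform,
    em_refine_lambda,
    gcv_select_lambda,
    localize_epoch,
    localize_epochs,
    maxpower_roi_signals,
)


class TestTransform:
    def test_square_invertible_unregularized_limit(self, rng):
        K = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        T = cloreta_transform(K, np.eye(5), 0.0)
        np.testing.assert_allclose(T, np.linalg.inv(K), atol=1e-8)

    def test_matches_dense_pseudoinverse_oracle(self, rng):
        """Independent oracle: explicit dense inverse of the regularized
        normal equations."""
        K = rng.standard_normal((8, 32))
        mesh = fwd.build_source_mesh(0)
        H = np.kron(np.eye(3), fwd.surface_laplacian(mesh))[:32, :32]
        lam = 0.1
        T = cloreta_transform(K, H, lam)
        dense = np.linalg.inv(K.T @ K + lam**2 * H.T @ H) @ K.T
        assert np.max(np.abs(T - dense)) < 1e-8

    def test_norm_shrinks_with_lambda(self, small_model):
        solver = CLoretaSolver(small_model.K, small_model.H_lap)
        scale = np.median(solver.s)
        norms = [np.linalg.norm(solver.transform(lam)) for lam in scale * np.array([1, 10, 100])]
        assert norms[0] > norms[1] > norms[2]

    def test_solver_matches_literal_transform_at_tiny_ridge(self, small_model):
        solver = CLoretaSolver(small_model.K, small_model.H_lap, ridge=1e-12)
        lam = 0.5 * np.median(solver.s)
        T_fast = solver.transform(lam)
        T_lit = cloreta_transform(small_model.K, small_model.H_lap, lam)
        assert np.max(np.abs(T_fast - T_lit)) < 1e-8 * np.max(np.abs(T_lit))

    def test_negative_lambda_rejected(self, small_model):
        with pytest.raises(ValueError):
            cloreta_transform(small_model.K, small_model.H_lap, -1.0)


class TestGCV:
    def test_noise_free_data_selects_smallest_lambdas(self, small_solver, small_model, rng):
        g = 40
        phi = np.outer(small_model.K[:, g], np.sin(np.linspace(0, 30, 200)))
        grid = small_solver.lambda_grid()
        lam, _ = small_solver.gcv(phi, grid)
        assert lam <= grid[len(grid) // 3]

    def test_selected_lambda_increases_with_noise(self, small_solver, small_model):
        gen = np.random.default_rng(4)
        grid = small_solver.lambda_grid()
        lams = {snr: [] for snr in (100.0, 1.0)}
        for rep in range(20):
            g = int(gen.integers(0, small_model.n_gridpoints))
            phi = np.outer(small_model.K[:, g], np.sin(np.linspace(0, 30, 150) + rep))
            for snr in lams:
                noise = gen.standard_normal(phi.shape) * np.sqrt(np.mean(phi**2) / snr)
                lam, _ = small_solver.gcv(phi + noise, grid)
                lams[snr].append(lam)
        assert np.median(lams[1.0]) > np.median(lams[100.0])

    def test_single_point_grid_returned(self, small_solver, small_model, rng):
        phi = rng.standard_normal((small_model.n_channels, 50))
        lam, (grid, scores) = gcv_select_lambda(
            small_model.K, small_model.H_lap, phi, grid=np.array([0.7]), solver=small_solver
        )
        assert lam == 0.7 and len(scores) == 1

    def test_all_zero_epoch_rejected(self, small_solver, small_model):
        with pytest.raises(ValueError):
            small_solver.gcv(np.zeros((small_model.n_channels, 10)), small_solver.lambda_grid())


class TestEMRefinement:
    def test_recovers_known_variance_ratio(self, small_solver):
        """Parameter recovery when data truly follow the hierarchical
        Gaussian model with a known noise-to-prior ratio."""
        gen = np.random.default_rng(0)
        lam2_true = 25.0
        errs = []
        for rep in range(20):
            y = gen.standard_normal((small_solver.rank, 200))
            phi = small_solver.U @ (small_solver.s[:, None] * y)
            phi = phi + gen.standard_normal(phi.shape) * np.sqrt(lam2_true)
            lam0, _ = small_solver.gcv(phi, small_solver.lambda_grid())
            lam, _, _, _ = small_solver.em_refine(phi, lam0, max_iter=200)
            errs.append(abs(lam**2 - lam2_true) / lam2_true)
        assert np.median(errs) < 0.25

    def test_huge_tolerance_stops_after_one_iteration(self, small_solver, rng):
        phi = rng.standard_normal((small_solver.C, 30))
        _, iters, converged, _ = small_solver.em_refine(phi, 1.0, tol=1e6, max_iter=50)
        assert iters == 1 and converged

    def test_evidence_non_decreasing(self, small_solver, rng):
        phi = rng.standard_normal((small_solver.C, 60))
        lam0, _ = small_solver.gcv(phi, small_solver.lambda_grid())
        _, _, _, ev = small_solver.em_refine(phi, lam0, max_iter=100)
        ev = np.asarray(ev)
        assert np.all(np.diff(ev) >= -1e-6 * np.abs(ev[0]))

    def test_nonpositive_lambda0_rejected(self, small_solver, rng):
        with pytest.raises(ValueError):
            em_refine_lambda(None, None, rng.standard_normal((small_solver.C, 10)), 0.0, solver=small_solver)


class TestLocalize:
    def test_zero_data_zero_current(self, small_solver):
        T = small_solver.transform(1.0)
        act = localize_epoch(T, np.zeros((small_solver.C, 20)))
        assert not np.any(act.J)

    def test_linear_superposition(self, small_solver, rng):
        T = small_solver.transform(np.median(small_solver.s))
        p1 = rng.standard_normal((small_solver.C, 30))
        p2 = rng.standard_normal((small_solver.C, 30))
        J12 = localize_epoch(T, p1 + p2).J
        np.testing.assert_allclose(J12, localize_epoch(T, p1).J + localize_epoch(T, p2).J, atol=1e-12)

    def test_shape_mismatch_raises(self, small_solver, rng):
        T = small_solver.transform(1.0)
        with pytest.raises(ValueError):
            localize_epoch(T, rng.standard_normal((small_solver.C + 1, 10)))

    def test_planted_dipole_argmax_with_small_lambda(self, small_model, small_solver):
        gen = np.random.default_rng(2)
        g = 33
        phi = np.outer(small_model.K[:, g], np.sin(np.linspace(0, 40, 300)))
        phi += gen.standard_normal(phi.shape) * np.sqrt(np.mean(phi**2) / 1000)
        J = small_solver.apply(1e-3 * np.median(small_solver.s), phi)
        assert int(np.argmax(np.mean(J**2, axis=1))) == g


class TestMaxPower:
    def make_acts(self, J, gridpoints, fs=128.0):
        return SourceActivationSet(
            J=J, gridpoints=np.asarray(gridpoints), lambdas=np.zeros(J.shape[2]), fs=fs
        )

    def test_single_active_gridpoint_chosen(self):
        J = np.zeros((3, 10, 2))
        J[1] = 5.0
        roi = maxpower_roi_signals(self.make_acts(J, [7, 8, 9]), {"A": np.array([7, 8, 9])})
        assert roi.chosen_gridpoint["A"] == 8

    def test_tie_breaks_to_lowest_vertex_index(self):
        J = np.ones((2, 10, 2))
        J[0] *= 2.0  # powers 4.0 vs 1.0
        roi = maxpower_roi_signals(self.make_acts(J, [3, 5]), {"A": np.array([3, 5])})
        assert roi.chosen_gridpoint["A"] == 3
        J_eq = np.ones((2, 10, 2))
        roi_eq = maxpower_roi_signals(self.make_acts(J_eq, [3, 5]), {"A": np.array([3, 5])})
        assert roi_eq.chosen_gridpoint["A"] == 3

    def test_per_subject_matches_per_epoch_majority_on_stationary_sources(self, rng):
        J = rng.standard_normal((4, 50, 30)) * np.array([1.0, 3.0, 1.0, 0.5])[:, None, None]
        acts = self.make_acts(J, [0, 1, 2, 3])
        roi_map = {"A": np.array([0, 1, 2, 3])}
        per_subj = maxpower_roi_signals(acts, roi_map, scope="per_subject")
        per_epoch = maxpower_roi_signals(acts, roi_map, scope="per_epoch")
        majority = np.bincount(per_epoch.chosen_gridpoint["A"]).argmax()
        assert per_subj.chosen_gridpoint["A"] == majority == 1

    def test_empty_roi_raises(self):
        J = np.ones((2, 5, 1))
        with pytest.raises(ValueError):
            maxpower_roi_signals(self.make_acts(J, [0, 1]), {"A": np.array([], dtype=int)})

    def test_invalid_scope_rejected(self):
        J = np.ones((2, 5, 1))
        with pytest.raises(ValueError):
            maxpower_roi_signals(self.make_acts(J, [0, 1]), {"A": np.array([0])}, scope="bogus")


class TestPerEpochLambda:
    def test_adaptive_lambda_not_worse_than_global_on_heteroscedastic_epochs(
        self, small_model, small_solver
    ):
        """Per-epoch re-estimation should track epoch-varying noise."""
        gen = np.random.default_rng(6)
        from cortconn.io import EpochedEEG

        g = 25
        T = 100
        snrs = [100.0, 1.0, 30.0, 3.0, 10.0, 0.5]
        clean, noisy = [], []
        for i, snr in enumerate(snrs):
            phi = np.outer(small_model.K[:, g], np.sin(np.linspace(0, 25, T) + i))
            n = gen.standard_normal(phi.shape) * np.sqrt(np.mean(phi**2) / snr)
            clean.append(phi)
            noisy.append(phi + n)
        data = np.stack(noisy, axis=2)
        eeg = EpochedEEG(
            data=data, fs=128.0, channel_names=small_model.electrode_names,
            channel_pos=small_model.electrode_pos,
            condition=np.array(["test"] * len(snrs), dtype=object),
        )
        acts = localize_epochs(eeg, small_model, lam_mode="gcv", solver=small_solver)
        # global lambda: median of the per-epoch choices
        lam_global = float(np.median(acts.lambdas))
        err_adaptive = 0.0
        err_global = 0.0
        for i in range(len(snrs)):
            J_a = small_solver.apply(acts.lambdas[i], data[:, :, i])
            J_g = small_solver.apply(lam_global, data[:, :, i])
            err_adaptive += np.mean((small_model.K @ J_a - clean[i]) ** 2)
            err_global += np.mean((small_model.K @ J_g - clean[i]) ** 2)
        assert err_adaptive <= err_global * 1.05
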