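import numpy as np
import pytest

import oracles
from cryogtm import engine
from cryogtm._errors import DataError
from cryogtm.ctf import CtfStack
from cryogtm.fourier import FourierStack, to_fourier
from cryogtm.latent import build_basis, build_latent_grid
from helpers import make_tiny_instance


class TestInitModel:
    def make_stack(self, seed=0, n=12, j=10):
        rng = np.random.default_rng(seed)
        from helpers import _SHARED_COMPONENTS

        return FourierStack(data=rng.normal(size=(n, j)), components=_SHARED_COMPONENTS)

    def grid_basis(self, k=4):
        grid = build_latent_grid((k,))
        return grid, build_basis(grid, n_gaussian=3, width=1.0)

    def test_zero_radius_maps_all_nodes_to_data_mean(self):
        stack = self.make_stack()
        grid, basis = self.grid_basis()
        model = engine.init_model(stack, grid, basis, seed=0, init_radius=0.0)
        mean = stack.data.mean(axis=0)
        assert np.allclose(model.mapped_points, np.tile(mean, (4, 1)))

    def test_same_seed_identical_weights(self):
        stack = self.make_stack()
        grid, basis = self.grid_basis()
        a = engine.init_model(stack, grid, basis, seed=42)
        b = engine.init_model(stack, grid, basis, seed=42)
        assert np.array_equal(a.W, b.W)
        c = engine.init_model(stack, grid, basis, seed=43)
        assert not np.array_equal(a.W, c.W)

    def test_auto_beta_on_unit_variance_components(self):
        rng = np.random.default_rng(7)
        from helpers import _SHARED_COMPONENTS

        data = rng.normal(0.0, 1.0, size=(4000, 6))
        stack = FourierStack(data=data, components=_SHARED_COMPONENTS)
        grid, basis = self.grid_basis()
        model = engine.init_model(stack, grid, basis, seed=0)
        # beta_bar = N J / sum (t - mean)^2 ~ 1 for unit-variance data
        expected = data.size / ((data - data.mean(0)) ** 2).sum()
        assert model.beta_bar == pytest.approx(expected, rel=1e-12)
        assert model.beta_bar == pytest.approx(1.0, rel=0.05)

    def test_all_zero_stack_rejected(self):
        from helpers import _SHARED_COMPONENTS

        stack = FourierStack(data=np.zeros((5, 6)), components=_SHARED_COMPONENTS)
        grid, basis = self.grid_basis()
        with pytest.raises(DataError):
            engine.init_model(stack, grid, basis, seed=0)

    def test_perturbation_scale_tracks_init_radius(self):
        stack = self.make_stack(n=200, j=50)
        grid, basis = self.grid_basis()
        mean = stack.data.mean(0)
        rms = np.sqrt(np.mean((stack.data - mean) ** 2))
        model = engine.init_model(stack, grid, basis, seed=1, init_radius=0.25)
        dev = np.sqrt(np.mean((model.mapped_points - mean) ** 2))
        assert 0.1 * rms < dev < 0.5 * rms


class TestOracleEquivalence:
    """Brute-force equivalence on >= 20 seeded random tiny instances."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_operations_match_brute_force(self, seed):
        stack, ctf, r, model = make_tiny_instance(seed)
        t, c = stack.data, ctf.values
        a = model.mapped_points

        r_impl = engine.e_step(stack, ctf, model)
        r_or = oracles.estep_brute(t, c, a, model.beta_bar)
        assert np.allclose(r_impl, r_or, rtol=1e-8, atol=1e-12)

        w_impl = engine.m_step_weights(stack, ctf, r, model)
        w_or = oracles.weights_brute(t, c, r, model.basis.values, model.beta_bar, model.alpha)
        assert np.abs(w_impl - w_or).max() <= 1e-8 * max(1.0, np.abs(w_or).max())

        l_impl = engine.weighted_loss(stack, ctf, r, model)
        assert l_impl == pytest.approx(oracles.loss_brute(t, c, r, a), rel=1e-8)

        ib_impl, bb_impl = engine.m_step_beta(stack, ctf, r, model)
        ib_or, bb_or = oracles.beta_brute(t, c, r, a)
        assert np.allclose(ib_impl, ib_or, rtol=1e-8, atol=1e-12)
        assert bb_impl == pytest.approx(bb_or, rel=1e-8)

        rows, _ = engine.class_average_rows(stack, ctf, r, model)
        avg_or = oracles.averages_brute(t, c, r, model.beta_bar, model.alpha)
        assert np.allclose(rows, avg_or, rtol=1e-8, atol=1e-12)


class TestEStep:
    def test_identical_mapped_points_give_uniform_posterior(self):
        stack, ctf, _, model = make_tiny_instance(3)
        model.W[:] = 0.0
        model.W[-1] = 1.3  # every node maps to the same point
        r = engine.e_step(stack, ctf, model)
        k = r.shape[0]
        assert np.allclose(r, 1.0 / k)

    def test_hand_computed_two_node_example(self):
        # N=1, K=2, J=2: t=(1,0), CTF=1, A_1=(1,0), A_2=(0,0), beta=1
        grid = build_latent_grid((2,))
        basis = build_basis(grid, n_gaussian=2, width=0.1)  # ~identity block
        from helpers import _SHARED_COMPONENTS

        # basis values ~ [[1,eps,1],[eps,1,1]]; choose W so A rows are exact
        phi = basis.values
        a_target = np.array([[1.0, 0.0], [0.0, 0.0]])
        w = np.linalg.lstsq(phi, a_target, rcond=None)[0]
        model = engine.GtmModel(W=w, beta_bar=1.0, alpha=0.0, basis=basis, grid=grid)
        stack = FourierStack(data=np.array([[1.0, 0.0]]), components=_SHARED_COMPONENTS)
        ctf = CtfStack(values=np.ones((1, 2)))
        r = engine.e_step(stack, ctf, model)
        # delta_1 = 0, delta_2 = 1 -> R_1 = 1 / (1 + e^{-1/2})
        expected = 1.0 / (1.0 + np.exp(-0.5))
        assert r[0, 0] == pytest.approx(expected, rel=1e-6)
        assert r[:, 0].sum() == pytest.approx(1.0)

    def test_columns_sum_to_one_tightly(self):
        for seed in range(5):
            stack, ctf, _, model = make_tiny_instance(seed)
            r = engine.e_step(stack, ctf, model)
            assert np.abs(r.sum(axis=0) - 1.0).max() < 1e-10
            assert r.min() >= 0.0 and r.max() <= 1.0

    def test_nonfinite_residual_names_image(self):
        stack, ctf, _, model = make_tiny_instance(1)
        stack.data[1, 0] = np.inf
        with pytest.raises(DataError, match="image 1"):
            engine.e_step(stack, ctf, model)


class TestMStepWeights:
    def test_huge_alpha_shrinks_weights_to_zero(self):
        stack, ctf, r, model = make_tiny_instance(5)
        model.alpha = 1e12 * np.abs(stack.data).max()
        w = engine.m_step_weights(stack, ctf, r, model)
        assert np.abs(w).max() < 1e-6

    def test_constant_basis_reduces_to_weighted_mean(self):
        # M=1 (constant basis only), CTF=1, alpha=0: W_1j is the plain mean
        rng = np.random.default_rng(8)
        n, j, k = 6, 4, 3
        grid = build_latent_grid((k,))
        basis = build_basis(grid, n_gaussian=1, width=1.0)
        # strip the Gaussian column to leave the constant basis alone
        from dataclasses import replace

        basis = replace(basis, centers=np.empty((0, 1)), values=basis.values[:, 1:])
        t = rng.normal(size=(n, j))
        r = rng.dirichlet(np.ones(k), size=n).T
        from helpers import _SHARED_COMPONENTS

        stack = FourierStack(data=t, components=_SHARED_COMPONENTS)
        ctf = CtfStack(values=np.ones((n, j)))
        model = engine.GtmModel(W=np.zeros((1, j)), beta_bar=1.0, alpha=0.0,
                                basis=basis, grid=grid)
        w = engine.m_step_weights(stack, ctf, r, model)
        # sum_ik R_ki t_ij / sum_ik R_ki = mean over images (R columns sum to 1)
        assert np.allclose(w[0], t.mean(axis=0), rtol=1e-10)


class TestMStepBeta:
    def test_uniform_residuals_give_reciprocal(self):
        # one-hot R, every residual r^2 -> beta_bar = 1 / r^2
        grid = build_latent_grid((2,))
        basis = build_basis(grid, n_gaussian=2, width=0.5)
        phi = basis.values
        a_target = np.zeros((2, 3))
        w = np.linalg.lstsq(phi, a_target, rcond=None)[0]
        model = engine.GtmModel(W=w, beta_bar=1.0, alpha=0.0, basis=basis, grid=grid)
        from helpers import _SHARED_COMPONENTS

        t = np.full((4, 3), 0.5)  # residual = 0.5 everywhere (A = 0)
        stack = FourierStack(data=t, components=_SHARED_COMPONENTS)
        ctf = CtfStack(values=np.ones((4, 3)))
        r = np.zeros((2, 4))
        r[0] = 1.0
        inv_beta, beta_bar = engine.m_step_beta(stack, ctf, r, model)
        assert np.allclose(inv_beta, 0.25)
        assert beta_bar == pytest.approx(4.0)

    def test_doubling_residuals_halves_beta(self):
        stack, ctf, r, model = make_tiny_instance(9)
        _, bb1 = engine.m_step_beta(stack, ctf, r, model)
        stack2 = FourierStack(data=2.0 * stack.data, components=stack.components)
        model2 = engine.GtmModel(W=2.0 * model.W, beta_bar=model.beta_bar,
                                 alpha=model.alpha, basis=model.basis, grid=model.grid)
        _, bb2 = engine.m_step_beta(stack2, ctf, r, model2)
        assert bb2 == pytest.approx(bb1 / 4.0, rel=1e-10)  # residuals scale by 2

    def test_perfect_fit_capped_with_warning(self):
        grid = build_latent_grid((1,))
        basis = build_basis(grid, n_gaussian=1, width=1.0)
        w = np.zeros((2, 2))
        model = engine.GtmModel(W=w, beta_bar=1.0, alpha=0.0, basis=basis, grid=grid)
        from helpers import _SHARED_COMPONENTS

        stack = FourierStack(data=np.zeros((3, 2)) + 0.0, components=_SHARED_COMPONENTS)
        stack.data[:] = 0.0
        ctf = CtfStack(values=np.ones((3, 2)))
        r = np.ones((1, 3))
        with pytest.warns(UserWarning, match="zero total residual"):
            _, bb = engine.m_step_beta(stack, ctf, r, model)
        assert bb == engine.BETA_MAX


class TestWeightedLoss:
    def test_perfect_reconstruction_gives_zero(self):
        grid = build_latent_grid((1,))
        basis = build_basis(grid, n_gaussian=1, width=1.0)
        rng = np.random.default_rng(10)
        j = 5
        a_row = rng.normal(size=j)
        w = np.linalg.lstsq(basis.values, a_row[None], rcond=None)[0]
        model = engine.GtmModel(W=w, beta_bar=1.0, alpha=0.0, basis=basis,
                                grid=grid)
        ctf_vals = rng.uniform(0.2, 1.0, size=(4, j))
        t = ctf_vals * (basis.values @ w)[0]
        from helpers import _SHARED_COMPONENTS

        stack = FourierStack(data=t, components=_SHARED_COMPONENTS)
        r = np.ones((1, 4))
        loss = engine.weighted_loss(stack, CtfStack(values=ctf_vals), r, model)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_homogeneity(self):
        stack, ctf, r, model = make_tiny_instance(11)
        l1 = engine.weighted_loss(stack, ctf, r, model)
        stack2 = FourierStack(data=3.0 * stack.data, components=stack.components)
        model2 = engine.GtmModel(W=3.0 * model.W, beta_bar=model.beta_bar,
                                 alpha=model.alpha, basis=model.basis, grid=model.grid)
        l2 = engine.weighted_loss(stack2, ctf, r, model2)
        assert l2 == pytest.approx(9.0 * l1, rel=1e-10)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [100, 101, 102, 103])
    def test_map_objective_non_decreasing_with_frozen_beta(self, seed):
        stack, ctf, _, model = make_tiny_instance(seed)
        rng = np.random.default_rng(seed)
        beta = rng.uniform(0.5, 2.0, size=stack.data.shape)
        prev = engine.map_objective(stack, ctf, model, beta)
        for _ in range(30):
            r = engine.e_step(stack, ctf, model, per_component_beta=beta)
            model.W = engine.m_step_weights(stack, ctf, r, model, per_component_beta=beta)
            cur = engine.map_objective(stack, ctf, model, beta)
            assert cur >= prev - 1e-9 * abs(prev)
            prev = cur


class TestFit:
    def test_single_class_noiseless_copies(self):
        rng = np.random.default_rng(12)
        img = rng.normal(size=(16, 16))
        stack = to_fourier(np.repeat(img[None], 6, axis=0), 1.0)
        ctf = CtfStack(values=np.ones((6, stack.n_components)))
        grid = build_latent_grid((1,))
        basis = build_basis(grid, n_gaussian=1, width=1.0)
        with pytest.warns(UserWarning):  # N >= K holds; perfect fit warns on beta
            model, r, hist = engine.fit(stack, ctf, grid, basis, seed=0, alpha=1e-8)
        assert np.allclose(r, 1.0)
        # mapped point matches the image coefficients (alpha-shrunk)
        assert np.allclose(model.mapped_points[0], stack.data[0], rtol=1e-6, atol=1e-6)

    def test_reproducible_given_seed(self):
        stack, ctf, _, model = make_tiny_instance(13)
        grid, basis = model.grid, model.basis
        m1, r1, h1 = engine.fit(stack, ctf, grid, basis, seed=5, max_iter=5)
        m2, r2, h2 = engine.fit(stack, ctf, grid, basis, seed=5, max_iter=5)
        assert np.array_equal(m1.W, m2.W)
        assert np.array_equal(r1, r2)
        assert h1.loss == h2.loss

    def test_history_length_matches_iterations(self):
        stack, ctf, _, model = make_tiny_instance(14)
        _, _, hist = engine.fit(stack, ctf, model.grid, model.basis, seed=0, max_iter=7)
        assert hist.n_iterations <= 7
        assert len(hist.beta_bar) == hist.n_iterations

    def test_warns_when_fewer_images_than_classes(self):
        rng = np.random.default_rng(15)
        from helpers import _SHARED_COMPONENTS

        stack = FourierStack(data=rng.normal(size=(3, 6)), components=_SHARED_COMPONENTS)
        ctf = CtfStack(values=np.ones((3, 6)))
        grid = build_latent_grid((8,))
        basis = build_basis(grid)
        with pytest.warns(UserWarning, match="N < K"):
            engine.fit(stack, ctf, grid, basis, seed=0, max_iter=2)

    def test_permutation_equivariance(self):
        stack, ctf, r0, model = make_tiny_instance(16)
        grid, basis = model.grid, model.basis
        m1, r1, h1 = engine.fit(stack, ctf, grid, basis, seed=2, max_iter=4)
        perm = np.random.default_rng(0).permutation(stack.n_images)
        stack_p = FourierStack(data=stack.data[perm], components=stack.components)
        ctf_p = CtfStack(values=ctf.values[perm])
        # same model state applied to permuted images permutes R columns
        r_full = engine.e_step(stack, ctf, m1)
        r_perm = engine.e_step(stack_p, ctf_p, m1)
        assert np.allclose(r_perm, r_full[:, perm])
        assert engine.weighted_loss(stack_p, ctf_p, r_perm, m1) == pytest.approx(
            engine.weighted_loss(stack, ctf, r_full, m1)
        )


class TestClassAverages:
    def test_unit_ctf_one_hot_r_gives_arithmetic_mean(self):
        stack, ctf_unused, _, model = make_tiny_instance(17)
        n, j = stack.data.shape
        k = model.grid.n_nodes
        ctf = CtfStack(values=np.ones((n, j)))
        model.alpha = 0.0
        r = np.zeros((k, n))
        members = [0, 1]
        r[1, members] = 1.0
        rows, blank = engine.class_average_rows(stack, ctf, r, model)
        assert np.allclose(rows[1], stack.data[members].mean(axis=0), rtol=1e-12)
        assert blank[0] and not blank[1]

    def test_huge_alpha_shrinks_averages(self):
        stack, ctf, r, model = make_tiny_instance(18)
        model.alpha = 1e15 * np.abs(stack.data).max()
        rows, _ = engine.class_average_rows(stack, ctf, r, model)
        assert np.abs(rows).max() < 1e-6

    def test_two_image_scalar_oracle_with_mixed_ctf(self):
        grid = build_latent_grid((1,))
        basis = build_basis(grid, n_gaussian=1, width=1.0)
        model = engine.GtmModel(W=np.zeros((2, 1)), beta_bar=2.0, alpha=0.05,
                                basis=basis, grid=grid)
        from helpers import _SHARED_COMPONENTS

        t = np.array([[1.0], [0.8]])
        ctf = np.array([[1.0], [0.5]])
        stack = FourierStack(data=t, components=_SHARED_COMPONENTS)
        r = np.ones((1, 2))
        rows, _ = engine.class_average_rows(stack, CtfStack(values=ctf), r, model)
        expected = (2.0 * 1.0 + 2.0 * 0.5 * 0.8) / (2.0 * 1.0 + 2.0 * 0.25 + 0.05)
        assert rows[0, 0] == pytest.approx(expected, rel=1e-12)


class TestAssign:
    def test_one_hot_and_tie_rules(self):
        r = np.array([[1.0, 0.25, 0.2], [0.0, 0.25, 0.5], [0.0, 0.25, 0.3],
                      [0.0, 0.25, 0.0]])
        labels = engine.assign(r)
        assert labels.tolist() == [0, 0, 1]  # uniform column ties to class 0

    def test_matches_independent_scan(self):
        rng = np.random.default_rng(19)
        r = rng.dirichlet(np.ones(6), size=40).T
        labels = engine.assign(r)
        for i in range(40):
            best = 0
            for k in range(6):
                if r[k, i] > r[best, i]:
                    best = k
            assert labels[i] == best
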