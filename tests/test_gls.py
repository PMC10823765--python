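import numpy as np
import pytest
from scipy.stats import norm

from momlme import simulate
from momlme.gls import (
    BlockCovariance,
    assign_bins,
    compose_covariance,
    contrast,
    fit,
    fit_gls,
    wald_inference,
    wild_bootstrap_ci,
)
from momlme.model_core import ObservationFrame, build_design, build_pair_index
from momlme.moments import (
    VarianceComponents,
    estimate_components_mom,
    fit_ols,
    residual_products,
)

from conftest import random_nested_frame


def _components(theta_cols, labels=("F", "S", "E")):
    theta = np.array(theta_cols, dtype=float).T
    return VarianceComponents(
        theta=theta,
        sigma2_total=np.ones(theta.shape[1]),
        labels=list(labels),
    )


class TestAssignBins:
    def test_grid_arithmetic(self):
        comps = _components([[0.32, 0.41, 0.27]])
        bins = assign_bins(comps, 20)
        assert tuple(bins.cell_index[0]) == (6, 8)

    def test_identical_components_share_one_cell(self):
        comps = _components([[0.3, 0.4, 0.3]] * 7)
        for K in (1, 5, 20, 100):
            assert assign_bins(comps, K).n_cells == 1

    def test_top_edge_maps_to_last_cell(self):
        comps = _components([[1.0, 0.0, 0.0]])
        bins = assign_bins(comps, 20)
        assert tuple(bins.cell_index[0]) == (19, 0)

    def test_representative_within_cell_width(self):
        rng = np.random.default_rng(0)
        J, K = 500, 20
        raw = rng.dirichlet(np.ones(3), size=J).T
        comps = _components(raw.T)
        bins = assign_bins(comps, K)
        for _, members, rep in bins.cells:
            for j in members:
                assert np.all(np.abs(rep[:2] - comps.theta[:2, j]) < 1.0 / K)

    def test_invalid_bin_count(self):
        with pytest.raises(ValueError):
            assign_bins(_components([[0.3, 0.3, 0.4]]), 0)


class TestComposeCovariance:
    def test_three_obs_direct_substitution(self):
        frame = ObservationFrame(
            subject_id=np.array(["s1", "s1", "s2"]),
            family_id=np.array(["f1", "f1", "f1"]),
            X=np.random.default_rng(0).standard_normal((3, 1)),
        )
        design = build_design(frame, ("F", "S"))
        V = compose_covariance(np.array([0.2, 0.3, 0.5]), design).dense()
        expect = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.2], [0.2, 0.2, 1.0]])
        np.testing.assert_allclose(V, expect)

    def test_error_only_model_is_identity(self, nested_frame):
        design = build_design(nested_frame, ("F", "S"))
        V = compose_covariance(np.array([0.0, 0.0, 1.0]), design).dense()
        np.testing.assert_allclose(V, np.eye(nested_frame.n_obs))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_dense_assembly_with_grm(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_nested_frame(rng, n_families=6)
        structure = simulate.FamilyStructure(
            family_id=frame.family_id, subject_id=frame.subject_id
        )
        grm = simulate.simulate_grm(structure, seed=seed)
        design = build_design(frame, ("F", "S", "A"), {"A": grm})
        theta = np.array([0.2, 0.2, 0.3, 0.3])
        V = compose_covariance(theta, design).dense()
        n = frame.n_obs
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        expect = theta[3] * np.eye(n)
        for e, eff in enumerate(design.effects):
            expect += theta[e] * eff.kernel_entries(i.ravel(), j.ravel()).reshape(n, n)
        np.testing.assert_allclose(V, expect, atol=1e-12)

    def test_solver_matches_dense_inverse(self, nested_frame):
        design = build_design(nested_frame, ("F", "S"))
        cov = compose_covariance(np.array([0.25, 0.35, 0.4]), design)
        rng = np.random.default_rng(1)
        M = rng.standard_normal((nested_frame.n_obs, 4))
        np.testing.assert_allclose(
            cov.solve(M), np.linalg.solve(cov.dense(), M), atol=1e-10
        )

    def test_error_floor_keeps_v_positive_definite(self, nested_frame):
        design = build_design(nested_frame, ("F", "S"))
        cov = compose_covariance(np.array([0.6, 0.4, 0.0]), design)
        assert np.all(np.linalg.eigvalsh(cov.dense()) > 0)


class TestFitGls:
    def test_identity_covariance_reduces_to_ols(self, nested_frame):
        rng = np.random.default_rng(2)
        design = build_design(nested_frame, ("F", "S"))
        cov = compose_covariance(np.array([0.0, 0.0, 1.0]), design)
        Y = rng.standard_normal((nested_frame.n_obs, 3))
        ols = fit_ols(nested_frame.X, Y)
        beta, se, _ = fit_gls(nested_frame.X, Y, cov, ols.sigma2_total)
        np.testing.assert_allclose(beta, ols.beta, atol=1e-10)

    def test_two_point_exchangeable_closed_form(self):
        # X = 1, y = (1, 3), V = [[1, .5], [.5, 1]]: beta = 2, var factor 0.75
        frame = ObservationFrame(
            subject_id=np.array(["s1", "s2"]),
            family_id=np.array(["f1", "f1"]),
            X=np.ones((2, 1)),
        )
        design = build_design(frame, ("F",))
        cov = compose_covariance(np.array([0.5, 0.5]), design)
        beta, se, base = fit_gls(np.ones((2, 1)), np.array([[1.0], [3.0]]), cov, np.ones(1))
        assert beta[0, 0] == pytest.approx(2.0)
        assert base[0, 0] == pytest.approx(0.75)

    def test_beta_invariant_to_covariance_scale(self, nested_frame):
        rng = np.random.default_rng(3)
        design = build_design(nested_frame, ("F", "S"))
        theta = np.array([0.3, 0.3, 0.4])
        Y = rng.standard_normal((nested_frame.n_obs, 2))
        s2 = np.ones(2)
        b1, _, _ = fit_gls(nested_frame.X, Y, compose_covariance(theta, design), s2)
        b2, _, _ = fit_gls(
            nested_frame.X, Y, compose_covariance(theta * 4.0, design), s2
        )
        np.testing.assert_allclose(b1, b2, atol=1e-10)


class TestWaldInference:
    def test_tabulated_quantiles(self):
        z, p = wald_inference(np.array([0.0, 1.959964, -1.959964]), np.ones(3))
        np.testing.assert_allclose(p[0], 1.0)
        np.testing.assert_allclose(p[1:], 0.05, atol=1e-6)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(4)
        zs = rng.standard_normal(100) * 3
        _, p_pos = wald_inference(zs, np.ones(100))
        _, p_neg = wald_inference(-zs, np.ones(100))
        np.testing.assert_allclose(p_pos, p_neg)
        assert np.all((p_pos > 0) & (p_pos <= 1))
        np.testing.assert_allclose(p_pos, 2 * norm.sf(np.abs(zs)))

    def test_zero_se_reported_missing(self):
        _, p = wald_inference(np.array([1.0]), np.array([0.0]))
        assert np.isnan(p[0])


class TestContrast:
    def _fit(self, seed=0, J=4):
        rng = np.random.default_rng(seed)
        frame = random_nested_frame(rng, n_families=10, p=3)
        Y = rng.standard_normal((frame.n_obs, J))
        return frame, fit(frame, Y, n_bins=5)

    def test_unit_vector_recovers_marginal(self):
        _, res = self._fit()
        for k in range(res.fixed.beta.shape[0]):
            c = np.zeros(res.fixed.beta.shape[0])
            c[k] = 1.0
            est, se, z, p = contrast(res.fixed, c)
            np.testing.assert_allclose(est, res.fixed.beta[k], atol=1e-12)
            np.testing.assert_allclose(se, res.fixed.se[k], atol=1e-12)

    def test_equal_coefficient_null(self):
        res = self._fit()[1].fixed
        res.beta[0, :] = res.beta[1, :] = 2.0
        est, _, z, p = contrast(res, np.array([1.0, -1.0, 0.0]))
        np.testing.assert_allclose(est, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, 1.0)

    def test_variance_matches_quadratic_form(self):
        rng = np.random.default_rng(9)
        _, res = self._fit(seed=9)
        c = rng.standard_normal(3)
        est, se, _, _ = contrast(res.fixed, c)
        for j in range(res.fixed.beta.shape[1]):
            expect = c @ res.fixed.cov_beta(j) @ c
            assert se[j] ** 2 == pytest.approx(expect, rel=1e-10)

    def test_length_mismatch(self):
        _, res = self._fit()
        with pytest.raises(ValueError, match="contrast length"):
            contrast(res.fixed, np.ones(5))


class TestPipeline:
    def test_pure_error_data_equals_ols_inference(self):
        structure = simulate.simulate_structure(3000, seed=7)
        truth = simulate.sample_true_params(3, 2, seed=1)
        truth.theta_true[:] = np.array([[0.0], [0.0], [1.0]])
        frame, Y = simulate.simulate_outcomes(truth, structure, seed=2)
        res = fit(frame, Y, n_bins=20)
        ols = fit_ols(frame.X, Y)
        # estimated F/S fractions are near zero, so GLS is essentially OLS
        np.testing.assert_allclose(res.fixed.beta, ols.beta, atol=2e-3)
        np.testing.assert_allclose(res.fixed.se, ols.sigma2_total**0.5 *
                                   np.linalg.inv(frame.X.T @ frame.X).diagonal()[:, None]**0.5,
                                   rtol=0.05)

    def test_one_bin_per_outcome_equals_exact_gls(self):
        structure = simulate.simulate_structure(300, seed=5)
        truth = simulate.sample_true_params(6, 2, seed=6)
        frame, Y = simulate.simulate_outcomes(truth, structure, seed=7)
        design = build_design(frame, ("F", "S"))
        res = fit(frame, Y, n_bins=10**6, design=design)
        # oracle: per-outcome GLS at that outcome's own estimated components
        pidx = build_pair_index(design)
        ols = fit_ols(frame.X, Y)
        comps = estimate_components_mom(
            pidx, residual_products(ols, pidx), ols.sigma2_total
        )
        for j in range(Y.n_outcomes):
            cov = BlockCovariance(comps.theta[:, j], design)
            Vinv_X = cov.solve(frame.X)
            beta_j = np.linalg.solve(
                frame.X.T @ Vinv_X, Vinv_X.T @ Y.Y[:, j]
            )
            np.testing.assert_allclose(res.fixed.beta[:, j], beta_j, atol=1e-8)

    def test_gls_no_less_efficient_than_ols(self):
        # across repeats, empirical variance of GLS beta <= OLS beta
        truth = simulate.sample_true_params(1, 2, seed=20)
        truth.theta_true[:] = np.array([[0.45], [0.3], [0.25]])
        truth.beta_true[:] = 0.0
        b_gls, b_ols = [], []
        for r in range(30):
            structure = simulate.simulate_structure(300, seed=100 + r)
            frame, Y = simulate.simulate_outcomes(truth, structure, seed=200 + r)
            res = fit(frame, Y, n_bins=20)
            b_gls.append(res.fixed.beta[:, 0])
            b_ols.append(res.ols.beta[:, 0])
        assert np.var(np.array(b_gls), axis=0).sum() <= np.var(
            np.array(b_ols), axis=0
        ).sum()

    def test_ml_estimator_path(self, small_sim):
        frame, Y, _ = small_sim
        res = fit(frame, Y, n_bins=10, estimator="ml")
        assert res.components.estimator_tag == "ml"
        assert np.all(np.isfinite(res.fixed.beta))
        np.testing.assert_allclose(res.components.theta.sum(axis=0), 1.0, atol=1e-8)

    def test_grm_random_effect_in_pipeline(self):
        structure = simulate.simulate_structure(500, seed=50)
        grm = simulate.simulate_grm(structure, seed=51)
        truth = simulate.sample_true_params(4, 2, seed=52)
        truth.labels = ["F", "A", "E"]
        frame, Y = simulate.simulate_outcomes(truth, structure, grm=grm, seed=53)
        res = fit(frame, Y, effects=("F", "A"), kernels={"A": grm}, n_bins=10)
        assert res.components.labels == ["F", "A", "E"]
        assert np.all(np.isfinite(res.fixed.p_value))
        # normalization uses the GRM's diagonal mean (1.0 here)
        np.testing.assert_allclose(
            res.components.theta.sum(axis=0), 1.0, atol=1e-8
        )

    def test_refinement_iterations_stay_close(self, small_sim):
        frame, Y, _ = small_sim
        one = fit(frame, Y, n_bins=20, iterations=1)
        two = fit(frame, Y, n_bins=20, iterations=2)
        np.testing.assert_allclose(
            one.fixed.beta, two.fixed.beta, atol=0.02
        )

    def test_deterministic_given_inputs(self, small_sim):
        frame, Y, _ = small_sim
        r1 = fit(frame, Y, n_bins=20)
        r2 = fit(frame, Y, n_bins=20)
        np.testing.assert_array_equal(r1.fixed.beta, r2.fixed.beta)
        np.testing.assert_array_equal(r1.components.theta, r2.components.theta)


class TestWildBootstrap:
    def test_percentiles_ordered(self, small_sim):
        frame, Y, _ = small_sim
        ci = wild_bootstrap_ci(frame, Y, n_draws=40, seed=0)
        assert np.all(ci.lower <= ci.upper + 1e-12)
        assert ci.n_draws == 40

    def test_seed_reproducibility(self, small_sim):
        frame, Y, _ = small_sim
        a = wild_bootstrap_ci(frame, Y, n_draws=25, seed=3)
        b = wild_bootstrap_ci(frame, Y, n_draws=25, seed=3)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_too_few_draws_warns(self, small_sim):
        frame, Y, _ = small_sim
        with pytest.warns(UserWarning, match="percentile"):
            wild_bootstrap_ci(frame, Y, n_draws=5, seed=0)

    def test_coverage_near_nominal(self):
        # 95% CIs should cover the true fractions for roughly 95% of outcomes
        structure = simulate.simulate_structure(2000, seed=30)
        truth = simulate.sample_true_params(40, 2, seed=31)
        frame, Y = simulate.simulate_outcomes(truth, structure, seed=32)
        ci = wild_bootstrap_ci(frame, Y, n_draws=60, seed=33)
        covered = (ci.lower <= truth.theta_true) & (truth.theta_true <= ci.upper)
        # binomial error on 3 x 40 correlated indicators is generous
        assert covered.mean() > 0.8
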