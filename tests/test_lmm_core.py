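import numpy as np
import pytest
from scipy import stats

from gridgwas.kinships import RelationshipMatrix, normalize_kinship
from gridgwas.lmm_core import (
    GridVertex,
    ModelSpec,
    RotationError,
    assemble_covariance,
    fit_gls,
    likelihood_ratio_test,
    profile_loglik,
    rotate_model,
    wald_test,
)

from ._oracles import (
    assemble_V,
    continuous_reml_max,
    gls_direct,
    ml_profile_direct,
    reml_profile_direct,
)


def _kinship(rng, n):
    A = rng.standard_normal((n, n))
    return normalize_kinship(RelationshipMatrix([f"s{i}" for i in range(n)], A @ A.T / n))


def _random_problem(seed, n=30, L=1, c=2, p=1):
    rng = np.random.default_rng(seed)
    Ks = [_kinship(rng, n) for _ in range(L)]
    W = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(c - 1)])
    X = rng.standard_normal((n, p)) if p else None
    y = rng.standard_normal(n)
    spec = ModelSpec(y, W, X, [(None, K) for K in Ks])
    return spec, Ks


class TestGridVertex:
    def test_invariants(self):
        v = GridVertex((0.2, 0.3))
        assert v.he2 == pytest.approx(0.5)
        with pytest.raises(ValueError):
            GridVertex((-0.1,))
        with pytest.raises(ValueError):
            GridVertex((0.5, 0.5))  # he2 must stay positive


class TestRotateModel:
    def test_pure_residual_vertex_is_identity(self):
        spec, _ = _random_problem(0)
        rot = rotate_model(spec, GridVertex((0.0,)))
        np.testing.assert_allclose(rot.chol, np.eye(spec.n))
        assert rot.logdetL == 0.0
        np.testing.assert_allclose(rot.y_star, spec.y)

    def test_hand_2x2_cholesky(self):
        K = RelationshipMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        spec = ModelSpec(np.array([1.0, 2.0]), np.ones((2, 1)), None, [(None, K)])
        rot = rotate_model(spec, GridVertex((0.5,)))
        V = assemble_covariance(spec, GridVertex((0.5,)))
        np.testing.assert_allclose(V, [[1.0, 0.25], [0.25, 1.0]])
        np.testing.assert_allclose(rot.chol[1], [0.25, np.sqrt(0.9375)])
        assert rot.logdetL == pytest.approx(0.5 * np.log(0.9375))

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction(self, seed):
        spec, _ = _random_problem(seed, n=20, L=2)
        v = GridVertex((0.3, 0.25))
        rot = rotate_model(spec, v)
        V = assemble_covariance(spec, v)
        np.testing.assert_allclose(rot.chol @ rot.chol.T, V, atol=1e-10)
        assert rot.logdetL == pytest.approx(np.sum(np.log(np.diag(rot.chol))))

    def test_rotation_failure_names_vertex(self):
        # indefinite "kinship" sneaks past construction tolerance at h2 ~ 1
        K = RelationshipMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, -1.0]]))
        spec = ModelSpec(np.zeros(2), np.ones((2, 1)), None, [(None, K)])
        with pytest.raises(RotationError, match="0.9"):
            rotate_model(spec, GridVertex((0.9,)))

    def test_rotation_succeeds_across_whole_grid(self):
        from gridgwas.grid_engine import build_grid

        spec, _ = _random_problem(3, n=15, L=2)
        for v in build_grid(2, 5).vertices:
            rotate_model(spec, v)  # he2 >= 1/m > 0 guarantees PD


class TestFitGLS:
    def test_hand_ols(self):
        spec = ModelSpec(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)))
        fit = fit_gls(rotate_model(spec, GridVertex(())))
        assert fit.alpha_hat[0] == pytest.approx(2.0)
        assert fit.RSS == pytest.approx(2.0)
        assert fit.sigma2_ml == pytest.approx(2.0 / 3.0)

    def test_perfect_fit_flagged(self):
        W = np.column_stack([np.ones(3), np.arange(3.0)])
        spec = ModelSpec(W @ np.array([1.0, 2.0]), W)
        fit = fit_gls(rotate_model(spec, GridVertex(())))
        assert fit.flag == "perfect_fit"
        assert profile_loglik(fit.rot, fit, "ML") == -np.inf

    def test_rank_deficiency_flagged_not_raised(self):
        spec, _ = _random_problem(1, p=0)
        rot = rotate_model(spec, GridVertex((0.2,)))
        dup = spec.W[:, 1:2].copy()
        fit = fit_gls(rot, rot.rotate(dup), dup)
        assert fit.flag == "rank_deficient"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_gls_oracle(self, seed):
        spec, Ks = _random_problem(seed, n=25, L=1, c=2, p=2)
        v = GridVertex((0.45,))
        rot = rotate_model(spec, v)
        fit = fit_gls(rot)
        V = assemble_V([0.45], [K.values for K in Ks], spec.n)
        Xt = np.hstack([spec.W, spec.X])
        theta, RSS, Gi = gls_direct(spec.y, Xt, V)
        np.testing.assert_allclose(
            np.concatenate([fit.alpha_hat, fit.beta_hat]), theta, atol=1e-8
        )
        assert fit.RSS == pytest.approx(RSS, abs=1e-8)
        np.testing.assert_allclose(fit.xtx_inv, Gi, atol=1e-8)


class TestProfileLoglik:
    def test_identity_covariance_equals_ols_profile(self):
        spec, _ = _random_problem(4)
        rot = rotate_model(spec, GridVertex((0.0,)))
        fit = fit_gls(rot)
        Xt = np.hstack([spec.W, spec.X])
        expected = ml_profile_direct(spec.y, Xt, np.eye(spec.n))
        assert profile_loglik(rot, fit, "ML") == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("kind", ["ML", "REML"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_oracle(self, seed, kind):
        spec, Ks = _random_problem(seed, n=40, L=2, c=2, p=1)
        v = GridVertex((0.3, 0.2))
        rot = rotate_model(spec, v)
        fit = fit_gls(rot)
        Xt = np.hstack([spec.W, spec.X])
        V = assemble_V([0.3, 0.2], [K.values for K in Ks], spec.n)
        direct = (ml_profile_direct if kind == "ML" else reml_profile_direct)(
            spec.y, Xt, V
        )
        assert profile_loglik(rot, fit, kind) == pytest.approx(direct, abs=1e-6)

    def test_ml_profile_matches_numerical_maximization(self):
        """Profile value equals direct maximization of the MVN density."""
        from scipy import optimize

        spec, Ks = _random_problem(7, n=20, L=1, c=1, p=1)
        v = GridVertex((0.35,))
        V = assemble_V([0.35], [K.values for K in Ks], spec.n)
        Xt = np.hstack([spec.W, spec.X])

        def neg(params):
            theta, ls2 = params[:2], params[2]
            return -stats.multivariate_normal.logpdf(
                spec.y, mean=Xt @ theta, cov=np.exp(ls2) * V
            )

        res = optimize.minimize(neg, [0.0, 0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        rot = rotate_model(spec, v)
        fit = fit_gls(rot)
        assert profile_loglik(rot, fit, "ML") == pytest.approx(-res.fun, abs=1e-6)

    def test_reml_invariant_under_reparameterization(self):
        spec, Ks = _random_problem(9, n=30, c=2, p=2)
        v = GridVertex((0.25,))
        T = np.array(
            [[1.0, 0.5, 0.0, 1.0], [0.0, 2.0, 0.0, 0.0],
             [0.0, 1.0, 1.0, 0.0], [0.0, 0.0, 0.0, 3.0]]
        )
        Xt = np.hstack([spec.W, spec.X])
        XT = Xt @ T
        spec2 = ModelSpec(spec.y, XT[:, :2], XT[:, 2:], spec.random_effects)
        f1 = fit_gls(rotate_model(spec, v))
        f2 = fit_gls(rotate_model(spec2, v))
        assert profile_loglik(f1.rot, f1, "REML") == pytest.approx(
            profile_loglik(f2.rot, f2, "REML"), abs=1e-8
        )

    def test_true_vertex_beats_distant_vertex_on_average(self, family_population):
        from gridgwas.simulate import simulate_phenotype

        _, K = family_population
        true_v, far_v = GridVertex((0.6,)), GridVertex((0.05,))
        wins = 0
        reps = 200
        for r in range(reps):
            y, _ = simulate_phenotype([K], (0.6,), seed=1000 + r)
            spec = ModelSpec(y, np.ones((K.n, 1)), None, [(None, K)])
            vals = []
            for v in (true_v, far_v):
                rot = rotate_model(spec, v)
                vals.append(profile_loglik(rot, fit_gls(rot), "ML"))
            wins += vals[0] > vals[1]
        assert wins / reps > 0.5


class TestWaldTest:
    def test_zero_effect_gives_f_zero(self):
        # marker orthogonal to y and the intercept: beta_hat is exactly 0
        y = np.array([2.0, 3.0, 3.0, 2.0])
        x = np.array([1.0, -1.0, 1.0, -1.0])
        spec = ModelSpec(y, np.ones((4, 1)), x)
        fit = fit_gls(rotate_model(spec, GridVertex(())))
        M = np.array([[0.0, 1.0]])
        res = wald_test(fit, M)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_singular_contrast_flagged(self):
        spec, _ = _random_problem(2)
        fit = fit_gls(rotate_model(spec, GridVertex((0.1,))))
        res = wald_test(fit, np.zeros((1, 3)))
        assert res.flag == "singular"

    def test_identity_covariance_equals_squared_t(self):
        spec, _ = _random_problem(6, p=1)
        fit = fit_gls(rotate_model(spec, GridVertex((0.0,))))
        Xt = np.hstack([spec.W, spec.X])
        theta, RSS, Gi = gls_direct(spec.y, Xt, np.eye(spec.n))
        s2 = RSS / (spec.n - 3)
        t2 = theta[2] ** 2 / (s2 * Gi[2, 2])
        M = np.zeros((1, 3))
        M[0, 2] = 1.0
        assert wald_test(fit, M).statistic == pytest.approx(t2, abs=1e-10)

    def test_pvalue_matches_distribution_oracle(self):
        spec, _ = _random_problem(8, p=1)
        fit = fit_gls(rotate_model(spec, GridVertex((0.2,))))
        M = np.zeros((1, 3))
        M[0, 2] = 1.0
        res = wald_test(fit, M)
        assert res.p_value == pytest.approx(
            1.0 - stats.f.cdf(res.statistic, res.df1, res.df2), abs=1e-12
        )


class TestLikelihoodRatioTest:
    def test_identical_models(self):
        res = likelihood_ratio_test(-10.0, -10.0, 1)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_classical_ols_lrt(self):
        rng = np.random.default_rng(13)
        n = 50
        W = np.ones((n, 1))
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        null = ModelSpec(y, W)
        alt = ModelSpec(y, W, x)
        vals = {}
        for name, sp in (("null", null), ("alt", alt)):
            rot = rotate_model(sp, GridVertex(()))
            vals[name] = profile_loglik(rot, fit_gls(rot), "ML")
        res = likelihood_ratio_test(vals["null"], vals["alt"], 1)
        rss0 = np.sum((y - y.mean()) ** 2)
        th, rss1, _ = gls_direct(y, np.column_stack([W, x]), np.eye(n))
        classical = n * np.log(rss0 / rss1)
        assert res.statistic == pytest.approx(classical, abs=1e-8)

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="coarse"):
            res = likelihood_ratio_test(-5.0, -5.1, 1)
        assert res.statistic == 0.0 and res.flag == "alt_below_null"

    def test_null_calibration(self):
        """Empirical type-I error of the grid LRT at alpha = 0.05."""
        from gridgwas.grid_engine import build_grid, grid_search

        rng = np.random.default_rng(99)
        n, reps = 100, 1000
        A = rng.standard_normal((n, n))
        K = normalize_kinship(
            RelationshipMatrix([f"s{i}" for i in range(n)], A @ A.T / n)
        )
        grid = build_grid(1, 10)
        W = np.ones((n, 1))
        X = rng.standard_normal((n, reps))  # one marker per replicate
        Y = rng.standard_normal((n, reps))  # null phenotypes
        hits = 0
        for r in range(reps):
            spec = ModelSpec(Y[:, r], W, None, [(None, K)])
            alt = grid_search(spec, grid, markers=X[:, r : r + 1], criterion="ML")
            null = grid_search(spec, grid, tests="per-trait", criterion="ML")
            res = likelihood_ratio_test(null.best_score[0], alt.best_score[0], 1)
            hits += res.p_value < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)


def test_model_spec_validation():
    with pytest.raises(ValueError, match="rank deficient"):
        ModelSpec(np.zeros(3), np.ones((3, 2)))
    with pytest.raises(ValueError, match="missing"):
        ModelSpec(np.array([1.0, np.nan]), np.ones((2, 1)))
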