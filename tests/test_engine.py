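"""Variational engine: bound primitives, coordinate updates, ELBO, stages."""

import numpy as np
import pytest
from scipy.special import expit, logsumexp
from scipy.stats import multivariate_normal

import funmap
from funmap import engine
from funmap.data_model import GenotypePhenotype, suffstats_from_individual
from funmap.engine import (
    AnnotationWeightPosterior,
    ModelConfig,
    lambda_xi,
    logsumexp_bound,
    update_q_w,
    update_single_effect,
    update_variance_components,
    update_xi_rho,
)


class TestLambdaXi:
    def test_limit_at_zero(self):
        assert lambda_xi(0.0) == pytest.approx(0.125, abs=1e-12)

    def test_matches_direct_formula(self):
        # (1/2ξ)(sigmoid(ξ) − 1/2) evaluated directly at ξ = 4
        xi = 4.0
        direct = (expit(xi) - 0.5) / (2 * xi)
        assert lambda_xi(xi) == pytest.approx(direct, abs=1e-12)
        assert lambda_xi(xi) == pytest.approx(0.060251724, abs=1e-8)

    def test_series_branch_matches_formula(self):
        # series branch (ξ < 1e-4) must agree with the direct formula
        xi = 5e-5
        direct = (expit(xi) - 0.5) / (2 * xi)
        assert lambda_xi(xi) == pytest.approx(direct, abs=1e-10)

    def test_strictly_decreasing_and_bounded(self):
        grid = np.linspace(0.01, 10, 200)
        vals = lambda_xi(grid)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals > 0) and np.all(vals <= 0.125)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lambda_xi(-0.1)


class TestLogsumexpBound:
    def test_single_term_at_rho(self):
        rho = 1.3
        val = logsumexp_bound(np.array([rho]), np.array([0.0]), rho)
        assert val == pytest.approx(rho + np.log(2), abs=1e-12)
        assert val >= rho

    def test_tightness_form(self):
        # at ξ_j = |a_j − ρ| the quadratic terms vanish and the bound is
        # ρ + Σ log(1 + e^{a_j − ρ})
        rng = np.random.default_rng(0)
        a = rng.normal(0, 2, 20)
        rho = 0.7
        xi = np.abs(a - rho)
        expected = rho + np.sum(np.logaddexp(0, a - rho))
        assert logsumexp_bound(a, xi, rho) == pytest.approx(expected, abs=1e-10)

    def test_always_upper_bounds_logsumexp(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            p = rng.integers(1, 30)
            a = rng.normal(0, 3, p)
            xi = np.abs(rng.normal(0, 2, p))
            rho = rng.normal(0, 2)
            assert logsumexp_bound(a, xi, rho) >= logsumexp(a) - 1e-10


def _orthonormal_design(n, p, seed):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    Q = Q - Q.mean(axis=0)
    X = Q / Q.std(axis=0)
    return X


class TestUpdateSingleEffect:
    def test_uniform_when_no_signal(self):
        X = _orthonormal_design(50, 4, 2)
        data = GenotypePhenotype(X, X[:, 0] * 0 + np.zeros(50), list("abcd"))
        ss = suffstats_from_individual(
            GenotypePhenotype(X, np.zeros(50), list("abcd"))
        )
        ss.yty = 50.0
        post, _ = update_single_effect(
            ss, np.zeros(4), np.zeros(4), 1.0, 0.2, estimate_prior_variance=False
        )
        np.testing.assert_allclose(post.alpha, 0.25, atol=1e-12)

    def test_dominant_prior_logit(self):
        X = _orthonormal_design(50, 4, 3)
        ss = suffstats_from_individual(GenotypePhenotype(X, X[:, 1], list("abcd")))
        logits = np.zeros(4)
        logits[2] = 50.0
        post, _ = update_single_effect(
            ss, ss.Xty, logits, 1.0, 0.2, estimate_prior_variance=False
        )
        assert post.alpha[2] > 0.99

    def test_matches_exact_enumeration(self):
        # 3 orthogonal SNPs, fixed variances: alpha must equal the exact
        # posterior over the 3 single-SNP models by marginal likelihood
        n, s2, sb2 = 40, 0.8, 0.3
        X = _orthonormal_design(n, 3, 4)
        rng = np.random.default_rng(5)
        y = X[:, 1] * 0.4 + rng.standard_normal(n) * 0.9
        y = (y - y.mean()) / y.std()
        data = GenotypePhenotype(X, y, list("abc"))
        ss = suffstats_from_individual(data)
        post, _ = update_single_effect(
            ss, ss.Xty, np.zeros(3), s2, sb2, estimate_prior_variance=False
        )
        logml = np.array(
            [
                multivariate_normal.logpdf(
                    y, mean=np.zeros(n),
                    cov=s2 * np.eye(n) + sb2 * np.outer(X[:, j], X[:, j]),
                )
                for j in range(3)
            ]
        )
        alpha_exact = np.exp(logml - logsumexp(logml))
        np.testing.assert_allclose(post.alpha, alpha_exact, atol=1e-10)

    def test_non_finite_residual_rejected(self):
        X = _orthonormal_design(20, 2, 6)
        ss = suffstats_from_individual(GenotypePhenotype(X, X[:, 0], ["a", "b"]))
        with pytest.raises(ValueError, match="non-finite"):
            update_single_effect(
                ss, np.array([np.nan, 0.0]), np.zeros(2), 1.0, 0.2
            )


class TestUpdateQW:
    def test_zero_annotations_give_prior(self):
        A = np.zeros((10, 3))
        post = update_q_w(np.full(10, 0.1), A, np.ones(10), 0.0, 0.5)
        np.testing.assert_allclose(post.mu_w, 0.0, atol=1e-12)
        np.testing.assert_allclose(post.Sigma_w, 0.5 * np.eye(3), atol=1e-12)

    def test_shrinks_to_prior_as_variance_vanishes(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((30, 4))
        alpha = rng.dirichlet(np.ones(30))
        xi = np.abs(rng.normal(0, 1, 30))
        big = update_q_w(alpha, A, xi, 0.5, 1.0)
        tiny = update_q_w(alpha, A, xi, 0.5, 1e-10)
        assert np.linalg.norm(tiny.mu_w) < 1e-7
        assert np.linalg.norm(tiny.mu_w) < np.linalg.norm(big.mu_w)

    def test_mean_is_stationary_point(self):
        # central-difference gradient of the bound-augmented objective
        rng = np.random.default_rng(8)
        p, m = 5, 2
        A = rng.standard_normal((p, m))
        alpha = rng.dirichlet(np.ones(p))
        xi = np.abs(rng.normal(0, 1, p))
        rho, sw2 = 0.3, 0.7
        post = update_q_w(alpha, A, xi, rho, sw2)
        lam = lambda_xi(xi)

        def obj(w):
            a = A @ w
            B = rho + np.sum(
                (a - rho - xi) / 2 + lam * ((a - rho) ** 2 - xi**2)
                + np.logaddexp(0, xi)
            )
            return alpha @ a - B - w @ w / (2 * sw2)

        h = 1e-6
        grad = np.array(
            [
                (obj(post.mu_w + h * e) - obj(post.mu_w - h * e)) / (2 * h)
                for e in np.eye(m)
            ]
        )
        assert np.linalg.norm(grad) < 1e-6


class TestUpdateXiRho:
    def test_degenerate_weights_give_zero_xi(self):
        A = np.ones((6, 2))
        w = AnnotationWeightPosterior(np.zeros(2), np.zeros((2, 2)))
        xi, rho = update_xi_rho(np.full(6, 1 / 6), A, w, rho_l=0.0, n_sweeps=1)
        # with mu_w = 0, Sigma_w = 0 and rho fixed at its optimum for this
        # symmetric instance, xi = |A w - rho| = |rho|
        np.testing.assert_allclose(xi, abs(rho), atol=1e-12)

    def test_point_mass_weights_give_abs_logits(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((12, 3))
        mu = rng.normal(0, 1, 3)
        w = AnnotationWeightPosterior(mu, np.zeros((3, 3)))
        xi, rho = update_xi_rho(np.full(12, 1 / 12), A, w)
        np.testing.assert_allclose(xi, np.abs(A @ mu - rho), atol=1e-10)

    def test_never_increases_expected_majorizer(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p, m = 15, 3
            A = rng.standard_normal((p, m))
            mu = rng.normal(0, 0.5, m)
            S = rng.standard_normal((m, m))
            Sigma = S @ S.T * 0.01
            w = AnnotationWeightPosterior(mu, Sigma)
            alpha = rng.dirichlet(np.ones(p))
            rho0 = rng.normal()
            a_hat = A @ mu
            a_var = np.maximum((A @ Sigma * A).sum(axis=1), 0)
            xi0 = np.abs(rng.normal(0, 1, p))
            before = engine._expected_bound_term(a_hat, a_var, xi0, rho0)
            xi1, rho1 = update_xi_rho(alpha, A, w, rho_l=rho0)
            after = engine._expected_bound_term(a_hat, a_var, xi1, rho1)
            assert after <= before + 1e-9


class TestVarianceComponents:
    def test_null_state_recovers_unit_sigma2(self):
        # all posterior mass on one SNP with zero mean effect: ERSS = y'y
        X = _orthonormal_design(30, 3, 11)
        ss = suffstats_from_individual(GenotypePhenotype(X, X[:, 0], list("abc")))
        alpha = np.array([1.0, 0.0, 0.0])
        eff = engine.SingleEffectPosterior(alpha, np.zeros(3), np.full(3, 0.1))
        state = engine.VariationalState(
            effects=[eff], weights=None, xi=None, rho=None,
            theta=engine.VarianceComponents(0.5, np.array([0.2]), np.array([1.0])),
        )
        # zero out the quadratic contribution of the held SNP
        eff.var_b[:] = 0.0 + 1e-30
        theta = update_variance_components(state, ss)
        assert theta.sigma2 == pytest.approx(1.0, abs=1e-6)

    def test_sigma_w_trace_identity(self):
        c = 0.37
        w = AnnotationWeightPosterior(np.zeros(4), c * np.eye(4))
        eff = engine.SingleEffectPosterior(
            np.array([1.0, 0.0]), np.zeros(2), np.full(2, 1e-30)
        )
        X = _orthonormal_design(20, 2, 12)
        ss = suffstats_from_individual(GenotypePhenotype(X, X[:, 0], ["a", "b"]))
        state = engine.VariationalState(
            effects=[eff], weights=[w], xi=np.zeros((1, 2)), rho=np.zeros(1),
            theta=engine.VarianceComponents(1.0, np.array([0.2]), np.array([9.9])),
        )
        theta = update_variance_components(state, ss)
        assert theta.sigma_w2[0] == pytest.approx(c, abs=1e-12)

    def test_erss_matches_monte_carlo(self):
        # draw (gamma_l, b_l) from q for each component and average ||y-Xb||^2
        rng = np.random.default_rng(13)
        n, p, L = 60, 4, 2
        X = rng.standard_normal((n, p))
        data = GenotypePhenotype.from_raw(X, rng.standard_normal(n))
        ss = suffstats_from_individual(data)
        effects = []
        for l in range(L):
            alpha = rng.dirichlet(np.ones(p))
            effects.append(
                engine.SingleEffectPosterior(
                    alpha, rng.normal(0, 0.3, p), np.abs(rng.normal(0.05, 0.01, p))
                )
            )
        state = engine.VariationalState(
            effects=effects, weights=None, xi=None, rho=None,
            theta=engine.VarianceComponents(1.0, np.full(L, 0.2), np.full(L, 1.0)),
        )
        exact = engine._expected_rss(state, ss)
        draws = 200_000
        b = np.zeros((draws, p))
        for eff in effects:
            j = rng.choice(p, size=draws, p=eff.alpha)
            bl = rng.normal(eff.mu_b[j], np.sqrt(eff.var_b[j]))
            b[np.arange(draws), j] += bl
        resid = data.y[None, :] - b @ data.X.T
        rss = (resid**2).sum(axis=1).mean()
        assert rss == pytest.approx(exact, rel=0.01)


class TestElbo:
    def test_equals_exact_marginal_for_single_effect(self):
        # L = 1, fixed variances: the single-effect posterior is exact, so
        # the bound attains the exact log marginal by 3-model enumeration
        rng = np.random.default_rng(14)
        n, p, s2, sb2 = 40, 3, 0.9, 0.3
        X = rng.standard_normal((n, p))
        y = X[:, 1] * 0.5 + rng.standard_normal(n)
        data = GenotypePhenotype.from_raw(X, y)
        ss = suffstats_from_individual(data)
        cfg = ModelConfig(
            L=1, estimate_residual_variance=False, estimate_prior_variances=False
        )
        state = engine._init_state(ss, cfg)
        state.theta.sigma2 = s2
        state.theta.sigma_b2[:] = sb2
        post, _ = update_single_effect(
            ss, ss.Xty, np.zeros(p), s2, sb2, estimate_prior_variance=False
        )
        state.effects[0] = post
        F = engine.elbo(state, ss, None)
        logml = logsumexp(
            [
                multivariate_normal.logpdf(
                    data.y, mean=np.zeros(n),
                    cov=s2 * np.eye(n) + sb2 * np.outer(data.X[:, j], data.X[:, j]),
                )
                for j in range(p)
            ]
        ) - np.log(p)
        assert F == pytest.approx(logml, abs=1e-8)

    def test_non_decreasing_under_random_update_sequences(self, signal_dataset):
        _, ss, _ = signal_dataset
        rng = np.random.default_rng(15)
        A = rng.standard_normal((ss.p, 5))
        state, diag = funmap.fit(ss, A, ModelConfig(L=4))
        tr = np.array(diag.elbo_trace)
        b = diag.stage_boundaries + [len(tr)]
        for s in range(len(b) - 1):
            seg = tr[b[s]:b[s + 1]]
            assert np.all(np.diff(seg) >= -1e-6)


class TestStages:
    def test_stage1_finds_strong_causal(self, signal_dataset, small_fit):
        _, _, causal = signal_dataset
        state, _ = small_fit
        best = max(eff.alpha[causal] for eff in state.effects)
        assert best >= 0.95

    def test_null_phenotype_rarely_confident(self):
        # measured null rate of max PIP >= 0.5 is ~5%; over 50 seeded
        # replicates require <= 5 exceedances and a small median
        from funmap.simulation import SimulationDesign, simulate_genotypes

        rng = np.random.default_rng(16)
        des = SimulationDesign(n=500, p=50, ld_rho=0.5, seed=16)
        mx = []
        for _ in range(50):
            X = simulate_genotypes(des, rng)
            y = rng.standard_normal(500)
            data = GenotypePhenotype.from_raw(X, y)
            ss = suffstats_from_individual(data)
            st, _ = funmap.fit(ss, None, ModelConfig(L=5))
            mx.append(funmap.compute_pip(st.effects).max())
        mx = np.array(mx)
        assert (mx < 0.5).mean() >= 0.90
        assert np.median(mx) < 0.3

    def test_stage2_ranks_informative_annotation_first(self, signal_dataset):
        _, ss, causal = signal_dataset
        rng = np.random.default_rng(17)
        A = rng.standard_normal((ss.p, 6))
        A[:, 2] = -1.0
        A[causal, 2] = 5.0  # one annotation flags the causal SNP
        A = (A - A.mean(axis=0)) / A.std(axis=0)
        cfg = ModelConfig(L=4)
        st, _, _ = engine.fit_stage1(ss, cfg)
        st, _, _ = engine.fit_stage2(st, A, ss, cfg)
        # the component holding the causal signal must load on annotation 2
        l_best = int(np.argmax([e.alpha[causal] for e in st.effects]))
        mu = st.weights[l_best].mu_w
        assert np.argmax(np.abs(mu)) == 2

    def test_stage2_null_annotations_stay_small(self, signal_dataset):
        _, ss, causal = signal_dataset
        rng = np.random.default_rng(18)
        A_null = rng.standard_normal((ss.p, 6))
        A_inf = A_null.copy()
        A_inf[:, 2] = -1.0
        A_inf[causal, 2] = 5.0
        A_inf = (A_inf - A_inf.mean(0)) / A_inf.std(0)
        cfg = ModelConfig(L=4)
        st0, _, _ = engine.fit_stage1(ss, cfg)
        import copy

        st_null, _, _ = engine.fit_stage2(copy.deepcopy(st0), A_null, ss, cfg)
        st_inf, _, _ = engine.fit_stage2(copy.deepcopy(st0), A_inf, ss, cfg)
        l_best = int(np.argmax([e.alpha[causal] for e in st0.effects]))
        norm_null = np.linalg.norm(st_null.weights[l_best].mu_w)
        norm_inf = np.linalg.norm(st_inf.weights[l_best].mu_w)
        assert norm_null < norm_inf

    def test_no_annotations_equals_stage1(self, signal_dataset, small_fit):
        _, ss, _ = signal_dataset
        state1, _ = small_fit
        # explicit zero-column annotation matrix reduces to the plain model
        state0, diag0 = funmap.fit(ss, np.empty((ss.p, 0)), ModelConfig(L=5))
        pip1 = funmap.compute_pip(state1.effects)
        pip0 = funmap.compute_pip(state0.effects)
        np.testing.assert_allclose(pip0, pip1, atol=1e-12)
        assert len(diag0.stage_boundaries) == 1

    def test_deterministic(self, signal_dataset):
        _, ss, _ = signal_dataset
        rng = np.random.default_rng(19)
        A = rng.standard_normal((ss.p, 4))
        s1, d1 = funmap.fit(ss, A, ModelConfig(L=4))
        s2, d2 = funmap.fit(ss, A, ModelConfig(L=4))
        assert d1.elbo_trace == d2.elbo_trace
        np.testing.assert_array_equal(
            funmap.compute_pip(s1.effects), funmap.compute_pip(s2.effects)
        )

    def test_permutation_equivariance(self, signal_dataset):
        _, ss, _ = signal_dataset
        rng = np.random.default_rng(20)
        A = rng.standard_normal((ss.p, 4))
        perm = rng.permutation(ss.p)
        ss_perm = funmap.SufficientStatistics(
            XtX=ss.XtX[np.ix_(perm, perm)], Xty=ss.Xty[perm], yty=ss.yty, n=ss.n
        )
        s1, d1 = funmap.fit(ss, A, ModelConfig(L=3))
        s2, d2 = funmap.fit(ss_perm, A[perm], ModelConfig(L=3))
        np.testing.assert_allclose(
            funmap.compute_pip(s2.effects), funmap.compute_pip(s1.effects)[perm],
            atol=1e-8,
        )
        assert d1.elbo_trace[-1] == pytest.approx(d2.elbo_trace[-1], abs=1e-8)

    def test_excess_components_stay_diffuse(self):
        # L = 10 with 2 true signals: at most 3 components concentrate
        from funmap.simulation import SimulationDesign, simulate_genotypes

        rng = np.random.default_rng(21)
        des = SimulationDesign(n=2000, p=100, ld_rho=0.5, seed=21)
        n_ok = 0
        reps = 10
        for _ in range(reps):
            X = simulate_genotypes(des, rng)
            y = X[:, 20] * 0.15 + X[:, 70] * 0.15 + rng.standard_normal(2000)
            data = GenotypePhenotype.from_raw(X, y)
            ss = suffstats_from_individual(data)
            st, _ = funmap.fit(ss, None, ModelConfig(L=10))
            n_conc = sum(eff.alpha.max() > 0.5 for eff in st.effects)
            n_ok += n_conc <= 3
        assert n_ok >= 0.9 * reps
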