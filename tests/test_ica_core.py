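"""Likelihood, derivatives, Newton safeguards, Amari metric and the ICA loop."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from psica.ica_core import (
    ICAConfig,
    SingularMatrixError,
    amari_distance,
    amari_index,
    likelihood_gradient,
    likelihood_hessian,
    log_likelihood,
    newton_step,
    run_ica,
    standardize_sources,
)
from psica.parcellation import ParcellationMap, fit_region_densities


def _fit_global_densities(S):
    pmap = ParcellationMap.single(S.shape[1])
    return [fit_region_densities(S[q], pmap) for q in range(S.shape[0])]


@pytest.fixture(scope="module")
def random_instance():
    rng = np.random.default_rng(42)
    Q, V = 3, 500
    X = rng.standard_normal((Q, Q)) @ rng.standard_normal((Q, V))
    X -= X.mean(axis=1, keepdims=True)
    B = np.eye(Q) + 0.1 * rng.standard_normal((Q, Q))
    densities = _fit_global_densities(B @ X)
    return B, X, densities


class _GaussianDensity:
    """Analytic standard-normal stand-in implementing the density protocol."""

    def log_density(self, s):
        return norm.logpdf(np.asarray(s, dtype=float))

    def score(self, s):
        return -np.asarray(s, dtype=float)

    def score_prime(self, s):
        return -np.ones_like(np.asarray(s, dtype=float))


class _FlatDensity(_GaussianDensity):
    """Constant log-density: isolates the V log|det B| likelihood term."""

    def log_density(self, s):
        return np.zeros_like(np.asarray(s, dtype=float))

    def score(self, s):
        return np.zeros_like(np.asarray(s, dtype=float))

    def score_prime(self, s):
        return np.zeros_like(np.asarray(s, dtype=float))


class TestLogLikelihood:
    def test_matches_brute_force_double_loop(self, random_instance):
        B, X, densities = random_instance
        Q, V = X.shape
        S = B @ X
        brute = V * np.log(abs(np.linalg.det(B)))
        for v in range(V):
            for q in range(Q):
                brute += densities[q][0].log_density(np.array([S[q, v]]))[0]
        assert log_likelihood(B, X, densities) == pytest.approx(brute, abs=1e-9)

    def test_single_component_single_sample(self):
        dens = [_GaussianDensity()]
        X = np.array([[0.0, 0.5]])  # two samples so shapes stay 2-D
        ll = log_likelihood(np.array([[1.0]]), X, dens)
        assert ll == pytest.approx(norm.logpdf(0.0) + norm.logpdf(0.5))

    def test_rescaling_shifts_det_term(self, random_instance):
        B, X, densities = random_instance
        Q, V = X.shape
        c = 1.7
        ll_base = log_likelihood(B, X, densities)
        ll_scaled = log_likelihood(c * B, X, densities)
        S, cS = B @ X, c * (B @ X)
        dens_shift = sum(
            float(np.sum(densities[q][0].log_density(cS[q])
                         - densities[q][0].log_density(S[q])))
            for q in range(Q))
        assert ll_scaled - ll_base == pytest.approx(V * Q * np.log(c) + dens_shift, abs=1e-8)

    def test_singular_unmixing_rejected(self, random_instance):
        _, X, densities = random_instance
        with pytest.raises(SingularMatrixError):
            log_likelihood(np.zeros((3, 3)), X, densities)


class TestDerivatives:
    def test_gradient_matches_finite_differences(self, random_instance):
        B, X, densities = random_instance
        Q = B.shape[0]
        G = likelihood_gradient(B, X, densities)
        h = 1e-6
        for q in range(Q):
            for j in range(Q):
                E = np.zeros((Q, Q))
                E[q, j] = h
                fd = (log_likelihood(B + E, X, densities)
                      - log_likelihood(B - E, X, densities)) / (2 * h)
                assert G[q, j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_hessian_matches_finite_differences_of_gradient(self, random_instance):
        B, X, densities = random_instance
        Q = B.shape[0]
        H = likelihood_hessian(B, X, densities)
        h = 1e-6
        for q in range(Q):
            for j in range(Q):
                E = np.zeros((Q, Q))
                E[q, j] = h
                fd = (likelihood_gradient(B + E, X, densities)
                      - likelihood_gradient(B - E, X, densities)) / (2 * h)
                np.testing.assert_allclose(H[q * Q + j], fd.ravel(), rtol=1e-4, atol=1e-4)

    def test_hessian_symmetry(self, random_instance):
        B, X, densities = random_instance
        H = likelihood_hessian(B, X, densities)
        assert np.max(np.abs(H - H.T)) < 1e-8

    def test_det_term_gradient_at_identity(self):
        # flat densities isolate d/dB of V log|det B|, which is V * I at B = I
        Q, V = 3, 50
        rng = np.random.default_rng(0)
        X = rng.standard_normal((Q, V))
        G = likelihood_gradient(np.eye(Q), X, [_FlatDensity()] * Q)
        np.testing.assert_allclose(G, V * np.eye(Q), atol=1e-9)


class TestNewtonStep:
    def test_zero_gradient_leaves_matrix_unchanged(self):
        B = np.array([[2.0, 0.1], [0.0, 1.0]])
        H = -np.eye(4)
        B_new, _ = newton_step(B, np.zeros((2, 2)), H, loglik_fn=lambda M: 0.0)
        np.testing.assert_allclose(B_new, B)

    def test_quadratic_objective_solved_in_one_step(self):
        # L(B) = -0.5 (b - b*)^T A (b - b*): one Newton step lands on b*
        rng = np.random.default_rng(3)
        Q = 2
        M = rng.standard_normal((4, 4))
        A = M @ M.T + 4 * np.eye(4)
        b_star = rng.standard_normal(4) * 0.1 + np.eye(Q).ravel()

        def ll(B):
            d = B.ravel() - b_star
            return -0.5 * d @ A @ d

        B0 = np.eye(Q)
        g = (-A @ (B0.ravel() - b_star)).reshape(Q, Q)
        B_new, _ = newton_step(B0, g, -A, loglik_fn=ll, ridge=0.0)
        np.testing.assert_allclose(B_new.ravel(), b_star, atol=1e-10)

    def test_det_sign_preserved_by_halving(self):
        # a full step would flip det; halving must keep the original sign
        B = np.array([[1.0]])
        g = np.array([[2.0]])
        H = np.array([[-1.0]])  # newton step = -H^{-1} g = +2 -> B - 2 flips sign
        B_new, _ = newton_step(B, -g, H, loglik_fn=lambda M: 0.0)
        assert np.sign(np.linalg.det(B_new)) == 1.0


class TestStandardize:
    def test_rows_get_unit_variance(self, rng):
        X = rng.standard_normal((2, 1000))
        X -= X.mean(axis=1, keepdims=True)
        B = np.diag([2.0, 0.5])
        B2, S, sd = standardize_sources(B, X)
        np.testing.assert_allclose(S.std(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(B2 * sd[:, None], B)

    def test_idempotent(self, rng):
        X = rng.standard_normal((3, 500))
        B = rng.standard_normal((3, 3))
        B1, S1, _ = standardize_sources(B, X)
        B2, S2, sd2 = standardize_sources(B1, X)
        np.testing.assert_allclose(B1, B2, atol=1e-12)
        np.testing.assert_allclose(sd2, 1.0, atol=1e-12)

    def test_likelihood_shift_is_analytic(self, rng):
        X = rng.standard_normal((2, 2000)) * np.array([[3.0], [0.4]])
        X -= X.mean(axis=1, keepdims=True)
        B = np.eye(2)
        dens = _fit_global_densities(B @ X)
        B2, S2, sd = standardize_sources(B, X)
        dens2 = [[dens[q][0].rescale(1.0 / sd[q])] for q in range(2)]
        ll_before = log_likelihood(B, X, dens)
        ll_after = log_likelihood(B2, X, dens2)
        assert ll_after == pytest.approx(ll_before, abs=1e-8)

    def test_zero_variance_row_raises(self):
        from psica.ica_core import DegenerateComponentError

        X = np.vstack([np.zeros(100), np.random.default_rng(0).normal(size=100)])
        with pytest.raises(DegenerateComponentError):
            standardize_sources(np.eye(2), X)


class TestAmariMetric:
    def test_identical_matrices_give_zero(self, rng):
        B = rng.standard_normal((4, 4))
        assert amari_distance(B, B) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_permutation_and_scaling(self, rng):
        B = rng.standard_normal((5, 5))
        P = np.eye(5)[rng.permutation(5)]
        L = np.diag(rng.uniform(0.2, 3.0, 5) * np.where(rng.random(5) < 0.5, -1, 1))
        assert amari_distance(B, P @ L @ B) == pytest.approx(0.0, abs=1e-12)
        assert amari_distance(P @ L @ B, B) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # rows: (2/1 - 1) + 0 = 1; cols: 0 + (2/1 - 1) = 1; total / (2*2) = 0.5
        assert amari_index(np.array([[1.0, 1.0], [0.0, 1.0]])) == pytest.approx(0.5)

    def test_nonnegative(self, rng):
        for _ in range(20):
            d = amari_distance(rng.standard_normal((3, 3)), rng.standard_normal((3, 3)))
            assert d >= 0.0


class TestRunICA:
    def test_recovers_uniform_laplace_mixture(self):
        rng = np.random.default_rng(7)
        V = 20_000
        S = np.vstack([rng.uniform(-1.0, 1.0, V), rng.laplace(0.0, 1.0, V)])
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        X = np.array([[2.0, 1.0], [3.0, 2.0]]) @ S
        state = run_ica(X)
        assert state.converged
        C = np.abs(np.corrcoef(np.vstack([state.S, S]))[:2, 2:])
        matched = np.sort(C.max(axis=1))
        assert np.all(matched >= 0.99)

    def test_identity_recovery_on_unmixed_sources(self):
        rng = np.random.default_rng(11)
        V = 10_000
        S = np.vstack([rng.uniform(-1.0, 1.0, V), rng.laplace(0.0, 1.0, V)])
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        state = run_ica(S)
        assert state.converged
        assert state.amari_trace[-1] < state.config.tol
        assert amari_distance(state.B, np.eye(2)) < 0.05

    def test_gaussian_sources_do_not_crash(self):
        # two Gaussian sources are unidentifiable; the run must still return
        # a finite likelihood and a valid state
        rng = np.random.default_rng(13)
        X = rng.standard_normal((2, 2)) @ rng.standard_normal((2, 5000))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state = run_ica(X)
        assert np.all(np.isfinite(state.loglik_trace))
        assert np.isfinite(np.linalg.det(state.B))

    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(5)
        V = 5000
        S = np.vstack([rng.uniform(-1, 1, V), rng.laplace(size=V)])
        X = np.array([[1.0, 0.6], [0.2, 1.0]]) @ S
        state = run_ica(X)
        assert np.all(np.diff(state.loglik_trace) >= -1e-8)

    def test_source_permutation_equivariance(self):
        rng = np.random.default_rng(19)
        V = 8000
        S = np.vstack([rng.uniform(-1, 1, V), rng.laplace(size=V)])
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        A = np.array([[2.0, 1.0], [3.0, 2.0]])
        st1 = run_ica(A @ S)
        st2 = run_ica(A[:, ::-1] @ S[::-1])  # same data, sources relabelled
        e1 = amari_index(st1.B @ A)
        Pflip = np.array([[0.0, 1.0], [1.0, 0.0]])
        e2 = amari_index(st2.B @ (A[:, ::-1] @ Pflip))
        assert e1 == pytest.approx(e2, abs=1e-6)

    def test_scale_invariance_of_fit(self):
        rng = np.random.default_rng(23)
        V = 5000
        S = np.vstack([rng.uniform(-1, 1, V), rng.laplace(size=V)])
        X = np.array([[2.0, 1.0], [3.0, 2.0]]) @ S
        st1 = run_ica(X)
        st2 = run_ica(10.0 * X)
        np.testing.assert_allclose(st2.B * 10.0, st1.B, rtol=1e-6)
        np.testing.assert_allclose(st2.S, st1.S, atol=1e-6)

    def test_final_likelihood_beats_derivative_free_optimizer(self):
        rng = np.random.default_rng(29)
        V = 2000
        S = np.vstack([rng.uniform(-1, 1, V), rng.laplace(size=V)])
        S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
        X = np.array([[1.5, 0.5], [1.0, 2.0]]) @ S
        X -= X.mean(axis=1, keepdims=True)
        state = run_ica(X)

        pmap = ParcellationMap.single(V)
        config = ICAConfig(delta_grid=(1.0,))

        def profile_ll(theta):
            B = theta.reshape(2, 2)
            if abs(np.linalg.det(B)) < 1e-8:
                return np.inf
            B, Sc, _ = standardize_sources(B, X)
            from psica.ica_core import _fit_densities

            dens = _fit_densities(Sc, pmap, config, [None, None])
            return -log_likelihood(B, X, dens)

        res = minimize(profile_ll, np.eye(2).ravel(), method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-8})
        assert state.loglik_trace[-1] >= -res.fun - 1e-3

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(31)
        X = np.array([[2.0, 1.0], [3.0, 2.0]]) @ rng.laplace(size=(2, 3000))
        st1 = run_ica(X)
        st2 = run_ica(X)
        np.testing.assert_array_equal(st1.B, st2.B)
        np.testing.assert_array_equal(st1.loglik_trace, st2.loglik_trace)
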