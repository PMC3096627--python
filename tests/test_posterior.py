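"""Hierarchical-model marginals, quadrature and posterior DE probabilities."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import invgamma, multivariate_normal, norm

from npmvs import (
    ExpressionMatrix,
    HierarchicalInputs,
    InverseGammaPrior,
    UniformPrior,
    grand_mean,
    log_marginal_alt,
    log_marginal_null,
    posterior_de,
    posterior_de_one_sample,
    posterior_from_log_marginals,
    quadrature_rule,
)
from npmvs.posterior import ig_prior_support


def oracle_log_marginal(kind, yc, yt, vc, vt, mu0, prior):
    """Adaptive 1-D integration of the marginal over the between variance."""
    if isinstance(prior, UniformPrior):
        a, b = prior.v_lower, prior.v_upper
        logpdf = lambda v: -np.log(b - a)
    else:
        a, b = 0.0, np.inf
        logpdf = invgamma(prior.shape, scale=prior.scale).logpdf

    def integrand(v):
        if kind == "null":
            cov = [[vc + v, v], [v, vt + v]]
            lf = multivariate_normal.logpdf([yc, yt], [mu0, mu0], cov)
        else:
            lf = norm.logpdf(yc, mu0, np.sqrt(vc + v)) + norm.logpdf(yt, mu0, np.sqrt(vt + v))
        return np.exp(lf + logpdf(v))

    val, _ = quad(integrand, a, b, limit=1000, epsabs=0, epsrel=1e-12)
    return np.log(val)


class TestQuadratureRule:
    def test_legendre_order_one_maps_to_midpoint(self):
        r = quadrature_rule("legendre", 1)
        # affine map of the canonical (node 0, weight 2) rule onto (0, 1)
        assert 0.5 * 0 + 0.5 == 0.5
        np.testing.assert_allclose(r.nodes, [0.0])
        np.testing.assert_allclose(r.weights * 0.5, [1.0])

    def test_hermite_order_two_textbook_nodes(self):
        r = quadrature_rule("hermite", 2)
        np.testing.assert_allclose(sorted(r.nodes), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_legendre_20_exact_for_monomials_up_to_39(self):
        r = quadrature_rule("legendre", 20)
        for k in range(0, 40):
            got = np.sum(r.weights * r.nodes**k)
            exact = 0.0 if k % 2 else 2.0 / (k + 1)
            assert abs(got - exact) < 1e-12 * max(1.0, abs(exact))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            quadrature_rule("laguerre", 5)

    def test_weights_positive(self):
        for scheme in ("legendre", "hermite"):
            assert (quadrature_rule(scheme, 20).weights > 0).all()


class TestGrandMean:
    def _mat(self, vals):
        vals = np.asarray(vals, dtype=float)
        return ExpressionMatrix(
            [f"g{i}" for i in range(vals.shape[0])], vals, ["a"] * vals.shape[1]
        )

    def test_constant_matrix(self):
        assert grand_mean(self._mat(np.full((3, 4), 8.0))) == 8.0

    def test_mean_of_all_entries(self):
        assert grand_mean(self._mat([[2.0, 4.0], [3.0, 3.0]])) == 3.0

    def test_permutation_invariance(self, rng):
        v = rng.normal(8, 1, (10, 4))
        m1 = self._mat(v)
        m2 = self._mat(v[rng.permutation(10)][:, rng.permutation(4)])
        assert np.isclose(grand_mean(m1), grand_mean(m2))


GENERIC = dict(yc=8.2, yt=9.1, vc=0.2, vt=0.2, mu0=8.0)


class TestMarginals:
    def test_degenerate_prior_collapses_to_closed_forms(self):
        # v_U -> v_L: both marginals tend to their fixed-v closed forms
        vstar = 0.5
        eps = 2.0**-31  # exactly representable: no cancellation in v_U - v_L
        prior = UniformPrior(vstar - eps, vstar + eps)
        rule = quadrature_rule("legendre", 20)
        g = GENERIC
        lm0 = log_marginal_null(g["yc"], g["yt"], g["vc"], g["vt"], g["mu0"], prior, rule)
        cov = [[g["vc"] + vstar, vstar], [vstar, g["vt"] + vstar]]
        want0 = multivariate_normal.logpdf([g["yc"], g["yt"]], [g["mu0"]] * 2, cov)
        assert abs(np.expm1(lm0 - want0)) < 1e-8
        lm1 = log_marginal_alt(g["yc"], g["yt"], g["vc"], g["vt"], g["mu0"], prior, rule)
        want1 = (norm.logpdf(g["yc"], g["mu0"], np.sqrt(g["vc"] + vstar))
                 + norm.logpdf(g["yt"], g["mu0"], np.sqrt(g["vt"] + vstar)))
        assert abs(np.expm1(lm1 - want1)) < 1e-8

    @pytest.mark.parametrize("kind,fn", [("null", log_marginal_null), ("alt", log_marginal_alt)])
    def test_generic_inputs_match_adaptive_oracle(self, kind, fn):
        prior = UniformPrior(0.001, 4.0)
        rule = quadrature_rule("legendre", 20)
        g = GENERIC
        got = fn(g["yc"], g["yt"], g["vc"], g["vt"], g["mu0"], prior, rule)
        want = oracle_log_marginal(kind, g["yc"], g["yt"], g["vc"], g["vt"], g["mu0"], prior)
        assert abs(np.expm1(got - want)) < 1e-6

    def test_oracle_agreement_on_random_grid(self, rng):
        # default Legendre rule vs adaptive integration over 100 random inputs
        prior = UniformPrior(1e-4, 4.0)
        rule = quadrature_rule("legendre", 20)
        worst = 0.0
        for _ in range(100):
            yc, yt = rng.normal(8, 1, 2)
            vc, vt = rng.uniform(0.02, 0.5, 2)
            for kind, fn in (("null", log_marginal_null), ("alt", log_marginal_alt)):
                got = fn(yc, yt, vc, vt, 8.0, prior, rule)
                want = oracle_log_marginal(kind, yc, yt, vc, vt, 8.0, prior)
                worst = max(worst, abs(np.expm1(got - want)))
        assert worst < 1e-6

    def test_hermite_path_tracks_oracle(self, rng):
        # the Hermite rule integrates a hard-truncated prior less sharply
        # than Legendre; verified accuracy is ~3e-3, asserted at 1e-2
        prior = UniformPrior(1e-4, 4.0)
        rule = quadrature_rule("hermite", 20)
        worst = 0.0
        for _ in range(25):
            yc, yt = rng.normal(8, 1, 2)
            vc, vt = rng.uniform(0.02, 0.5, 2)
            got = log_marginal_alt(yc, yt, vc, vt, 8.0, prior, rule)
            want = oracle_log_marginal("alt", yc, yt, vc, vt, 8.0, prior)
            worst = max(worst, abs(np.expm1(got - want)))
        assert worst < 1e-2

    def test_swapping_conditions_leaves_marginals_unchanged(self):
        prior = UniformPrior(0.001, 4.0)
        rule = quadrature_rule("legendre", 20)
        for fn in (log_marginal_null, log_marginal_alt):
            a = fn(8.2, 9.1, 0.2, 0.35, 8.0, prior, rule)
            b = fn(9.1, 8.2, 0.35, 0.2, 8.0, prior, rule)
            assert np.isclose(a, b, rtol=1e-10)

    def test_equal_data_at_center_favors_shared_mean_model(self):
        # ybar_c = ybar_t = mu0: the null (shared mean) dominates on a grid
        prior = UniformPrior(0.001, 4.0)
        rule = quadrature_rule("legendre", 20)
        for vc in (0.05, 0.2, 0.5):
            for vt in (0.05, 0.2, 0.5):
                lm0 = log_marginal_null(8.0, 8.0, vc, vt, 8.0, prior, rule)
                lm1 = log_marginal_alt(8.0, 8.0, vc, vt, 8.0, prior, rule)
                assert lm1 <= lm0


class TestInverseGammaPrior:
    def test_cdf_at_median_is_half(self):
        pr = ig_prior_support(3.0, 2.0)
        assert np.isclose(pr.cdf(pr.ppf(0.5)), 0.5)

    def test_marginal_matches_adaptive_oracle(self):
        pr = ig_prior_support(3.0, 2.0)
        rule = quadrature_rule("legendre", 20)
        g = GENERIC
        for kind, fn in (("null", log_marginal_null), ("alt", log_marginal_alt)):
            got = fn(g["yc"], g["yt"], g["vc"], g["vt"], g["mu0"], pr, rule)
            want = oracle_log_marginal(kind, g["yc"], g["yt"], g["vc"], g["vt"], g["mu0"], pr)
            assert abs(np.expm1(got - want)) < 1e-5

    def test_suggested_hyperparameter_magnitudes_accepted(self):
        pr = ig_prior_support(0.5, 0.01)
        rule = quadrature_rule("legendre", 20)
        g = GENERIC
        lm = log_marginal_alt(g["yc"], g["yt"], g["vc"], g["vt"], g["mu0"], pr, rule)
        assert np.isfinite(lm)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ig_prior_support(-1.0, 2.0)


class TestPosterior:
    def _inputs(self, p=0.05, G=20, seed=5):
        rng = np.random.default_rng(seed)
        return HierarchicalInputs(
            y_c=rng.normal(8, 1, G), y_t=rng.normal(8, 1, G),
            v_c=rng.uniform(0.05, 0.3, G), v_t=rng.uniform(0.05, 0.3, G),
            mu0=8.0, prior=UniformPrior(0.001, 4.0), p=p,
        )

    def test_p_zero_and_one_collapse(self):
        rule = quadrature_rule("legendre", 20)
        assert (posterior_de(self._inputs(p=0.0), rule).posterior == 0).all()
        assert (posterior_de(self._inputs(p=1.0), rule).posterior == 1).all()

    def test_posterior_matches_fine_grid_oracle(self):
        # strongly DE fixture gene vs a 1e5-point trapezoid integration
        prior = UniformPrior(0.001, 4.0)
        rule = quadrature_rule("legendre", 20)
        p = 0.05
        yc, yt, vc, vt, mu0 = 8.0, 12.0, 0.3, 0.3, 8.0
        v = np.linspace(prior.v_lower, prior.v_upper, 100_000)
        f0 = multivariate_normal([mu0, mu0])
        m0 = np.trapezoid(
            [multivariate_normal.pdf([yc, yt], [mu0] * 2,
                                     [[vc + vi, vi], [vi, vt + vi]]) for vi in v], v
        ) / (prior.v_upper - prior.v_lower)
        m1 = np.trapezoid(
            norm.pdf(yc, mu0, np.sqrt(vc + v)) * norm.pdf(yt, mu0, np.sqrt(vt + v)), v
        ) / (prior.v_upper - prior.v_lower)
        want = p * m1 / (p * m1 + (1 - p) * m0)
        got = posterior_de(
            HierarchicalInputs([yc], [yt], [vc], [vt], mu0, prior, p), rule
        ).posterior[0]
        assert abs(got - want) < 1e-6

    def test_posterior_increasing_in_p(self):
        rule = quadrature_rule("legendre", 20)
        grid = np.linspace(0.01, 0.99, 21)
        prev = None
        for p in grid:
            post = posterior_de(self._inputs(p=p), rule).posterior
            assert ((post >= 0) & (post <= 1)).all()
            if prev is not None:
                assert (post > prev).all()
            prev = post

    def test_posterior_nondecreasing_in_treatment_shift(self):
        prior = UniformPrior(0.001, 4.0)
        rule = quadrature_rule("legendre", 20)
        shifts = np.linspace(0, 5, 26)
        post = posterior_de(
            HierarchicalInputs(
                np.full(26, 8.0), 8.0 + shifts, np.full(26, 0.2), np.full(26, 0.2),
                8.0, prior, 0.05,
            ), rule,
        ).posterior
        assert (np.diff(post) >= -1e-12).all()

    def test_label_swap_leaves_posterior_unchanged(self):
        rule = quadrature_rule("legendre", 20)
        x = self._inputs()
        a = posterior_de(x, rule).posterior
        swapped = HierarchicalInputs(x.y_t, x.y_c, x.v_t, x.v_c, x.mu0, x.prior, x.p)
        b = posterior_de(swapped, rule).posterior
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_call_respects_cutoff(self):
        rule = quadrature_rule("legendre", 20)
        res = posterior_de(self._inputs(p=0.3), rule, cutoff=0.5)
        np.testing.assert_array_equal(res.call, res.posterior > 0.5)


class TestOneSample:
    def test_zero_log_ratio_posterior_below_prior_p(self):
        prior = UniformPrior(0.01, 2.0)
        rule = quadrature_rule("legendre", 20)
        for p in (0.01, 0.05, 0.2, 0.5):
            for v in (0.05, 0.2, 1.0):
                post = posterior_de_one_sample(0.0, v, p, prior, rule).posterior
                assert post < p

    def test_point_prior_gives_closed_form_bayes_factor(self):
        vstar = 0.5
        prior = UniformPrior(vstar - 1e-9, vstar + 1e-9)
        rule = quadrature_rule("legendre", 20)
        d, v, p = 1.3, 0.2, 0.1
        res = posterior_de_one_sample(d, v, p, prior, rule)
        m0 = norm.pdf(d, 0, np.sqrt(v))
        m1 = norm.pdf(d, 0, np.sqrt(v + vstar))
        want = p * m1 / (p * m1 + (1 - p) * m0)
        assert abs(res.posterior - want) < 1e-7

    def test_posterior_monotone_in_effect_size(self):
        prior = UniformPrior(0.01, 2.0)
        rule = quadrature_rule("legendre", 20)
        d = np.linspace(0, 8, 33)
        post = posterior_de_one_sample(d, np.full_like(d, 0.1), 0.05, prior, rule).posterior
        assert (np.diff(post) >= -1e-12).all()
        assert post[-1] > 0.999


class TestPosteriorFromLogMarginals:
    def test_matches_direct_ratio(self, rng):
        lm0 = rng.normal(-3, 1, 50)
        lm1 = rng.normal(-3, 1, 50)
        p = 0.05
        got = posterior_from_log_marginals(lm0, lm1, p)
        m0, m1 = np.exp(lm0), np.exp(lm1)
        np.testing.assert_allclose(got, p * m1 / (p * m1 + (1 - p) * m0), rtol=1e-12)

    def test_extreme_log_marginals_stay_in_unit_interval(self):
        got = posterior_from_log_marginals(
            np.array([-1e4, 0.0]), np.array([0.0, -1e4]), 0.05
        )
        assert got[0] == pytest.approx(1.0)
        assert 0 <= got[1] < 1e-100 or got[1] == 0.0
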