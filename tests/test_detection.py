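"""Detection functions: closed forms, quadrature, and ML recovery."""

import numpy as np
import pytest
from scipy import integrate, special

from ctds.detection import (
    DetectionModel,
    ParameterError,
    eval_key,
    fit_mle,
    n_free_parameters,
    wald_ci,
)
from ctds.io import BinningScheme


class TestKeyFunctions:
    @pytest.mark.parametrize(
        "family,kwargs,r,expected",
        [
            ("uniform", {}, 3.7, 1.0),
            ("half-normal", {"sigma": 2.0}, 0.0, 1.0),
            ("half-normal", {"sigma": 2.0}, 2.0, np.exp(-0.5)),
            ("hazard-rate", {"sigma": 1.0, "shape": 2.0}, 1.0, 1.0 - np.exp(-1.0)),
            ("hazard-rate", {"sigma": 2.0, "shape": 3.0}, 0.0, 1.0),
        ],
    )
    def test_closed_forms(self, family, kwargs, r, expected):
        assert eval_key(family, r, **kwargs) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [{"sigma": 0.0}, {"sigma": -1.0}],
    )
    def test_invalid_scale_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            eval_key("half-normal", 1.0, **kwargs)

    def test_hazard_rate_shape_must_exceed_one(self):
        with pytest.raises(ParameterError):
            eval_key("hazard-rate", 1.0, sigma=1.0, shape=1.0)

    def test_values_stay_in_unit_interval(self, rng):
        r = rng.uniform(0, 20, 200)
        for family, kw in [
            ("half-normal", {"sigma": 2.0}),
            ("hazard-rate", {"sigma": 2.0, "shape": 3.0}),
        ]:
            g = eval_key(family, r, **kw)
            assert np.all((g >= 0) & (g <= 1))


class TestAdjustedDetectionFunction:
    def test_no_adjustment_equals_key(self, rng):
        scheme = BinningScheme.regular(1.0, 0.0, 5.0)
        m = DetectionModel("half-normal", scheme, sigma=2.0)
        r = rng.uniform(0, 5, 50)
        assert m.g(r) == pytest.approx(eval_key("half-normal", r, 2.0))

    def test_uniform_cosine_rescaled_to_one_at_peak(self):
        # uniform + cosine order 1, a1 = 0.5, w = 5: raw value at r=0 is 1.5
        scheme = BinningScheme.regular(1.0, 0.0, 5.0)
        m = DetectionModel(
            "uniform", scheme, adjustment="cosine", orders=(1,), coefficients=(0.5,)
        )
        assert m._g_unscaled(0.0)[0] == pytest.approx(1.5)
        assert m.g(0.0)[0] == pytest.approx(1.0)

    def test_halfnormal_cosine_matches_direct_formula(self):
        """Adjusted g equals an independently coded evaluation on a grid."""
        w = 5.0
        scheme = BinningScheme.regular(1.0, 0.0, w)
        a = (0.3, -0.1)
        m = DetectionModel(
            "half-normal",
            scheme,
            sigma=2.0,
            adjustment="cosine",
            orders=(2, 3),
            coefficients=a,
        )
        def raw(x):
            return np.clip(
                np.exp(-(x**2) / 8.0)
                * (
                    1
                    + a[0] * np.cos(2 * np.pi * x / w)
                    + a[1] * np.cos(3 * np.pi * x / w)
                ),
                0,
                None,
            )

        r = np.linspace(0, w, 100)
        direct = raw(r) / raw(np.linspace(0, w, 20001)).max()
        assert m.g(r) == pytest.approx(direct, abs=1e-6)

    def test_negative_lobe_clamped(self):
        scheme = BinningScheme.regular(1.0, 0.0, 5.0)
        m = DetectionModel(
            "uniform", scheme, adjustment="cosine", orders=(1,), coefficients=(-2.0,)
        )
        assert np.all(m.g(np.linspace(0, 5, 200)) >= 0)


class TestDetectionProbability:
    def test_uniform_is_exactly_one(self):
        for w in (2.0, 5.0, 10.0):
            m = DetectionModel("uniform", BinningScheme.regular(1.0, 0.0, w))
            assert m.detection_probability() == 1.0

    def test_halfnormal_closed_form(self):
        sigma, w = 2.0, 5.0
        m = DetectionModel("half-normal", BinningScheme.regular(1.0, 0.0, w), sigma=sigma)
        closed = (2 * sigma**2 / w**2) * (1 - np.exp(-(w**2) / (2 * sigma**2)))
        assert m.detection_probability() == pytest.approx(closed, abs=1e-8)

    def test_hazard_rate_against_riemann_oracle(self):
        sigma, b, w = 2.0, 3.0, 6.0
        m = DetectionModel(
            "hazard-rate", BinningScheme.regular(1.0, 0.0, w), sigma=sigma, shape=b
        )
        r = (np.arange(1_000_000) + 0.5) * (w / 1_000_000)
        g = 1 - np.exp(-((r / sigma) ** (-b)))
        riemann = np.sum(g * 2 * r) * (w / 1_000_000) / w**2
        assert m.detection_probability() == pytest.approx(riemann, abs=1e-6)

    def test_left_truncation_uses_annulus(self):
        sigma, l, w = 2.0, 1.0, 5.0
        m = DetectionModel("half-normal", BinningScheme.regular(1.0, l, w), sigma=sigma)
        # independent quadrature of the annulus-normalized, max-rescaled g
        gmax = np.exp(-(l**2) / (2 * sigma**2))  # half-normal peaks at r = l here
        val, _ = integrate.quad(
            lambda r: np.exp(-(r**2) / (2 * sigma**2)) / gmax * 2 * r, l, w
        )
        assert m.detection_probability() == pytest.approx(val / (w**2 - l**2), abs=1e-8)


class TestBinProbabilities:
    def test_uniform_annulus_areas(self):
        m = DetectionModel("uniform", BinningScheme((0.0, 1.0, 2.0)))
        assert m.bin_probabilities() == pytest.approx([0.25, 0.75], abs=1e-12)

    @pytest.mark.parametrize(
        "family,kwargs",
        [
            ("half-normal", {"sigma": 1.5}),
            ("hazard-rate", {"sigma": 2.0, "shape": 3.0}),
            ("uniform", {}),
        ],
    )
    def test_probabilities_normalized(self, family, kwargs):
        m = DetectionModel(
            family, BinningScheme.regular(1.0, 0.0, 5.0), **kwargs
        )
        pi = m.bin_probabilities()
        assert np.all(pi >= 0)
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_halfnormal_bins_match_quadrature_oracle(self):
        sigma, w = 1.5, 5.0
        scheme = BinningScheme.regular(1.0, 0.0, w)
        m = DetectionModel("half-normal", scheme, sigma=sigma)
        f = lambda r: r * np.exp(-(r**2) / (2 * sigma**2))
        per_bin = np.array(
            [integrate.quad(f, a, b)[0] for a, b in zip(scheme.cutpoints, scheme.cutpoints[1:])]
        )
        assert m.bin_probabilities() == pytest.approx(per_bin / per_bin.sum(), abs=1e-8)


class TestLikelihoodAndFit:
    def test_two_bin_arithmetic(self):
        m = DetectionModel("uniform", BinningScheme((0.0, 1.0, 2.0)))
        ll = m.loglikelihood(np.array([1, 1]))
        assert ll == pytest.approx(np.log(0.25) + np.log(0.75))

    def test_all_mass_in_certain_bin_gives_zero(self):
        # a one-bin scheme has pi = (1,): the multinomial is degenerate, ll = 0
        m = DetectionModel("uniform", BinningScheme((0.0, 2.0, 4.0)))
        assert m.loglikelihood(np.array([1, 3])) == pytest.approx(
            np.log(0.25) + 3 * np.log(0.75)
        )

    def test_halfnormal_recovery_from_binned_draws(self, rng):
        scheme = BinningScheme.regular(1.0, 0.0, 5.0)
        truth = DetectionModel("half-normal", scheme, sigma=2.0)
        counts = rng.multinomial(2000, truth.bin_probabilities())
        m = fit_mle("half-normal", "none", (), counts, scheme, rng=rng)
        assert m.converged
        assert 1.9 <= m.sigma <= 2.1

    def test_mle_is_a_maximum(self, rng):
        scheme = BinningScheme.regular(1.0, 0.0, 5.0)
        truth = DetectionModel("half-normal", scheme, sigma=2.0)
        counts = rng.multinomial(800, truth.bin_probabilities())
        m = fit_mle("half-normal", "none", (), counts, scheme, rng=rng)
        ll_hat = m.loglikelihood(counts)
        x = m.internal
        for _ in range(100):
            perturbed = m.with_internal(x + rng.normal(scale=0.05, size=x.size))
            assert perturbed.loglikelihood(counts) <= ll_hat + 1e-9

    def test_single_occupied_bin_flagged_degenerate(self, scheme10):
        counts = np.zeros(10, dtype=int)
        counts[2] = 40
        m = fit_mle("half-normal", "none", (), counts, scheme10)
        assert not m.converged and "degenerate" in m.message

    def test_uniform_null_has_no_free_parameters(self, scheme10, rng):
        counts = rng.multinomial(100, np.full(10, 0.1))
        m = fit_mle("uniform", "none", (), counts, scheme10, rng=rng)
        assert m.converged and m.n_params == 0
        assert np.isfinite(m.loglik)

    def test_nested_orders_never_decrease_loglik(self, scheme10, rng):
        truth = DetectionModel("half-normal", scheme10, sigma=2.5)
        counts = rng.multinomial(1500, truth.bin_probabilities())
        lls = []
        for orders in [(), (2,), (2, 3)]:
            adj = "cosine" if orders else "none"
            m = fit_mle("half-normal", adj, orders, counts, scheme10, rng=rng)
            assert m.converged
            lls.append(m.loglik)
        assert lls == sorted(lls)

    def test_wald_interval_brackets_truth_typically(self, scheme10, rng):
        truth = DetectionModel("hazard-rate", scheme10, sigma=2.0, shape=3.0)
        hits = 0
        for _ in range(40):
            counts = rng.multinomial(500, truth.bin_probabilities())
            m = fit_mle("hazard-rate", "none", (), counts, scheme10, rng=rng)
            lo, hi = wald_ci(m, "sigma")
            hits += lo <= 2.0 <= hi
        assert hits >= 30  # ~95% nominal; allows sampling slack

    def test_parameter_count(self):
        assert n_free_parameters("uniform", ()) == 0
        assert n_free_parameters("half-normal", (2, 3)) == 3
        assert n_free_parameters("hazard-rate", ()) == 2
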