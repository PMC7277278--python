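"""Gravity building blocks, mean flows and the negative-binomial law."""

import numpy as np
import pytest
from scipy import optimize, stats

import gravroute as gr
from gravroute.gravity import nb_shape


class TestBuildingBlocks:
    def test_half_saturation(self):
        b = gr.BuildingBlock("x", "saturating", alpha1=1.0, alpha0=5.0)
        assert b(5.0) == pytest.approx(0.5)

    def test_saturation_limit(self):
        b = gr.BuildingBlock("x", "saturating", alpha1=1.0, alpha0=5.0)
        assert b(1e12) == pytest.approx(1.0, abs=1e-10)

    def test_near_lake_population_block(self):
        # saturating block at the fitted half-saturation of 888 thousand
        b = gr.BuildingBlock("lpop", "saturating", alpha1=1.0, alpha0=888.0)
        assert b(23.81) == pytest.approx(0.0261, abs=5e-5)

    def test_power_form(self):
        b = gr.BuildingBlock("x", "power", alpha1=2.0)
        assert b(3.0) == pytest.approx(9.0)

    def test_negative_covariate_rejected(self):
        with pytest.raises(ValueError):
            gr.BuildingBlock("x", "power")(-1.0)

    def test_saturating_requires_alpha0(self):
        with pytest.raises(ValueError):
            gr.BuildingBlock("x", "saturating")

    def test_covariate_model_sum_of_products(self):
        model = gr.CovariateModel(
            terms=(
                ("b1", (gr.BuildingBlock("x"),)),
                ("b2", (gr.BuildingBlock("x"), gr.BuildingBlock("y"))),
            ),
            constant=1.0,
        )
        val = model.evaluate({"x": 2.0, "y": 3.0}, {"b1": 0.5, "b2": 2.0})
        assert val == pytest.approx(1.0 + 0.5 * 2.0 + 2.0 * 2.0 * 3.0)


class TestMeanFlow:
    def test_facilities_only_attractiveness_factor(self):
        """A lake with only 'other facilities' is 1 + beta_fac = 5.51
        times as attractive as an identical bare lake."""
        p = gr.GravityParams()
        o = gr.OriginCovariates(pop=2.0, CA=1)
        bare = gr.DestinationCovariates(A=50.0)
        fac = gr.DestinationCovariates(A=50.0, fac=1)
        ratio = gr.mean_flow(p, o, fac, 800.0) / gr.mean_flow(p, o, bare, 800.0)
        assert ratio == pytest.approx(5.51)

    def test_distance_decay_cubic_order(self):
        p = gr.GravityParams()
        o = gr.OriginCovariates(pop=2.0)
        d = gr.DestinationCovariates(A=50.0)
        ratio = gr.mean_flow(p, o, d, 1600.0) / gr.mean_flow(p, o, d, 800.0)
        assert ratio == pytest.approx(2.0**-3.45, rel=1e-12)

    def test_zero_attractiveness_gives_zero_flow(self):
        p = gr.GravityParams()
        o = gr.OriginCovariates(pop=2.0)
        d = gr.DestinationCovariates(A=0.0)  # size gate zero
        assert gr.mean_flow(p, o, d, 800.0) == 0.0

    def test_unreachable_destination_gives_zero_flow(self):
        p = gr.GravityParams()
        o = gr.OriginCovariates(pop=2.0)
        d = gr.DestinationCovariates(A=50.0)
        assert gr.mean_flow(p, o, d, np.inf) == 0.0

    def test_monotone_in_attractiveness_covariates(self):
        p = gr.GravityParams()
        o = gr.OriginCovariates(pop=2.0)
        base = gr.mean_flow(p, o, gr.DestinationCovariates(A=50.0), 800.0)
        for kw in ({"camp": 1}, {"fac": 1}, {"mar": 1}, {"lpop": 10.0}):
            assert gr.mean_flow(p, o, gr.DestinationCovariates(A=50.0, **kw), 800.0) > base
        assert gr.mean_flow(p, o, gr.DestinationCovariates(A=80.0), 800.0) > base

    def test_strictly_decreasing_in_distance(self):
        p = gr.GravityParams()
        o = gr.OriginCovariates(pop=2.0)
        d = gr.DestinationCovariates(A=50.0)
        flows = [gr.mean_flow(p, o, d, t) for t in (400.0, 700.0, 1100.0, 2000.0)]
        assert all(a > b for a, b in zip(flows, flows[1:]))

    def test_marina_equivalent_population(self):
        """The near-lake population at which the population term equals
        the marina weight is about 23.8 thousand persons."""
        p = gr.GravityParams()
        x = optimize.brentq(
            lambda v: p.beta_lpop * v / (v + p.lpop0) - p.beta_mar, 1.0, 1000.0
        )
        assert x == pytest.approx(23.8, abs=0.1)

    def test_linear_in_scaling_factor(self):
        o = gr.OriginCovariates(pop=2.0)
        d = gr.DestinationCovariates(A=50.0, camp=1)
        f1 = gr.mean_flow(gr.GravityParams(), o, d, 800.0)
        f2 = gr.mean_flow(gr.GravityParams(c=2 * 3.73e-8), o, d, 800.0)
        assert f2 == pytest.approx(2 * f1)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gr.GravityParams(p=0.0)
        with pytest.raises(ValueError):
            gr.GravityParams(p=1.2)
        with pytest.raises(ValueError):
            gr.GravityParams(c=-1.0)
        with pytest.raises(ValueError):
            gr.GravityParams(beta_mar=-0.1)


class TestCountLaw:
    @pytest.mark.parametrize("mu", [0.01, 0.5, 3.0, 40.0])
    def test_mean_variance_ratio(self, mu):
        law = gr.nb_count_law(mu, 0.23)
        assert law.mean() == pytest.approx(mu)
        assert law.mean() / law.var() == pytest.approx(0.23)

    def test_additivity_under_shared_p(self):
        """NB(mu1, p) + NB(mu2, p) = NB(mu1 + mu2, p): numeric
        convolution oracle on support 0..200."""
        p = 0.4
        mu1, mu2 = 2.0, 5.0
        k = np.arange(201)
        pmf1 = gr.nb_count_law(mu1, p).pmf(k)
        pmf2 = gr.nb_count_law(mu2, p).pmf(k)
        conv = np.convolve(pmf1, pmf2)[:201]
        target = gr.nb_count_law(mu1 + mu2, p).pmf(k)
        assert np.max(np.abs(conv - target)) < 1e-10

    def test_poisson_limit(self):
        k = np.arange(50)
        nb = gr.nb_count_law(3.0, 0.999).pmf(k)
        po = stats.poisson(3.0).pmf(k)
        assert 0.5 * np.abs(nb - po).sum() < 1e-3  # total variation

    def test_p_equal_one_is_poisson(self):
        law = gr.nb_count_law(3.0, 1.0)
        assert law.pmf(2) == pytest.approx(stats.poisson(3.0).pmf(2))

    def test_zero_mean_is_point_mass(self):
        law = gr.nb_count_law(0.0, 0.23)
        assert law.pmf(0) == 1.0
        assert law.pmf(3) == 0.0
        assert law.mean() == 0.0

    def test_invalid_p_rejected(self):
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                gr.nb_count_law(1.0, p)

    def test_shape_parametrization(self):
        # success parameter equals p in the scipy parametrization
        mu, p = 4.0, 0.3
        law = gr.nb_count_law(mu, p)
        assert law.kwds == {} and law.args == (nb_shape(mu, p), p)

    def test_pooling_invariance(self):
        """Splitting a destination's flow into parts with the same p
        leaves the predicted count distribution unchanged."""
        p = 0.23
        whole = gr.nb_count_law(6.0, p)
        parts = [1.5, 2.5, 2.0]
        k = np.arange(120)
        pmfs = [gr.nb_count_law(m, p).pmf(k) for m in parts]
        conv = np.convolve(np.convolve(pmfs[0], pmfs[1]), pmfs[2])[:120]
        assert np.max(np.abs(conv - whole.pmf(k))) < 1e-10
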