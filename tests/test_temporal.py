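"""Daily traffic pattern: density, window probabilities, conditional fit."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import gravroute as gr


def sample_conditional_times(params, shifts, n, rng):
    """Times from the daily pattern restricted to randomly assigned
    survey windows (each accepted time recorded with its shift)."""
    out = []
    while len(out) < n:
        ts = (
            stats.vonmises.rvs(params.kappa, size=4 * n, random_state=rng)
            * 24.0 / (2 * math.pi) + params.theta
        ) % 24.0
        picks = rng.integers(len(shifts), size=len(ts))
        for t, s in zip(ts, picks):
            sh = shifts[s]
            if sh.contains(t):
                out.append((float(t), sh.shift_id))
                if len(out) == n:
                    break
    return out


DAY_SHIFTS = [
    gr.SurveyShift("s0", "k", 8.0, 14.0),
    gr.SurveyShift("s1", "k", 10.0, 16.0),
    gr.SurveyShift("s2", "k", 12.0, 18.0),
    gr.SurveyShift("s3", "k", 9.0, 17.0),
]


class TestDailyDensity:
    def test_uniform_at_zero_kappa(self):
        params = gr.TemporalParams(theta=14.0, kappa=0.0)
        t = np.linspace(0, 23.9, 40)
        assert gr.daily_density(params, t) == pytest.approx(np.full(40, 1 / 24))

    def test_peak_to_trough_ratio(self):
        """Midday/night density ratio is exp(2 kappa): about 15 at the
        fitted concentration 1.34."""
        params = gr.TemporalParams(theta=14.0, kappa=1.34)
        ratio = gr.daily_density(params, 14.0) / gr.daily_density(params, 2.0)
        assert ratio == pytest.approx(math.exp(2 * 1.34), rel=1e-9)
        assert ratio == pytest.approx(15.0, abs=0.5)

    def test_symmetry_about_peak(self):
        params = gr.TemporalParams(theta=14.0, kappa=2.0)
        for h in (1.0, 3.5, 9.0):
            assert gr.daily_density(params, 14.0 + h) == pytest.approx(
                gr.daily_density(params, 14.0 - h)
            )

    def test_integrates_to_one(self):
        params = gr.TemporalParams(theta=5.0, kappa=0.7)
        total, _ = quad(lambda t: gr.daily_density(params, t), 0, 24, limit=200)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            gr.TemporalParams(theta=12.0, kappa=-0.5)


class TestWindowProbability:
    def test_full_day_is_one(self):
        params = gr.TemporalParams(theta=14.0, kappa=1.34)
        assert gr.window_probability(params, gr.SurveyShift("s", "k", 0.0, 24.0)) == pytest.approx(1.0)

    def test_uniform_six_hours_is_quarter(self):
        params = gr.TemporalParams(theta=14.0, kappa=0.0)
        assert gr.window_probability(params, gr.SurveyShift("s", "k", 3.0, 9.0)) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "theta,kappa,start,end",
        [
            (14.0, 1.34, 11.0, 16.0),
            (14.0, 1.34, 22.0, 4.0),  # wraps midnight
            (2.0, 3.0, 0.0, 6.5),
            (23.0, 0.4, 20.0, 2.0),
            (6.0, 8.0, 5.0, 7.0),
        ],
    )
    def test_matches_adaptive_quadrature(self, theta, kappa, start, end):
        params = gr.TemporalParams(theta, kappa)
        shift = gr.SurveyShift("s", "k", start, end)
        if end > start:
            target, _ = quad(lambda t: gr.daily_density(params, t), start, end, limit=400)
        else:
            a, _ = quad(lambda t: gr.daily_density(params, t), start, 24.0, limit=400)
            b, _ = quad(lambda t: gr.daily_density(params, t), 0.0, end, limit=400)
            target = a + b
        assert gr.window_probability(params, shift) == pytest.approx(target, abs=1e-8)

    def test_additive_over_disjoint_windows(self):
        params = gr.TemporalParams(theta=15.0, kappa=2.0)
        whole = gr.window_probability(params, gr.SurveyShift("s", "k", 8.0, 18.0))
        parts = gr.window_probability(params, gr.SurveyShift("a", "k", 8.0, 12.5)) + gr.window_probability(
            params, gr.SurveyShift("b", "k", 12.5, 18.0)
        )
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_station_independent(self):
        params = gr.TemporalParams(theta=14.0, kappa=1.34)
        a = gr.window_probability(params, gr.SurveyShift("s", "k1", 9.0, 15.0))
        b = gr.window_probability(params, gr.SurveyShift("s", "k2", 9.0, 15.0))
        assert a == b


class TestConditionalFit:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(5)
        truth = gr.TemporalParams(theta=14.0, kappa=1.34)
        obs = sample_conditional_times(truth, DAY_SHIFTS, 2000, rng)
        fit = gr.fit_temporal(obs, DAY_SHIFTS)
        assert fit.theta_ci.contains(14.0)
        assert fit.kappa_ci.contains(1.34)

    def test_full_day_shifts_match_unconditional_mle(self):
        """When every shift covers the whole day the conditional fit
        reduces to the ordinary von Mises MLE."""
        rng = np.random.default_rng(9)
        truth = gr.TemporalParams(theta=10.0, kappa=2.0)
        shifts = [gr.SurveyShift("full", "k", 0.0, 24.0)]
        times = (
            stats.vonmises.rvs(2.0, size=1500, random_state=rng) * 24 / (2 * math.pi) + 10.0
        ) % 24.0
        obs = [(float(t), "full") for t in times]
        fit = gr.fit_temporal(obs, shifts, compute_ci=False)
        kappa_mle, loc, _ = stats.vonmises.fit(
            (times - 10.0) * 2 * math.pi / 24.0, fscale=1
        )
        theta_mle = (loc * 24 / (2 * math.pi) + 10.0) % 24.0
        assert fit.params.theta == pytest.approx(theta_mle, abs=0.02)
        assert fit.params.kappa == pytest.approx(kappa_mle, rel=0.02)

    def test_uniform_times_drive_kappa_to_zero(self):
        rng = np.random.default_rng(3)
        shifts = [gr.SurveyShift("full", "k", 0.0, 24.0)]
        obs = [(float(t), "full") for t in rng.uniform(0, 24, 3000)]
        fit = gr.fit_temporal(obs, shifts, compute_ci=False)
        assert fit.params.kappa < 0.1

    def test_windowed_sampling_without_correction_is_biased(self):
        """Morning-heavy survey windows pull the naive circular mean away
        from the afternoon peak; the conditional fit corrects this."""
        rng = np.random.default_rng(17)
        truth = gr.TemporalParams(theta=15.0, kappa=1.34)
        shifts = [
            gr.SurveyShift("m1", "k", 6.0, 12.0),
            gr.SurveyShift("m2", "k", 7.0, 13.0),
            gr.SurveyShift("a1", "k", 13.0, 17.0),
        ]
        obs = sample_conditional_times(truth, shifts, 3000, rng)
        times = np.array([t for t, _ in obs])
        ang = times * 2 * math.pi / 24
        naive = (math.atan2(np.sin(ang).mean(), np.cos(ang).mean()) * 24 / (2 * math.pi)) % 24
        fit = gr.fit_temporal(obs, shifts, compute_ci=False)
        assert abs(naive - 15.0) > 0.8  # raw mean clearly biased
        assert abs(fit.params.theta - 15.0) < 0.5

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            gr.fit_temporal([(12.0, "s0")], DAY_SHIFTS)

    def test_observation_outside_window_rejected(self):
        with pytest.raises(ValueError):
            gr.fit_temporal([(2.0, "s0"), (9.0, "s0")], DAY_SHIFTS)
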