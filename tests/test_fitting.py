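"""Observation law, composite likelihood and the staged fitting pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

import gravroute as gr
from gravroute.ci import profile_ci
from gravroute.fitting import (
    GravityFitProblem,
    aic_select,
    fit_gravity,
    fit_null_model,
    nb_logpmf,
)
from gravroute.gravity import nb_shape


def make_dataset(shifts, od_pairs, records):
    df = pd.DataFrame(records, columns=["shift_id", "origin", "destination", "count"])
    return gr.CountDataset(shifts, od_pairs, df)


SHIFTS = [
    gr.SurveyShift("t0", "k1", 9.0, 15.0),
    gr.SurveyShift("t1", "k1", 9.0, 15.0),
    gr.SurveyShift("t2", "k2", 11.0, 16.0),
]
ODS = [("o1", "d1"), ("o1", "d2"), ("o2", "d1"), ("o2", "d2")]


class TestShiftCountLaw:
    def test_zero_window_gives_point_mass(self):
        law = gr.shift_count_law(3.0, 0.5, 0.0, 0.7, 0.23)
        assert law.pmf(0) == 1.0

    def test_mean_is_product_of_thinnings(self):
        law = gr.shift_count_law(3.0, 0.5, 0.4, 0.7, 0.23)
        assert law.mean() == pytest.approx(3.0 * 0.5 * 0.4 * 0.7)

    def test_expectation_linear_in_compliance(self):
        m1 = gr.shift_count_law(3.0, 0.5, 0.4, 0.35, 0.23).mean()
        m2 = gr.shift_count_law(3.0, 0.5, 0.4, 0.70, 0.23).mean()
        assert m2 == pytest.approx(2 * m1)

    def test_matches_event_level_hierarchy_mean(self):
        """Monte-Carlo oracle: sample daily totals and thin agent by
        agent through route, window and compliance stages; the empirical
        mean must match the closed-form law within 3 standard errors."""
        rng = np.random.default_rng(101)
        mu, p, rho, tau, xi = 4.0, 0.23, 0.4, 0.3, 0.744
        n_rep = 100_000
        totals = rng.negative_binomial(nb_shape(mu, p), p, size=n_rep)
        via_station = rng.binomial(totals, rho)
        in_window = rng.binomial(via_station, tau)
        surveyed = rng.binomial(in_window, xi)
        law = gr.shift_count_law(mu, rho, tau, xi, p)
        se = surveyed.std(ddof=1) / math.sqrt(n_rep)
        assert abs(surveyed.mean() - law.mean()) < 3 * se


class TestCompositeLikelihood:
    def mean_fn(self, scale=1.0):
        base = {"k1": np.array([0.4, 0.1, 0.3, 0.2]), "k2": np.array([0.05, 0.5, 0.1, 0.25])}

        def fn(shift):
            tau = (shift.end - shift.start) / 24.0
            return scale * base[shift.station] * tau

        return fn

    def test_empty_dataset_is_zero(self):
        data = make_dataset([], [], [])
        assert gr.composite_log_likelihood(data, lambda s: np.array([]), 0.3) == 0.0

    def test_grouped_equals_naive_double_loop(self):
        records = [
            ("t0", "o1", "d1", 2),
            ("t0", "o2", "d2", 1),
            ("t2", "o1", "d2", 3),
        ]
        data = make_dataset(SHIFTS, ODS, records)
        fn = self.mean_fn()
        grouped = gr.composite_log_likelihood(data, fn, 0.23, grouped=True)
        naive = gr.composite_log_likelihood(data, fn, 0.23, grouped=False)
        assert grouped == pytest.approx(naive, abs=1e-8)

    def test_all_zero_data(self):
        data = make_dataset(SHIFTS, ODS, [])
        fn = self.mean_fn()
        grouped = gr.composite_log_likelihood(data, fn, 0.23)
        naive = gr.composite_log_likelihood(data, fn, 0.23, grouped=False)
        assert grouped == pytest.approx(naive, abs=1e-10)
        assert grouped < 0

    def test_extra_zero_shift_decreases_likelihood(self):
        data1 = make_dataset(SHIFTS[:2], ODS, [("t0", "o1", "d1", 1)])
        data2 = make_dataset(SHIFTS, ODS, [("t0", "o1", "d1", 1)])
        fn = self.mean_fn()
        assert gr.composite_log_likelihood(data2, fn, 0.23) < gr.composite_log_likelihood(
            data1, fn, 0.23
        )

    def test_record_order_invariance(self):
        records = [("t0", "o1", "d1", 2), ("t2", "o1", "d2", 3), ("t1", "o2", "d1", 1)]
        fn = self.mean_fn()
        a = gr.composite_log_likelihood(make_dataset(SHIFTS, ODS, records), fn, 0.3)
        b = gr.composite_log_likelihood(make_dataset(SHIFTS, ODS, records[::-1]), fn, 0.3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_shift_splitting_invariance(self):
        """Splitting one shift into two adjoining sub-shifts whose counts
        sum to the original leaves the likelihood unchanged (NB
        additivity over disjoint windows at shared p)."""
        whole = [gr.SurveyShift("w", "k1", 9.0, 15.0)]
        halves = [
            gr.SurveyShift("w1", "k1", 9.0, 12.0),
            gr.SurveyShift("w2", "k1", 12.0, 15.0),
        ]
        ods = [("o1", "d1")]
        base = np.array([2.0])

        def fn(shift):
            return base * (shift.end - shift.start) / 24.0

        p = 0.4
        ll_whole = gr.composite_log_likelihood(
            make_dataset(whole, ods, [("w", "o1", "d1", 3)]), fn, p
        )
        # sum the probabilities over every split of 3 counts
        total = 0.0
        for a in range(4):
            ll = gr.composite_log_likelihood(
                make_dataset(
                    halves, ods, [("w1", "o1", "d1", a), ("w2", "o1", "d1", 3 - a)]
                ),
                fn,
                p,
            )
            total += math.exp(ll)
        assert math.log(total) == pytest.approx(ll_whole, abs=1e-10)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            make_dataset(SHIFTS, ODS, [("t0", "o1", "d1", 1.5)])


class TestGravityFit:
    def test_staged_order_enforced(self, small_scenario):
        sc = small_scenario
        data, _, _ = gr.simulate_surveys(sc, mode="cells", seed=1)
        with pytest.raises(ValueError, match="staged"):
            GravityFitProblem(
                data, sc.origin_cov, sc.dest_cov, sc.distances, sc.path_sets,
                None, sc.config.temporal, sc.config.compliance,
            )

    def test_scale_confounding_of_c_and_xi(self, small_scenario):
        """The likelihood depends on c and xi only through their product:
        halving xi doubles the fitted c."""
        sc = small_scenario
        data, _, _ = gr.simulate_surveys(sc, mode="cells", seed=2)
        half_xi = gr.ComplianceParams(
            sc.config.compliance.xi_p / 2, sc.config.compliance.xi_c,
            sc.config.compliance.xi / 2,
        )
        fits = []
        for comp in (sc.config.compliance, half_xi):
            problem = GravityFitProblem(
                data, sc.origin_cov, sc.dest_cov, sc.distances, sc.path_sets,
                sc.config.route_choice, sc.config.temporal, comp,
            )
            fits.append(
                fit_gravity(problem, free=("c",), n_restarts=2, compute_ci=False)
            )
        assert fits[1].params.c * half_xi.xi == pytest.approx(
            fits[0].params.c * sc.config.compliance.xi, rel=1e-4
        )
        assert fits[1].log_likelihood == pytest.approx(fits[0].log_likelihood, abs=1e-6)

    def test_c_recovered_exactly_from_expected_counts(self, small_scenario):
        """Poisson-limit check: with observed counts equal to their
        expectations (integer by construction), the scale c is recovered
        exactly when all other parameters are held at truth."""
        sc = small_scenario
        truth = sc.config.gravity.updated(p=1.0)
        shifts = [gr.SurveyShift("e0", sc.network.stations[0], 0.0, 24.0)]
        problem_probe = GravityFitProblem(
            make_dataset(shifts, sc.od_pairs, []),
            sc.origin_cov, sc.dest_cov, sc.distances, sc.path_sets,
            sc.config.route_choice, sc.config.temporal, sc.config.compliance,
        )
        means = problem_probe.thin[0] * problem_probe.mu(truth)
        # integer expected counts: scale c so the largest-mean cell is 8,
        # then round means and treat the rounded values as the data
        scale = 8.0 / means.max()
        truth = truth.updated(c=truth.c * scale)
        exp_counts = np.rint(problem_probe.thin[0] * problem_probe.mu(truth)).astype(int)
        keep = exp_counts > 0
        # Poisson ML for a pure scale: c_hat = c_true * sum(n) / sum(mu)
        records = [
            ("e0", od[0], od[1], int(n))
            for od, n in zip(np.array(sc.od_pairs, dtype=object)[keep], exp_counts[keep])
        ]
        data = make_dataset(shifts, sc.od_pairs, records)
        problem = GravityFitProblem(
            data, sc.origin_cov, sc.dest_cov, sc.distances, sc.path_sets,
            sc.config.route_choice, sc.config.temporal, sc.config.compliance,
        )
        fit = fit_gravity(problem, start=truth, free=("c",), n_restarts=1, compute_ci=False)
        model_means = problem.thin[0] * problem.mu(truth)
        c_expected = truth.c * exp_counts.sum() / model_means.sum()
        assert fit.params.c == pytest.approx(c_expected, rel=1e-5)


class TestNullModel:
    def test_null_fits_constant_mean(self):
        rng = np.random.default_rng(4)
        shifts = [gr.SurveyShift(f"n{i}", "k1", 9.0, 15.0) for i in range(100)]
        ods = [("o", f"d{j}") for j in range(10)]
        m0, p = 0.8, 0.4
        records = []
        for s in shifts:
            counts = rng.negative_binomial(nb_shape(m0 * 0.25, p), p, size=10)
            for j, c in enumerate(counts):
                if c:
                    records.append((s.shift_id, "o", f"d{j}", int(c)))
        data = make_dataset(shifts, ods, records)
        fit = fit_null_model(data)
        assert fit.mean_per_day == pytest.approx(m0, rel=0.15)
        assert fit.p == pytest.approx(p, rel=0.25)


class TestProfileCI:
    def test_quadratic_log_likelihood_matches_wald(self):
        """For a quadratic NLL the profile interval is the analytic
        estimate +/- 1.96 SE."""
        se = 0.7
        nll = lambda x: 0.5 * ((x - 3.0) / se) ** 2
        ci = profile_ci(nll, 3.0, 0.0, -100.0, 100.0)
        assert ci.lower == pytest.approx(3.0 - 1.959964 * se, abs=1e-4)
        assert ci.upper == pytest.approx(3.0 + 1.959964 * se, abs=1e-4)

    def test_monotone_profile_gives_open_side(self):
        # upper-side profile rises too slowly to reach the drop in range
        nll = lambda x: 0.01 * (x - 3.0) if x > 3.0 else (3.0 - x) ** 2
        ci = profile_ci(nll, 3.0, 0.0, -100.0, 100.0)
        assert not ci.lower_open
        assert ci.upper_open  # never drops far enough before the bound
        assert ci.contains(1e9)


class TestAicSelect:
    def test_definition_and_ranking(self):
        table = aic_select({"b": (-100.0, 3), "a": (-100.0, 3), "rich": (-90.0, 8)})
        assert table.iloc[0]["model"] == "rich"  # 2*8 + 180 = 196
        assert table.iloc[0]["aic"] == pytest.approx(196.0)
        assert table["delta_aic"].iloc[0] == 0.0
        # identical models tie at AIC = 2*3 + 200 = 206, ordered by name
        assert list(table["model"][1:]) == ["a", "b"]
        assert table.iloc[1]["aic"] == pytest.approx(206.0)

    def test_better_likelihood_wins_at_equal_k(self):
        table = aic_select({"good": (-50.0, 4), "bad": (-70.0, 4)})
        assert table.iloc[0]["model"] == "good"
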