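import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prscox as px
from prscox.prs import ValidationError
from prscox.survival import (
    concordance,
    rcs_basis,
    schoenfeld_ph_test,
    schoenfeld_residuals,
)

from _oracles import auc_by_pairs, km_by_hand, logrank_p

SPEC_SMOKE = px.ModelSpec(
    "follow_up_years", "event",
    exposures=(px.CategoricalTerm("packyear_category", "no",
                                  ("light", "intermediate", "heavy")),),
)


class TestTrend:
    def test_strong_monotone_trend_detected(self, sim_cohort):
        p = px.trend_test(sim_cohort, SPEC_SMOKE, "packyear_category")
        assert p < 0.001

    def test_two_level_exposure_rejected(self, sim_cohort):
        spec = px.ModelSpec(
            "follow_up_years", "event",
            exposures=(px.CategoricalTerm("sexcat", "f", ("m",)),),
        )
        df = sim_cohort.copy()
        df["sexcat"] = np.where(df["sex"] > 0, "m", "f")
        with pytest.raises(ValidationError, match="3"):
            px.trend_test(df, spec, "sexcat")


class TestInteraction:
    def test_absent_term_rejected(self, sim_cohort):
        with pytest.raises(ValidationError, match="not present"):
            px.interaction_test(sim_cohort, SPEC_SMOKE, "packyear_category", "prs_z")

    def test_strong_product_effect_detected(self):
        # simulate a real multiplicative interaction on the log hazard
        rng = np.random.default_rng(30)
        n = 20_000
        z = rng.normal(size=n)
        g = rng.binomial(1, 0.4, size=n).astype(float)
        eta = 0.3 * z + 0.8 * g + 0.8 * z * g
        t = rng.exponential(1.0 / (0.01 * np.exp(eta)))
        cens = rng.uniform(5, 10, size=n)
        df = pd.DataFrame(
            {
                "follow_up_years": np.minimum(t, cens),
                "event": (t <= cens).astype(int),
                "z": z,
                "grp": np.where(g > 0, "b", "a"),
            }
        )
        spec = px.ModelSpec(
            "follow_up_years", "event",
            exposures=(px.ContinuousTerm("z"),
                       px.CategoricalTerm("grp", "a", ("b",))),
        )
        p, fit1, fit0 = px.interaction_test(df, spec, "z", "grp")
        assert p < 0.001
        assert fit1.loglik >= fit0.loglik


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_estimate(self, sim_cohort):
        fit = px.fit_cox(sim_cohort, px.ModelSpec(
            "follow_up_years", "event", exposures=(px.ContinuousTerm("prs_z"),)))
        resid = schoenfeld_residuals(fit, sim_cohort)
        # the summed residuals are the score equations, zero at the MLE
        assert np.abs(resid["prs_z"].sum()) < 1e-4

    def test_detects_sign_flipping_hazard(self):
        # hazard ratio exp(+0.8) before t0 and exp(-0.8) after: clear PH violation
        rng = np.random.default_rng(31)
        n = 10_000
        x = rng.binomial(1, 0.5, size=n).astype(float)
        lam, beta, t0 = 0.15, 0.8, 3.0
        e = rng.exponential(size=n)
        r1 = lam * np.exp(beta * x)
        r2 = lam * np.exp(-beta * x)
        t = np.where(e < r1 * t0, e / r1, t0 + (e - r1 * t0) / r2)
        cens = np.full(n, 8.0)
        df = pd.DataFrame({
            "follow_up_years": np.minimum(t, cens),
            "event": (t <= cens).astype(int),
            "x": x,
        })
        fit = px.fit_cox(df, px.ModelSpec("follow_up_years", "event",
                                          exposures=(px.ContinuousTerm("x"),)))
        ph = schoenfeld_ph_test(fit, df)
        assert ph.loc["x", "p"] < 0.01

    def test_null_data_not_flagged(self, sim_cohort):
        # generator satisfies PH by construction
        fit = px.fit_cox(sim_cohort, px.ModelSpec(
            "follow_up_years", "event",
            exposures=(px.ContinuousTerm("prs_z"),
                       px.CategoricalTerm("smoking_status", "never",
                                          ("former", "current")))))
        ph = schoenfeld_ph_test(fit, sim_cohort)
        assert ph.loc["GLOBAL", "p"] > 0.001

    def test_single_event_time_rejected(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 1.0, 2.0], "event": [1, 1, 0],
                           "x": [0.0, 1.0, 1.0]})
        fit = px.fit_cox(df, px.ModelSpec("follow_up_years", "event",
                                          exposures=(px.ContinuousTerm("x"),)))
        with pytest.raises(ValidationError, match="one time"):
            schoenfeld_ph_test(fit, df)


class TestRcs:
    def test_tail_linearity_below_first_knot(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=500)
        basis, knots = rcs_basis(x, n_knots=4)
        below = x < knots[0]
        assert below.any()
        np.testing.assert_allclose(basis.loc[below, "rcs1"], x[below])
        for c in ("rcs2", "rcs3"):
            np.testing.assert_allclose(basis.loc[below, c], 0.0, atol=1e-12)

    def test_matches_direct_formula_at_knots(self):
        x = np.linspace(-3, 3, 200)
        basis, knots = rcs_basis(x, knots=(-2.0, -0.5, 0.5, 2.0))
        # independent evaluation of the restricted-cubic construction
        t = np.asarray([-2.0, -0.5, 0.5, 2.0])
        span2 = (t[-1] - t[0]) ** 2
        plus = lambda u: np.maximum(u, 0.0) ** 3
        for j in range(2):
            expected = (
                plus(x - t[j])
                - plus(x - t[2]) * (t[3] - t[j]) / (t[3] - t[2])
                + plus(x - t[3]) * (t[2] - t[j]) / (t[3] - t[2])
            ) / span2
            np.testing.assert_allclose(basis[f"rcs{j + 2}"], expected, atol=1e-12)

    def test_linear_outside_boundary_knots(self):
        grid = np.linspace(-10, 10, 2001)
        basis, knots = rcs_basis(grid, knots=(-1.0, 0.0, 0.5, 1.0))
        h = grid[1] - grid[0]
        for c in basis.columns:
            y = basis[c].to_numpy()
            second = np.diff(y, 2) / h**2
            centers = grid[1:-1]
            outside = (centers < knots[0] - h) | (centers > knots[-1] + h)
            np.testing.assert_allclose(second[outside], 0.0, atol=1e-6)

    def test_invalid_knot_count(self):
        with pytest.raises(ValidationError):
            rcs_basis(np.arange(10.0), n_knots=7)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValidationError):
            rcs_basis(np.array([1.0, 1.0, 1.0, 2.0]), n_knots=4)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 1.5, 2.0],
                           "event": [1, 0, 1], "g": ["a", "a", "a"]})
        ci = px.cumulative_incidence(df, "g")
        oracle = {t: 1 - s for t, s in km_by_hand(df["follow_up_years"].to_numpy(),
                                                  df["event"].to_numpy())}
        got = dict(zip(ci["time"], ci["cum_risk"]))
        for t, risk in oracle.items():
            assert got[t] == pytest.approx(risk, abs=1e-12)
        assert got[2.0] == pytest.approx(1.0)

    def test_no_events_flat_zero(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 2.0], "event": [0, 0],
                           "g": ["a", "a"]})
        ci = px.cumulative_incidence(df, "g")
        assert (ci["cum_risk"] == 0).all()

    def test_monotone_and_bounded(self, sim_cohort):
        ci = px.cumulative_incidence(sim_cohort, "smoking_status")
        for _, sub in ci.groupby("group"):
            risks = sub.sort_values("time")["cum_risk"].to_numpy()
            assert (np.diff(risks) >= -1e-12).all()
            assert risks.max() <= 1.0 and risks.min() >= 0.0


class TestAuc:
    def test_perfect_and_constant(self):
        assert px.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert px.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_exhaustive_pair_count_with_ties(self):
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        s = [0.9, 0.7, 0.7, 0.2, 0.7, 0.4, 0.2, 0.1]
        assert px.roc_auc(y, s) == pytest.approx(auc_by_pairs(y, s), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(33)
        y = rng.binomial(1, 0.3, 200)
        s = rng.normal(size=200) + y
        assert px.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            px.roc_auc([1, 1], [0.1, 0.2])

    def test_concordance_runs(self, sim_cohort):
        c = concordance(sim_cohort["follow_up_years"], sim_cohort["event"],
                        sim_cohort["prs_z"])
        assert 0.4 < c < 0.8


class TestIncidenceRate:
    @pytest.mark.parametrize(
        "events,py,expected",
        [(248, 491_385, 0.50), (655, 131_912, 4.97), (254, 1_574_709, 0.16),
         (715, 239_414, 2.99), (0, 1000, 0.0)],
    )
    def test_published_style_rates(self, events, py, expected):
        assert round(px.incidence_rate(events, py), 2) == expected

    def test_invalid_person_years(self):
        with pytest.raises(ValidationError):
            px.incidence_rate(10, 0)


class TestPosthocPower:
    def test_null_hazard_ratio_gives_alpha_tail(self):
        assert px.posthoc_power(100, 0.5, 1.0) == pytest.approx(0.025, abs=1e-9)

    def test_monotone_in_events(self):
        powers = [px.posthoc_power(d, 0.3, 1.5) for d in (50, 100, 200, 400)]
        assert all(np.diff(powers) > 0)

    def test_matches_logrank_simulation(self):
        # oracle: empirical rejection rate of the log-rank test at d=100,
        # p=0.5, HR=1.5, no censoring
        rng = np.random.default_rng(34)
        n, reps = 100, 2000
        group = np.repeat([0, 1], n // 2)
        rate = np.where(group == 1, 1.5, 1.0)
        hits = 0
        event = np.ones(n, dtype=int)
        for _ in range(reps):
            t = rng.exponential(1.0 / rate)
            if logrank_p(t, event, group) < 0.05:
                hits += 1
        simulated = hits / reps
        formula = px.posthoc_power(n, 0.5, 1.5)
        assert abs(formula - simulated) < 0.03


def test_group_summaries_conserve_totals(sim_cohort):
    gs = px.group_summaries(sim_cohort, "smoking_status")
    assert sum(g.n for g in gs) == len(sim_cohort)
    assert sum(g.events for g in gs) == sim_cohort["event"].sum()
    assert sum(g.person_years for g in gs) == pytest.approx(
        sim_cohort["follow_up_years"].sum()
    )
    for g in gs:
        assert g.ir_per_1000 == pytest.approx(g.events / g.person_years * 1000)
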