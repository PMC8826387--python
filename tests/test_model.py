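"""Likelihood, diagnostics, summaries and sampler behaviour."""

import math

import arviz as az
import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.stats import norm

from heterostat import model as mdl
from heterostat.config import SamplerSettings
from heterostat.covariates import ExamTable
from heterostat.types import StateError, ValidationError


def _params_3cls():
    """Hand-set parameter point for the 3-class toy model."""
    return mdl.Parameters(
        tau=np.array([35.0]),
        d=np.array([20.0]),
        gamma_mass=np.array([[1.0], [-2.0]]),
        gamma_dt=np.array([[0.5], [-1.0]]),
        u=np.array([2.0, -3.0]),  # bats sorted: a, b
        sigma_u=5.0,
        sigma_eps=4.0,
    )


class TestLogLikelihood:
    def test_matches_independent_hand_computation(self, toy_exam_table):
        spec = mdl.ModelSpec(n_classes=3, impute_missing=False)
        p = _params_3cls()
        got = mdl.log_likelihood(p, toy_exam_table, spec)

        # independent recomputation straight from the model definition
        expected = 0.0
        u = {"a": 2.0, "b": -3.0}
        for r in toy_exam_table.df.itertuples(index=False):
            g = 1 if r.treatment == "T10" else 0
            T2 = 35.0 + 20.0 * g + p.gamma_mass[g, 0] * r.mass_c + p.gamma_dt[g, 0] * r.delta_t_c
            z = r.day + u[r.bat_id]
            c1 = norm.cdf((z - 10.0) / 4.0)
            c2 = norm.cdf((z - T2) / 4.0)
            prob = [1.0 - c1, c1 - c2, c2][r.cls]
            expected += math.log(prob)
        expected += norm.logpdf(2.0, 0, 5.0) + norm.logpdf(-3.0, 0, 5.0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_cell_probabilities_sum_to_one(self, toy_exam_table):
        spec = mdl.ModelSpec(n_classes=3, impute_missing=False)
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = _params_3cls()
            p.tau = p.tau + rng.normal(0, 10)
            p.gamma_mass = rng.normal(0, 20, (2, 1))  # may reorder thresholds
            p.gamma_dt = rng.normal(0, 20, (2, 1))
            p.u = rng.normal(0, 5, 2)
            cells = mdl.cell_probabilities(p, toy_exam_table, spec)
            np.testing.assert_allclose(cells.sum(axis=1), 1.0, atol=1e-10)

    def test_exam_at_threshold_gives_half(self, toy_exam_table):
        spec = mdl.ModelSpec(n_classes=3, impute_missing=False)
        p = _params_3cls()
        p.u = np.zeros(2)
        p.gamma_mass = np.zeros((2, 1))
        p.gamma_dt = np.zeros((2, 1))
        table = ExamTable(
            toy_exam_table.df.assign(day=10), 11.0, 4.0
        )  # exam exactly at the fixed first transition
        cells = mdl.cell_probabilities(p, table, spec)
        np.testing.assert_allclose(1.0 - cells[:, 0], 0.5, atol=1e-12)

    def test_small_sigma_eps_is_deterministic(self, toy_exam_table):
        spec = mdl.ModelSpec(n_classes=3, impute_missing=False)
        p = _params_3cls()
        p.u = np.zeros(2)
        p.d = np.zeros(1)
        p.gamma_mass = np.zeros((2, 1))
        p.gamma_dt = np.zeros((2, 1))
        p.sigma_eps = 1e-9
        table = ExamTable(toy_exam_table.df.assign(day=20), 11.0, 4.0)
        cells = mdl.cell_probabilities(p, table, spec)  # 10 < 20 < tau2 = 35
        np.testing.assert_allclose(cells[:, 1], 1.0, atol=1e-12)

    def test_missing_without_imputation_rejected(self, toy_exam_table):
        df = toy_exam_table.df.copy()
        df.loc[0, "mass_c"] = np.nan
        spec = mdl.ModelSpec(n_classes=3, impute_missing=False)
        with pytest.raises(ValidationError, match="imputation"):
            mdl.log_likelihood(_params_3cls(), ExamTable(df, 11.0, 4.0), spec)


class TestGelmanRubin:
    def test_hand_computed_two_by_four(self):
        # chains [1,2,3,4] and [2,3,4,5]: W = 5/3, B/n = var([2.5, 3.5]) = 0.5,
        # var+ = (3/4)(5/3) + 0.5 = 1.75, R = sqrt(1.75 / (5/3)) = sqrt(1.05)
        got = mdl.gelman_rubin([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
        assert got == pytest.approx(math.sqrt(1.05), abs=1e-12)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert mdl.gelman_rubin(chains) > 1.1

    def test_identical_chains_equal_one(self):
        rng = np.random.default_rng(2)
        c = rng.normal(0, 1, 500)
        assert mdl.gelman_rubin([c, c]) == pytest.approx(1.0, abs=1e-6)

    def test_zero_within_variance(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            assert mdl.gelman_rubin([[1.0] * 10, [2.0] * 10]) == math.inf
        assert mdl.gelman_rubin([[3.0] * 10, [3.0] * 10]) == 1.0

    def test_requires_two_chains(self):
        with pytest.raises(ValidationError):
            mdl.gelman_rubin([[1.0, 2.0, 3.0, 4.0]])


def _mk_fit(tau_draws, delay_draws=None, n_classes=3):
    """Assemble a FitResult around given draws (2 chains)."""
    tau = np.asarray(tau_draws, float).reshape(2, -1, 1)
    n = tau.shape[1]
    delay = (np.asarray(delay_draws, float).reshape(2, -1, 1)
             if delay_draws is not None else np.zeros_like(tau))
    em = np.tile(np.array([0.0, 1.0])[None, None, :, None], (2, n, 1, 1))
    ed = np.zeros((2, n, 2, 1))
    ds = xr.Dataset(
        {
            "transition_day": (("chain", "draw", "transition"), tau),
            "t10_delay": (("chain", "draw", "transition"), delay),
            "effect_mass": (("chain", "draw", "treatment", "transition"), em),
            "effect_dt": (("chain", "draw", "treatment", "transition"), ed),
            "u": (("chain", "draw", "bat"), np.zeros((2, n, 2))),
            "sigma_u": (("chain", "draw"), np.ones((2, n))),
            "sigma_eps": (("chain", "draw"), np.ones((2, n))),
        },
        coords={"chain": [0, 1], "draw": np.arange(n), "transition": ["1to2"],
                "treatment": ["T25", "T10"], "bat": ["a", "b"]},
    )
    rhat = {
        "transition_day": np.array([1.0]),
        "t10_delay": np.array([1.0]),
        "effect_mass": np.ones((2, 1)),
        "effect_dt": np.ones((2, 1)),
        "u": np.ones(2),
        "sigma_u": np.array(1.0),
        "sigma_eps": np.array(1.0),
    }
    return mdl.FitResult(
        draws=ds, rhat=rhat, converged=True, n_clipped=0,
        n_bats_reaching=np.array([2, 2, 1]),
        spec=mdl.ModelSpec(n_classes=n_classes),
        settings=SamplerSettings(chains=2, iterations=30, burn_in=10, thin=1),
    )


class TestSummarize:
    def test_constant_draws(self):
        fit = _mk_fit(np.full(300, 7.0))
        row = mdl.summarize(fit).set_index("parameter").loc["transition_1to2_T25"]
        assert row["mean"] == 7.0 and row["sd"] == 0.0
        assert row["q2.5"] == 7.0 and row["q97.5"] == 7.0
        assert bool(row["significant"])

    def test_symmetric_draws_not_significant(self):
        sym = np.concatenate([np.linspace(-3, 3, 150), np.linspace(-3, 3, 150)])
        fit = _mk_fit(np.full(300, 7.0), delay_draws=sym)
        row = mdl.summarize(fit).set_index("parameter").loc["delay_1to2_T10"]
        assert not bool(row["significant"])

    def test_normal_quantiles(self):
        rng = np.random.default_rng(5)
        fit = _mk_fit(rng.normal(3.0, 1.0, 10_000))
        row = mdl.summarize(fit).set_index("parameter").loc["transition_1to2_T25"]
        assert row["q2.5"] == pytest.approx(3 - 1.959964, abs=0.1)
        assert row["q97.5"] == pytest.approx(3 + 1.959964, abs=0.1)

    def test_too_few_draws_rejected(self):
        fit = _mk_fit(np.ones(60))
        with pytest.raises(ValidationError, match="draws"):
            mdl.summarize(fit)

    def test_requires_fit_result(self):
        with pytest.raises(StateError):
            mdl.summarize(pd.DataFrame())


class TestPredictTransitionDays:
    def test_profiles_are_linear_in_draws(self):
        rng = np.random.default_rng(6)
        tau = rng.normal(40, 2, 300)
        delay = rng.normal(30, 3, 300)
        fit = _mk_fit(tau, delay_draws=delay)
        np.testing.assert_allclose(
            mdl.predict_transition_days(fit, "T25"), tau)
        np.testing.assert_allclose(
            mdl.predict_transition_days(fit, "T10"), tau + delay)
        # +1 g under T10 adds that treatment's mass effect (1 day/g here)
        np.testing.assert_allclose(
            mdl.predict_transition_days(fit, "T10", mass_c=1.0), tau + delay + 1.0)

    def test_unknown_treatment_rejected(self):
        fit = _mk_fit(np.ones(300))
        with pytest.raises(ValidationError, match="treatment"):
            mdl.predict_transition_days(fit, "T15")


def _toy_table(day_shift=0.0):
    """Four bats (two per treatment), classes 0-2, delayed T10 group."""
    rows = []
    days = [15, 25, 35, 45]
    classes = {
        ("a", "T25"): [1, 1, 2, 2],
        ("b", "T25"): [0, 1, 2, 2],
        ("c", "T10"): [0, 0, 1, 1],
        ("d", "T10"): [0, 1, 1, 1],
    }
    mass_vals = [-1.0, -0.5, 0.5, 1.0]
    dt_vals = [0.3, -0.3, 0.6, -0.6]
    for (bat, treat), cls in classes.items():
        for k, (t, y) in enumerate(zip(days, cls)):
            rows.append(
                {"bat_id": bat, "day": t + day_shift, "cls": y, "treatment": treat,
                 "group_id": "g", "mass_c": mass_vals[k], "delta_t_c": dt_vals[k],
                 "mass_missing": False, "delta_t_missing": False}
            )
    return ExamTable(pd.DataFrame(rows), 11.0, 4.0)


def _mcse(draws_2d):
    flat_sd = float(np.std(draws_2d, ddof=1))
    ess = float(az.ess(np.asarray(draws_2d)))
    return flat_sd / math.sqrt(max(ess, 1.0))


class TestFit:
    SETTINGS = SamplerSettings(chains=3, iterations=3000, burn_in=1000, thin=2)

    def test_all_constant_classes_rejected(self):
        t = _toy_table()
        t.df["cls"] = 1
        with pytest.raises(ValidationError, match="unidentifiable"):
            mdl.fit(t, mdl.ModelSpec(), self.SETTINGS, seed=0)

    def test_seed_reproducibility(self):
        spec = mdl.ModelSpec(n_classes=3, include_delays=False,
                             include_covariates=False, impute_missing=False,
                             sigma_u=4.0, sigma_eps=4.0)
        small = SamplerSettings(chains=2, iterations=600, burn_in=200, thin=2)
        a = mdl.fit(_toy_table(), spec, small, seed=11)
        b = mdl.fit(_toy_table(), spec, small, seed=11)
        assert a.draws.identical(b.draws)

    def test_day_shift_translates_posterior(self):
        """Shifting all exam days and the fixed first threshold by +c
        shifts the transition-day posterior by +c (within MC error)."""
        c = 30.0
        spec0 = mdl.ModelSpec(n_classes=3, include_delays=False,
                              include_covariates=False, impute_missing=False,
                              sigma_u=4.0, sigma_eps=4.0)
        spec1 = mdl.ModelSpec(n_classes=3, first_transition_day=10.0 + c,
                              include_delays=False, include_covariates=False,
                              impute_missing=False, sigma_u=4.0, sigma_eps=4.0)
        f0 = mdl.fit(_toy_table(), spec0, self.SETTINGS, seed=21)
        f1 = mdl.fit(_toy_table(day_shift=c), spec1, self.SETTINGS, seed=22)
        m0 = float(f0.draws["transition_day"].mean())
        m1 = float(f1.draws["transition_day"].mean())
        err = math.hypot(_mcse(f0.draws["transition_day"].values[:, :, 0]),
                         _mcse(f1.draws["transition_day"].values[:, :, 0]))
        assert m1 - m0 == pytest.approx(c, abs=max(4 * err, 0.3))

    def test_imputation_machinery_is_inert_on_complete_data(self):
        """With no missing covariates, enabling imputation changes no
        posterior mean beyond Monte-Carlo error (the covariate-model
        factor is separable)."""
        from helpers import make_recovery_study

        table = make_recovery_study(seed=5, n_bats=12)
        spec_on = mdl.ModelSpec(n_classes=4, impute_missing=True)
        spec_off = mdl.ModelSpec(n_classes=4, impute_missing=False)
        settings = SamplerSettings(chains=3, iterations=4000, burn_in=1500, thin=2)
        f_on = mdl.fit(table, spec_on, settings, seed=31)
        f_off = mdl.fit(table, spec_off, settings, seed=32)
        for var, j in (("transition_day", 0), ("transition_day", 1), ("t10_delay", 0)):
            a = f_on.draws[var].values[:, :, j]
            b = f_off.draws[var].values[:, :, j]
            err = math.hypot(_mcse(a), _mcse(b))
            assert abs(float(a.mean()) - float(b.mean())) <= max(2 * err, 0.1)
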