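"""Shared test utilities: independent oracles and study builders.

The oracles here deliberately re-derive results by the most transparent
route available (explicit scans, closed forms, dense numerical
integration) and never call the code paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from heterostat.covariates import build_exam_table
from heterostat.simulate import (
    SimConfig,
    TrueParameters,
    exam_covariate_truth,
    simulate_cohort,
    simulate_maturation,
)
from heterostat.types import DailySummary, TempSeries, TorporEvent


# --------------------------------------------------------------------------
# brute-force torpor-event oracle
# --------------------------------------------------------------------------

def brute_force_torpor_events(series: TempSeries, threshold: float, min_run: int):
    """Enumerate maximal sub-threshold runs by a plain index scan."""
    events = []
    run: list[int] = []

    def flush():
        if len(run) >= min_run:
            events.append(
                TorporEvent(
                    bat_id=series.bat_id,
                    start=series.t[run[0]],
                    end=series.t[run[-1]],
                    n_readings=len(run),
                    duration_h=len(run) / 6.0,
                    min_tsk_c=float(min(series.tsk_c[i] for i in run)),
                )
            )
        run.clear()

    for i in range(len(series)):
        if series.included[i] and series.tsk_c[i] < threshold:
            run.append(i)
        else:
            flush()
    flush()
    return events


def random_quantized_series(rng: np.random.Generator, bat_id: str = "x") -> TempSeries:
    """A random 0.5 °C-quantized series with a random inclusion mask."""
    n = int(rng.integers(5, 80))
    t = np.datetime64("2017-07-01T00:00", "ns") + np.arange(n) * np.timedelta64(10, "m")
    tsk = rng.integers(40, 80, n) * 0.5  # 20.0 .. 39.5 °C
    ta = np.full(n, float(rng.choice([10.0, 25.0])))
    included = rng.random(n) < 0.85
    return TempSeries(bat_id, t, tsk, ta, included)


# --------------------------------------------------------------------------
# study builders for model-level checks
# --------------------------------------------------------------------------

RECOVERY_TRUTH = TrueParameters(
    tau=(40.0, 62.0),
    d=(30.0, 35.0),
    gamma_mass=((0.0, 0.0), (0.0, 0.0)),
    gamma_dt=((0.0, 0.0), (0.0, 0.0)),
    sigma_u=5.0,
    sigma_eps=5.0,
)


def make_recovery_study(seed: int, n_bats: int = 30):
    """Simulated cohort under the recovery-study conditions.

    30 bats, exams every 10 days to day 60, true transition days 40/62,
    cold delays 30/35, no covariate effects, sigma_u = sigma_eps = 5.
    Covariates are complete (no missing values).
    """
    cfg = SimConfig(n_bats=n_bats, study_days=60, seed=seed, truth=RECOVERY_TRUTH)
    bats, masses = simulate_cohort(cfg)
    cov = exam_covariate_truth(cfg, bats, masses)
    obs = simulate_maturation(cfg, bats, cov)
    dailies = [
        DailySummary(r.bat_id, int(r.day), float("nan"), r.delta_t, 0, float("nan"), 144)
        for r in cov.itertuples(index=False)
    ]
    return build_exam_table(obs, masses, dailies, bats)


# --------------------------------------------------------------------------
# dense grid-integration oracle for the reduced model
# --------------------------------------------------------------------------

def grid_posterior_mean_tau2(
    days: np.ndarray,
    classes_a: np.ndarray,
    classes_b: np.ndarray,
    sigma_u: float,
    sigma_eps: float,
    first_day: float = 10.0,
    prior_tau_scale: float = 50.0,
    tau_grid: np.ndarray | None = None,
    u_grid: np.ndarray | None = None,
) -> float:
    """Posterior mean of the free transition day by brute-force quadrature.

    Two bats share exam days; classes are in {0, 1, 2} with the first
    threshold fixed at ``first_day``.  The posterior over
    (tau2, u_a, u_b) is integrated on a dense grid, with a half-normal
    prior on tau2 − first_day and N(0, sigma_u^2) priors on the
    intercepts — an independent re-derivation of the model's posterior.
    """
    if tau_grid is None:
        tau_grid = np.arange(first_day + 0.05, 90.0, 0.1)
    if u_grid is None:
        u_grid = np.arange(-16.0, 16.0 + 1e-9, 0.4)

    tau = tau_grid[:, None]  # broadcast over u

    def bat_loglik(classes: np.ndarray) -> np.ndarray:
        """log p(classes | tau2, u) on the (tau, u) grid."""
        out = np.zeros((len(tau_grid), len(u_grid)))
        for t, y in zip(days, classes):
            c1 = ndtr((t + u_grid[None, :] - first_day) / sigma_eps)
            c2 = ndtr((t + u_grid[None, :] - tau) / sigma_eps)
            if y == 0:
                p = 1.0 - c1
            elif y == 1:
                p = c1 - c2
            else:
                p = c2
            out += np.log(np.maximum(p, 1e-300))
        return out

    log_prior_tau = -0.5 * ((tau_grid - first_day) / prior_tau_scale) ** 2
    log_prior_u = -0.5 * (u_grid / sigma_u) ** 2

    la = bat_loglik(classes_a) + log_prior_u[None, :]
    lb = bat_loglik(classes_b) + log_prior_u[None, :]
    # integrate each bat's intercept, then combine over tau
    m = max(la.max(), lb.max())
    ia = np.exp(la - m).sum(axis=1)
    ib = np.exp(lb - m).sum(axis=1)
    w = ia * ib * np.exp(log_prior_tau)
    return float(np.sum(tau_grid * w) / np.sum(w))
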