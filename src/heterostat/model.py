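"""Hierarchical Bayesian ordinal model of maturation transition times.

The ordinal maturation class :math:`y_{ij} \\in \\{0..4\\}` of bat *i*
examined on day :math:`t_{ij}` is modelled as a cumulative ordered
probit **on the day axis**, so every reported quantity — transition day,
treatment delay, covariate effect — is a parameter in days:

.. math::

    P(y_{ij} \\ge k) = \\Phi\\!\\left(
        \\frac{t_{ij} + u_i - T_{k,ij}}{\\sigma_\\varepsilon}\\right)

with per-transition effective thresholds

.. math::

    T_{1,ij} = 10, \\qquad
    T_{k,ij} = \\tau_k + d_k\\,[g_i = T10]
             + \\gamma^M_{g_i,k}\\,m_{ij} + \\gamma^\\Delta_{g_i,k}\\,\\delta_{ij}
    \\quad (k \\ge 2)

where :math:`\\tau_k` are the baseline (T25) transition days (ordered
:math:`\\tau_2 < \\tau_3 < \\tau_4`), :math:`d_k` the T10 delays in days,
:math:`\\gamma` the effects (days per centred gram, days per centred °C)
per treatment and transition, and :math:`u_i \\sim N(0, \\sigma_u^2)` a
per-bat random intercept in days.  The first transition (class 0 → 1)
is fixed at day 10 of captivity, the start of the treatment, and carries
no effects.  Cell probabilities come from differencing the cumulative
probabilities; numerically degenerate cells (possible when covariate
effects reorder thresholds for an extreme observation) are floored at a
small configurable constant and counted.

Missing exam-day covariates are modelled as draws from Gaussians with a
single estimated mean and spread per covariate; observed values inform
those hyperparameters and missing values are sampled jointly with the
rest (one-block Bayesian imputation).

Inference is by adaptive Metropolis-within-Gibbs: scalar random-walk
updates for structural parameters; vectorized independent-block updates
for the random intercepts (conditionally independent across bats) and
for imputed covariates (independent across exams).  Proposal scales
adapt by Robbins–Monro during burn-in only, so the post-burn-in kernel
is a fixed, valid Metropolis–Hastings kernel.  Convergence is assessed
by the potential scale reduction factor with the usual
R-hat < 1.1 rule.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import ndtr

from .config import SamplerSettings
from .covariates import ExamTable
from .io import POSTERIOR_COLUMNS
from .types import StateError, ValidationError

log = logging.getLogger("heterostat")

TRANSITION_LABELS = ("1to2", "2to3", "3to4")
TREATMENT_LEVELS = ("T25", "T10")  # index 0 is the baseline

_LOG_2PI = math.log(2.0 * math.pi)


# --------------------------------------------------------------------------
# specification and parameters
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Structural choices and priors of the transition-time model.

    Prior scales are in days (effects: days per centred covariate unit).
    ``prior_scale_factor`` is a sensitivity knob multiplying every prior
    scale (double/halve to probe prior influence).  Setting ``sigma_u``
    or ``sigma_eps`` fixes that standard deviation instead of sampling
    it (used by the reduced-model oracle checks).
    """

    n_classes: int = 5
    first_transition_day: float = 10.0
    include_delays: bool = True
    include_covariates: bool = True
    impute_missing: bool = True
    prior_tau_scale: float = 50.0
    prior_effect_scale: float = 50.0
    prior_sigma_scale: float = 20.0
    prior_impute_mu_scale: float = 10.0
    prior_impute_sigma_scale: float = 10.0
    prior_scale_factor: float = 1.0
    sigma_u: float | None = None
    sigma_eps: float | None = None
    prob_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_classes < 3:
            raise ValidationError("need >= 3 ordinal classes (>= 1 free threshold)")
        if self.prob_floor <= 0:
            raise ValidationError("prob_floor must be > 0")

    @property
    def n_free_thresholds(self) -> int:
        return self.n_classes - 2  # first threshold is fixed


@dataclass
class Parameters:
    """One point in parameter space (all time quantities in days)."""

    tau: np.ndarray              # (J,) baseline transition days, k = 2..K
    d: np.ndarray                # (J,) T10 delays
    gamma_mass: np.ndarray       # (2, J) per treatment (T25, T10)
    gamma_dt: np.ndarray         # (2, J)
    u: np.ndarray                # (n_bats,) random intercepts
    sigma_u: float
    sigma_eps: float
    mu_mass: float = 0.0
    sigma_mass: float = 1.0
    mu_dt: float = 0.0
    sigma_dt: float = 1.0
    mass_imputed: np.ndarray = field(default_factory=lambda: np.empty(0))
    dt_imputed: np.ndarray = field(default_factory=lambda: np.empty(0))


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------

class _Data:
    """Exam table flattened to arrays for the likelihood."""

    def __init__(self, exams: ExamTable, spec: ModelSpec):
        df = exams.df.reset_index(drop=True)
        self.bat_ids = sorted(df["bat_id"].unique())
        idx = {b: i for i, b in enumerate(self.bat_ids)}
        self.n = len(df)
        self.n_bats = len(self.bat_ids)
        self.bat_idx = df["bat_id"].map(idx).to_numpy(int)
        self.t = df["day"].to_numpy(float)
        self.cls = df["cls"].to_numpy(int)
        if self.cls.max() > spec.n_classes - 1 or self.cls.min() < 0:
            raise ValidationError("observed class outside the model's class range")
        self.is_t10 = (df["treatment"] == "T10").to_numpy(float)
        self.treat_idx = self.is_t10.astype(int)
        self.mass = df["mass_c"].to_numpy(float) if "mass_c" in df else np.full(self.n, np.nan)
        self.dt = df["delta_t_c"].to_numpy(float) if "delta_t_c" in df else np.full(self.n, np.nan)
        self.mass_mis = np.flatnonzero(np.isnan(self.mass))
        self.dt_mis = np.flatnonzero(np.isnan(self.dt))
        self.rows = np.arange(self.n)
        # precomputed gather indices for the two cumulative cells each
        # observation needs: P(y >= cls) and P(y >= cls + 1)
        K = spec.n_classes - 1
        self.is_cls0 = self.cls == 0
        self.is_clsK = self.cls == K
        self.k_up = np.clip(self.cls - 1, 0, K - 1)  # threshold index of P(y >= cls)
        self.k_lo = np.clip(self.cls, 0, K - 1)      # threshold index of P(y >= cls + 1)
        self.free_up = np.clip(self.k_up - 1, 0, None)  # tau index for k_up
        self.free_lo = np.clip(self.k_lo - 1, 0, None)
        self.up_is_fixed = self.k_up == 0  # gathered threshold is the fixed day-10 one
        self.lo_is_fixed = self.k_lo == 0
        # bats reaching each class at least once (for reporting gates)
        max_cls = df.groupby("bat_id")["cls"].max()
        self.n_bats_reaching = np.array(
            [(max_cls >= c).sum() for c in range(spec.n_classes)]
        )


# --------------------------------------------------------------------------
# densities
# --------------------------------------------------------------------------

_LOG2 = math.log(2.0)


def _hn_scalar(x: float, scale: float) -> float:
    """Half-normal log density at a scalar (−inf outside the support)."""
    if x <= 0:
        return -math.inf
    return _LOG2 - math.log(scale) - 0.5 * _LOG_2PI - 0.5 * (x / scale) ** 2


def _n_scalar(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2 - math.log(scale) - 0.5 * _LOG_2PI


def _norm_logpdf(x, mu, sigma):
    z = (np.asarray(x, float) - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * _LOG_2PI


def _half_norm_logpdf(x, scale):
    x = np.asarray(x, float)
    out = np.where(
        x > 0,
        math.log(2.0) - math.log(scale) - 0.5 * _LOG_2PI - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def _thresholds(data: _Data, spec: ModelSpec, tau, d, gm, gd, mass, dt) -> np.ndarray:
    """Effective per-observation thresholds, shape (n, K)."""
    J = len(tau)
    T = np.empty((data.n, J + 1))
    T[:, 0] = spec.first_transition_day
    if J:
        base = tau + d * data.is_t10[:, None]
        if spec.include_covariates:
            base = base + gm[data.treat_idx, :] * mass[:, None] \
                        + gd[data.treat_idx, :] * dt[:, None]
        T[:, 1:] = base
    return T


def _gather_threshold(data, spec, tau, d, gm, gd, mass, dt, free, fixed_mask):
    """Effective threshold T_{k,ij} for one gathered threshold index per row."""
    T = tau[free] + d[free] * data.is_t10
    if spec.include_covariates:
        T = T + gm[data.treat_idx, free] * mass + gd[data.treat_idx, free] * dt
    return np.where(fixed_mask, spec.first_transition_day, T)


def _obs_logp(data, spec, tau, d, gm, gd, u, sigma_eps, mass, dt):
    """Per-exam log cell probability (floored) and the number of floored cells.

    Only the two cumulative cells each observation needs are evaluated,
    via precomputed gather indices.
    """
    z = data.t + u[data.bat_idx]
    T_up = _gather_threshold(data, spec, tau, d, gm, gd, mass, dt,
                             data.free_up, data.up_is_fixed)
    T_lo = _gather_threshold(data, spec, tau, d, gm, gd, mass, dt,
                             data.free_lo, data.lo_is_fixed)
    upper = np.where(data.is_cls0, 1.0, ndtr((z - T_up) / sigma_eps))
    lower = np.where(data.is_clsK, 0.0, ndtr((z - T_lo) / sigma_eps))
    p = upper - lower
    n_clip = int(np.count_nonzero(p < spec.prob_floor))
    return np.log(np.maximum(p, spec.prob_floor)), n_clip


def _fill(values: np.ndarray, mis: np.ndarray, imputed: np.ndarray) -> np.ndarray:
    out = values.copy()
    if mis.size:
        if len(imputed) != mis.size:
            raise ValidationError("imputed-value vector does not match missingness pattern")
        out[mis] = imputed
    return out


def cell_probabilities(params: Parameters, exams: ExamTable, spec: ModelSpec) -> np.ndarray:
    """Unclipped cell probabilities, one row per exam, columns classes 0..K.

    Rows sum to 1 exactly (telescoping of the cumulative differences);
    individual cells can be negative for parameter points whose
    covariate effects reorder the thresholds of an observation.
    """
    data = _Data(exams, spec)
    mass = _fill(data.mass, data.mass_mis, params.mass_imputed)
    dt = _fill(data.dt, data.dt_mis, params.dt_imputed)
    T = _thresholds(data, spec, params.tau, params.d, params.gamma_mass,
                    params.gamma_dt, mass, dt)
    z = data.t + params.u[data.bat_idx]
    c = ndtr((z[:, None] - T) / params.sigma_eps)
    cum = np.hstack([np.ones((data.n, 1)), c, np.zeros((data.n, 1))])
    return cum[:, :-1] - cum[:, 1:]


def log_likelihood(params: Parameters, exams: ExamTable, spec: ModelSpec) -> float:
    """Joint log density of data and latent quantities at ``params``.

    Sum over exams of the (floored) ordinal log cell probability, plus
    the random-intercept densities :math:`u_i \\sim N(0, \\sigma_u^2)`,
    plus — when imputation is on — the covariate-model Gaussian
    densities of all exam-day covariate values (observed values at their
    data, missing values at their imputed values).  Structural priors
    are *not* included (see the sampler for the full posterior).
    """
    data = _Data(exams, spec)
    if not spec.impute_missing and (data.mass_mis.size or data.dt_mis.size):
        raise ValidationError("missing covariates present but imputation disabled")
    mass = _fill(data.mass, data.mass_mis, params.mass_imputed)
    dt = _fill(data.dt, data.dt_mis, params.dt_imputed)
    logp, _ = _obs_logp(data, spec, params.tau, params.d, params.gamma_mass,
                        params.gamma_dt, params.u, params.sigma_eps, mass, dt)
    total = float(logp.sum())
    total += float(np.sum(_norm_logpdf(params.u, 0.0, params.sigma_u)))
    if spec.impute_missing and spec.include_covariates:
        if not np.all(np.isnan(mass)):
            total += float(np.nansum(_norm_logpdf(mass, params.mu_mass, params.sigma_mass)))
        if not np.all(np.isnan(dt)):
            total += float(np.nansum(_norm_logpdf(dt, params.mu_dt, params.sigma_dt)))
    return total


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------

class _Sampler:
    _ADAPT_TARGET = 0.44

    def __init__(self, data: _Data, spec: ModelSpec, settings: SamplerSettings):
        self.data = data
        self.spec = spec
        self.settings = settings
        J = spec.n_free_thresholds
        self.J = J
        f = spec.prior_scale_factor
        self.tau_scale = spec.prior_tau_scale * f
        self.effect_scale = spec.prior_effect_scale * f
        self.sigma_scale = spec.prior_sigma_scale * f
        self.imu_scale = spec.prior_impute_mu_scale * f
        self.isig_scale = spec.prior_impute_sigma_scale * f
        # scalar update registry: (array name, flat index or None,
        # likelihood components the parameter enters); the prior term is
        # always handled incrementally per parameter
        self.entries: list[tuple[str, int | None, tuple[str, ...]]] = []
        for j in range(J):
            self.entries.append(("tau", j, ("ord",)))
        if spec.include_delays:
            for j in range(J):
                self.entries.append(("d", j, ("ord",)))
        if spec.include_covariates:
            for g in range(2):
                for j in range(J):
                    self.entries.append(("gm", 2 * j + g, ("ord",)))
                    self.entries.append(("gd", 2 * j + g, ("ord",)))
        if spec.sigma_u is None:
            self.entries.append(("sigma_u", None, ("u",)))
        if spec.sigma_eps is None:
            self.entries.append(("sigma_eps", None, ("ord",)))
        self.has_cov_model = spec.impute_missing and spec.include_covariates
        if self.has_cov_model:
            if not np.all(np.isnan(data.mass)) or data.mass_mis.size:
                self.entries.append(("mu_mass", None, ("cov",)))
                self.entries.append(("sigma_mass", None, ("cov",)))
            if not np.all(np.isnan(data.dt)) or data.dt_mis.size:
                self.entries.append(("mu_dt", None, ("cov",)))
                self.entries.append(("sigma_dt", None, ("cov",)))
        self.n_clip_total = 0

    # -- initial state -------------------------------------------------
    def _init_state(self, rng: np.random.Generator) -> dict:
        spec, data, J = self.spec, self.data, self.J
        st: dict = {}
        st["tau"] = spec.first_transition_day + np.cumsum(rng.uniform(5.0, 30.0, J))
        st["d"] = rng.normal(0.0, 5.0, J) if spec.include_delays else np.zeros(J)
        if spec.include_covariates:
            st["gm"] = rng.normal(0.0, 2.0, (2, J))
            st["gd"] = rng.normal(0.0, 2.0, (2, J))
        else:
            st["gm"] = np.zeros((2, J))
            st["gd"] = np.zeros((2, J))
        st["sigma_u"] = spec.sigma_u if spec.sigma_u is not None else rng.uniform(2.0, 10.0)
        st["sigma_eps"] = spec.sigma_eps if spec.sigma_eps is not None else rng.uniform(2.0, 10.0)
        st["u"] = rng.normal(0.0, 1.0, data.n_bats)
        m_obs = data.mass[~np.isnan(data.mass)]
        d_obs = data.dt[~np.isnan(data.dt)]
        st["mu_mass"] = (float(m_obs.mean()) if m_obs.size else 0.0) + rng.normal(0, 0.5)
        st["sigma_mass"] = max(float(m_obs.std()), 0.5) * rng.uniform(0.5, 2.0) if m_obs.size else rng.uniform(0.5, 2.0)
        st["mu_dt"] = (float(d_obs.mean()) if d_obs.size else 0.0) + rng.normal(0, 0.5)
        st["sigma_dt"] = max(float(d_obs.std()), 0.5) * rng.uniform(0.5, 2.0) if d_obs.size else rng.uniform(0.5, 2.0)
        st["mass_fill"] = data.mass.copy()
        if data.mass_mis.size:
            st["mass_fill"][data.mass_mis] = rng.normal(st["mu_mass"], st["sigma_mass"], data.mass_mis.size)
        st["dt_fill"] = data.dt.copy()
        if data.dt_mis.size:
            st["dt_fill"][data.dt_mis] = rng.normal(st["mu_dt"], st["sigma_dt"], data.dt_mis.size)
        return st

    # -- posterior components -----------------------------------------
    def _comp_ord(self, st) -> tuple[float, np.ndarray, int]:
        logp, n_clip = _obs_logp(
            self.data, self.spec, st["tau"], st["d"], st["gm"], st["gd"],
            st["u"], st["sigma_eps"], st["mass_fill"], st["dt_fill"])
        return float(logp.sum()), logp, n_clip

    def _comp_u(self, st) -> float:
        if st["sigma_u"] <= 0:
            return -np.inf
        return float(np.sum(_norm_logpdf(st["u"], 0.0, st["sigma_u"])))

    def _comp_cov(self, st) -> float:
        if not self.has_cov_model:
            return 0.0
        total = 0.0
        if st["sigma_mass"] <= 0 or st["sigma_dt"] <= 0:
            return -np.inf
        m = st["mass_fill"]
        if not np.all(np.isnan(m)):
            total += float(np.nansum(_norm_logpdf(m, st["mu_mass"], st["sigma_mass"])))
        d = st["dt_fill"]
        if not np.all(np.isnan(d)):
            total += float(np.nansum(_norm_logpdf(d, st["mu_dt"], st["sigma_dt"])))
        return total

    def _comp_prior(self, st) -> float:
        spec = self.spec
        inc = np.diff(np.concatenate([[spec.first_transition_day], st["tau"]]))
        if np.any(inc <= 0):
            return -np.inf
        lp = float(np.sum(_half_norm_logpdf(inc, self.tau_scale)))
        if spec.include_delays:
            lp += float(np.sum(_norm_logpdf(st["d"], 0.0, self.effect_scale)))
        if spec.include_covariates:
            lp += float(np.sum(_norm_logpdf(st["gm"], 0.0, self.effect_scale)))
            lp += float(np.sum(_norm_logpdf(st["gd"], 0.0, self.effect_scale)))
        if spec.sigma_u is None:
            lp += float(_half_norm_logpdf(st["sigma_u"], self.sigma_scale))
        if spec.sigma_eps is None:
            lp += float(_half_norm_logpdf(st["sigma_eps"], self.sigma_scale))
        if self.has_cov_model:
            lp += float(_norm_logpdf(st["mu_mass"], 0.0, self.imu_scale))
            lp += float(_norm_logpdf(st["mu_dt"], 0.0, self.imu_scale))
            lp += float(_half_norm_logpdf(st["sigma_mass"], self.isig_scale))
            lp += float(_half_norm_logpdf(st["sigma_dt"], self.isig_scale))
        return lp

    def _component(self, name: str, st) -> float:
        if name == "ord":
            val, _, n_clip = self._comp_ord(st)
            self.n_clip_total += n_clip
            return val
        if name == "u":
            return self._comp_u(st)
        if name == "cov":
            return self._comp_cov(st)
        return self._comp_prior(st)

    # -- updates -------------------------------------------------------
    @staticmethod
    def _get(st, name, idx):
        return st[name] if idx is None else st[name].flat[idx]

    @staticmethod
    def _set(st, name, idx, value):
        if idx is None:
            st[name] = value
        else:
            st[name].flat[idx] = value

    def _prior_term(self, st, name, idx) -> float:
        """Prior log-density terms involving one scalar parameter.

        For an interior transition day both adjacent increments change,
        so both half-normal terms are included; the difference of two
        such terms is the correct prior contribution to the MH ratio.
        """
        if name == "tau":
            tau = st["tau"]
            prev = tau[idx - 1] if idx > 0 else self.spec.first_transition_day
            t = _hn_scalar(tau[idx] - prev, self.tau_scale)
            if idx + 1 < self.J:
                t += _hn_scalar(tau[idx + 1] - tau[idx], self.tau_scale)
            return t
        if name in ("d", "gm", "gd"):
            return _n_scalar(st[name].flat[idx], self.effect_scale)
        if name in ("sigma_u", "sigma_eps"):
            return _hn_scalar(st[name], self.sigma_scale)
        if name in ("mu_mass", "mu_dt"):
            return _n_scalar(st[name], self.imu_scale)
        return _hn_scalar(st[name], self.isig_scale)  # sigma_mass / sigma_dt

    def _update_scalar(self, st, comps, entry, scale, rng) -> float:
        name, idx, affected = entry
        old = self._get(st, name, idx)
        term_old = self._prior_term(st, name, idx)
        self._set(st, name, idx, old + scale * rng.standard_normal())
        term_new = self._prior_term(st, name, idx)
        if not math.isfinite(term_new):  # outside the prior support
            self._set(st, name, idx, old)
            return 0.0
        new = {k: self._component(k, st) for k in affected}
        delta = (term_new - term_old) + sum(new[k] - comps[k] for k in affected)
        if np.isfinite(delta) and (delta >= 0 or rng.random() < math.exp(delta)):
            comps.update(new)
            comps["prior"] += term_new - term_old
            return min(1.0, math.exp(min(delta, 0.0)))
        self._set(st, name, idx, old)
        return 0.0 if not np.isfinite(delta) else min(1.0, math.exp(min(delta, 0.0)))

    def _update_u(self, st, comps, scales, rng) -> np.ndarray:
        data = self.data
        _, logp_cur, _ = self._comp_ord(st)
        ord_cur = np.bincount(data.bat_idx, weights=logp_cur, minlength=data.n_bats)
        pri_cur = _norm_logpdf(st["u"], 0.0, st["sigma_u"])
        u_old = st["u"].copy()
        st["u"] = u_old + scales * rng.standard_normal(data.n_bats)
        _, logp_prop, _ = self._comp_ord(st)
        ord_prop = np.bincount(data.bat_idx, weights=logp_prop, minlength=data.n_bats)
        pri_prop = _norm_logpdf(st["u"], 0.0, st["sigma_u"])
        delta = (ord_prop - ord_cur) + (pri_prop - pri_cur)
        accept = np.log(rng.random(data.n_bats)) < delta
        st["u"] = np.where(accept, st["u"], u_old)
        comps["ord"] += float(np.sum((ord_prop - ord_cur)[accept]))
        comps["u"] += float(np.sum((pri_prop - pri_cur)[accept]))
        return np.minimum(1.0, np.exp(np.minimum(delta, 0.0)))

    def _update_missing(self, st, comps, key, mis, mu_key, sig_key, scales, rng) -> np.ndarray:
        _, logp_cur, _ = self._comp_ord(st)
        old = st[key][mis].copy()
        prop = old + scales * rng.standard_normal(mis.size)
        st[key][mis] = prop
        _, logp_prop, _ = self._comp_ord(st)
        cov_cur = _norm_logpdf(old, st[mu_key], st[sig_key])
        cov_prop = _norm_logpdf(prop, st[mu_key], st[sig_key])
        delta = (logp_prop[mis] - logp_cur[mis]) + (cov_prop - cov_cur)
        accept = np.log(rng.random(mis.size)) < delta
        st[key][mis] = np.where(accept, prop, old)
        comps["ord"] += float(np.sum((logp_prop[mis] - logp_cur[mis])[accept]))
        if self.has_cov_model:
            comps["cov"] += float(np.sum((cov_prop - cov_cur)[accept]))
        return np.minimum(1.0, np.exp(np.minimum(delta, 0.0)))

    @staticmethod
    def _adapt(scale, acc, it, target=_ADAPT_TARGET):
        step = min(0.25, 3.0 * (it + 1.0) ** -0.6)
        return scale * np.exp(step * (acc - target))

    # -- one chain -----------------------------------------------------
    def run_chain(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        data, spec, settings = self.data, self.spec, self.settings
        st = self._init_state(rng)
        comps = {
            "ord": self._component("ord", st),
            "u": self._comp_u(st),
            "cov": self._comp_cov(st),
            "prior": self._comp_prior(st),
        }
        # a prior-drawn start can sit on a zero-prior point; nudge
        tries = 0
        while not np.isfinite(comps["prior"]) and tries < 100:
            st = self._init_state(rng)
            comps["prior"] = self._comp_prior(st)
            tries += 1
        comps["ord"] = self._component("ord", st)
        comps["u"] = self._comp_u(st)
        comps["cov"] = self._comp_cov(st)

        scales = {i: 2.0 if e[0] in ("tau", "d", "gm", "gd") else 0.5
                  for i, e in enumerate(self.entries)}
        scales_u = np.full(data.n_bats, 2.0)
        scales_m = np.full(data.mass_mis.size, 1.0)
        scales_d = np.full(data.dt_mis.size, 1.0)

        keep = []
        for it in range(settings.iterations):
            adapting = it < settings.burn_in
            for i, entry in enumerate(self.entries):
                acc = self._update_scalar(st, comps, entry, scales[i], rng)
                if adapting:
                    scales[i] = float(self._adapt(scales[i], acc, it))
            acc_u = self._update_u(st, comps, scales_u, rng)
            if adapting:
                scales_u = self._adapt(scales_u, acc_u, it)
            if data.mass_mis.size:
                acc_m = self._update_missing(st, comps, "mass_fill", data.mass_mis,
                                             "mu_mass", "sigma_mass", scales_m, rng)
                if adapting:
                    scales_m = self._adapt(scales_m, acc_m, it)
            if data.dt_mis.size:
                acc_d = self._update_missing(st, comps, "dt_fill", data.dt_mis,
                                             "mu_dt", "sigma_dt", scales_d, rng)
                if adapting:
                    scales_d = self._adapt(scales_d, acc_d, it)
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                keep.append(
                    {
                        "tau": st["tau"].copy(),
                        "d": st["d"].copy(),
                        "gm": st["gm"].copy(),
                        "gd": st["gd"].copy(),
                        "u": st["u"].copy(),
                        "sigma_u": st["sigma_u"],
                        "sigma_eps": st["sigma_eps"],
                        "mu_mass": st["mu_mass"],
                        "sigma_mass": st["sigma_mass"],
                        "mu_dt": st["mu_dt"],
                        "sigma_dt": st["sigma_dt"],
                        "mass_imputed": st["mass_fill"][data.mass_mis].copy(),
                        "dt_imputed": st["dt_fill"][data.dt_mis].copy(),
                    }
                )
        return {k: np.stack([rec[k] for rec in keep]) for k in keep[0]}


# --------------------------------------------------------------------------
# fit result
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws and diagnostics of one model fit."""

    draws: xr.Dataset
    rhat: dict[str, np.ndarray]
    converged: bool
    n_clipped: int
    n_bats_reaching: np.ndarray
    spec: ModelSpec
    settings: SamplerSettings

    @property
    def n_draws(self) -> int:
        return self.draws.sizes["chain"] * self.draws.sizes["draw"]

    def max_rhat(self) -> float:
        vals = [np.max(v) for v in self.rhat.values() if np.size(v)]
        return float(np.max(vals)) if vals else float("nan")

    def to_zarr(self, path) -> None:
        """Persist the draws as a self-describing array store."""
        self.draws.to_zarr(str(path), mode="w")


def fit(
    exams: ExamTable,
    spec: ModelSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> FitResult:
    """Run seeded multi-chain MCMC on the transition-time model.

    Chains are initialised from broad seeded draws spanning the
    plausible parameter range and run sequentially, so identical seeds
    and settings reproduce the draws bit-identically on one platform.
    Non-convergence (any R-hat >= 1.1) flags the result but never
    suppresses it.
    """
    spec = spec or ModelSpec()
    settings = settings or SamplerSettings()
    data = _Data(exams, spec)
    if np.all(data.cls == data.cls[0]):
        raise ValidationError(
            "all observed classes identical: transition days are unidentifiable")
    if not spec.impute_missing and (data.mass_mis.size or data.dt_mis.size):
        raise ValidationError("missing covariates present but imputation disabled")

    sampler = _Sampler(data, spec, settings)
    children = np.random.SeedSequence(seed).spawn(settings.chains)
    chains = [sampler.run_chain(np.random.default_rng(children[c]))
              for c in range(settings.chains)]

    J = spec.n_free_thresholds
    labels = list(TRANSITION_LABELS[:J])
    n_draw = chains[0]["tau"].shape[0]

    def stack(key):
        return np.stack([c[key] for c in chains])  # (chain, draw, ...)

    data_vars = {
        "transition_day": (("chain", "draw", "transition"), stack("tau")),
        "t10_delay": (("chain", "draw", "transition"), stack("d")),
        "effect_mass": (("chain", "draw", "treatment", "transition"), stack("gm")),
        "effect_dt": (("chain", "draw", "treatment", "transition"), stack("gd")),
        "u": (("chain", "draw", "bat"), stack("u")),
        "sigma_u": (("chain", "draw"), stack("sigma_u")),
        "sigma_eps": (("chain", "draw"), stack("sigma_eps")),
    }
    if sampler.has_cov_model:
        for k in ("mu_mass", "sigma_mass", "mu_dt", "sigma_dt"):
            data_vars[f"impute_{k}"] = (("chain", "draw"), stack(k))
        if data.mass_mis.size:
            data_vars["mass_imputed"] = (("chain", "draw", "mass_missing"), stack("mass_imputed"))
        if data.dt_mis.size:
            data_vars["dt_imputed"] = (("chain", "draw", "dt_missing"), stack("dt_imputed"))
    ds = xr.Dataset(
        data_vars,
        coords={
            "chain": np.arange(settings.chains),
            "draw": np.arange(n_draw),
            "transition": labels,
            "treatment": list(TREATMENT_LEVELS),
            "bat": data.bat_ids,
        },
        attrs={"seed": seed, "n_classes": spec.n_classes,
               "first_transition_day": spec.first_transition_day},
    )

    rhat: dict[str, np.ndarray] = {}
    # sampled scalars only: fixed sigmas / disabled effect blocks are constant
    skip = set()
    if spec.sigma_u is not None:
        skip.add("sigma_u")
    if spec.sigma_eps is not None:
        skip.add("sigma_eps")
    if not spec.include_delays:
        skip.add("t10_delay")
    if not spec.include_covariates:
        skip.update({"effect_mass", "effect_dt"})
    for name, da in ds.data_vars.items():
        if name in skip:
            continue
        arr = da.values  # (chain, draw, ...)
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        rhat[name] = np.array(
            [gelman_rubin(flat[:, :, k]) for k in range(flat.shape[2])]
        ).reshape(arr.shape[2:])
    converged = all(np.all(np.asarray(v) < 1.1) for v in rhat.values())
    if not converged:
        log.warning("non-convergence: max R-hat = %.3f (result flagged)",
                    max(float(np.max(v)) for v in rhat.values()))
    return FitResult(
        draws=ds,
        rhat=rhat,
        converged=converged,
        n_clipped=sampler.n_clip_total,
        n_bats_reaching=data.n_bats_reaching,
        spec=spec,
        settings=settings,
    )


# --------------------------------------------------------------------------
# diagnostics & summaries
# --------------------------------------------------------------------------

def gelman_rubin(chains) -> float:
    """Potential scale reduction factor (Brooks–Gelman–Rubin R-hat).

    Compares the pooled-variance estimate
    ``(n−1)/n · W + B/n`` with the mean within-chain variance ``W``,
    where ``B/n`` is the variance of the per-chain means.  Values below
    1 arise only from finite-sample noise and are reported as 1.0, so
    chains that are exact copies of each other give R-hat = 1.  Zero
    within-chain variance with non-identical chains returns +inf with a
    warning.
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValidationError("need a 2-D array with >= 2 chains")
    n = a.shape[1]
    if n < 2:
        raise ValidationError("need >= 2 draws per chain")
    W = float(np.mean(np.var(a, axis=1, ddof=1)))
    b_over_n = float(np.var(a.mean(axis=1), ddof=1))
    if W == 0.0:
        if b_over_n == 0.0:
            return 1.0
        warnings.warn("zero within-chain variance; R-hat undefined", stacklevel=2)
        return float("inf")
    var_plus = (n - 1) / n * W + b_over_n
    return max(1.0, math.sqrt(var_plus / W))


def _report_rows(fit_result: FitResult, include_unreported: bool):
    """Yield (parameter name, flat draw array, rhat) for reported parameters."""
    ds = fit_result.draws
    spec = fit_result.spec
    labels = list(ds.coords["transition"].values)
    for j, label in enumerate(labels):
        if (label == "3to4" and not include_unreported
                and fit_result.n_bats_reaching[-1] < 2):
            # prior-only transition: too few bats ever reached the last
            # class for the data to inform it
            continue
        yield (f"transition_{label}_T25",
               ds["transition_day"].values[:, :, j],
               fit_result.rhat["transition_day"][j])
        if spec.include_delays:
            yield (f"delay_{label}_T10",
                   ds["t10_delay"].values[:, :, j],
                   fit_result.rhat["t10_delay"][j])
        if spec.include_covariates:
            for g, treat in enumerate(TREATMENT_LEVELS):
                yield (f"effect_mass_{label}_{treat}",
                       ds["effect_mass"].values[:, :, g, j],
                       fit_result.rhat["effect_mass"][g, j])
                yield (f"effect_dt_{label}_{treat}",
                       ds["effect_dt"].values[:, :, g, j],
                       fit_result.rhat["effect_dt"][g, j])
    if spec.sigma_u is None:
        yield "sigma_u", ds["sigma_u"].values, fit_result.rhat["sigma_u"][()]
    if spec.sigma_eps is None:
        yield "sigma_eps", ds["sigma_eps"].values, fit_result.rhat["sigma_eps"][()]


def summarize(
    fit_result: FitResult,
    include_unreported: bool = False,
    min_draws: int = 100,
) -> pd.DataFrame:
    """Posterior-summary table: mean, sd, 2.5/50/97.5 percentiles, R-hat.

    A parameter is flagged significant when its 95% credible interval
    excludes 0.  Transition-day and delay parameters are in days.  The
    last transition is reported only when at least two bats were ever
    observed in the final class (otherwise its posterior reflects the
    prior, not the data).
    """
    if not isinstance(fit_result, FitResult):
        raise StateError("summarize() requires a fitted model (FitResult)")
    if fit_result.n_draws < min_draws:
        raise ValidationError(
            f"only {fit_result.n_draws} retained draws; need >= {min_draws}")
    rows = []
    for name, arr, rhat in _report_rows(fit_result, include_unreported):
        flat = np.asarray(arr).ravel()
        lo, med, hi = np.percentile(flat, [2.5, 50.0, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(lo),
                "q50": float(med),
                "q97.5": float(hi),
                "rhat": float(rhat),
                "significant": not (lo <= 0.0 <= hi),
            }
        )
    return pd.DataFrame(rows, columns=POSTERIOR_COLUMNS)


def predict_transition_days(
    fit_result: FitResult,
    treatment: str,
    transition: str = "1to2",
    mass_c: float = 0.0,
    dt_c: float = 0.0,
) -> np.ndarray:
    """Posterior draws of the effective transition day for a profile.

    The baseline profile (T25, covariates at 0) returns the draws of
    the transition day itself; a T10 profile adds the delay; covariate
    offsets add linearly (days per centred unit).
    """
    if treatment not in TREATMENT_LEVELS:
        raise ValidationError(f"unknown treatment {treatment!r}")
    ds = fit_result.draws
    labels = list(ds.coords["transition"].values)
    if transition not in labels:
        raise ValidationError(f"unknown transition {transition!r}; have {labels}")
    j = labels.index(transition)
    g = TREATMENT_LEVELS.index(treatment)
    out = ds["transition_day"].values[:, :, j].astype(float).copy()
    if treatment == "T10":
        out += ds["t10_delay"].values[:, :, j]
    if fit_result.spec.include_covariates:
        out += ds["effect_mass"].values[:, :, g, j] * mass_c
        out += ds["effect_dt"].values[:, :, g, j] * dt_c
    return out.ravel()
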