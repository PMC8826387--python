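"""Seeded generator of complete synthetic studies.

Emulates the study design end to end: a cohort captured with intake
mass/forearm in the published ranges, BCI-matched treatment assignment,
daily body-mass trajectories (dip-then-rise at 25 °C, rise-then-fall at
10 °C), 10-min skin-temperature traces with torpor and evening arousals
(10 °C) or bounded shallow fluctuation (25 °C), and ordinal maturation
trajectories drawn from the transition-time model itself — the
generative twin of the likelihood in :mod:`heterostat.model`.

All randomness derives from one root seed through named substreams, so
adding a generator stage never perturbs the others, and per-bat streams
are keyed by a CRC of the bat id, so cohort size changes do not shuffle
existing bats' traces.

Mass and skin-temperature trajectory shapes are qualitative mimics of
the published treatment-level patterns (piecewise trends, fixed arousal
clock window), not refits: the transition-time model only consumes
exam-day values, so only those need to be realistic.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .config import StudyConfig
from .covariates import assign_treatments
from .thermo import apply_exclusions, daily_summaries, detect_torpor_events, per_individual_thresholds
from .types import (
    BatRecord,
    MassRecord,
    MaturationObs,
    TempSeries,
    Treatment,
    ValidationError,
)

_STREAMS = {"cohort": 1, "mass": 2, "tsk": 3, "maturation": 4, "exam_dt": 5, "assign": 6}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream], extra]))


def _bat_key(bat_id: str) -> int:
    return zlib.crc32(bat_id.encode()) % (2**31)


@dataclass
class TrueParameters:
    """Generating values of the transition-time model (days).

    Defaults are the study's reported posterior means: baseline
    transition days 39.37 / 62.81, cold-treatment delays 33.48 / 37.12,
    and the per-treatment covariate effects; the last transition is
    placed past the study end (only a single bat ever reached class 4).
    """

    tau: tuple[float, ...] = (39.37, 62.81, 85.0)
    # the last delay is a beyond-study placeholder keeping the cold
    # treatment's effective thresholds ordered
    d: tuple[float, ...] = (33.48, 37.12, 37.0)
    gamma_mass: tuple[tuple[float, ...], ...] = (
        (-2.19, -5.89, 0.0),   # T25
        (-11.9, -7.54, 0.0),   # T10
    )
    gamma_dt: tuple[tuple[float, ...], ...] = (
        (1.63, 2.72, 0.0),
        (-5.38, -5.32, 0.0),
    )
    sigma_u: float = 5.0
    sigma_eps: float = 5.0
    first_transition_day: float = 10.0

    def __post_init__(self) -> None:
        taus = (self.first_transition_day,) + tuple(self.tau)
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValidationError("true transition days must be strictly increasing")
        if self.sigma_u < 0 or self.sigma_eps < 0:
            raise ValidationError("true standard deviations must be >= 0")


@dataclass
class SimConfig:
    """Study conditions of a synthetic cohort.

    Defaults follow the experimental design: ~32 bats in groups of
    three, treatments at 10/25 °C, 10 acclimation days plus a 52-day
    treatment (study days 0–62 since capture), examinations every ten
    days, intake mass 9.4–12.8 g and forearm 34.0–46.9 mm.
    """

    n_bats: int = 32
    group_size: int = 3
    treatment_ta: dict[str, float] = field(default_factory=lambda: {"T10": 10.0, "T25": 25.0})
    study_days: int = 62
    exam_interval: int = 10
    truth: TrueParameters = field(default_factory=TrueParameters)
    forearm_range: tuple[float, float] = (34.0, 46.9)
    capture_mass_range: tuple[float, float] = (9.4, 12.8)
    mass_noise_sd: float = 0.15
    tsk_noise_sd: float = 0.3
    normothermic_c: float = 33.0
    torpid_offset_c: float = 0.7
    arousal_window: tuple[str, str] = ("18:00", "19:30")
    #: time constant (h) of passive cooling after the evening
    #: handling/feeding arousal — digesting bats stay warm for hours
    arousal_cooling_h: float = 2.5
    #: log-sd of the day-to-day lognormal jitter on the cooling time
    #: constant (cooling speed tracks digestion intensity), the main
    #: source of within-treatment ΔT variation
    arousal_cooling_logsd: float = 0.5
    t25_band: tuple[float, float] = (24.2, 30.6)
    #: fraction of study days each bat carries a logger (deployment
    #: start drawn per bat; loggers detached spontaneously in the study)
    logger_coverage: float = 1.0
    #: ΔT values outside logger coverage (latent truth for generation)
    dt_exam_mean: float = 4.5
    dt_exam_sd: float = 1.5
    monotone_classes: bool = True
    day0: _dt.date = _dt.date(2017, 6, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bats < 4:
            raise ValidationError("n_bats must be >= 4")
        if isinstance(self.truth, dict):
            self.truth = TrueParameters(**self.truth)
        for sd in (self.mass_noise_sd, self.tsk_noise_sd, self.dt_exam_sd):
            if sd < 0:
                raise ValidationError("noise standard deviations must be >= 0")
        if not 0.0 < self.logger_coverage <= 1.0:
            raise ValidationError("logger_coverage must be in (0, 1]")

    @property
    def exam_days(self) -> list[int]:
        return list(range(0, self.study_days + 1, self.exam_interval))

    def study_config(self) -> StudyConfig:
        return StudyConfig(treatment_ta=dict(self.treatment_ta), day0=self.day0,
                           seed=self.seed)


# --------------------------------------------------------------------------
# cohort & masses
# --------------------------------------------------------------------------

_MASS_TREND_NODES = {
    # piecewise-linear offsets (days, grams) relative to capture mass
    Treatment.T25: ([0.0, 10.0, 20.0, 62.0], [0.0, -0.3, -1.2, -0.4]),
    Treatment.T10: ([0.0, 17.0, 20.0, 62.0], [0.0, 0.3, 0.3, -1.0]),
}


def simulate_cohort(cfg: SimConfig) -> tuple[list[BatRecord], list[MassRecord]]:
    """Draw a cohort with BCI-matched treatments and daily mass records."""
    rng = _rng(cfg.seed, "cohort")
    width = len(str(cfg.n_bats))
    bats = [
        BatRecord(
            bat_id=f"b{i + 1:0{width}d}",
            forearm_mm=float(rng.uniform(*cfg.forearm_range)),
            capture_mass_g=float(rng.uniform(*cfg.capture_mass_range)),
            treatment=None,
        )
        for i in range(cfg.n_bats)
    ]
    assign_seed = int(np.random.SeedSequence([cfg.seed, _STREAMS["assign"]]).generate_state(1)[0] % (2**31))
    bats = assign_treatments(bats, seed=assign_seed)
    # housing groups of group_size within each treatment
    counters: dict[str, int] = {}
    grouped = []
    for b in bats:
        tr = b.treatment.value
        k = counters.get(tr, 0)
        counters[tr] = k + 1
        grouped.append(dataclasses.replace(b, group_id=f"{tr}-g{k // cfg.group_size + 1}"))
    bats = grouped

    masses: list[MassRecord] = []
    for b in bats:
        mrng = _rng(cfg.seed, "mass", _bat_key(b.bat_id))
        days = np.arange(cfg.study_days + 1)
        nodes_d, nodes_g = _MASS_TREND_NODES[b.treatment]
        trend = b.capture_mass_g + np.interp(days, nodes_d, nodes_g)
        vals = trend + mrng.normal(0.0, cfg.mass_noise_sd, len(days))
        masses.extend(
            MassRecord(b.bat_id, int(d), float(max(v, 1.0)))
            for d, v in zip(days, vals)
        )
    return bats, masses


# --------------------------------------------------------------------------
# skin-temperature traces
# --------------------------------------------------------------------------

def simulate_tsk(cfg: SimConfig, bat: BatRecord) -> TempSeries:
    """One logger deployment for a bat, on the 10-min grid.

    Cold-treatment bats sit just above ambient with one normothermic
    arousal excursion in the evening handling/feeding window;
    warm-treatment bats fluctuate within the shallow-torpor band with
    the same evening excursion.  Both cool passively (exponentially)
    back to their torpid level after the arousal — digesting bats stay
    warm for hours, which is what keeps daily thermoregulation effort
    (ΔT) comparable between treatments.  Gaussian noise is added,
    values are quantized to 0.5 °C, and tsk >= ta is enforced.
    """
    if bat.treatment is None:
        raise ValidationError(f"bat {bat.bat_id} has no treatment assigned")
    rng = _rng(cfg.seed, "tsk", _bat_key(bat.bat_id))
    cov_days = max(1, int(round(cfg.logger_coverage * (cfg.study_days + 1))))
    start_day = int(rng.integers(0, cfg.study_days + 2 - cov_days))
    n = cov_days * 144
    t0 = np.datetime64(cfg.day0.isoformat()) + np.timedelta64(start_day, "D")
    t = t0.astype("datetime64[ns]") + np.arange(n) * np.timedelta64(10, "m")
    minutes = (np.arange(n) % 144) * 10.0
    ta = cfg.treatment_ta[bat.treatment.value]
    h0, m0 = map(int, cfg.arousal_window[0].split(":"))
    h1, m1 = map(int, cfg.arousal_window[1].split(":"))
    a0, a1 = h0 * 60 + m0, h1 * 60 + m1
    if bat.treatment is Treatment.T10:
        base = np.full(n, ta + cfg.torpid_offset_c)
    else:
        lo, hi = cfg.t25_band
        mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
        base = mid + amp * np.sin(2.0 * np.pi * (minutes - 600.0) / 1440.0)
    tsk = base.copy()
    in_arousal = (minutes >= a0) & (minutes < a1)
    tsk[in_arousal] = cfg.normothermic_c
    if cfg.arousal_cooling_h > 0:
        # minutes since the end of the last arousal, continuous across
        # midnight so the overnight cooling tail has no jump; the time
        # constant is re-drawn per arousal (digestion intensity varies)
        g = np.arange(n) * 10.0
        k = np.floor((g - a1) / 1440.0).astype(int)  # index of last arousal
        msa = g - (a1 + 1440.0 * k)
        mult = np.exp(rng.normal(0.0, cfg.arousal_cooling_logsd, cov_days + 1))
        tau_min = 60.0 * cfg.arousal_cooling_h * mult[np.clip(k + 1, 0, cov_days)]
        outside = ~in_arousal
        decay = np.exp(-msa[outside] / tau_min[outside])
        tsk[outside] = base[outside] + (cfg.normothermic_c - base[outside]) * decay
    if cfg.tsk_noise_sd > 0:
        tsk = tsk + rng.normal(0.0, cfg.tsk_noise_sd, n)
    tsk = np.round(tsk * 2.0) / 2.0
    tsk = np.maximum(tsk, ta)
    return TempSeries(bat.bat_id, t, tsk, np.full(n, ta))


# --------------------------------------------------------------------------
# maturation
# --------------------------------------------------------------------------

def exam_covariate_truth(
    cfg: SimConfig,
    bats: list[BatRecord],
    masses: list[MassRecord],
    dailies=None,
) -> pd.DataFrame:
    """Complete (latent-truth) exam-day covariates for every bat.

    Mass comes from the daily records; ΔT comes from the daily
    summaries where logger coverage exists and is drawn from the
    treatment-typical distribution otherwise.  Columns ``mass_c`` /
    ``delta_t_c`` are centred on the pooled means; ``dt_covered`` marks
    exam days with actual logger-derived ΔT.
    """
    mass_map = {(m.bat_id, m.day): m.mass_g for m in masses}
    dt_map = {(d.bat_id, d.day): d.delta_t_c for d in (dailies or [])}
    rng = _rng(cfg.seed, "exam_dt")
    rows = []
    for b in bats:
        for day in cfg.exam_days:
            dt = dt_map.get((b.bat_id, day))
            covered = dt is not None
            if not covered:
                dt = float(rng.normal(cfg.dt_exam_mean, cfg.dt_exam_sd))
            rows.append(
                {"bat_id": b.bat_id, "day": day,
                 "treatment": b.treatment.value if b.treatment else "",
                 "mass_g": mass_map[(b.bat_id, day)], "delta_t": dt,
                 "dt_covered": covered}
            )
    df = pd.DataFrame(rows)
    df["mass_c"] = df["mass_g"] - df["mass_g"].mean()
    # centre ΔT on the logger-covered values only: that is the centering
    # a downstream analysis of the written study can compute, so the
    # generated classes and the refit share one covariate scale
    dt_ref = df.loc[df["dt_covered"], "delta_t"] if df["dt_covered"].any() else df["delta_t"]
    df["delta_t_c"] = df["delta_t"] - dt_ref.mean()
    return df


def simulate_maturation(
    cfg: SimConfig,
    bats: list[BatRecord],
    exam_cov: pd.DataFrame,
    return_latent: bool = False,
):
    """Draw ordinal maturation trajectories from the transition-time model.

    For each bat a random intercept u ~ N(0, sigma_u); each exam adds
    eps ~ N(0, sigma_eps) and the emitted class counts the effective
    thresholds crossed by day + u + eps — exactly the observation rule
    the model's likelihood integrates over.  Monotone post-processing
    (class never decreases across a bat's exams; spermatogenesis stages
    are sequential) is on by default and can be disabled for
    likelihood-consistency checks.
    """
    truth = cfg.truth
    tau = np.asarray(truth.tau, float)
    d = np.asarray(truth.d, float)
    gm = np.asarray(truth.gamma_mass, float)
    gd = np.asarray(truth.gamma_dt, float)
    rng = _rng(cfg.seed, "maturation")
    u_map = {b.bat_id: float(rng.normal(0.0, truth.sigma_u)) for b in bats}
    treat_map = {b.bat_id: b.treatment for b in bats}
    obs: list[MaturationObs] = []
    for bat_id, g in exam_cov.groupby("bat_id", sort=True):
        g = g.sort_values("day")
        tr = treat_map[bat_id]
        gi = 1 if tr is Treatment.T10 else 0
        u = u_map[bat_id]
        classes = []
        for row in g.itertuples(index=False):
            T = np.concatenate([
                [truth.first_transition_day],
                tau + d * gi + gm[gi] * row.mass_c + gd[gi] * row.delta_t_c,
            ])
            z = row.day + u + rng.normal(0.0, truth.sigma_eps)
            classes.append(int(np.sum(z >= T)))
        if cfg.monotone_classes:
            classes = np.maximum.accumulate(classes).tolist()
        obs.extend(MaturationObs(bat_id, int(day), c)
                   for day, c in zip(g["day"], classes))
    if return_latent:
        return obs, u_map
    return obs


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

def simulate_study(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete synthetic study.

    Produces cohort/temps/masses/obs CSVs parseable by the package's
    readers, plus ``truth.json`` with the generating parameters.  The
    exam-day ΔT values used to generate maturation classes come from
    the package's own torpor/daily-summary pipeline where the simulated
    logger was attached, so the generated data and the downstream
    analysis share one definition of ΔT.  Existing output files raise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv" for k in ("cohort", "temps", "masses", "obs")}
    paths["truth"] = outdir / "truth.json"
    clashes = [p for p in paths.values() if p.exists()]
    if clashes:
        raise FileExistsError(f"output file(s) already exist: {clashes}")

    study_cfg = cfg.study_config()
    bats, masses = simulate_cohort(cfg)
    series = [simulate_tsk(cfg, b) for b in bats]

    thresholds = per_individual_thresholds(bats, masses, study_cfg)
    dailies = []
    for s in series:
        masked = apply_exclusions(s, study_cfg.exclusion_windows)
        events = detect_torpor_events(masked, thresholds[s.bat_id],
                                      study_cfg.torpor_min_run)
        dailies.extend(daily_summaries(masked, events, study_cfg.day0,
                                       study_cfg.min_daily_readings))

    exam_cov = exam_covariate_truth(cfg, bats, masses, dailies)
    obs = simulate_maturation(cfg, bats, exam_cov)

    hio.write_cohort(bats, paths["cohort"])
    hio.write_temp_series(series, paths["temps"])
    hio.write_masses(masses, paths["masses"])
    hio.write_maturation(obs, paths["obs"])
    paths["truth"].write_text(json.dumps(truth_to_dict(cfg.truth), indent=2))
    return paths


def truth_to_dict(truth: TrueParameters) -> dict:
    d = dataclasses.asdict(truth)
    d["tau"] = list(d["tau"])
    d["d"] = list(d["d"])
    d["gamma_mass"] = [list(r) for r in d["gamma_mass"]]
    d["gamma_dt"] = [list(r) for r in d["gamma_dt"]]
    return d


def truth_from_json(path: str | Path) -> TrueParameters:
    d = json.loads(Path(path).read_text())
    d["tau"] = tuple(d["tau"])
    d["d"] = tuple(d["d"])
    d["gamma_mass"] = tuple(tuple(r) for r in d["gamma_mass"])
    d["gamma_dt"] = tuple(tuple(r) for r in d["gamma_dt"])
    return TrueParameters(**d)
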