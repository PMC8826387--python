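"""Torpor detection and daily thermoregulation summaries.

A bat counts as torpid when its skin temperature falls below an
individual onset threshold for at least ``min_run`` consecutive 10-min
readings.  The threshold is the linear body-mass / ambient-temperature
rule (already including the 1-SE buffer on its left-hand side):

    threshold(°C) = 0.041 · Mb(g) + 0.04 · Ta(°C) + 31.083

Daily summaries report mean skin temperature, ΔT = mean(tsk − ta) over
included readings (the thermoregulation-effort proxy), and torpor event
counts/durations.  ΔT is signed: logger noise can push tsk below ta and
clamping would bias the energetic interpretation of the mean.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from collections import defaultdict

import numpy as np

from .config import StudyConfig
from .types import (
    READINGS_PER_HOUR,
    BatRecord,
    DailySummary,
    MassRecord,
    TempSeries,
    TorporEvent,
    ValidationError,
    parse_clock,
)

log = logging.getLogger("heterostat")

# coefficients of the published torpor-onset rule
_MASS_COEF = 0.041
_TA_COEF = 0.04
_INTERCEPT = 31.083


def torpor_onset_threshold(mass_g: float, ta_c: float) -> float:
    """Individual torpor-onset skin temperature in °C.

    Linear in body mass and ambient temperature; deterministic.
    """
    if not mass_g > 0:
        raise ValidationError(f"mass_g must be > 0, got {mass_g}")
    return _MASS_COEF * mass_g + _TA_COEF * ta_c + _INTERCEPT


def per_individual_thresholds(
    bats: list[BatRecord],
    masses: list[MassRecord],
    config: StudyConfig,
) -> dict[str, float]:
    """One torpor-onset threshold per bat.

    Uses the bat's mean mass over the deployment (one stable threshold
    per individual) and its treatment's ambient temperature.  With
    ``config.daily_mass_thresholds`` daily thresholds should be computed
    instead via :func:`torpor_onset_threshold` on daily masses; this
    function always returns the per-individual constant.
    """
    by_bat: dict[str, list[float]] = defaultdict(list)
    for m in masses:
        by_bat[m.bat_id].append(m.mass_g)
    out = {}
    for bat in bats:
        if bat.bat_id not in by_bat:
            raise ValidationError(f"no mass record for bat {bat.bat_id}")
        if bat.treatment is None:
            raise ValidationError(f"bat {bat.bat_id} has no treatment assigned")
        mean_mass = float(np.mean(by_bat[bat.bat_id]))
        out[bat.bat_id] = torpor_onset_threshold(mean_mass, config.ta_for(bat.treatment))
    return out


def _minutes_of_day(t: np.ndarray) -> np.ndarray:
    return ((t - t.astype("datetime64[D]")) / np.timedelta64(1, "m")).astype(float)


def apply_exclusions(
    series: TempSeries, windows: list[tuple[str, str]]
) -> TempSeries:
    """Mask readings inside daily clock windows; never deletes readings.

    Windows are half-open ``[start, end)`` clock intervals; a window with
    end < start wraps past midnight.  Overlapping windows merge silently.
    """
    included = series.included.copy()
    if windows:
        mod = _minutes_of_day(series.t)
        for w0, w1 in windows:
            s = parse_clock(w0)
            e = parse_clock(w1)
            sm = s.hour * 60 + s.minute
            em = e.hour * 60 + e.minute
            if sm <= em:
                inside = (mod >= sm) & (mod < em)
            else:  # wraps midnight
                inside = (mod >= sm) | (mod < em)
            included &= ~inside
    return TempSeries(series.bat_id, series.t, series.tsk_c, series.ta_c, included)


def detect_torpor_events(
    series: TempSeries, threshold: float, min_run: int = 3
) -> list[TorporEvent]:
    """Maximal runs of consecutive included sub-threshold readings.

    Runs are broken by excluded readings (no information while a bat is
    handled) and, implicitly, by deployment boundaries since a
    :class:`TempSeries` is gap-free.  Event duration is
    ``n_readings × 10 min``: a single reading contributes one sampling
    interval, which stays unambiguous under gaps.
    """
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if min_run < 1:
        raise ValidationError("min_run must be >= 1")
    if len(series) == 0:
        return []
    below = series.included & (series.tsk_c < threshold)
    # run boundaries of the boolean mask
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    events = []
    for a, b in zip(starts, ends):
        n = int(b - a)
        if n < min_run:
            continue
        events.append(
            TorporEvent(
                bat_id=series.bat_id,
                start=series.t[a],
                end=series.t[b - 1],
                n_readings=n,
                duration_h=n / READINGS_PER_HOUR,
                min_tsk_c=float(series.tsk_c[a:b].min()),
            )
        )
    return events


def _day_index(t: np.ndarray, day0: _dt.date) -> np.ndarray:
    d0 = np.datetime64(day0.isoformat(), "D")
    return (t.astype("datetime64[D]") - d0).astype(int)


def daily_summaries(
    series: TempSeries | list[TempSeries],
    events: list[TorporEvent],
    day0: _dt.date,
    min_included: int = 1,
) -> list[DailySummary]:
    """One summary per calendar day with enough included readings.

    Day boundaries are at midnight clock time; a torpor event is
    credited to the day containing its start.  Days with zero included
    readings are omitted with a log line, days below ``min_included``
    silently.
    """
    series_list = [series] if isinstance(series, TempSeries) else list(series)

    # torpor events grouped by (bat, start day)
    ev_count: dict[tuple[str, int], int] = defaultdict(int)
    ev_dur: dict[tuple[str, int], list[float]] = defaultdict(list)
    for e in events:
        key = (e.bat_id, int(_day_index(np.asarray([e.start], "datetime64[ns]"), day0)[0]))
        ev_count[key] += 1
        ev_dur[key].append(e.duration_h)

    acc: dict[tuple[str, int], dict[str, float]] = {}
    for s in series_list:
        days = _day_index(s.t, day0)
        for day in np.unique(days):
            sel = days == day
            inc = sel & s.included
            key = (s.bat_id, int(day))
            a = acc.setdefault(key, {"sum_tsk": 0.0, "sum_diff": 0.0, "n": 0})
            a["sum_tsk"] += float(s.tsk_c[inc].sum())
            a["sum_diff"] += float((s.tsk_c[inc] - s.ta_c[inc]).sum())
            a["n"] += int(inc.sum())

    out = []
    for (bat_id, day), a in sorted(acc.items()):
        n = a["n"]
        if n == 0:
            log.info("bat %s day %d: no included readings; day omitted", bat_id, day)
            continue
        if n < min_included:
            continue
        durs = ev_dur.get((bat_id, day), [])
        out.append(
            DailySummary(
                bat_id=bat_id,
                day=day,
                mean_tsk_c=a["sum_tsk"] / n,
                delta_t_c=a["sum_diff"] / n,
                n_torpor_events=ev_count.get((bat_id, day), 0),
                mean_event_duration_h=float(np.mean(durs)) if durs else float("nan"),
                n_included_readings=n,
            )
        )
    return out
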