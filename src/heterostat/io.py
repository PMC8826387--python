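"""CSV readers and writers for the pipeline's interchange formats.

All formats are plain CSV with ISO-8601 timestamps; missing values are
empty fields.  Temperature logger exports are long format
(bat_id, timestamp, tsk_c, ta_c) and are split into gap-free deployments
on read: any gap larger than one sampling interval starts a new
deployment (loggers detach spontaneously).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    SAMPLING_INTERVAL,
    BatRecord,
    DailySummary,
    MassRecord,
    MaturationObs,
    SchemaError,
    TempSeries,
    TorporEvent,
    Treatment,
    ValidationError,
)

log = logging.getLogger("heterostat")

POSTERIOR_COLUMNS = ["parameter", "mean", "sd", "q2.5", "q50", "q97.5", "rhat", "significant"]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_cohort(path: str | Path) -> list[BatRecord]:
    """Read per-bat metadata; rejects unknown treatments and duplicate ids."""
    df = pd.read_csv(path, dtype={"bat_id": str, "group_id": str})
    _require(df, ["bat_id", "forearm_mm", "capture_mass_g", "treatment", "group_id"], path)
    dupes = df["bat_id"][df["bat_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicated bat_id(s) {sorted(set(dupes))}")
    out = []
    for row in df.itertuples(index=False):
        tr = None if pd.isna(row.treatment) or row.treatment == "" else Treatment.parse(str(row.treatment))
        gid = "" if pd.isna(row.group_id) else str(row.group_id)
        out.append(BatRecord(str(row.bat_id), float(row.forearm_mm),
                             float(row.capture_mass_g), tr, gid))
    return out


def write_cohort(bats: list[BatRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bat_id": [b.bat_id for b in bats],
            "forearm_mm": [b.forearm_mm for b in bats],
            "capture_mass_g": [b.capture_mass_g for b in bats],
            "treatment": [b.treatment.value if b.treatment else "" for b in bats],
            "group_id": [b.group_id for b in bats],
        }
    ).to_csv(path, index=False)


def read_temp_series(path: str | Path) -> list[TempSeries]:
    """Read long-format logger CSV and split into per-bat deployments.

    Within a bat, timestamps must be strictly increasing; a gap larger
    than one sampling interval (10 min) starts a new deployment.
    """
    df = pd.read_csv(path, dtype={"bat_id": str})
    _require(df, ["bat_id", "timestamp", "tsk_c", "ta_c"], path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    series: list[TempSeries] = []
    for bat_id, g in df.groupby("bat_id", sort=True):
        t = g["timestamp"].to_numpy(dtype="datetime64[ns]")
        if len(t) > 1 and np.any(np.diff(t) <= np.timedelta64(0, "ns")):
            raise ValidationError(f"{path}: non-monotone timestamps for bat {bat_id}")
        gaps = np.flatnonzero(np.diff(t) > SAMPLING_INTERVAL)
        bounds = np.concatenate([[0], gaps + 1, [len(t)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            series.append(
                TempSeries(
                    bat_id=str(bat_id),
                    t=t[a:b],
                    tsk_c=g["tsk_c"].to_numpy(float)[a:b],
                    ta_c=g["ta_c"].to_numpy(float)[a:b],
                )
            )
        n_dep = len(bounds) - 1
        if n_dep > 1:
            log.info("bat %s: %d logger deployments (gaps found)", bat_id, n_dep)
    return series


def write_temp_series(series: list[TempSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"bat_id": s.bat_id, "timestamp": s.t, "tsk_c": s.tsk_c, "ta_c": s.ta_c}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_masses(path: str | Path) -> list[MassRecord]:
    df = pd.read_csv(path, dtype={"bat_id": str})
    _require(df, ["bat_id", "day", "mass_g"], path)
    if df.duplicated(["bat_id", "day"]).any():
        raise ValidationError(f"{path}: duplicate (bat_id, day) mass records")
    return [
        MassRecord(str(r.bat_id), int(r.day), float(r.mass_g))
        for r in df.itertuples(index=False)
    ]


def write_masses(masses: list[MassRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bat_id": [m.bat_id for m in masses],
            "day": [m.day for m in masses],
            "mass_g": [m.mass_g for m in masses],
        }
    ).to_csv(path, index=False)


def read_maturation(path: str | Path) -> list[MaturationObs]:
    """Read ordinal examination records; warns when exam spacing strays
    far from the nominal ten days."""
    df = pd.read_csv(path, dtype={"bat_id": str})
    _require(df, ["bat_id", "day", "cls"], path)
    obs = [
        MaturationObs(str(r.bat_id), int(r.day), int(r.cls))
        for r in df.itertuples(index=False)
    ]
    for bat_id, g in df.groupby("bat_id"):
        days = np.sort(g["day"].to_numpy(int))
        if len(days) > 1 and (np.diff(days).max() > 20 or np.diff(days).min() < 5):
            log.warning("bat %s: exam spacing %s days departs from the nominal 10",
                        bat_id, np.diff(days).tolist())
    return obs


def write_maturation(obs: list[MaturationObs], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bat_id": [o.bat_id for o in obs],
            "day": [o.day for o in obs],
            "cls": [o.cls for o in obs],
        }
    ).to_csv(path, index=False)


def write_torpor_events(events: list[TorporEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bat_id": [e.bat_id for e in events],
            "start": [np.datetime_as_string(np.datetime64(e.start, "s")) for e in events],
            "end": [np.datetime_as_string(np.datetime64(e.end, "s")) for e in events],
            "n_readings": [e.n_readings for e in events],
            "duration_h": [e.duration_h for e in events],
            "min_tsk_c": [e.min_tsk_c for e in events],
        }
    ).to_csv(path, index=False)


def read_torpor_events(path: str | Path) -> list[TorporEvent]:
    df = pd.read_csv(path, dtype={"bat_id": str})
    _require(df, ["bat_id", "start", "end", "n_readings", "duration_h", "min_tsk_c"], path)
    return [
        TorporEvent(
            str(r.bat_id),
            np.datetime64(r.start, "ns"),
            np.datetime64(r.end, "ns"),
            int(r.n_readings),
            float(r.duration_h),
            float(r.min_tsk_c),
        )
        for r in df.itertuples(index=False)
    ]


def write_daily_summaries(dailies: list[DailySummary], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bat_id": [d.bat_id for d in dailies],
            "day": [d.day for d in dailies],
            "mean_tsk_c": [d.mean_tsk_c for d in dailies],
            "delta_t_c": [d.delta_t_c for d in dailies],
            "n_torpor_events": [d.n_torpor_events for d in dailies],
            "mean_event_duration_h": [d.mean_event_duration_h for d in dailies],
            "n_included_readings": [d.n_included_readings for d in dailies],
        }
    ).to_csv(path, index=False)


def read_daily_summaries(path: str | Path) -> list[DailySummary]:
    df = pd.read_csv(path, dtype={"bat_id": str})
    _require(
        df,
        ["bat_id", "day", "mean_tsk_c", "delta_t_c", "n_torpor_events",
         "mean_event_duration_h", "n_included_readings"],
        path,
    )
    return [
        DailySummary(
            str(r.bat_id), int(r.day), float(r.mean_tsk_c), float(r.delta_t_c),
            int(r.n_torpor_events),
            float(r.mean_event_duration_h) if pd.notna(r.mean_event_duration_h) else float("nan"),
            int(r.n_included_readings),
        )
        for r in df.itertuples(index=False)
    ]


def write_posterior_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a posterior-summary table (one row per reported parameter)."""
    missing = [c for c in POSTERIOR_COLUMNS if c not in summary.columns]
    if missing:
        raise SchemaError(f"posterior summary missing column(s) {missing}")
    summary[POSTERIOR_COLUMNS].to_csv(path, index=False)


def read_posterior_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, POSTERIOR_COLUMNS, path)
    return df
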