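"""Exam-day covariate table and BCI-matched treatment assignment.

The transition-time model consumes, per maturation examination, the
body mass and ΔT recorded on the exam day, centred on their pooled
means.  Values with no matching record stay missing and are imputed
inside the model rather than interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import (
    BatRecord,
    DailySummary,
    MassRecord,
    MaturationObs,
    Treatment,
    ValidationError,
)

log = logging.getLogger("heterostat")

#: days-per-year divisor for the sampler-internal time scale
DAYS_PER_YEAR = 365.0


@dataclass
class ExamTable:
    """Per-examination covariates with their centering constants.

    ``df`` columns: bat_id, day, cls, treatment, group_id, mass_c,
    delta_t_c, mass_missing, delta_t_missing.  Centered columns are NaN
    where the raw value was missing.
    """

    df: pd.DataFrame
    mass_center: float
    delta_t_center: float

    def uncenter(self) -> pd.DataFrame:
        """Recover raw covariate values (inverse of centering)."""
        out = self.df.copy()
        out["mass_g"] = out["mass_c"] + self.mass_center
        out["delta_t"] = out["delta_t_c"] + self.delta_t_center
        return out


def assign_treatments(bats: list[BatRecord], seed: int) -> list[BatRecord]:
    """Split a cohort between T10 and T25 with matched BCI distributions.

    Bats are ranked by body condition index (forearm/mass); each
    consecutive pair is split randomly between the treatments, so the
    per-treatment BCI distributions match to within the within-pair gaps.
    An odd cohort's last bat is assigned randomly with a warning.
    """
    if not bats:
        return []
    rng = np.random.default_rng(seed)
    ranked = sorted(bats, key=lambda b: (-b.bci, b.bat_id))
    out: list[BatRecord] = []
    for i in range(0, len(ranked) - 1, 2):
        first, second = (Treatment.T10, Treatment.T25) if rng.random() < 0.5 else (
            Treatment.T25, Treatment.T10)
        out.append(replace(ranked[i], treatment=first))
        out.append(replace(ranked[i + 1], treatment=second))
    if len(ranked) % 2:
        tr = Treatment.T10 if rng.random() < 0.5 else Treatment.T25
        log.warning("odd cohort size %d: bat %s assigned to %s at random",
                    len(ranked), ranked[-1].bat_id, tr.value)
        out.append(replace(ranked[-1], treatment=tr))
    order = {b.bat_id: i for i, b in enumerate(bats)}
    return sorted(out, key=lambda b: order[b.bat_id])


def build_exam_table(
    obs: list[MaturationObs],
    masses: list[MassRecord],
    dailies: list[DailySummary],
    bats: list[BatRecord],
) -> ExamTable:
    """Join exam-day mass and ΔT onto the examination records.

    A pure join: one output row per observation.  Centering constants
    are the means over the non-missing attached values, pooled across
    treatments.
    """
    bat_map = {b.bat_id: b for b in bats}
    mass_map = {(m.bat_id, m.day): m.mass_g for m in masses}
    dt_map = {(d.bat_id, d.day): d.delta_t_c for d in dailies}
    rows = []
    for o in obs:
        if o.bat_id not in bat_map:
            raise ValidationError(f"maturation observation for unknown bat {o.bat_id}")
        b = bat_map[o.bat_id]
        rows.append(
            {
                "bat_id": o.bat_id,
                "day": o.day,
                "cls": o.cls,
                "treatment": b.treatment.value if b.treatment else "",
                "group_id": b.group_id,
                "mass_raw": mass_map.get((o.bat_id, o.day), np.nan),
                "delta_t_raw": dt_map.get((o.bat_id, o.day), np.nan),
            }
        )
    df = pd.DataFrame(rows)
    mass_center = float(df["mass_raw"].mean()) if df["mass_raw"].notna().any() else 0.0
    dt_center = float(df["delta_t_raw"].mean()) if df["delta_t_raw"].notna().any() else 0.0
    df["mass_c"] = df["mass_raw"] - mass_center
    df["delta_t_c"] = df["delta_t_raw"] - dt_center
    df["mass_missing"] = df["mass_raw"].isna()
    df["delta_t_missing"] = df["delta_t_raw"].isna()
    df = df.drop(columns=["mass_raw", "delta_t_raw"])
    return ExamTable(df=df, mass_center=mass_center, delta_t_center=dt_center)


def scale_time(day):
    """Days-since-capture divided by 365 (sampler-internal scale)."""
    return np.asarray(day, dtype=float) / DAYS_PER_YEAR if np.ndim(day) else float(day) / DAYS_PER_YEAR


def write_exam_table(table: ExamTable, path) -> None:
    df = table.df.copy()
    df.attrs = {}
    df.insert(0, "mass_center", table.mass_center)
    df.insert(1, "delta_t_center", table.delta_t_center)
    df.to_csv(path, index=False)


def read_exam_table(path) -> ExamTable:
    df = pd.read_csv(path, dtype={"bat_id": str, "group_id": str})
    mass_center = float(df.pop("mass_center").iloc[0])
    dt_center = float(df.pop("delta_t_center").iloc[0])
    df["group_id"] = df["group_id"].fillna("")
    df["mass_missing"] = df["mass_c"].isna()
    df["delta_t_missing"] = df["delta_t_c"].isna()
    return ExamTable(df=df, mass_center=mass_center, delta_t_center=dt_center)
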