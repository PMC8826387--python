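"""Domain types shared across the pipeline.

The study design these types describe: male heterothermic bats are held
under one of two constant ambient-temperature treatments (10 °C or 25 °C),
carry skin-temperature loggers sampling every 10 minutes at 0.5 °C
resolution, are weighed daily, and are staged for seasonal sexual
maturation on an ordinal 0–4 scale roughly every ten days.  Day 0 is the
day of capture; the temperature treatment starts on day 10.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: logger sampling interval
SAMPLING_INTERVAL = np.timedelta64(10, "m")

#: readings per hour at the 10-minute sampling interval
READINGS_PER_HOUR = 6

#: logger temperature resolution in °C
TSK_RESOLUTION_C = 0.5

#: ordinal maturation classes (0 = immature … 4 = regressed testes,
#: filled cauda epididymis)
N_MATURATION_CLASSES = 5


class SchemaError(ValueError):
    """A required column or field is absent from an input file."""


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class StateError(RuntimeError):
    """An operation was called before its prerequisites were computed."""


class Treatment(str, Enum):
    """Ambient-temperature treatment arm."""

    T10 = "T10"
    T25 = "T25"

    @classmethod
    def parse(cls, token: str) -> "Treatment":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(
                f"unknown treatment token {token!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


@dataclass(frozen=True)
class BatRecord:
    """Per-individual metadata captured at intake."""

    bat_id: str
    forearm_mm: float
    capture_mass_g: float
    treatment: Treatment | None
    group_id: str = ""

    def __post_init__(self) -> None:
        if not self.bat_id:
            raise ValidationError("bat_id must be non-empty")
        if not self.forearm_mm > 0:
            raise ValidationError(f"{self.bat_id}: forearm_mm must be > 0")
        if not self.capture_mass_g > 0:
            raise ValidationError(f"{self.bat_id}: capture_mass_g must be > 0")

    @property
    def bci(self) -> float:
        """Body condition index, forearm length / capture mass (mm/g)."""
        return self.forearm_mm / self.capture_mass_g


@dataclass
class TempSeries:
    """One logger deployment: a gap-free 10-minute grid of readings.

    ``included`` marks readings usable for analysis; exclusion windows
    (handling, flight) flip entries to False but never delete readings.
    """

    bat_id: str
    t: np.ndarray  # datetime64[ns], strictly increasing, 10-min spacing
    tsk_c: np.ndarray
    ta_c: np.ndarray
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype="datetime64[ns]")
        self.tsk_c = np.asarray(self.tsk_c, dtype=float)
        self.ta_c = np.asarray(self.ta_c, dtype=float)
        n = len(self.t)
        if self.included is None:
            self.included = np.ones(n, dtype=bool)
        self.included = np.asarray(self.included, dtype=bool)
        if not (len(self.tsk_c) == len(self.ta_c) == len(self.included) == n):
            raise ValidationError(f"{self.bat_id}: field lengths differ")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= np.timedelta64(0, "ns")):
                raise ValidationError(
                    f"{self.bat_id}: timestamps must be strictly increasing"
                )
            if np.any(dt != SAMPLING_INTERVAL):
                raise ValidationError(
                    f"{self.bat_id}: readings within a deployment must be "
                    f"{SAMPLING_INTERVAL} apart"
                )
        off = np.abs(self.tsk_c / TSK_RESOLUTION_C
                     - np.round(self.tsk_c / TSK_RESOLUTION_C))
        if np.any(off > 1e-6):
            warnings.warn(
                f"{self.bat_id}: {int(np.sum(off > 1e-6))} tsk reading(s) are "
                f"not multiples of {TSK_RESOLUTION_C} °C; values kept",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class MassRecord:
    """One evening body-mass measurement."""

    bat_id: str
    day: int
    mass_g: float

    def __post_init__(self) -> None:
        if not self.mass_g > 0:
            raise ValidationError(f"{self.bat_id} day {self.day}: mass_g must be > 0")


@dataclass(frozen=True)
class MaturationObs:
    """One ordinal maturation-stage examination (class 0–4)."""

    bat_id: str
    day: int
    cls: int

    def __post_init__(self) -> None:
        if self.cls not in range(N_MATURATION_CLASSES):
            raise ValidationError(
                f"{self.bat_id} day {self.day}: class {self.cls} outside 0–"
                f"{N_MATURATION_CLASSES - 1}"
            )


@dataclass(frozen=True)
class TorporEvent:
    """A maximal run of >= min_run consecutive sub-threshold readings."""

    bat_id: str
    start: np.datetime64
    end: np.datetime64
    n_readings: int
    duration_h: float
    min_tsk_c: float


@dataclass(frozen=True)
class DailySummary:
    """Per-bat, per-day thermoregulation summary.

    ``delta_t_c`` is the mean of (tsk − ta) over included readings: the
    thermoregulation-effort proxy ΔT.  ``mean_event_duration_h`` is NaN
    when no torpor event started that day.
    """

    bat_id: str
    day: int
    mean_tsk_c: float
    delta_t_c: float
    n_torpor_events: int
    mean_event_duration_h: float
    n_included_readings: int


def parse_clock(token: str) -> _dt.time:
    """Parse 'HH:MM' into a time of day."""
    try:
        hh, mm = token.split(":")
        return _dt.time(int(hh), int(mm))
    except Exception:
        raise ValidationError(f"bad clock token {token!r}; expected 'HH:MM'") from None
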