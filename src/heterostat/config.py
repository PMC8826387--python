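"""Study-level configuration.

Holds the conventions the raw data do not carry: treatment temperatures,
daily handling/flight exclusion windows (clock intervals), the torpor
run-length rule, the day-0 calendar date, and MCMC sampler settings.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .types import Treatment, ValidationError


@dataclass
class SamplerSettings:
    """Multi-chain MCMC run lengths (iterations counted before thinning)."""

    chains: int = 3
    iterations: int = 50_000
    burn_in: int = 20_000
    thin: int = 3

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError("need >= 2 chains for the R-hat diagnostic")
        if not 0 <= self.burn_in < self.iterations:
            raise ValidationError("require 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class StudyConfig:
    treatment_ta: dict[str, float] = field(
        default_factory=lambda: {"T10": 10.0, "T25": 25.0}
    )
    #: daily clock intervals during which readings are excluded
    #: (evening handling for feeding/weighing by default)
    exclusion_windows: list[tuple[str, str]] = field(
        default_factory=lambda: [("18:00", "19:00")]
    )
    torpor_min_run: int = 3
    #: calendar date of capture; all day indices count from it
    day0: _dt.date = _dt.date(2017, 6, 14)
    #: minimum included readings for a day to be summarised
    min_daily_readings: int = 6
    #: use each day's own mass for the torpor threshold instead of the
    #: bat's mean deployment mass
    daily_mass_thresholds: bool = False
    seed: int = 0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self) -> None:
        if self.torpor_min_run < 1:
            raise ValidationError("torpor_min_run must be >= 1")
        if isinstance(self.day0, str):
            self.day0 = _dt.date.fromisoformat(self.day0)
        if isinstance(self.sampler, dict):
            self.sampler = SamplerSettings(**self.sampler)

    def ta_for(self, treatment: Treatment | str) -> float:
        key = treatment.value if isinstance(treatment, Treatment) else treatment
        try:
            return self.treatment_ta[key]
        except KeyError:
            raise ValidationError(f"no ambient temperature for treatment {key!r}") from None

    # -- serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["day0"] = self.day0.isoformat()
        d["exclusion_windows"] = [list(w) for w in self.exclusion_windows]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "exclusion_windows" in d:
            d["exclusion_windows"] = [tuple(w) for w in d["exclusion_windows"]]
        return cls(**d)
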