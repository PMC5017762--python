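"""Domain types for risk-chart recalibration.

The calibration combines three ingredients per sex and 5-year age band:

* observed cause-specific mortality rates (CVD vs non-CVD deaths over
  population person-years) — the baseline hazard,
* population mean risk-factor levels (systolic blood pressure, total
  cholesterol or TC/HDL-C ratio, smoking prevalence) — the reference
  point of the relative risks,
* log hazard ratios for the risk factors — the relative-risk component,
  supplied as configuration (they come from an external pooled-cohort
  analysis and are not re-estimated here).

All tables are keyed by ``(sex, band_start)`` where ``sex`` is
``"female"`` or ``"male"`` and ``band_start`` is a multiple of 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

from .errors import ConfigurationError, CoverageError, ValidationError

SEXES = ("female", "male")

#: ICD-10 codes counted as CVD death in the default cause definition.
DEFAULT_CAUSE_DEFINITION = "ICD-10 I10-I15, I20-I25, I44-I51, I61-I73"


class CholMeasure(str, Enum):
    """Which cholesterol axis a profile or chart uses."""

    TC = "tc"
    RATIO = "ratio"


@dataclass(frozen=True, order=True)
class AgeBand:
    """A 5-year age band [start, start+5)."""

    start: int
    width: int = 5

    def __post_init__(self) -> None:
        if self.width != 5:
            raise ValidationError(f"age band width must be 5, got {self.width}")
        if self.start % 5 != 0:
            raise ValidationError(f"band start must be a multiple of 5, got {self.start}")

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def midpoint(self) -> float:
        return self.start + self.width / 2.0

    @staticmethod
    def containing(age: float) -> "AgeBand":
        """The band that contains ``age``."""
        return AgeBand(int(math.floor(age / 5.0)) * 5)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start}-{self.end - 1}"


@dataclass(frozen=True)
class MortalityEntry:
    deaths_cvd: float
    deaths_noncvd: float
    population: float

    def __post_init__(self) -> None:
        if self.deaths_cvd < 0 or self.deaths_noncvd < 0:
            raise ValidationError("death counts must be non-negative")
        if self.population <= 0:
            raise ValidationError("population must be strictly positive")
        for d in (self.deaths_cvd, self.deaths_noncvd):
            if d / self.population >= 1.0:
                raise ValidationError(
                    f"annual rate {d / self.population:.3f} >= 1 is not a valid mortality rate"
                )


@dataclass
class MortalityTable:
    """Cause-specific death counts and population by sex x 5-year band.

    ``entries`` maps ``(sex, band_start)`` to a :class:`MortalityEntry`.
    The derived annual rates ``m = deaths / population`` are used directly
    as cause-specific hazards.
    """

    entries: dict[tuple[str, int], MortalityEntry]
    cause_definition: str = DEFAULT_CAUSE_DEFINITION

    def __post_init__(self) -> None:
        for sex, start in self.entries:
            if sex not in SEXES:
                raise ValidationError(f"unknown sex {sex!r}")
            AgeBand(start)  # validates multiple-of-5
        for sex in SEXES:
            if not any(s == sex for s, _ in self.entries):
                raise ValidationError(f"mortality table missing sex {sex!r}")

    def bands(self, sex: str) -> list[AgeBand]:
        return sorted(AgeBand(s) for sx, s in self.entries if sx == sex)

    def entry(self, sex: str, band: AgeBand) -> MortalityEntry:
        try:
            return self.entries[(sex, band.start)]
        except KeyError:
            raise CoverageError(
                f"mortality table has no entry for sex={sex!r}, band {band}"
            ) from None

    def require_coverage(self, sex: str, age_lo: float, age_hi: float) -> None:
        """Raise :class:`CoverageError` naming the first band missing on [age_lo, age_hi)."""
        start = int(math.floor(age_lo / 5.0)) * 5
        while start < age_hi:
            if (sex, start) not in self.entries:
                raise CoverageError(
                    f"mortality table does not cover band {AgeBand(start)} for sex={sex!r}"
                )
            start += 5

    def __iter__(self) -> Iterator[tuple[str, AgeBand, MortalityEntry]]:
        for (sex, start), e in sorted(self.entries.items()):
            yield sex, AgeBand(start), e


@dataclass(frozen=True)
class MeansEntry:
    mean_sbp: float
    mean_tc: float
    mean_ratio: float
    smoking_prev: float

    def __post_init__(self) -> None:
        if not 60 <= self.mean_sbp <= 250:
            raise ValidationError(f"mean SBP {self.mean_sbp} outside [60, 250] mmHg")
        if not 1 <= self.mean_tc <= 15:
            raise ValidationError(f"mean TC {self.mean_tc} outside [1, 15] mmol/L")
        if not 1 <= self.mean_ratio <= 15:
            raise ValidationError(f"mean TC/HDL-C {self.mean_ratio} outside [1, 15]")
        if not 0 <= self.smoking_prev <= 1:
            raise ValidationError(f"smoking prevalence {self.smoking_prev} outside [0, 1]")

    def chol_mean(self, measure: CholMeasure) -> float:
        return self.mean_tc if measure is CholMeasure.TC else self.mean_ratio


@dataclass
class RiskFactorMeans:
    """Population mean risk-factor levels by sex x 5-year band (the x-bar)."""

    entries: dict[tuple[str, int], MeansEntry]

    def entry(self, sex: str, band: AgeBand) -> MeansEntry:
        try:
            return self.entries[(sex, band.start)]
        except KeyError:
            raise CoverageError(
                f"risk-factor means have no entry for sex={sex!r}, band {band}"
            ) from None

    def bands(self, sex: str) -> list[AgeBand]:
        return sorted(AgeBand(s) for sx, s in self.entries if sx == sex)


@dataclass(frozen=True)
class CoefficientSet:
    beta_sbp: float
    beta_tc: float
    beta_ratio: float
    beta_smoke: float

    def __post_init__(self) -> None:
        for name in ("beta_sbp", "beta_tc", "beta_ratio", "beta_smoke"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")

    def beta_chol(self, measure: CholMeasure) -> float:
        return self.beta_tc if measure is CholMeasure.TC else self.beta_ratio


@dataclass
class Coefficients:
    """Log hazard ratios for SBP (per mmHg), cholesterol (per mmol/L for TC,
    per unit for TC/HDL-C) and current smoking (vs non-smoking).

    ``per_sex`` optionally overrides the shared set for one or both sexes.
    ``provenance`` records where the values came from; they are always
    user-supplied configuration, never constants of this package.
    """

    shared: CoefficientSet
    per_sex: Mapping[str, CoefficientSet] = field(default_factory=dict)
    provenance: str = "unspecified"

    def for_sex(self, sex: str) -> CoefficientSet:
        if sex in self.per_sex:
            return self.per_sex[sex]
        if self.shared is None:  # pragma: no cover - defensive
            raise ConfigurationError(f"no coefficients resolvable for sex={sex!r}")
        return self.shared


@dataclass(frozen=True)
class RiskProfile:
    """An individual's risk-factor vector (the x in exp(beta'(x - xbar)))."""

    sex: str
    age: float
    sbp: float
    chol_value: float
    chol_measure: CholMeasure
    smoker: bool

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if not 40 <= self.age <= 65:
            raise ValidationError(f"age {self.age} outside the supported range [40, 65]")
        if self.sbp <= 0 or self.chol_value <= 0:
            raise ValidationError("sbp and chol_value must be strictly positive")


@dataclass(frozen=True)
class BandHazards:
    """Annual cause-specific hazards over one segment of an individual's
    10-year horizon, with the years of exposure spent in that segment."""

    h_cvd: float
    h_noncvd: float
    exposure: float

    def __post_init__(self) -> None:
        if self.h_cvd < 0 or self.h_noncvd < 0:
            raise ValidationError("hazards must be non-negative")
        if not (math.isfinite(self.h_cvd) and math.isfinite(self.h_noncvd)):
            raise ValidationError("hazards must be finite")
        if not 0 < self.exposure <= 5:
            raise ValidationError(f"exposure {self.exposure} outside (0, 5]")
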