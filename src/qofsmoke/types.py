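"""Shared domain types.

The record and estimate types are deliberately plain frozen dataclasses:
they are value objects passed between the IO, estimator and aggregation
layers, and equality comparison must be structural (round-trip tests rely
on it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Optional

from .errors import ConfigError, RecordValidationError

#: role name -> (numerator field, denominator field) on PracticeIndicatorRecord
ROLE_FIELDS: Dict[str, tuple] = {
    "status_general": ("sm07_num", "sm07_den"),
    "cessation_general": ("sm08_num", "sm08_den"),
    "status_chronic": ("sm05_num", "sm05_den"),
    "cessation_chronic": ("sm06_num", "sm06_den"),
}


@dataclass(frozen=True)
class PracticeIndicatorRecord:
    """One practice-year of smoking-indicator counts.

    General-population fields (``sm07_*``, ``sm08_*``) and chronic-condition
    fields (``sm05_*``, ``sm06_*``) are each optional as a pair: years in
    which an indicator was not collected carry ``None``, never zero, so that
    absence stays distinguishable from a legal zero count.
    """

    practice_id: str
    year: str
    postcode: str = ""
    sm07_num: Optional[int] = None  # patients aged 15+ with smoking status recorded
    sm07_den: Optional[int] = None  # eligible patients aged 15+
    sm08_num: Optional[int] = None  # recorded current smokers offered support
    sm08_den: Optional[int] = None  # recorded current smokers
    sm05_num: Optional[int] = None
    sm05_den: Optional[int] = None
    sm06_num: Optional[int] = None
    sm06_den: Optional[int] = None

    @property
    def has_general(self) -> bool:
        return self.sm07_den is not None

    @property
    def has_chronic(self) -> bool:
        return self.sm05_den is not None

    def validate(self) -> None:
        """Raise :class:`RecordValidationError` if any invariant fails."""
        problems = []

        def _pair(num_name, den_name):
            num, den = getattr(self, num_name), getattr(self, den_name)
            if (num is None) != (den is None):
                problems.append(f"{num_name}/{den_name} must be both present or both absent")
                return None
            if num is None:
                return None
            for name, v in ((num_name, num), (den_name, den)):
                if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                    problems.append(f"{name} must be a non-negative integer, got {v!r}")
                    return None
            if num > den:
                problems.append(f"{num_name} ({num}) > {den_name} ({den})")
            return num, den

        g_status = _pair("sm07_num", "sm07_den")
        g_cess = _pair("sm08_num", "sm08_den")
        c_status = _pair("sm05_num", "sm05_den")
        c_cess = _pair("sm06_num", "sm06_den")

        # smokers are a subset of patients with a recorded status
        if g_status and g_cess and self.sm08_den > self.sm07_num:
            problems.append(f"sm08_den ({self.sm08_den}) > sm07_num ({self.sm07_num})")
        if c_status and c_cess and self.sm06_den > self.sm05_num:
            problems.append(f"sm06_den ({self.sm06_den}) > sm05_num ({self.sm05_num})")
        if g_status and c_status and self.sm05_den > self.sm07_den:
            problems.append(f"sm05_den ({self.sm05_den}) > sm07_den ({self.sm07_den})")
        if not (g_status or c_status):
            problems.append("record carries no status indicator at all")
        if g_cess and not g_status:
            problems.append("sm08 present without sm07")
        if c_cess and not c_status:
            problems.append("sm06 present without sm05")

        if problems:
            raise RecordValidationError([(self.practice_id, p) for p in problems])


@dataclass(frozen=True)
class YearCodes:
    """Indicator codes filling the four roles for one financial year."""

    status_general: Optional[str] = None
    cessation_general: Optional[str] = None
    status_chronic: Optional[str] = None
    cessation_chronic: Optional[str] = None

    def validate(self) -> None:
        codes = [c for c in (self.status_general, self.cessation_general,
                             self.status_chronic, self.cessation_chronic) if c is not None]
        if not codes:
            raise ConfigError("year maps no indicator codes")
        if len(set(codes)) != len(codes):
            raise ConfigError(f"indicator codes must be distinct, got {codes}")

    def role_of(self, code: str) -> Optional[str]:
        for f in fields(self):
            if getattr(self, f.name) == code:
                return f.name
        return None


@dataclass
class IndicatorCodeMap:
    """Mapping from financial-year label to that year's indicator codes.

    Year labels are opaque tokens matched exactly; no date arithmetic.
    """

    years: Dict[str, YearCodes] = field(default_factory=dict)

    def __post_init__(self):
        for year, codes in self.years.items():
            codes.validate()

    def codes_for(self, year: str) -> YearCodes:
        try:
            return self.years[year]
        except KeyError:
            raise ConfigError(f"year {year!r} not present in indicator code map") from None

    def role_of(self, year: str, code: str) -> Optional[str]:
        return self.codes_for(year).role_of(code)


@dataclass(frozen=True)
class SurveyAreaEstimate:
    """An area-level survey prevalence estimate with its sample size."""

    district_code: str
    prevalence: float
    sample_size: int

    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise RecordValidationError(
                [(self.district_code, f"prevalence {self.prevalence} outside [0, 1]")])
        if self.sample_size < 1:
            raise RecordValidationError(
                [(self.district_code, f"sample_size {self.sample_size} < 1")])


@dataclass(frozen=True)
class PracticeEstimate:
    """Derived proportions for one practice-year (full precision)."""

    practice_id: str
    year: str
    prevalence_general: Optional[float] = None   # sm08_den / sm07_den
    prevalence_chronic: Optional[float] = None   # sm06_den / sm05_den
    ua_status_general: Optional[float] = None    # sm07_num / sm07_den
    ua_status_chronic: Optional[float] = None    # sm05_num / sm05_den
    ua_cessation_general: Optional[float] = None  # sm08_num / sm08_den
    chronic_share: Optional[float] = None        # sm05_den / sm07_den
    status_denominator: Optional[int] = None     # sm07_den, kept for weighting


@dataclass(frozen=True)
class DistrictAggregate:
    """Pooled counts and derived prevalence for one district."""

    district_code: str
    n_practices: int
    pooled_status_denominator: int
    pooled_smokers: int
    prevalence: float
    census_population_15plus: Optional[int] = None


@dataclass(frozen=True)
class AgreementSummary:
    """Paired-comparison statistics (differences are first minus second)."""

    n_pairs: int
    pearson_r: float
    lin_ccc: float
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of general prevalence on chronic prevalence after outlier removal."""

    slope: float
    intercept: float
    n_used: int
    removed_ids: frozenset
    residual_sd: float


@dataclass(frozen=True)
class PracticeCovariates:
    """Outcome, exposure and named covariates for one practice."""

    practice_id: str
    death_count: int
    exposure: float
    covariates: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.death_count < 0:
            raise RecordValidationError([(self.practice_id, "death_count < 0")])
        if not self.exposure > 0:
            raise RecordValidationError([(self.practice_id, "exposure must be > 0")])
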