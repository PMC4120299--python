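"""Practice-level prevalence estimators.

The central manipulation: the denominator of the cessation-offer indicator
counts recorded current smokers, the denominator of the status-recording
indicator approximates the eligible 15+ population, so their ratio
estimates smoking prevalence. All values are stored as full-precision
proportions; rounding happens only at presentation time.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional

import pandas as pd

from .errors import InvariantError, UndefinedEstimateError
from .types import PracticeEstimate, PracticeIndicatorRecord


def estimate_prevalence(cessation_denominator: int, status_denominator: int) -> float:
    """Smoking prevalence as recorded-smokers / status-recording-eligible.

    This is the primary (status-denominator) estimator. See
    :func:`list_based_prevalence` for the list-size fallback variant.
    """
    if status_denominator <= 0:
        raise UndefinedEstimateError("status denominator must be positive")
    if cessation_denominator < 0:
        raise InvariantError("cessation denominator must be non-negative")
    if cessation_denominator > status_denominator:
        raise InvariantError(
            f"cessation denominator ({cessation_denominator}) exceeds "
            f"status denominator ({status_denominator})")
    return cessation_denominator / status_denominator


def underlying_achievement(numerator: int, denominator: int) -> float:
    """Underlying achievement: numerator / denominator, before payment thresholds."""
    if denominator <= 0:
        raise UndefinedEstimateError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise InvariantError(f"numerator {numerator} outside [0, {denominator}]")
    return numerator / denominator


def list_based_prevalence(cessation_denominator: int,
                          registered_population_15plus: int) -> float:
    """Prevalence with the registered 15+ population as denominator.

    Fallback once the general status-recording indicator is retired
    (2014/15 onwards): only recorded-smoker counts remain published. Biased
    downward relative to :func:`estimate_prevalence` whenever recording is
    incomplete, because unrecorded patients stay in the denominator.
    """
    if registered_population_15plus <= 0:
        raise UndefinedEstimateError("registered population must be positive")
    if cessation_denominator < 0:
        raise InvariantError("cessation denominator must be non-negative")
    return cessation_denominator / registered_population_15plus


def derive_practice_estimate(record: PracticeIndicatorRecord) -> PracticeEstimate:
    """Compute every derivable proportion for one validated practice-year.

    Chronic fields come out absent (``None``) exactly when the source
    chronic indicators are absent; likewise for the general fields in years
    where only chronic indicators were collected.
    """
    record.validate()
    prev_g = ua_g = ua_cess_g = None
    if record.has_general:
        if record.sm07_den == 0:
            raise UndefinedEstimateError(
                f"practice {record.practice_id} ({record.year}): sm07_den is zero")
        prev_g = estimate_prevalence(record.sm08_den, record.sm07_den)
        ua_g = underlying_achievement(record.sm07_num, record.sm07_den)
        ua_cess_g = (underlying_achievement(record.sm08_num, record.sm08_den)
                     if record.sm08_den else None)
    prev_c = ua_c = share = None
    if record.has_chronic:
        if record.sm05_den > 0:
            prev_c = (estimate_prevalence(record.sm06_den, record.sm05_den)
                      if record.sm06_den is not None else None)
            ua_c = underlying_achievement(record.sm05_num, record.sm05_den)
        if record.has_general and record.sm07_den > 0:
            share = record.sm05_den / record.sm07_den
    return PracticeEstimate(
        practice_id=record.practice_id,
        year=record.year,
        prevalence_general=prev_g,
        prevalence_chronic=prev_c,
        ua_status_general=ua_g,
        ua_status_chronic=ua_c,
        ua_cessation_general=ua_cess_g,
        chronic_share=share,
        status_denominator=record.sm07_den,
    )


def derive_estimates(records: Iterable[PracticeIndicatorRecord]) -> List[PracticeEstimate]:
    return [derive_practice_estimate(r) for r in records]


def percent_value(proportion: float, decimals: int = 1) -> float:
    """Proportion -> percentage rounded half-up to ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(repr(proportion)) * 100).quantize(q, rounding=ROUND_HALF_UP))


def percent_string(proportion: float, decimals: int = 1, display_decimals: int = None) -> str:
    """Render a proportion as a percentage string.

    ``decimals`` controls the rounding precision; ``display_decimals`` pads
    with trailing zeros (published tables print one-decimal values at two
    decimal places, e.g. ``92.70%``).
    """
    value = percent_value(proportion, decimals)
    shown = decimals if display_decimals is None else display_decimals
    return f"{value:.{shown}f}%"


def estimates_to_frame(estimates: Iterable[PracticeEstimate]) -> pd.DataFrame:
    """Tabulate estimates for CSV output (proportions, not percentages)."""
    rows = [{
        "practice_id": e.practice_id,
        "year": e.year,
        "prevalence_general": e.prevalence_general,
        "prevalence_chronic": e.prevalence_chronic,
        "ua_status_general": e.ua_status_general,
        "ua_status_chronic": e.ua_status_chronic,
        "ua_cessation_general": e.ua_cessation_general,
        "chronic_share": e.chronic_share,
        "status_denominator": e.status_denominator,
    } for e in estimates]
    return pd.DataFrame(rows)
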