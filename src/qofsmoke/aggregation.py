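"""Linking practices to districts and aggregating estimates to area level.

Default aggregation pools counts (sum of numerators over sum of
denominators) rather than averaging practice prevalences: a district's
estimate should weight each practice by the population it actually
covers. The mean variants are retained for sensitivity checks; the
denominator-weighted mean is algebraically identical to pooling.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .errors import LinkageError, UndefinedEstimateError
from .qof_io import normalize_postcode
from .types import DistrictAggregate, PracticeEstimate, PracticeIndicatorRecord

logger = logging.getLogger(__name__)

TOTAL_CODE = "TOTAL"


def assign_districts(
    records: Sequence[PracticeIndicatorRecord],
    lookup: Mapping[str, str],
) -> Dict[str, str]:
    """Map each practice to a district via its postcode.

    Whole-practice assignment: the practice postcode decides the district,
    with no apportionment of the list across boundaries. Every unmatched
    postcode is collected and reported together — silent dropping would
    bias the area totals.
    """
    assignment: Dict[str, str] = {}
    unmatched: Dict[str, str] = {}
    for rec in records:
        if rec.practice_id in assignment or rec.practice_id in unmatched:
            continue
        pc = normalize_postcode(rec.postcode) if rec.postcode else ""
        if pc in lookup:
            assignment[rec.practice_id] = lookup[pc]
        else:
            unmatched[rec.practice_id] = pc
    if unmatched:
        raise LinkageError(unmatched)
    return assignment


def aggregate_pooled(
    records: Sequence[PracticeIndicatorRecord],
    assignment: Mapping[str, str],
    population: str = "general",
    include_total: bool = True,
    census: Optional[Mapping[str, int]] = None,
) -> List[DistrictAggregate]:
    """Pooled-count aggregation: per district, sum smokers and eligible then divide.

    ``population`` selects the general (``sm08_den / sm07_den``) or chronic
    (``sm06_den / sm05_den``) indicator pair. A grand-total aggregate over
    every assigned practice is appended under district code ``TOTAL`` when
    ``include_total`` is set; it uses the same pooled rule.
    """
    if population == "general":
        num_field, den_field = "sm08_den", "sm07_den"
    elif population == "chronic":
        num_field, den_field = "sm06_den", "sm05_den"
    else:
        raise ValueError(f"unknown population {population!r}")

    sums: Dict[str, List[int]] = {}
    for rec in records:
        district = assignment[rec.practice_id]
        num, den = getattr(rec, num_field), getattr(rec, den_field)
        if num is None or den is None:
            raise UndefinedEstimateError(
                f"practice {rec.practice_id} ({rec.year}) lacks {population} counts")
        entry = sums.setdefault(district, [0, 0, 0])
        entry[0] += num
        entry[1] += den
        entry[2] += 1

    out = []
    for district in sorted(sums):
        smokers, pooled_den, n = sums[district]
        if pooled_den == 0:
            raise UndefinedEstimateError(f"district {district}: pooled denominator is zero")
        out.append(DistrictAggregate(
            district_code=district,
            n_practices=n,
            pooled_status_denominator=pooled_den,
            pooled_smokers=smokers,
            prevalence=smokers / pooled_den,
            census_population_15plus=census.get(district) if census else None,
        ))
    if include_total and out:
        smokers = sum(a.pooled_smokers for a in out)
        pooled_den = sum(a.pooled_status_denominator for a in out)
        out.append(DistrictAggregate(
            district_code=TOTAL_CODE,
            n_practices=sum(a.n_practices for a in out),
            pooled_status_denominator=pooled_den,
            pooled_smokers=smokers,
            prevalence=smokers / pooled_den,
            census_population_15plus=(sum(census.values()) if census else None),
        ))
    return out


def aggregate_mean(
    estimates: Sequence[PracticeEstimate],
    assignment: Mapping[str, str],
    weights: str = "none",
    include_total: bool = True,
) -> List[DistrictAggregate]:
    """Mean-of-prevalences aggregation (sensitivity variant).

    ``weights='none'`` gives the unweighted mean of practice prevalences;
    ``weights='status_denominator'`` weights by each practice's eligible
    population, which reproduces :func:`aggregate_pooled` exactly.
    """
    if weights not in ("none", "status_denominator"):
        raise ValueError(f"unknown weights {weights!r}")
    groups: Dict[str, List[PracticeEstimate]] = {}
    for est in estimates:
        groups.setdefault(assignment[est.practice_id], []).append(est)

    def _one(code: str, members: Sequence[PracticeEstimate]) -> DistrictAggregate:
        if not members:
            raise UndefinedEstimateError(f"district {code}: no practices")
        for est in members:
            if est.prevalence_general is None or est.status_denominator is None:
                raise UndefinedEstimateError(
                    f"practice {est.practice_id}: missing general prevalence")
        dens = [est.status_denominator for est in members]
        smokers = [round(est.prevalence_general * d) for est, d in zip(members, dens)]
        if weights == "none":
            prevalence = sum(est.prevalence_general for est in members) / len(members)
        else:
            if sum(dens) == 0:
                raise UndefinedEstimateError(f"district {code}: zero total weight")
            prevalence = (sum(est.prevalence_general * d for est, d in zip(members, dens))
                          / sum(dens))
        return DistrictAggregate(
            district_code=code,
            n_practices=len(members),
            pooled_status_denominator=sum(dens),
            pooled_smokers=sum(smokers),
            prevalence=prevalence,
        )

    out = [_one(code, groups[code]) for code in sorted(groups)]
    if include_total and out:
        out.append(_one(TOTAL_CODE, list(estimates)))
    return out


def aggregates_to_frame(aggregates: Iterable[DistrictAggregate]) -> pd.DataFrame:
    rows = [{
        "district_code": a.district_code,
        "n_practices": a.n_practices,
        "pooled_status_denominator": a.pooled_status_denominator,
        "pooled_smokers": a.pooled_smokers,
        "prevalence": a.prevalence,
        "census_population_15plus": a.census_population_15plus,
    } for a in aggregates]
    return pd.DataFrame(rows)
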