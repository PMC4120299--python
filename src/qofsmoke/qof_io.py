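"""Reading, validating and filtering QOF-style indicator extracts.

The canonical on-disk dialect is the *long* format published with QOF
extracts: one row per practice x indicator with NUMERATOR / DENOMINATOR
columns. A convenience wide-format reader is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import (
    ConfigError,
    DuplicateRecordError,
    RecordValidationError,
)
from .types import (
    ROLE_FIELDS,
    IndicatorCodeMap,
    PracticeIndicatorRecord,
    SurveyAreaEstimate,
    YearCodes,
)

logger = logging.getLogger(__name__)

#: Indicator history: which codes fill which role in which financial year.
#: General-population indicators exist only from 2012/13 onwards.
DEFAULT_CODE_MAP = IndicatorCodeMap({
    "2006/07": YearCodes(status_chronic="SM01", cessation_chronic="SM02"),
    "2007/08": YearCodes(status_chronic="SM01", cessation_chronic="SM02"),
    "2008/09": YearCodes(status_chronic="SM03", cessation_chronic="SM04"),
    "2009/10": YearCodes(status_chronic="SM03", cessation_chronic="SM04"),
    "2010/11": YearCodes(status_chronic="SM03", cessation_chronic="SM04"),
    "2011/12": YearCodes(status_chronic="SM03", cessation_chronic="SM04"),
    "2012/13": YearCodes(status_general="SM07", cessation_general="SM08",
                         status_chronic="SM05", cessation_chronic="SM06"),
    "2013/14": YearCodes(status_general="SMOK001", cessation_general="SMOK004",
                         status_chronic="SMOK002", cessation_chronic="SMOK005"),
})

_COLUMN_ALIASES = {
    "practice_id": {"practice_id", "practice", "practice_code"},
    "year": {"year", "financial_year"},
    "postcode": {"postcode", "practice_postcode"},
    "indicator": {"indicator", "indicator_code", "code"},
    "numerator": {"numerator", "num"},
    "denominator": {"denominator", "den"},
}


def synthetic_code_map(years: Sequence[str]) -> IndicatorCodeMap:
    """Code map for synthetic registries: all four roles in every year."""
    return IndicatorCodeMap({
        y: YearCodes(status_general="SM07", cessation_general="SM08",
                     status_chronic="SM05", cessation_chronic="SM06")
        for y in years
    })


def normalize_postcode(postcode: str) -> str:
    """Uppercase and force a single space before the final three characters."""
    compact = "".join(postcode.split()).upper()
    if len(compact) <= 3:
        return compact
    return compact[:-3] + " " + compact[-3:]


def read_code_map(path) -> IndicatorCodeMap:
    """Load an :class:`IndicatorCodeMap` from a YAML file of year -> role: code."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"code map file {path} must contain a mapping")
    years = {}
    for year, roles in raw.items():
        if not isinstance(roles, dict):
            raise ConfigError(f"year {year!r}: expected role -> code mapping")
        unknown = set(roles) - set(ROLE_FIELDS)
        if unknown:
            raise ConfigError(f"year {year!r}: unknown roles {sorted(unknown)}")
        years[str(year)] = YearCodes(**{k: str(v) for k, v in roles.items()})
    return IndicatorCodeMap(years)


def _resolve_columns(df: pd.DataFrame) -> Dict[str, str]:
    lower = {c.lower().strip(): c for c in df.columns}
    out = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                out[canon] = lower[alias]
                break
    return out


def read_indicator_table(
    path,
    code_map: IndicatorCodeMap = DEFAULT_CODE_MAP,
    year: Optional[str] = None,
) -> List[PracticeIndicatorRecord]:
    """Read a long-format indicator extract into validated records.

    Parameters
    ----------
    path
        CSV with columns practice_id, indicator, numerator, denominator and
        optionally year and postcode. If the file has no year column the
        ``year`` argument supplies it.
    code_map
        Maps each year's indicator codes onto the four roles. Rows whose
        code fills no role for their year are ignored (count logged).
    year
        Fallback financial-year label applied to every row.

    Raises
    ------
    DuplicateRecordError
        On repeated (practice, year, indicator) rows.
    RecordValidationError
        On malformed numeric fields or invariant violations; the error
        lists every offending practice and field.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(df)
    for required in ("practice_id", "indicator", "numerator", "denominator"):
        if required not in cols:
            raise ConfigError(f"{path}: missing required column {required!r}")
    if "year" not in cols and year is None:
        raise ConfigError(f"{path}: no year column and no year argument given")

    if df.empty:
        logger.info("read 0 rows from %s", path)
        return []

    work = pd.DataFrame({
        "practice_id": df[cols["practice_id"]].str.strip(),
        "indicator": df[cols["indicator"]].str.strip(),
        "numerator": df[cols["numerator"]].str.strip(),
        "denominator": df[cols["denominator"]].str.strip(),
    })
    work["year"] = df[cols["year"]].str.strip() if "year" in cols else year
    work["postcode"] = df[cols["postcode"]].str.strip() if "postcode" in cols else ""

    dup_mask = work.duplicated(subset=["practice_id", "year", "indicator"], keep=False)
    if dup_mask.any():
        keys = work.loc[dup_mask, ["practice_id", "year", "indicator"]]
        uniq = sorted(set(map(tuple, keys.itertuples(index=False))))
        raise DuplicateRecordError(f"duplicate (practice, year, indicator) rows: {uniq}")

    failures = []
    builders: Dict[tuple, dict] = {}
    n_unknown = 0
    for row in work.itertuples(index=False):
        role = code_map.role_of(row.year, row.indicator)
        if role is None:
            n_unknown += 1
            continue
        try:
            num = int(row.numerator)
            den = int(row.denominator)
        except ValueError:
            failures.append((row.practice_id,
                             f"malformed numeric field for indicator {row.indicator}: "
                             f"numerator={row.numerator!r} denominator={row.denominator!r}"))
            continue
        key = (row.practice_id, row.year)
        b = builders.setdefault(key, {"postcode": ""})
        num_field, den_field = ROLE_FIELDS[role]
        b[num_field], b[den_field] = num, den
        if row.postcode:
            b["postcode"] = normalize_postcode(row.postcode)
    if failures:
        raise RecordValidationError(failures)
    if n_unknown:
        logger.info("ignored %d row(s) with unknown indicator codes", n_unknown)

    records = []
    for (pid, yr), b in sorted(builders.items()):
        rec = PracticeIndicatorRecord(practice_id=pid, year=yr, **b)
        try:
            rec.validate()
        except RecordValidationError as exc:
            failures.extend(exc.failures)
            continue
        records.append(rec)
    if failures:
        raise RecordValidationError(failures)
    logger.info("read %d record(s) from %s", len(records), path)
    return records


def write_indicator_table(
    records: Iterable[PracticeIndicatorRecord],
    path,
    code_map: IndicatorCodeMap = DEFAULT_CODE_MAP,
) -> None:
    """Write records in the long CSV dialect (inverse of :func:`read_indicator_table`)."""
    rows = []
    for rec in records:
        codes = code_map.codes_for(rec.year)
        for role, (num_field, den_field) in ROLE_FIELDS.items():
            num = getattr(rec, num_field)
            if num is None:
                continue
            code = getattr(codes, role)
            if code is None:
                raise ConfigError(
                    f"record {rec.practice_id} {rec.year} has {role} counts but the "
                    f"code map assigns no code to that role")
            rows.append({
                "practice_id": rec.practice_id,
                "year": rec.year,
                "postcode": rec.postcode,
                "indicator": code,
                "numerator": num,
                "denominator": getattr(rec, den_field),
            })
    pd.DataFrame(rows, columns=["practice_id", "year", "postcode",
                                "indicator", "numerator", "denominator"]).to_csv(
        path, index=False)


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the complete-series filter."""

    records: List[PracticeIndicatorRecord]
    excluded: Dict[str, List[str]]  # practice_id -> missing years

    @property
    def retained_practices(self) -> List[str]:
        return sorted({r.practice_id for r in self.records})


def filter_complete_series(
    records: Sequence[PracticeIndicatorRecord],
    required_years: Sequence[str],
) -> FilterResult:
    """Keep only practices with chronic-indicator data for every required year.

    A year counts as present for a practice when a record exists for it with
    all four chronic fields populated. Returns the retained records plus an
    exclusion report of practice id -> sorted missing years. Idempotent.
    """
    if not required_years:
        raise ConfigError("required_years must be non-empty")
    required = list(dict.fromkeys(required_years))
    have: Dict[str, set] = {}
    for rec in records:
        have.setdefault(rec.practice_id, set())
        if rec.has_chronic and rec.sm06_den is not None and rec.year in required:
            have[rec.practice_id].add(rec.year)
    excluded = {
        pid: sorted(set(required) - years)
        for pid, years in have.items()
        if not set(required) <= years
    }
    retained = [r for r in records if r.practice_id not in excluded]
    if excluded:
        logger.info("excluded %d practice(s) lacking complete series", len(excluded))
    return FilterResult(records=retained, excluded=excluded)


def read_postcode_lookup(path) -> Dict[str, str]:
    """Read a two-column (postcode, district code) CSV into a normalized mapping.

    Duplicate postcodes are tolerated when they agree; a conflict is a hard
    error because silent arbitration would misplace a whole practice.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ConfigError(f"{path}: postcode lookup needs two columns")
    lookup: Dict[str, str] = {}
    for row in df.itertuples(index=False):
        pc = normalize_postcode(str(row[0]))
        district = str(row[1]).strip()
        if pc in lookup and lookup[pc] != district:
            raise DuplicateRecordError(
                f"postcode {pc!r} maps to both {lookup[pc]!r} and {district!r}")
        lookup[pc] = district
    logger.info("read %d postcode(s) across %d district(s) from %s",
                len(lookup), len(set(lookup.values())), path)
    return lookup


def read_survey_estimates(path) -> List[SurveyAreaEstimate]:
    """Read area survey estimates (district_code, prevalence, sample_size)."""
    df = pd.read_csv(path)
    required = {"district_code", "prevalence", "sample_size"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    estimates = []
    for row in df.itertuples(index=False):
        est = SurveyAreaEstimate(district_code=str(row.district_code),
                                 prevalence=float(row.prevalence),
                                 sample_size=int(row.sample_size))
        est.validate()
        estimates.append(est)
    return estimates


def read_wide_indicator_table(path, year: str) -> List[PracticeIndicatorRecord]:
    """Convenience reader for a wide per-practice layout.

    Expects columns practice_id and any of sm07_num/sm07_den/... plus an
    optional postcode column; blank cells mean absent.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    if "practice_id" not in lower:
        raise ConfigError(f"{path}: missing practice_id column")
    count_fields = [f for pair in ROLE_FIELDS.values() for f in pair]
    failures, records = [], []
    for row in df.itertuples(index=False):
        data = {c.lower(): getattr(row, c) for c in df.columns}
        kwargs = {}
        for f in count_fields:
            raw = str(data.get(f, "")).strip()
            if raw == "":
                continue
            try:
                kwargs[f] = int(raw)
            except ValueError:
                failures.append((data["practice_id"], f"malformed {f}={raw!r}"))
        pc = str(data.get("postcode", "")).strip()
        rec = PracticeIndicatorRecord(
            practice_id=str(data["practice_id"]).strip(), year=year,
            postcode=normalize_postcode(pc) if pc else "", **kwargs)
        try:
            rec.validate()
        except RecordValidationError as exc:
            failures.extend(exc.failures)
            continue
        records.append(rec)
    if failures:
        raise RecordValidationError(failures)
    return records
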