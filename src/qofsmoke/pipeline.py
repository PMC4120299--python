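"""End-to-end orchestration: simulate -> estimate -> aggregate -> agree -> model.

Stages communicate only through CSV files in the run directory so any
stage can be re-run or audited standalone; the summary report is a single
deterministic JSON document.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import agreement_stats, aggregation, estimators, mortality_model, qof_io
from .errors import ConfigError, QofSmokeError
from .synthetic_data import (
    CohortConfig,
    DEFAULT_YEAR,
    generate_mortality,
    generate_registry,
    generate_survey_estimates,
    write_lookup_csv,
    write_survey_csv,
    write_truth_csv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    When ``registry_csv`` is given the simulate stage is skipped and the
    pipeline runs on that extract (lookup/survey/covariates paths optional;
    missing ones cause the dependent stage to be skipped with a notice).
    """

    outdir: str = "run"
    seed: int = 0
    year: str = DEFAULT_YEAR
    n_practices: int = 215
    n_districts: int = 16
    aggregation_method: str = "pooled"  # pooled | mean | weighted-mean
    outlier_threshold: float = 3.0
    model_covariates: List[str] = field(default_factory=lambda: ["deprivation"])
    model_added_covariate: str = "smoking_pp"
    model_offset: str = "log-exposure"
    registry_csv: Optional[str] = None
    lookup_csv: Optional[str] = None
    survey_csv: Optional[str] = None
    covariates_csv: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write per-stage CSVs plus ``report.json``.

    Returns the report dict. Any stage failure is re-raised wrapped with
    the stage name; outputs of completed stages are left on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(config).items()}, "stages": {}}
    notices: List[str] = []
    stage = "simulate"
    try:
        # --- simulate (or load) -------------------------------------------
        if config.registry_csv is None:
            cohort = CohortConfig(n_practices=config.n_practices,
                                  n_districts=config.n_districts, seed=config.seed)
            records, truth = generate_registry(cohort, year=config.year)
            years = [config.year]
            code_map = qof_io.synthetic_code_map(years)
            registry_path = outdir / "registry.csv"
            qof_io.write_indicator_table(records, registry_path, code_map)
            lookup_path = outdir / "lookup.csv"
            write_lookup_csv(truth, lookup_path)
            survey_path = outdir / "survey.csv"
            size_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
            lo, hi = CohortConfig().survey_sample_size_range
            sizes = {
                code: int(size_rng.integers(lo, hi + 1))
                for code in sorted(truth.district_truth()["district_code"])
            }
            write_survey_csv(generate_survey_estimates(truth, sizes, seed=config.seed + 1),
                             survey_path)
            covariates_path = outdir / "covariates.csv"
            generate_mortality(truth, seed=config.seed + 2).to_csv(covariates_path, index=False)
            write_truth_csv(truth, outdir / "truth.csv")
            report["stages"]["simulate"] = {"n_practices": len(records)}
        else:
            code_map = qof_io.DEFAULT_CODE_MAP
            registry_path = Path(config.registry_csv)
            records = qof_io.read_indicator_table(registry_path, code_map, year=config.year)
            lookup_path = Path(config.lookup_csv) if config.lookup_csv else None
            survey_path = Path(config.survey_csv) if config.survey_csv else None
            covariates_path = Path(config.covariates_csv) if config.covariates_csv else None
            report["stages"]["simulate"] = {"skipped": True, "n_practices": len(records)}

        # --- estimate ------------------------------------------------------
        stage = "estimate"
        estimates = estimators.derive_estimates(records)
        est_frame = estimators.estimates_to_frame(estimates)
        est_frame.to_csv(outdir / "estimates.csv", index=False)
        prev = est_frame["prevalence_general"].dropna() * 100
        report["stages"]["estimate"] = {
            "n": int(len(est_frame)),
            "prevalence_pct": {
                "median": float(prev.median()),
                "min": float(prev.min()),
                "max": float(prev.max()),
                "iqr": [float(prev.quantile(0.25)), float(prev.quantile(0.75))],
            },
        }

        # --- aggregate -----------------------------------------------------
        stage = "aggregate"
        if lookup_path is not None and Path(lookup_path).exists():
            lookup = qof_io.read_postcode_lookup(lookup_path)
            assignment = aggregation.assign_districts(records, lookup)
            if config.aggregation_method == "pooled":
                aggs = aggregation.aggregate_pooled(records, assignment)
            else:
                weights = ("status_denominator"
                           if config.aggregation_method == "weighted-mean" else "none")
                aggs = aggregation.aggregate_mean(estimates, assignment, weights=weights)
            agg_frame = aggregation.aggregates_to_frame(aggs)
            agg_frame.to_csv(outdir / "districts.csv", index=False)
            total = next(a for a in aggs if a.district_code == aggregation.TOTAL_CODE)
            report["stages"]["aggregate"] = {
                "method": config.aggregation_method,
                "n_districts": int(len(aggs) - 1),
                "total_prevalence_pct": 100.0 * total.prevalence,
            }
        else:
            aggs = None
            notices.append("aggregate: no postcode lookup available; stage skipped")
            logger.info(notices[-1])

        # --- agreement -----------------------------------------------------
        stage = "agree"
        agreement = {}
        if aggs is not None and survey_path is not None and Path(survey_path).exists():
            survey = {e.district_code: e for e in qof_io.read_survey_estimates(survey_path)}
            shared = [a for a in aggs
                      if a.district_code in survey and a.district_code != aggregation.TOTAL_CODE]
            if len(shared) >= 3:
                qof_pct = np.array([100.0 * a.prevalence for a in shared])
                ihs_pct = np.array([100.0 * survey[a.district_code].prevalence for a in shared])
                summary = agreement_stats.bland_altman(qof_pct, ihs_pct)
                agreement_stats.bland_altman_pairs(
                    qof_pct, ihs_pct, ids=[a.district_code for a in shared]
                ).to_csv(outdir / "bland_altman_qof_vs_survey.csv", index=False)
                agreement["qof_vs_survey"] = asdict(summary)
            else:
                notices.append("agree: fewer than 3 shared districts; survey comparison skipped")
        else:
            notices.append("agree: no survey estimates available; survey comparison skipped")
            logger.info(notices[-1])
        chronic_pairs = est_frame.dropna(subset=["prevalence_chronic", "prevalence_general"])
        if len(chronic_pairs) >= 10:
            chronic = 100.0 * chronic_pairs["prevalence_chronic"].to_numpy()
            general = 100.0 * chronic_pairs["prevalence_general"].to_numpy()
            agreement["chronic_vs_general"] = asdict(agreement_stats.bland_altman(chronic, general))
            fit = agreement_stats.fit_calibration(
                chronic, general, outlier_threshold=config.outlier_threshold,
                ids=chronic_pairs["practice_id"].tolist())
            agreement["calibration"] = {
                "slope": fit.slope, "intercept": fit.intercept, "n_used": fit.n_used,
                "removed_ids": sorted(fit.removed_ids), "residual_sd": fit.residual_sd,
            }
        report["stages"]["agree"] = agreement

        # --- model ---------------------------------------------------------
        stage = "model"
        if covariates_path is not None and Path(covariates_path).exists():
            data = pd.read_csv(covariates_path)
            comparison = mortality_model.compare_models(
                data, config.model_covariates, config.model_added_covariate,
                offset=config.model_offset)
            comparison.table.to_csv(outdir / "irr_comparison.csv")
            report["stages"]["model"] = {
                "n": comparison.base.n,
                "added_covariate": comparison.added_covariate,
                "lr_statistic": comparison.lr_statistic,
                "lr_p_value": comparison.lr_p_value,
                "dispersion_with_added": comparison.augmented.dispersion,
                "irr": {
                    term: {
                        "base": row["irr_base"],
                        "with_added": row["irr_with_added"],
                        "p_base": row["p_base"],
                        "p_with_added": row["p_with_added"],
                    }
                    for term, row in comparison.table.iterrows()
                    if term != "intercept"
                },
            }
        else:
            notices.append("model: no covariate table available; stage skipped")
            logger.info(notices[-1])
    except QofSmokeError as exc:
        raise QofSmokeError(f"stage {stage!r} failed: {exc}") from exc

    report["notices"] = notices
    report = _round_floats(report)
    report = json.loads(json.dumps(report, sort_keys=True))
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report
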