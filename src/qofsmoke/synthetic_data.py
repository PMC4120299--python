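"""Synthetic QOF-like registries with known ground truth.

Every generator is deterministic under a fixed seed: one global seed is
expanded into independent substreams (registry, survey, mortality,
multiyear) via :class:`numpy.random.SeedSequence` so each stage can be
regenerated in isolation.

Generation mechanism per practice
---------------------------------
Draw an eligible 15+ list size, a true smoker fraction and a chronic-
condition share; realize actual smokers binomially; then apply the
recording model. Recording (smoking-status ascertainment) decides whether
a patient enters the published status-indicator denominator at all —
never-assessed patients are excluded from it, as refusers and excepted
patients are in real extracts. Every assessed smoker is identified as a
smoker; assessed non-smokers may lack an in-window record, which is what
keeps underlying achievement below 100%:

* ``sm07_den`` = assessed patients, ``sm07_num`` = assessed patients with
  an in-window status record,
* ``sm08_den`` = assessed (identified) current smokers, ``sm08_num`` =
  those offered cessation support,
* chronic register nested within the assessed population, with analogous
  counts.

Differential (MAR) recording is a log-odds shift applied to smokers'
ascertainment probability. A shift of zero is MCAR: the assessed
population is then a simple random subsample, so the status-denominator
estimator is unbiased; a negative shift (smokers less likely assessed)
biases it downward, a positive one upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import PracticeIndicatorRecord, SurveyAreaEstimate

DEFAULT_YEAR = "2012/13"


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution for eligible list sizes."""
    mean_log: float = 8.55   # median ~ 5200 patients
    sd_log: float = 0.55

    def validate(self):
        if self.sd_log < 0:
            raise ConfigError("sd_log must be >= 0")


@dataclass(frozen=True)
class BetaSpec:
    a: float
    b: float

    def validate(self):
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class RecordingModel:
    """Smoking-status recording (ascertainment) model.

    ``probability_general`` is the chance a patient's status is ever
    ascertained and hence counted in the status-indicator denominator;
    ``mar_log_odds_shift`` shifts that chance for smokers (0 = MCAR).
    ``record_window_general`` / ``probability_chronic`` are the chances an
    assessed non-smoker has an *in-window* record in the general / chronic
    indicator, which set the underlying achievement below 100%.
    """
    probability_general: float = 0.95
    probability_chronic: float = 0.96
    record_window_general: float = 0.85
    mar_log_odds_shift: float = 0.0

    def validate(self):
        for p in (self.probability_general, self.probability_chronic,
                  self.record_window_general):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"recording probability {p} outside [0, 1]")

    def smoker_probability(self, base: float) -> float:
        if self.mar_log_odds_shift == 0.0 or base in (0.0, 1.0):
            return base
        return float(_expit(_logit(base) + self.mar_log_odds_shift))


@dataclass(frozen=True)
class MortalityConfig:
    """True data-generating model for premature CHD death counts."""
    coefficients: Dict[str, float] = field(
        default_factory=lambda: {"smoking_pp": np.log(1.031), "deprivation": np.log(1.017)})
    dispersion: float = 0.1
    intercept: float = -7.5
    confounder_rho: float = 0.6  # corr(deprivation, smoking_pp)
    deprivation_mean: float = 22.0
    deprivation_sd: float = 8.0

    def validate(self):
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not -1.0 < self.confounder_rho < 1.0:
            raise ConfigError("confounder_rho must be in (-1, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic cohort; the seed determines everything.

    Defaults are calibrated to the published summaries (practice prevalence
    centred near 19% with a wide spread; chronic prevalence about 3 pp
    lower; recording around 88% general / 97% chronic) — scenario defaults,
    not assertion targets.
    """
    n_practices: int = 215
    n_districts: int = 16
    seed: int = 0
    list_size: LogNormalSpec = field(default_factory=LogNormalSpec)
    true_prevalence: BetaSpec = field(default_factory=lambda: BetaSpec(8.0, 34.0))
    chronic_share: BetaSpec = field(default_factory=lambda: BetaSpec(20.0, 60.0))
    chronic_smoking_offset: float = -0.0305  # proportion scale (-3.05 pp)
    recording: RecordingModel = field(default_factory=RecordingModel)
    cessation_offer_probability: float = 0.9
    survey_sample_size_range: Tuple[int, int] = (130, 1475)
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    min_list_size: int = 400

    def validate(self):
        if self.n_practices < 1:
            raise ConfigError("n_practices must be >= 1")
        if not 1 <= self.n_districts <= self.n_practices:
            raise ConfigError("need 1 <= n_districts <= n_practices")
        if not 0.0 <= self.cessation_offer_probability <= 1.0:
            raise ConfigError("cessation_offer_probability outside [0, 1]")
        lo, hi = self.survey_sample_size_range
        if not 1 <= lo <= hi:
            raise ConfigError("invalid survey sample size range")
        self.list_size.validate()
        self.true_prevalence.validate()
        self.chronic_share.validate()
        self.recording.validate()
        self.mortality.validate()


@dataclass(frozen=True)
class GroundTruth:
    """Per-practice truth behind a generated registry.

    ``practices`` columns: practice_id, postcode, district_code, list_size,
    true_prevalence, true_chronic_prevalence, chronic_share, true_smokers
    (the realized smoker count), restricted (bool flag).
    """

    practices: pd.DataFrame

    @property
    def restricted_ids(self) -> frozenset:
        return frozenset(self.practices.loc[self.practices["restricted"], "practice_id"])

    def lookup(self) -> Dict[str, str]:
        return dict(zip(self.practices["postcode"], self.practices["district_code"]))

    def district_truth(self) -> pd.DataFrame:
        """Population-weighted true prevalence per district.

        The district truth is the expected smoker total over the summed
        eligible population, i.e. the list-size-weighted mean of the
        member practices' true fractions.
        """
        g = self.practices.groupby("district_code")
        pop = g["list_size"].sum()
        smokers = g.apply(
            lambda d: (d["list_size"] * d["true_prevalence"]).sum(), include_groups=False)
        out = pd.DataFrame({
            "population": pop,
            "true_prevalence": smokers / pop,
        })
        return out.reset_index()


def _streams(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("registry", "survey", "mortality", "multiyear")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_truth(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_practices
    ids = [f"P{i + 1:04d}" for i in range(n)]
    postcodes = [f"ZZ{i + 1} {1 + i % 9}XY" for i in range(n)]
    # guarantee every district has at least one practice, then fill randomly
    districts = np.array([f"D{d + 1:02d}" for d in range(config.n_districts)])
    assignment = np.concatenate([
        districts,
        rng.choice(districts, size=n - config.n_districts),
    ])[:n]
    assignment = rng.permutation(assignment)
    list_size = np.maximum(
        np.round(rng.lognormal(config.list_size.mean_log, config.list_size.sd_log, n)),
        config.min_list_size).astype(int)
    prev = rng.beta(config.true_prevalence.a, config.true_prevalence.b, n)
    share = rng.beta(config.chronic_share.a, config.chronic_share.b, n)
    chronic_prev = np.clip(prev + config.chronic_smoking_offset, 1e-4, 1 - 1e-4)
    return pd.DataFrame({
        "practice_id": ids,
        "postcode": postcodes,
        "district_code": assignment,
        "list_size": list_size,
        "true_prevalence": prev,
        "true_chronic_prevalence": chronic_prev,
        "chronic_share": share,
        "restricted": False,
    })


def _realize_counts(truth: pd.DataFrame, config: CohortConfig, year: str,
                    rng: np.random.Generator,
                    prevalence: Optional[np.ndarray] = None,
                    chronic_prevalence: Optional[np.ndarray] = None):
    """Binomial realization of one year's indicator counts for all practices."""
    rec = config.recording
    n = len(truth)
    N = truth["list_size"].to_numpy()
    prev = truth["true_prevalence"].to_numpy() if prevalence is None else prevalence
    cprev = (truth["true_chronic_prevalence"].to_numpy()
             if chronic_prevalence is None else chronic_prevalence)
    share = truth["chronic_share"].to_numpy()

    smokers = rng.binomial(N, prev)
    assessed_smokers = rng.binomial(smokers, rec.smoker_probability(rec.probability_general))
    assessed_nonsmokers = rng.binomial(N - smokers, rec.probability_general)
    sm07_den = assessed_smokers + assessed_nonsmokers
    in_window_nonsmokers = rng.binomial(assessed_nonsmokers, rec.record_window_general)
    sm08_num = rng.binomial(assessed_smokers, config.cessation_offer_probability)

    # chronic register nested in the assessed population: sm05_den <= sm07_den
    # holds by construction, and CS ~ Binom(register, chronic prevalence) keeps
    # the chronic estimator exactly unbiased
    n_chronic = rng.binomial(sm07_den, share)
    chronic_smokers = rng.binomial(n_chronic, cprev)
    in_window_chronic_ns = rng.binomial(n_chronic - chronic_smokers, rec.probability_chronic)
    sm06_num = rng.binomial(chronic_smokers, config.cessation_offer_probability)

    records = []
    for i in range(n):
        records.append(PracticeIndicatorRecord(
            practice_id=truth["practice_id"].iat[i],
            year=year,
            postcode=truth["postcode"].iat[i],
            sm07_num=int(assessed_smokers[i] + in_window_nonsmokers[i]),
            sm07_den=int(sm07_den[i]),
            sm08_num=int(sm08_num[i]),
            sm08_den=int(assessed_smokers[i]),
            sm05_num=int(chronic_smokers[i] + in_window_chronic_ns[i]),
            sm05_den=int(n_chronic[i]),
            sm06_num=int(sm06_num[i]),
            sm06_den=int(chronic_smokers[i]),
        ))
    return records, smokers


def generate_registry(
    config: CohortConfig,
    year: str = DEFAULT_YEAR,
) -> Tuple[List[PracticeIndicatorRecord], GroundTruth]:
    """Generate one year's registry plus the ground truth behind it."""
    config.validate()
    rng = _streams(config.seed)["registry"]
    truth = _draw_truth(config, rng)
    records, smokers = _realize_counts(truth, config, year, rng)
    truth = truth.assign(true_smokers=smokers)
    return records, GroundTruth(truth)


def generate_survey_estimates(
    truth: GroundTruth,
    sample_sizes: Union[int, Dict[str, int]],
    seed: int,
) -> List[SurveyAreaEstimate]:
    """Binomial survey estimates of each district's true prevalence.

    ``sample_sizes`` is either one n for every district or a mapping
    district code -> n; every key must be a known district.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    district = truth.district_truth().set_index("district_code")
    if isinstance(sample_sizes, int):
        sizes = {code: sample_sizes for code in district.index}
    else:
        unknown = set(sample_sizes) - set(district.index)
        if unknown:
            raise ConfigError(f"unknown district(s) in sample sizes: {sorted(unknown)}")
        sizes = dict(sample_sizes)
    out = []
    for code in sorted(sizes):
        n = int(sizes[code])
        if n < 1:
            raise ConfigError(f"district {code}: sample size must be >= 1")
        p = float(district.loc[code, "true_prevalence"])
        est = SurveyAreaEstimate(district_code=code,
                                 prevalence=float(rng.binomial(n, p)) / n,
                                 sample_size=n)
        est.validate()
        out.append(est)
    return out


def generate_mortality(
    truth: GroundTruth,
    coefficients: Optional[Dict[str, float]] = None,
    dispersion: Optional[float] = None,
    seed: int = 0,
    config: Optional[MortalityConfig] = None,
) -> pd.DataFrame:
    """Simulate practice covariates and NB2 death counts with known betas.

    The smoking covariate (``smoking_pp``) is the practice's true
    prevalence in percentage points; deprivation is drawn correlated with
    it (``confounder_rho``) so omitted-smoking confounding is built in.
    Any other named coefficient gets an independent standard-normal
    covariate. Counts follow NB2 via a gamma-Poisson mixture with a
    log-list-size offset.
    """
    cfg = config or MortalityConfig()
    if coefficients is not None:
        cfg = replace(cfg, coefficients=dict(coefficients))
    if dispersion is not None:
        cfg = replace(cfg, dispersion=float(dispersion))
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tp = truth.practices
    n = len(tp)

    smoking_pp = 100.0 * tp["true_prevalence"].to_numpy()
    z = (smoking_pp - smoking_pp.mean()) / (smoking_pp.std() or 1.0)
    rho = cfg.confounder_rho
    deprivation = (cfg.deprivation_mean
                   + cfg.deprivation_sd * (rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)))
    frame = pd.DataFrame({
        "practice_id": tp["practice_id"].to_numpy(),
        "exposure": tp["list_size"].astype(float).to_numpy(),
        "smoking_pp": smoking_pp,
        "deprivation": deprivation,
    })
    linpred = np.full(n, cfg.intercept) + np.log(frame["exposure"].to_numpy())
    for name, beta in cfg.coefficients.items():
        if name not in frame.columns:
            frame[name] = rng.standard_normal(n)
        linpred = linpred + beta * frame[name].to_numpy()
    mu = np.exp(linpred)
    if cfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=cfg.dispersion * mu)
        deaths = rng.poisson(lam)
    else:
        deaths = rng.poisson(mu)
    frame.insert(1, "death_count", deaths.astype(int))
    return frame


def financial_year_labels(n_years: int, start: int = 2006) -> List[str]:
    """Financial-year tokens ``2006/07`` ... for ``n_years`` consecutive years."""
    return [f"{start + i}/{str(start + i + 1)[-2:]}" for i in range(n_years)]


@dataclass(frozen=True)
class MultiyearTruth:
    """Shared practice truth plus the per-year prevalence paths."""

    base: GroundTruth
    prevalence_by_year: pd.DataFrame          # index practice_id, one column per year
    chronic_prevalence_by_year: pd.DataFrame
    missing_years: Dict[str, List[str]]       # practice_id -> years with no record

    @property
    def restricted_ids(self) -> frozenset:
        return self.base.restricted_ids


def generate_multiyear(
    config: CohortConfig,
    n_years: int,
    drift_sd: float = 0.002,
    seed: Optional[int] = None,
    n_missing: int = 0,
    n_restricted: int = 0,
    year_labels: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, List[PracticeIndicatorRecord]], MultiyearTruth]:
    """Generate per-year registries with random-walk drift in practice truth.

    ``n_missing`` practices each lose one randomly chosen year's record
    entirely (for testing the complete-series filter); ``n_restricted``
    further practices are flagged restricted in the truth (records kept —
    excluding them is the caller's decision, as in the source cohort).
    """
    config.validate()
    if n_years < 2:
        raise ConfigError("n_years must be >= 2")
    if drift_sd < 0:
        raise ConfigError("drift_sd must be >= 0")
    if n_missing + n_restricted > config.n_practices:
        raise ConfigError("more flagged practices than practices")
    years = list(year_labels) if year_labels is not None else financial_year_labels(n_years)
    if len(years) != n_years:
        raise ConfigError("year_labels length must equal n_years")
    rng = (_streams(config.seed)["multiyear"] if seed is None
           else np.random.default_rng(np.random.SeedSequence(seed)))

    truth = _draw_truth(config, rng)
    ids = truth["practice_id"].to_list()
    flagged = rng.choice(ids, size=n_missing + n_restricted, replace=False)
    missing_ids = list(flagged[:n_missing])
    restricted_ids = set(flagged[n_missing:])
    truth.loc[truth["practice_id"].isin(restricted_ids), "restricted"] = True
    missing_years = {pid: [years[rng.integers(n_years)]] for pid in missing_ids}

    prev = truth["true_prevalence"].to_numpy().copy()
    cprev = truth["true_chronic_prevalence"].to_numpy().copy()
    registries: Dict[str, List[PracticeIndicatorRecord]] = {}
    prev_paths, cprev_paths = {}, {}
    for year in years:
        records, _ = _realize_counts(truth, config, year, rng,
                                     prevalence=prev, chronic_prevalence=cprev)
        registries[year] = [
            r for r in records
            if year not in missing_years.get(r.practice_id, ())
        ]
        prev_paths[year] = prev.copy()
        cprev_paths[year] = cprev.copy()
        step = rng.normal(0.0, drift_sd, len(truth)) if drift_sd > 0 else 0.0
        prev = np.clip(prev + step, 1e-4, 1 - 1e-4)
        cprev = np.clip(cprev + step, 1e-4, 1 - 1e-4)

    truth = truth.assign(true_smokers=np.round(
        truth["list_size"].to_numpy() * truth["true_prevalence"].to_numpy()).astype(int))
    return registries, MultiyearTruth(
        base=GroundTruth(truth),
        prevalence_by_year=pd.DataFrame(prev_paths, index=ids),
        chronic_prevalence_by_year=pd.DataFrame(cprev_paths, index=ids),
        missing_years=missing_years,
    )


def write_truth_csv(truth: GroundTruth, path) -> None:
    truth.practices.to_csv(path, index=False)


def write_lookup_csv(truth: GroundTruth, path) -> None:
    pd.DataFrame(
        {"postcode": truth.practices["postcode"],
         "district_code": truth.practices["district_code"]}
    ).to_csv(path, index=False)


def write_survey_csv(estimates: Sequence[SurveyAreaEstimate], path) -> None:
    pd.DataFrame([{
        "district_code": e.district_code,
        "prevalence": e.prevalence,
        "sample_size": e.sample_size,
    } for e in estimates]).to_csv(path, index=False)
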