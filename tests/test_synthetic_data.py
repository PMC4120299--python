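import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qofsmoke.errors import ConfigError
from qofsmoke.qof_io import filter_complete_series, synthetic_code_map, write_indicator_table
from qofsmoke.synthetic_data import (
    BetaSpec,
    CohortConfig,
    RecordingModel,
    financial_year_labels,
    generate_mortality,
    generate_multiyear,
    generate_registry,
    generate_survey_estimates,
)


class TestGenerateRegistry:
    def test_same_seed_identical_output(self):
        cfg = CohortConfig(n_practices=30, n_districts=5, seed=9)
        r1, t1 = generate_registry(cfg)
        r2, t2 = generate_registry(cfg)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1.practices, t2.practices)

    def test_different_seed_differs(self):
        r1, _ = generate_registry(CohortConfig(n_practices=30, n_districts=5, seed=9))
        r2, _ = generate_registry(CohortConfig(n_practices=30, n_districts=5, seed=10))
        assert r1 != r2

    def test_byte_identical_csv(self, tmp_path):
        cfg = CohortConfig(n_practices=30, n_districts=5, seed=9)
        cmap = synthetic_code_map(["2012/13"])
        for name in ("a.csv", "b.csv"):
            records, _ = generate_registry(cfg)
            write_indicator_table(records, tmp_path / name, cmap)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_complete_recording_mechanism(self):
        cfg = CohortConfig(n_practices=15, n_districts=3, seed=12,
                           recording=RecordingModel(1.0, 1.0, 1.0, 0.0))
        records, truth = generate_registry(cfg)
        by_id = truth.practices.set_index("practice_id")
        for rec in records:
            row = by_id.loc[rec.practice_id]
            assert rec.sm07_den == row["list_size"]
            assert rec.sm08_den == row["true_smokers"]

    def test_mcar_unbiased_quick(self):
        biases = []
        for rep in range(300):
            cfg = CohortConfig(
                n_practices=20, n_districts=4, seed=30_000 + rep,
                recording=RecordingModel(probability_general=0.85, mar_log_odds_shift=0.0))
            records, truth = generate_registry(cfg)
            est = np.array([r.sm08_den / r.sm07_den for r in records])
            biases.append((est - truth.practices["true_prevalence"].to_numpy()).mean())
        assert abs(100 * np.mean(biases)) < 0.25

    def test_mar_shift_biases_in_stated_direction(self):
        def mean_bias(shift, seed0):
            out = []
            for rep in range(100):
                cfg = CohortConfig(
                    n_practices=20, n_districts=4, seed=seed0 + rep,
                    recording=RecordingModel(probability_general=0.7,
                                             mar_log_odds_shift=shift))
                records, truth = generate_registry(cfg)
                est = np.array([r.sm08_den / r.sm07_den for r in records])
                out.append((est - truth.practices["true_prevalence"].to_numpy()).mean())
            return float(np.mean(out))

        # smokers more likely assessed than non-smokers -> over-estimate, and vice versa
        assert mean_bias(+1.0, 40_000) > 0.01
        assert mean_bias(-1.0, 41_000) < -0.01

    def test_every_record_valid(self, default_registry):
        records, _ = default_registry
        for rec in records:
            rec.validate()

    @given(p_gen=st.floats(0.0, 1.0), p_chr=st.floats(0.0, 1.0),
           window=st.floats(0.0, 1.0), shift=st.floats(-2.0, 2.0),
           offer=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_invariants_hold_over_random_configs(self, p_gen, p_chr, window, shift, offer, seed):
        cfg = CohortConfig(
            n_practices=6, n_districts=2, seed=seed, min_list_size=50,
            recording=RecordingModel(p_gen, p_chr, window, shift),
            cessation_offer_probability=offer)
        records, _ = generate_registry(cfg)
        for rec in records:
            rec.validate()

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ConfigError):
            generate_registry(CohortConfig(n_practices=3, n_districts=5))
        with pytest.raises(ConfigError):
            generate_registry(CohortConfig(true_prevalence=BetaSpec(-1, 2)))
        with pytest.raises(ConfigError):
            generate_registry(CohortConfig(
                recording=RecordingModel(probability_general=1.2)))


class TestGroundTruth:
    def test_district_truth_is_population_weighted_mean(self, default_registry):
        _, truth = default_registry
        district = truth.district_truth().set_index("district_code")
        for code, group in truth.practices.groupby("district_code"):
            expected = ((group["list_size"] * group["true_prevalence"]).sum()
                        / group["list_size"].sum())
            assert district.loc[code, "true_prevalence"] == pytest.approx(expected)

    def test_lookup_covers_all_practices(self, default_registry):
        _, truth = default_registry
        assert len(truth.lookup()) == len(truth.practices)


class TestGenerateSurveyEstimates:
    def test_large_n_approaches_truth(self, default_registry):
        _, truth = default_registry
        estimates = generate_survey_estimates(truth, 2_000_000, seed=1)
        district = truth.district_truth().set_index("district_code")
        for est in estimates:
            assert est.prevalence == pytest.approx(
                district.loc[est.district_code, "true_prevalence"], abs=0.002)

    def test_sampling_sd_matches_binomial_theory(self, default_registry):
        _, truth = default_registry
        district = truth.district_truth().set_index("district_code")
        code = district.index[0]
        p = district.loc[code, "true_prevalence"]
        n = 150
        draws = [generate_survey_estimates(truth, {code: n}, seed=s)[0].prevalence
                 for s in range(400)]
        assert np.std(draws) == pytest.approx(np.sqrt(p * (1 - p) / n), rel=0.15)

    def test_unknown_district_is_error(self, default_registry):
        _, truth = default_registry
        with pytest.raises(ConfigError, match="NOPE"):
            generate_survey_estimates(truth, {"NOPE": 100}, seed=1)

    def test_reproducible(self, default_registry):
        _, truth = default_registry
        assert (generate_survey_estimates(truth, 150, seed=5)
                == generate_survey_estimates(truth, 150, seed=5))


class TestGenerateMortality:
    def test_dispersion_zero_is_marginally_poisson(self, default_registry):
        _, truth = default_registry
        small = truth.practices.head(5)
        from qofsmoke.synthetic_data import GroundTruth
        sub = GroundTruth(small)
        counts = np.array([
            generate_mortality(sub, coefficients={}, dispersion=0.0,
                               seed=s)["death_count"].to_numpy()
            for s in range(500)
        ])
        ratio = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        assert np.all(np.abs(ratio - 1.0) < 0.25)

    def test_positive_dispersion_overdisperses(self, default_registry):
        _, truth = default_registry
        from qofsmoke.synthetic_data import GroundTruth
        sub = GroundTruth(truth.practices.head(5))
        counts = np.array([
            generate_mortality(sub, coefficients={}, dispersion=0.5,
                               seed=s)["death_count"].to_numpy()
            for s in range(300)
        ])
        ratio = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        assert np.all(ratio > 1.5)

    def test_negative_dispersion_rejected(self, default_registry):
        _, truth = default_registry
        with pytest.raises(ConfigError):
            generate_mortality(truth, dispersion=-0.1, seed=1)

    def test_null_model_irrs_near_one(self, default_registry):
        from qofsmoke.mortality_model import fit_negative_binomial
        _, truth = default_registry
        data = generate_mortality(truth,
                                  coefficients={"smoking_pp": 0.0, "deprivation": 0.0},
                                  dispersion=0.05, seed=31)
        fit = fit_negative_binomial(data, ["smoking_pp", "deprivation"],
                                    offset="log-exposure")
        for term in ("smoking_pp", "deprivation"):
            row = fit.table.loc[term]
            assert row["ci_lower"] <= 1.0 <= row["ci_upper"]

    def test_confounder_correlation_built_in(self, default_registry):
        _, truth = default_registry
        data = generate_mortality(truth, seed=32)
        rho = np.corrcoef(data["smoking_pp"], data["deprivation"])[0, 1]
        assert rho == pytest.approx(0.6, abs=0.15)


class TestGenerateMultiyear:
    def test_zero_drift_keeps_truth_constant(self):
        cfg = CohortConfig(n_practices=12, n_districts=3, seed=13)
        _, mt = generate_multiyear(cfg, n_years=3, drift_sd=0.0)
        first = mt.prevalence_by_year.iloc[:, 0]
        for col in mt.prevalence_by_year.columns[1:]:
            pd.testing.assert_series_equal(
                mt.prevalence_by_year[col], first, check_names=False)

    def test_missing_and_restricted_fixture(self):
        registries, mt = generate_multiyear(
            CohortConfig(n_practices=230, n_districts=16, seed=1),
            n_years=7, drift_sd=0.002, n_missing=14, n_restricted=1)
        all_records = [r for recs in registries.values() for r in recs]
        result = filter_complete_series(all_records, list(registries))
        assert len(result.retained_practices) == 216
        assert len(mt.restricted_ids) == 1
        assert len([p for p in result.retained_practices
                    if p not in mt.restricted_ids]) == 215
        for pid, years in mt.missing_years.items():
            for year in years:
                assert pid not in {r.practice_id for r in registries[year]}

    def test_year_labels(self):
        assert financial_year_labels(3) == ["2006/07", "2007/08", "2008/09"]

    def test_n_years_validation(self):
        with pytest.raises(ConfigError):
            generate_multiyear(CohortConfig(n_practices=5, n_districts=2), n_years=1)
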