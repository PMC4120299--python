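import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qofsmoke import qof_io
from qofsmoke.errors import (
    ConfigError,
    DuplicateRecordError,
    RecordValidationError,
)
from qofsmoke.qof_io import (
    DEFAULT_CODE_MAP,
    filter_complete_series,
    normalize_postcode,
    read_code_map,
    read_indicator_table,
    read_postcode_lookup,
    read_wide_indicator_table,
    synthetic_code_map,
    write_indicator_table,
)
from qofsmoke.synthetic_data import CohortConfig, generate_multiyear, generate_registry
from qofsmoke.types import PracticeIndicatorRecord


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestReadIndicatorTable:
    def test_long_format_single_practice(self, tmp_path):
        path = _write(tmp_path, "qof.csv", """\
            practice_id,year,indicator,numerator,denominator
            A,2012/13,SM07,3450,3721
            A,2012/13,SM08,1024,1129
        """)
        (rec,) = read_indicator_table(path)
        assert rec.practice_id == "A"
        assert (rec.sm07_num, rec.sm07_den) == (3450, 3721)
        assert (rec.sm08_num, rec.sm08_den) == (1024, 1129)
        assert not rec.has_chronic

    def test_header_only_file_gives_empty_collection(self, tmp_path):
        path = _write(tmp_path, "empty.csv",
                      "practice_id,year,indicator,numerator,denominator\n")
        assert read_indicator_table(path) == []

    def test_invariant_violation_names_practice(self, tmp_path):
        # sm08_den (recorded smokers) exceeds sm07_num (recorded statuses)
        path = _write(tmp_path, "bad.csv", """\
            practice_id,year,indicator,numerator,denominator
            X9,2012/13,SM07,100,400
            X9,2012/13,SM08,90,150
        """)
        with pytest.raises(RecordValidationError, match="X9"):
            read_indicator_table(path)

    def test_malformed_numeric_names_practice_and_field(self, tmp_path):
        path = _write(tmp_path, "bad.csv", """\
            practice_id,year,indicator,numerator,denominator
            A,2012/13,SM07,34x0,3721
        """)
        with pytest.raises(RecordValidationError, match="A.*SM07"):
            read_indicator_table(path)

    def test_duplicate_rows_are_a_hard_error(self, tmp_path):
        path = _write(tmp_path, "dup.csv", """\
            practice_id,year,indicator,numerator,denominator
            A,2012/13,SM07,3450,3721
            A,2012/13,SM07,3450,3721
        """)
        with pytest.raises(DuplicateRecordError):
            read_indicator_table(path)

    def test_unknown_codes_ignored(self, tmp_path, caplog):
        path = _write(tmp_path, "mixed.csv", """\
            practice_id,year,indicator,numerator,denominator
            A,2012/13,SM07,3450,3721
            A,2012/13,SM08,1024,1129
            A,2012/13,CHD08,50,60
        """)
        import logging
        with caplog.at_level(logging.INFO, logger="qofsmoke.qof_io"):
            (rec,) = read_indicator_table(path)
        assert rec.sm07_den == 3721
        assert any("unknown indicator" in m for m in caplog.messages)

    def test_year_argument_when_no_year_column(self, tmp_path):
        path = _write(tmp_path, "ny.csv", """\
            practice_id,indicator,numerator,denominator
            A,SM07,10,20
        """)
        (rec,) = read_indicator_table(path, year="2012/13")
        assert rec.year == "2012/13"
        with pytest.raises(ConfigError):
            read_indicator_table(path)

    def test_round_trip(self, tmp_path, default_registry):
        records, _ = default_registry
        code_map = synthetic_code_map(["2012/13"])
        path = tmp_path / "rt.csv"
        write_indicator_table(records, path, code_map)
        assert read_indicator_table(path, code_map) == sorted(
            records, key=lambda r: (r.practice_id, r.year))


class TestFilterCompleteSeries:
    @staticmethod
    def _rec(pid, year, chronic=True):
        kwargs = dict(sm05_num=90, sm05_den=100, sm06_num=10, sm06_den=12) if chronic else {}
        return PracticeIndicatorRecord(practice_id=pid, year=year, **kwargs,
                                       sm07_num=400, sm07_den=500, sm08_num=70, sm08_den=80)

    def test_missing_year_excludes_practice(self):
        years = ["2008/09", "2009/10"]
        records = [self._rec("P1", y) for y in years]
        records += [self._rec("P2", y) for y in years]
        records += [self._rec("P3", "2009/10")]
        result = filter_complete_series(records, years)
        assert result.retained_practices == ["P1", "P2"]
        assert result.excluded == {"P3": ["2008/09"]}

    def test_all_complete_is_identity(self):
        records = [self._rec(p, y) for p in ("A", "B") for y in ("2008/09", "2009/10")]
        result = filter_complete_series(records, ["2008/09", "2009/10"])
        assert result.records == records
        assert result.excluded == {}

    def test_record_without_chronic_fields_counts_as_missing(self):
        records = [self._rec("A", "2008/09", chronic=False), self._rec("A", "2009/10")]
        result = filter_complete_series(records, ["2008/09", "2009/10"])
        assert result.excluded == {"A": ["2008/09"]}

    def test_idempotent(self, default_registry):
        records, _ = default_registry
        once = filter_complete_series(records, ["2012/13"])
        twice = filter_complete_series(once.records, ["2012/13"])
        assert twice.records == once.records and twice.excluded == {}

    def test_230_practice_fixture_retains_215(self):
        # 230 practices, 14 with an injected gap, 1 flagged restricted
        registries, truth = generate_multiyear(
            CohortConfig(n_practices=230, n_districts=16, seed=1),
            n_years=7, drift_sd=0.002, n_missing=14, n_restricted=1)
        all_records = [r for recs in registries.values() for r in recs]
        result = filter_complete_series(all_records, list(registries))
        assert len(result.retained_practices) == 216
        assert len(result.excluded) == 14
        kept = [p for p in result.retained_practices if p not in truth.restricted_ids]
        assert len(kept) == 215

    def test_empty_required_years_rejected(self):
        with pytest.raises(ConfigError):
            filter_complete_series([], [])


class TestPostcodeLookup:
    def test_normalization(self, tmp_path):
        path = _write(tmp_path, "pc.csv", """\
            postcode,district_code
            le1 5ww,E06000016
            LE2  7XX,E06000016
        """)
        lookup = read_postcode_lookup(path)
        assert lookup == {"LE1 5WW": "E06000016", "LE2 7XX": "E06000016"}

    def test_empty_lookup(self, tmp_path):
        path = _write(tmp_path, "pc.csv", "postcode,district_code\n")
        assert read_postcode_lookup(path) == {}

    def test_conflicting_duplicate_is_error(self, tmp_path):
        path = _write(tmp_path, "pc.csv", """\
            postcode,district_code
            LE1 5WW,E06000016
            le15ww,E07000130
        """)
        with pytest.raises(DuplicateRecordError):
            read_postcode_lookup(path)

    def test_generated_fixture_counts(self, tmp_path):
        _, truth = generate_registry(CohortConfig(n_practices=215, n_districts=16, seed=2))
        from qofsmoke.synthetic_data import write_lookup_csv
        path = tmp_path / "lookup.csv"
        write_lookup_csv(truth, path)
        lookup = read_postcode_lookup(path)
        assert len(lookup) == 215
        assert len(set(lookup.values())) == 16


@given(st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"),
                                      max_codepoint=127), min_size=4, max_size=8))
def test_normalize_postcode_idempotent_and_shaped(raw):
    norm = normalize_postcode(raw)
    assert norm == normalize_postcode(norm)
    assert norm == norm.upper()
    assert norm[:-4].count(" ") == 0 and norm[-4] == " "


def test_normalize_postcode_examples():
    assert normalize_postcode("le1 5ww") == "LE1 5WW"
    assert normalize_postcode("LE15WW") == "LE1 5WW"
    assert normalize_postcode(" sw1a  2aa ") == "SW1A 2AA"


def test_read_code_map_yaml(tmp_path):
    path = _write(tmp_path, "codes.yaml", """\
        "2012/13":
          status_general: SM07
          cessation_general: SM08
          status_chronic: SM05
          cessation_chronic: SM06
    """)
    cmap = read_code_map(path)
    assert cmap.role_of("2012/13", "SM08") == "cessation_general"
    assert cmap.role_of("2012/13", "XYZ") is None


def test_default_code_map_history():
    assert DEFAULT_CODE_MAP.role_of("2006/07", "SM01") == "status_chronic"
    assert DEFAULT_CODE_MAP.role_of("2011/12", "SM04") == "cessation_chronic"
    # general-population codes exist only from 2012/13
    for year in ("2006/07", "2008/09", "2011/12"):
        assert DEFAULT_CODE_MAP.codes_for(year).status_general is None


def test_read_wide_indicator_table(tmp_path):
    path = _write(tmp_path, "wide.csv", """\
        practice_id,postcode,sm07_num,sm07_den,sm08_num,sm08_den
        A,le1 5ww,3450,3721,1024,1129
    """)
    (rec,) = read_wide_indicator_table(path, year="2012/13")
    assert rec.sm08_den == 1129 and rec.postcode == "LE1 5WW"


def test_every_read_record_satisfies_invariants(default_registry, tmp_path):
    records, _ = default_registry
    code_map = synthetic_code_map(["2012/13"])
    path = tmp_path / "reg.csv"
    write_indicator_table(records, path, code_map)
    for rec in read_indicator_table(path, code_map):
        rec.validate()  # must not raise
        assert rec.sm07_num <= rec.sm07_den
        assert rec.sm08_den <= rec.sm07_num
        assert rec.sm06_den <= rec.sm05_num
        assert rec.sm05_den <= rec.sm07_den
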