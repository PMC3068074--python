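"""Domain-type parsing and cohort file IO."""

import datetime as dt
import itertools

import pytest
from hypothesis import given, strategies as st

from psakit import (
    LoadError,
    MCategory,
    NCategory,
    ParseError,
    PatientRecord,
    PSAMeasurement,
    PSASeries,
    TCategory,
    parse_gleason,
    parse_tnm,
    read_cohort,
    write_cohort,
)
from psakit.simulate import SimulationParams, simulate_cohort


class TestParseTnm:
    @pytest.mark.parametrize(
        "text, t, n, m",
        [
            ("T2cN0M0", "T2c", "N0", "M0"),  # fully specified stage
            ("T1c", "T1c", "NX", "MX"),  # bare T: N/M recorded as not assessed
            ("t3aN1M1", "T3a", "N1", "M1"),  # case-insensitive
            ("T4NXMX", "T4", "NX", "MX"),
            ("T2bN0", "T2b", "N0", "MX"),  # M omitted
        ],
    )
    def test_parses_valid_stages(self, text, t, n, m):
        stage = parse_tnm(text)
        assert (stage.t_category.value, stage.n_category.value, stage.m_category.value) == (t, n, m)

    def test_total_over_enumerated_grid(self):
        for t, n, m in itertools.product(TCategory, NCategory, MCategory):
            stage = parse_tnm(f"{t.value}{n.value}{m.value}")
            assert (stage.t_category, stage.n_category, stage.m_category) == (t, n, m)

    @pytest.mark.parametrize("bad", ["", "T9N0M0", "T2d", "N0M0", "T2cN2M0", "T2cN0M2", "stage2"])
    def test_rejects_out_of_enumeration(self, bad):
        with pytest.raises(ParseError):
            parse_tnm(bad)


class TestParseGleason:
    def test_pattern_pairs_exhaustive(self):
        # every pattern pair 1..5 x 1..5 sums correctly
        for a, b in itertools.product(range(1, 6), repeat=2):
            score = parse_gleason(f"{a}+{b}")
            assert score.primary == a and score.secondary == b
            assert score.sum_set == {a + b}

    def test_range_notation_spans_interval(self):
        score = parse_gleason("5-6")
        assert score.sum_set == {5, 6}
        assert score.primary is None and score.secondary is None
        assert score.max_sum == 6

    def test_bare_sum(self):
        assert parse_gleason("7").sum_set == {7}

    @pytest.mark.parametrize("bad", ["0+3", "6+5", "3+0", "1-11", "11", "1", "7-5", "x+y", ""])
    def test_rejects_out_of_bounds(self, bad):
        with pytest.raises(ParseError):
            parse_gleason(bad)


class TestSeriesInvariants:
    def test_measurements_sorted_on_construction(self):
        d = dt.date(2020, 1, 1)
        s = PSASeries(
            patient_id="p",
            measurements=[
                PSAMeasurement(date=d + dt.timedelta(days=k), psa=v)
                for k, v in [(20, 3.0), (0, 1.0), (10, 2.0)]
            ],
        )
        assert s.values() == [1.0, 2.0, 3.0]

    def test_duplicate_dates_rejected(self):
        d = dt.date(2020, 1, 1)
        with pytest.raises(ValueError, match="duplicate"):
            PSASeries(
                patient_id="p",
                measurements=[PSAMeasurement(date=d, psa=1.0), PSAMeasurement(date=d, psa=2.0)],
            )


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadCohort:
    def test_header_only_gives_empty_cohort(self, tmp_path):
        p = _write(tmp_path / "psa.csv", "patient_id,date,psa_ng_ml\n")
        assert read_cohort(p) == []

    def test_rows_out_of_order_are_sorted(self, tmp_path):
        p = _write(
            tmp_path / "psa.csv",
            "patient_id,date,psa_ng_ml\n"
            "a,2020-03-01,3.0\n"
            "a,2020-01-01,1.0\n"
            "a,2020-02-01,2.0\n",
        )
        (rec,) = read_cohort(p)
        assert rec.psa_series.values() == [1.0, 2.0, 3.0]

    def test_two_patients_interleaved_join_by_id(self, tmp_path):
        psa = _write(
            tmp_path / "psa.csv",
            "patient_id,date,psa_ng_ml\n"
            "a,2020-01-01,1.0\n"
            "b,2020-01-02,5.0\n"
            "a,2020-02-01,2.0\n"
            "b,2020-02-02,6.0\n",
        )
        staging = _write(
            tmp_path / "staging.csv",
            "patient_id,tnm,gleason,prostate_volume_ml,life_expectancy_years\n"
            "b,T2b,4+3,55,12\n"
            "a,T1c,5-6,,\n",
        )
        treatments = _write(
            tmp_path / "treatments.csv",
            "patient_id,modality,date,pre_treatment_psa_ng_ml\n"
            "b,radiotherapy,2020-03-01,6.0\n"
            "a,surgery,2020-03-02,\n",
        )
        recs = {r.patient_id: r for r in read_cohort(psa, staging, treatments)}
        assert set(recs) == {"a", "b"}
        assert recs["a"].stage.t_category.value == "T1c"
        assert recs["a"].gleason.sum_set == {5, 6}
        assert recs["a"].prostate_volume_ml is None
        assert recs["a"].treatments[0].modality.value == "surgery"
        assert recs["b"].prostate_volume_ml == 55.0
        assert recs["b"].treatments[0].pre_treatment_psa == 6.0

    def test_duplicate_patient_date_row_is_error_with_location(self, tmp_path):
        p = _write(
            tmp_path / "psa.csv",
            "patient_id,date,psa_ng_ml\na,2020-01-01,1.0\na,2020-01-01,2.0\n",
        )
        with pytest.raises(LoadError, match=r"psa\.csv:3"):
            read_cohort(p)

    @pytest.mark.parametrize(
        "content, message",
        [
            ("patient_id,when,psa_ng_ml\n", "unexpected columns"),
            ("patient_id,date,psa_ng_ml\na,01/02/2020,1.0\n", "invalid ISO date"),
            ("patient_id,date,psa_ng_ml\na,2020-01-01,abc\n", "unparseable PSA"),
        ],
    )
    def test_format_violations_raise_load_error(self, tmp_path, content, message):
        p = _write(tmp_path / "psa.csv", content)
        with pytest.raises(LoadError, match=message):
            read_cohort(p)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_simulated_cohort_round_trips(self, tmp_path, seed):
        records, _ = simulate_cohort(SimulationParams(n_patients=10, seed=seed))
        paths = write_cohort(records, tmp_path)
        back = read_cohort(paths["psa.csv"], paths["staging.csv"], paths["treatments.csv"])
        assert back == records

    def test_absent_fields_round_trip_to_absent(self, tmp_path):
        rec = PatientRecord(
            patient_id="x",
            psa_series=PSASeries(
                patient_id="x",
                measurements=[
                    PSAMeasurement(date=dt.date(2020, 1, 1), psa=4.0),
                    PSAMeasurement(date=dt.date(2020, 6, 1), psa=5.0),
                ],
            ),
        )
        paths = write_cohort([rec], tmp_path)
        (back,) = read_cohort(paths["psa.csv"], paths["staging.csv"], paths["treatments.csv"])
        assert back == rec
        assert back.prostate_volume_ml is None and back.stage is None

    def test_empty_cohort_writes_header_only_files(self, tmp_path):
        paths = write_cohort([], tmp_path)
        for p in paths.values():
            assert len(p.read_text().splitlines()) == 1

    @given(
        rows=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=2000),
                st.floats(min_value=0.0, max_value=500.0, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
            unique_by=lambda t: t[0],
        )
    )
    def test_arbitrary_series_round_trip(self, rows, tmp_path_factory):
        # read∘write is the identity on any valid measurement series
        tmp = tmp_path_factory.mktemp("rt")
        origin = dt.date(2015, 1, 1)
        rec = PatientRecord(
            patient_id="h",
            psa_series=PSASeries(
                patient_id="h",
                measurements=[
                    PSAMeasurement(date=origin + dt.timedelta(days=d), psa=v) for d, v in rows
                ],
            ),
        )
        paths = write_cohort([rec], tmp)
        (back,) = read_cohort(paths["psa.csv"], paths["staging.csv"], paths["treatments.csv"])
        assert back == rec
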