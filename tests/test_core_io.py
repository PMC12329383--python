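import math

import pytest
from hypothesis import given, settings, strategies as st

from scedlab.core_io import (
    Dropout,
    Measure,
    MeasureObservation,
    ParseError,
    ParticipantSeries,
    Phase,
    StudyDataset,
    ValidationError,
    dataset_from_json,
    dataset_to_json,
    extract_phase,
    read_long_csv,
    validate_dataset,
    validate_observation,
    write_long_csv,
)


def _write(tmp_path, text):
    path = tmp_path / "data.csv"
    path.write_text(text, encoding="utf-8")
    return path


HEADER = "participant_id,measure,week_index,phase,value\n"


class TestReadLongCsv:
    def test_empty_file_gives_empty_dataset(self, tmp_path):
        ds = read_long_csv(_write(tmp_path, HEADER))
        assert ds.participants == []

    def test_single_row_maps_directly(self, tmp_path):
        ds = read_long_csv(_write(tmp_path, HEADER + "P09,ECBI_INTENSITY,3,A,151\n"))
        [series] = ds.participants
        [obs] = series.observations
        assert obs == MeasureObservation("P09", Measure.ECBI_INTENSITY, 3,
                                         Phase.A, 151.0)

    def test_blank_value_becomes_missing_not_zero(self, tmp_path):
        ds = read_long_csv(_write(tmp_path, HEADER + "P01,OBVL_K,0,A,\n"))
        assert ds.participants[0].observations[0].value is None

    def test_unknown_measure_names_row(self, tmp_path):
        with pytest.raises(ParseError, match="row 2"):
            read_long_csv(_write(tmp_path, HEADER + "P01,BOGUS,0,A,1\n"))

    def test_unknown_phase_rejected(self, tmp_path):
        with pytest.raises(ParseError, match="phase"):
            read_long_csv(_write(tmp_path, HEADER + "P01,OBVL_K,0,Z,1\n"))

    def test_duplicate_observation_rejected(self, tmp_path):
        rows = "P01,OBVL_K,0,A,50\nP01,OBVL_K,0,A,51\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_long_csv(_write(tmp_path, HEADER + rows))


class TestValidation:
    @pytest.mark.parametrize(
        "measure,value,ok",
        [
            (Measure.ECBI_INTENSITY, 36, True),
            (Measure.ECBI_INTENSITY, 252, True),
            (Measure.ECBI_INTENSITY, 35, False),
            (Measure.ECBI_INTENSITY, 253, False),
            (Measure.ECBI_PROBLEM, 0, True),
            (Measure.ECBI_PROBLEM, 36, True),
            (Measure.ECBI_PROBLEM, -1, False),
            (Measure.ECBI_PROBLEM, 37, False),
            (Measure.VR_COUNT, 2.5, False),
            (Measure.VR_COUNT, 3, True),
        ],
    )
    def test_instrument_ranges(self, measure, value, ok):
        obs = MeasureObservation("P", measure, 0, Phase.A, value)
        if ok:
            validate_observation(obs)
        else:
            with pytest.raises(ValidationError):
                validate_observation(obs)

    def test_negative_week_rejected(self):
        obs = MeasureObservation("P", Measure.OBVL_K, -1, Phase.A, 50.0)
        with pytest.raises(ValidationError):
            validate_observation(obs)

    def test_duplicate_participant_ids_rejected(self):
        ds = StudyDataset([ParticipantSeries("P1"), ParticipantSeries("P1")])
        with pytest.raises(ValidationError, match="unique"):
            validate_dataset(ds)


def _series(*rows, pid="P1"):
    return ParticipantSeries(
        pid,
        observations=[MeasureObservation(pid, m, w, ph, v) for m, w, ph, v in rows],
    )


class TestExtractPhase:
    def test_no_matching_phase_gives_empty(self):
        series = _series((Measure.OBVL_K, 0, Phase.B, 50.0))
        assert extract_phase(series, Measure.OBVL_K, {Phase.A}) == []

    def test_missing_values_dropped(self):
        series = _series(
            (Measure.OBVL_K, 0, Phase.A, 50.0),
            (Measure.OBVL_K, 1, Phase.A, None),
            (Measure.OBVL_K, 2, Phase.A, 52.0),
            (Measure.OBVL_K, 3, Phase.A, 51.0),
        )
        assert extract_phase(series, Measure.OBVL_K, {Phase.A}) == [50.0, 52.0, 51.0]

    @given(weeks=st.permutations(list(range(6))))
    @settings(deadline=None)
    def test_output_ordered_by_week_regardless_of_row_order(self, weeks):
        series = ParticipantSeries(
            "P1",
            observations=[
                MeasureObservation("P1", Measure.OBVL_K, w, Phase.A, float(w))
                for w in weeks
            ],
        )
        got = extract_phase(series, Measure.OBVL_K, {Phase.A})
        assert got == sorted(got)

    def test_phase_sets_partition_weekly_observations(self):
        series = _series(
            (Measure.OBVL_K, 0, Phase.A, 1.0),
            (Measure.OBVL_K, 4, Phase.B, 2.0),
            (Measure.OBVL_K, 7, Phase.B2, 3.0),
        )
        a = extract_phase(series, Measure.OBVL_K, {Phase.A})
        b = extract_phase(series, Measure.OBVL_K, {Phase.B, Phase.B2})
        both = extract_phase(series, Measure.OBVL_K,
                             {Phase.A, Phase.B, Phase.B2})
        assert sorted(a + b) == sorted(both)


class TestRoundTrip:
    def test_csv_round_trip_is_identity(self, tmp_path, simulated_dataset):
        path = tmp_path / "out.csv"
        write_long_csv(simulated_dataset, path)
        back = read_long_csv(path)
        assert back.participant_ids == sorted(simulated_dataset.participant_ids)
        for series in simulated_dataset.participants:
            other = back.participant(series.participant_id)
            assert other.dropout_status is series.dropout_status
            assert other.observations == series.observations

    def test_json_round_trip_preserves_sessions_and_design(
        self, tmp_path, simulated_dataset
    ):
        path = tmp_path / "out.json"
        dataset_to_json(simulated_dataset, path)
        back = dataset_from_json(path)
        assert back.design == simulated_dataset.design
        assert back.session_records == simulated_dataset.session_records
        for series in simulated_dataset.participants:
            assert back.participant(series.participant_id).observations == \
                series.observations

    def test_empty_dataset_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_long_csv(StudyDataset(), path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_single_observation_writes_two_lines(self, tmp_path):
        ds = StudyDataset([_series((Measure.OBVL_K, 0, Phase.A, 50.0))])
        path = tmp_path / "one.csv"
        write_long_csv(ds, path)
        assert len(path.read_text().strip().splitlines()) == 2
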