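"""Label mapping, the inter-patient split, count tables and record I/O."""

import logging

import numpy as np
import pytest

from focalbeat import (
    AAMIClass,
    EcgRecord,
    SyntheticConfig,
    generate_record,
    load_record,
    map_annotation_symbol,
    prepare_dataset,
    split_inter_patient,
    summarize_counts,
    write_record,
)
from focalbeat.mitdb_io import DS1_RECORDS, DS2_RECORDS, PACED_RECORDS

from wfdb_writer import write_record as write_wfdb_record

ALL_48_RECORDS = [
    "100", "101", "102", "103", "104", "105", "106", "107", "108", "109",
    "111", "112", "113", "114", "115", "116", "117", "118", "119", "121",
    "122", "123", "124", "200", "201", "202", "203", "205", "207", "208",
    "209", "210", "212", "213", "214", "215", "217", "219", "220", "221",
    "222", "223", "228", "230", "231", "232", "233", "234",
]


class TestSymbolMapping:
    @pytest.mark.parametrize(
        "symbol,expected",
        [
            ("N", AAMIClass.N), ("L", AAMIClass.N), ("R", AAMIClass.N),
            ("e", AAMIClass.N), ("j", AAMIClass.N),
            ("A", AAMIClass.SVEB), ("a", AAMIClass.SVEB), ("J", AAMIClass.SVEB),
            ("S", AAMIClass.SVEB),
            ("V", AAMIClass.VEB), ("E", AAMIClass.VEB),
            ("F", AAMIClass.F),
            ("Q", None), ("f", None), ("/", None),
        ],
    )
    def test_aami_mapping_table(self, symbol, expected):
        assert map_annotation_symbol(symbol) is expected

    def test_unknown_symbol_excluded_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert map_annotation_symbol("x") is None
        assert "x" in caplog.text

    def test_class_index_order_is_fixed(self):
        assert [c.value for c in AAMIClass] == [0, 1, 2, 3]
        assert [c.name for c in AAMIClass] == ["N", "SVEB", "VEB", "F"]


class TestSplit:
    def test_full_database_splits_22_22(self):
        ds1, ds2 = split_inter_patient(ALL_48_RECORDS)
        assert len(ds1) == 22 and len(ds2) == 22
        assert set(ds1) == set(DS1_RECORDS) and set(ds2) == set(DS2_RECORDS)
        assert not set(ds1) & set(ds2)

    @pytest.mark.parametrize("paced", PACED_RECORDS)
    def test_paced_records_in_neither_split(self, paced):
        ds1, ds2 = split_inter_patient([paced])
        assert ds1 == [] and ds2 == []

    def test_empty_input_gives_empty_splits(self):
        assert split_inter_patient([]) == ([], [])

    def test_unknown_ids_reported_not_placed(self, caplog):
        with caplog.at_level(logging.WARNING):
            ds1, ds2 = split_inter_patient(["999", "101"])
        assert ds1 == ["101"] and ds2 == []
        assert "999" in caplog.text


class TestCounts:
    def test_small_table(self):
        beats = [("101", AAMIClass.N)] * 3 + [("100", AAMIClass.VEB)] * 2 + [
            ("101", AAMIClass.F)
        ]
        table = summarize_counts(beats)
        assert table.loc["DS1", "N"] == 3 and table.loc["DS1", "F"] == 1
        assert table.loc["DS2", "VEB"] == 2
        assert table.loc["Total", "Total"] == 6

    def test_row_totals_equal_class_sums(self, rng):
        records = list(DS1_RECORDS[:3]) + list(DS2_RECORDS[:3])
        beats = [
            (records[rng.integers(6)], AAMIClass(rng.integers(4)))
            for _ in range(500)
        ]
        table = summarize_counts(beats)
        cols = ["N", "SVEB", "VEB", "F"]
        assert (table[cols].sum(axis=1) == table["Total"]).all()
        assert (
            table.loc["DS1", cols] + table.loc["DS2", cols] == table.loc["Total", cols]
        ).all()

    def test_empty_input_gives_zero_table(self):
        assert summarize_counts([]).to_numpy().sum() == 0


class TestRecordValidation:
    def test_non_increasing_annotations_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            EcgRecord("x", 360.0, np.zeros(100), [(5, "N"), (5, "N")])

    def test_out_of_range_annotation_rejected(self):
        with pytest.raises(ValueError, match="within"):
            EcgRecord("x", 360.0, np.zeros(100), [(150, "N")])


class TestSyntheticDialect:
    def test_round_trip_preserves_samples_and_annotations(self, tmp_path):
        rec = generate_record(SyntheticConfig(duration_s=20.0, seed=4))
        csv_path, _ = write_record(rec, tmp_path)
        loaded = load_record(csv_path)
        assert loaded.record_id == rec.record_id
        assert loaded.sampling_rate_hz == rec.sampling_rate_hz
        assert loaded.signal.size == rec.signal.size
        assert loaded.annotations == rec.annotations
        assert np.allclose(loaded.signal, rec.signal, atol=5e-7)  # %.6f text

    def test_missing_record_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope"):
            load_record(tmp_path / "nope")


class TestWfdbReader:
    @pytest.fixture
    def wfdb_record(self, tmp_path, rng):
        base = tmp_path / "t01"
        signal = np.round(rng.normal(0.0, 0.4, size=(5000, 2)), 3)
        samples = [100, 400, 900, 1500, 2200, 3000, 3900, 4500]
        # includes paced (/), noise (~) and rhythm (+) annotations
        symbols = ["N", "L", "V", "A", "/", "F", "~", "+"]
        write_wfdb_record(base, signal, 360.0, ["MLII", "V1"], samples, symbols)
        return base, signal, samples, symbols

    def test_round_trip_against_independent_writer(self, wfdb_record):
        base, signal, samples, symbols = wfdb_record
        rec = load_record(base, lead_name="MLII")
        assert rec.sampling_rate_hz == 360.0
        # format 212 quantizes at 1/gain = 5e-3 mV steps
        assert np.abs(rec.signal - signal[:, 0]).max() <= 0.5 / 200.0 + 1e-12
        beat = [(s, sym) for s, sym in zip(samples, symbols) if sym not in "~+"]
        assert rec.annotations == beat  # non-beat annotations dropped

    def test_second_lead_is_selectable(self, wfdb_record):
        base, signal, *_ = wfdb_record
        rec = load_record(base, lead_name="V1")
        assert np.abs(rec.signal - signal[:, 1]).max() <= 0.5 / 200.0 + 1e-12

    def test_missing_lead_error_lists_available(self, wfdb_record):
        base, *_ = wfdb_record
        with pytest.raises(ValueError, match="MLII.*V1"):
            load_record(base, lead_name="V9")

    def test_long_gaps_use_skip_encoding(self, tmp_path, rng):
        base = tmp_path / "t02"
        signal = np.round(rng.normal(0.0, 0.3, size=(250000, 1)), 3)
        samples, symbols = [10, 70000, 200000], ["N", "V", "N"]
        write_wfdb_record(base, signal, 360.0, ["MLII"], samples, symbols)
        rec = load_record(base)
        assert rec.annotations == list(zip(samples, symbols))


class TestPrepareDataset:
    def test_arrays_are_aligned_and_shaped(self):
        recs = [generate_record(SyntheticConfig(duration_s=30.0, seed=s)) for s in (1, 2)]
        data = prepare_dataset(recs)
        n = data["labels"].size
        assert data["segments"].shape == (n, 200)
        assert data["rr"].shape == (n, 4)
        assert data["record_ids"].shape == (n,)
        total_beats = sum(len(r.annotations) for r in recs)
        assert n + int(data["n_dropped"]) == total_beats
        assert set(np.unique(data["labels"])) <= {0, 1, 2, 3}
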