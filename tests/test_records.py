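"""Data model, table parsing and binary pattern encoding."""

import numpy as np
import pytest

from damlitter import (
    GrowthClass,
    IsolationRecord,
    MatrixType,
    ParseError,
    SampleMeta,
    SubjectRole,
    TimePoint,
    ValidationError,
    canonicalize_genus,
    classify_growth,
    encode_presence,
    isolation_frequency,
    read_records,
    write_records,
)


class TestClassifyGrowth:
    @pytest.mark.parametrize("cfu,expected", [
        (0, GrowthClass.NO_GROWTH),
        (1, GrowthClass.LOW),
        (5, GrowthClass.LOW),
        (10, GrowthClass.LOW),
        (11, GrowthClass.MODERATE),
        (30, GrowthClass.MODERATE),
        (31, GrowthClass.HIGH),
        (500, GrowthClass.HIGH),
    ])
    def test_cfu_boundaries(self, cfu, expected):
        assert classify_growth(cfu) is expected

    @pytest.mark.parametrize("bad", [-1, 2.5, "10", None, True])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValidationError):
            classify_growth(bad)


class TestCanonicalizeGenus:
    @pytest.mark.parametrize("raw,expected", [
        ("clostridium", "Clostridium"),
        ("  Proteus   spp. ", "Proteus"),
        ("Enterococcus sp.", "Enterococcus"),
        ("STREPTOCOCCUS", "Streptococcus"),
        ("escherichia\t coli".replace(" coli", ""), "Escherichia"),
    ])
    def test_normalization(self, raw, expected):
        assert canonicalize_genus(raw) == expected

    def test_synonym_map_applied(self):
        assert canonicalize_genus("E. coli", {"E. coli": "Escherichia"}) == "Escherichia"

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            canonicalize_genus("   ")


class TestSampleMeta:
    def test_meconium_only_puppy_at_birth(self):
        with pytest.raises(ValidationError):
            SampleMeta("x", "F", "d", SubjectRole.DAM,
                       MatrixType.MECONIUM, TimePoint.T0)
        with pytest.raises(ValidationError):
            SampleMeta("x", "F", "p", SubjectRole.PUPPY,
                       MatrixType.MECONIUM, TimePoint.T30)

    def test_dam_matrices_restricted_to_t0_t2(self):
        with pytest.raises(ValidationError):
            SampleMeta("x", "F", "d", SubjectRole.DAM,
                       MatrixType.VAGINAL, TimePoint.T60)
        with pytest.raises(ValidationError):
            SampleMeta("x", "F", "p", SubjectRole.PUPPY,
                       MatrixType.MAMMARY_SECRETION, TimePoint.T0)
        # valid combination passes
        SampleMeta("x", "F", "d", SubjectRole.DAM,
                   MatrixType.MAMMARY_SECRETION, TimePoint.T2)


class TestReadRecords:
    def test_toy_echo(self, toy_csv):
        samples, records = read_records(toy_csv)
        assert len(samples) == 2 and len(records) == 2
        assert {r.genus for r in records} == {"Escherichia", "Proteus"}
        s2 = next(s for s in samples if s.sample_id == "s2")
        assert s2.subject_role is SubjectRole.DAM

    def test_genus_synonym_map(self, tmp_path):
        path = tmp_path / "syn.csv"
        path.write_text(
            "sample_id,family_id,subject_id,subject_role,matrix,time_point,genus\n"
            "s1,A,p1,puppy,rectal,T2,E. coli\n")
        _, records = read_records(path, genus_synonyms={"E. coli": "Escherichia"})
        assert records[0].genus == "Escherichia"

    def test_unknown_time_label_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,family_id,subject_id,subject_role,matrix,time_point,genus\n"
            "s1,A,p1,puppy,rectal,T2,Proteus\n"
            "s2,A,p1,puppy,rectal,T15,Proteus\n")
        with pytest.raises(ParseError, match="row 2.*T15"):
            read_records(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,genus\ns1,Proteus\n")
        with pytest.raises(ParseError, match="missing required column"):
            read_records(path)

    def test_conflicting_duplicate_metadata(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sample_id,family_id,subject_id,subject_role,matrix,time_point,genus\n"
            "s1,A,p1,puppy,rectal,T2,Proteus\n"
            "s1,B,p1,puppy,rectal,T2,Escherichia\n")
        with pytest.raises(ParseError, match="conflicting"):
            read_records(path)

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(
            "sample_id\tfamily_id\tsubject_id\tsubject_role\tmatrix\ttime_point\tgenus\n"
            "s1\tA\tp1\tpuppy\trectal\tT2\tProteus\n")
        samples, records = read_records(path)
        assert len(samples) == 1 and records[0].genus == "Proteus"


class TestEncodePresence:
    def _samples(self, ids):
        return [SampleMeta(i, "A", "p1", SubjectRole.PUPPY,
                           MatrixType.RECTAL, TimePoint.T2) for i in ids]

    def test_direct_encoding_with_universe(self):
        records = [IsolationRecord("s1", "Escherichia"),
                   IsolationRecord("s1", "Proteus")]
        m = encode_presence(records, self._samples(["s1"]),
                            ["Clostridium", "Escherichia", "Proteus"])
        assert m.row("s1").tolist() == [0, 1, 1]

    def test_presence_idempotent_across_species(self):
        records = [IsolationRecord("s1", "Clostridium", species="perfringens"),
                   IsolationRecord("s1", "Clostridium", species="difficile")]
        m = encode_presence(records, self._samples(["s1"]))
        assert m.values.sum() == 1

    def test_sample_without_records_gets_zero_row(self):
        records = [IsolationRecord("s1", "Proteus")]
        m = encode_presence(records, self._samples(["s1", "s2"]))
        assert m.row("s2").sum() == 0

    def test_orphan_record_rejected_by_id(self):
        with pytest.raises(ValidationError, match="ghost"):
            encode_presence([IsolationRecord("ghost", "Proteus")],
                            self._samples(["s1"]))

    def test_order_independent(self, rng):
        ids = [f"s{i}" for i in range(5)]
        genera = ["Proteus", "Escherichia", "Clostridium", "Enterococcus"]
        records = [IsolationRecord(ids[int(i)], genera[int(j)])
                   for i, j in rng.integers(0, [5, 4], size=(30, 2))]
        samples = self._samples(ids)
        base = encode_presence(records, samples)
        perm = [records[k] for k in rng.permutation(len(records))]
        again = encode_presence(perm, samples)
        assert base.sample_ids == again.sample_ids
        assert base.genera == again.genera
        assert (base.values == again.values).all()

    def test_universe_missing_observed_genus(self):
        with pytest.raises(ValidationError, match="Proteus"):
            encode_presence([IsolationRecord("s1", "Proteus")],
                            self._samples(["s1"]), ["Clostridium"])


class TestRoundTrips:
    def test_records_roundtrip_preserves_presence(self, tmp_path, convergent_dataset):
        samples, records, _, matrix = convergent_dataset
        path = tmp_path / "rt.csv"
        write_records(samples, records, path)
        samples2, records2 = read_records(path)
        again = encode_presence(records2, samples2,
                                genus_universe=matrix.genera)
        assert again.sample_ids == matrix.sample_ids
        assert (again.values == matrix.values).all()

    def test_presence_tsv_roundtrip(self, tmp_path, convergent_dataset):
        *_, matrix = convergent_dataset
        path = tmp_path / "m.tsv"
        matrix.to_tsv(path)
        again = type(matrix).from_tsv(path)
        assert again.sample_ids == matrix.sample_ids
        assert again.genera == matrix.genera
        assert (again.values == matrix.values).all()


class TestIsolationFrequency:
    def _mammary(self, n, positive, tp=TimePoint.T0):
        samples = [SampleMeta(f"c{i}", f"F{i}", f"d{i}", SubjectRole.DAM,
                              MatrixType.MAMMARY_SECRETION, tp)
                   for i in range(n)]
        records = [IsolationRecord(f"c{i}", "Escherichia")
                   for i in range(positive)]
        return samples, records

    def test_half_positive_is_fifty_percent(self):
        samples, records = self._mammary(6, 3)
        m = encode_presence(records, samples, ["Escherichia", "Proteus"])
        tab = isolation_frequency(m, samples)
        assert tab.loc["Escherichia", "count"] == 3
        assert tab.loc["Escherichia", "percent"] == 50.0

    def test_absent_and_ubiquitous_genera(self):
        samples, records = self._mammary(4, 4)
        m = encode_presence(records, samples, ["Escherichia", "Proteus"])
        tab = isolation_frequency(m, samples)
        assert tab.loc["Proteus", "count"] == 0
        assert tab.loc["Proteus", "percent"] == 0.0
        assert tab.loc["Escherichia", "percent"] == 100.0

    def test_empty_selection_rejected(self):
        samples, records = self._mammary(3, 1)
        m = encode_presence(records, samples, ["Escherichia"])
        with pytest.raises(ValidationError):
            isolation_frequency(m, samples, lambda s: False)

    def test_counts_match_column_sums(self, convergent_dataset):
        samples, _, _, matrix = convergent_dataset
        tab = isolation_frequency(matrix, samples)
        assert (tab["count"].to_numpy() == matrix.values.sum(axis=0)).all()
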