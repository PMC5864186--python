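"""Hit-table parsing, validity filtering and hits/Mb profile computation."""

import numpy as np
import pandas as pd
import pytest

from ecosig import (
    HitRecord,
    HitTable,
    HitTableParseError,
    MetagenomeMeta,
    ProfileMatrix,
    compute_profile,
    cumulative_abundance,
    filter_min_orf_representation,
    is_valid_hit,
    read_hit_table,
    read_lengths,
    read_metadata,
)


def make_hit(query="read1", orf="ORF_16", identity=80.0, qstart=1, qend=100,
             evalue=1e-20, bits=100.0):
    return HitRecord(
        query_id=query, subject_id=orf, percent_identity=identity,
        alignment_length=qend - qstart + 1, mismatches=0, gap_opens=0,
        query_start=qstart, query_end=qend, subject_start=1,
        subject_end=qend - qstart + 1, evalue=evalue, bit_score=bits,
    )


class TestReadHitTable:
    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("# only a comment\n\n")
        table = read_hit_table(path, "read_query")
        assert len(table) == 0 and table.orientation == "read_query"

    def test_fields_mapped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("read1\tORF_16\t40.0\t50\t30\t0\t1\t150\t1\t50\t1e-10\t80.1\n")
        (hit,) = read_hit_table(path, "read_query").hits
        assert hit.query_id == "read1"
        assert hit.subject_id == "ORF_16"
        assert hit.percent_identity == 40.0
        assert hit.alignment_length == 50
        assert hit.query_start == 1 and hit.query_end == 150
        assert hit.evalue == 1e-10 and hit.bit_score == 80.1

    @pytest.mark.parametrize(
        "row",
        [
            "read1\tORF_16\t40.0\t50\t30\t0\t1\t150\t1\t50\t1e-10",  # 11 cols
            "read1\tORF_16\tnot_a_number\t50\t30\t0\t1\t150\t1\t50\t1e-10\t80.1",
        ],
    )
    def test_malformed_row_names_line(self, tmp_path, row):
        path = tmp_path / "hits.tsv"
        path.write_text("# header\n" + row + "\n")
        with pytest.raises(HitTableParseError, match="line 2"):
            read_hit_table(path, "read_query")

    def test_orientation_validated(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            read_hit_table(path, "sideways")


class TestValidity:
    @pytest.mark.parametrize(
        "identity,qstart,qend,length,evalue,expected",
        [
            (35.0, 1, 50, 100, 1e-5, True),    # every threshold exactly met
            (34.9, 1, 90, 100, 1e-20, False),  # identity just below
            (90.0, 1, 49, 100, 1e-20, False),  # coverage just below
            (90.0, 1, 90, 100, 1.1e-5, False), # e-value just above
            (35.0, 51, 100, 100, 1e-5, True),  # coverage from interior window
        ],
    )
    def test_boundaries_inclusive(self, identity, qstart, qend, length, evalue, expected):
        hit = make_hit(identity=identity, qstart=qstart, qend=qend, evalue=evalue)
        assert is_valid_hit(hit, length) is expected

    def test_unknown_length_errors(self):
        with pytest.raises(ValueError):
            is_valid_hit(make_hit(), None)


class TestComputeProfile:
    ORFS = ["ORF_16", "ORF_34", "ORF_56"]

    def test_hand_counted_abundances(self, simple_meta):
        hits = [make_hit(query=f"r{i}", orf="ORF_16") for i in range(3)]
        hits.append(make_hit(query="r9", orf="ORF_34"))
        profile = compute_profile(
            HitTable(hits, "read_query"),
            query_lengths={h.query_id: 100 for h in hits},
            orf_ids=self.ORFS,
            meta=simple_meta,
        )
        assert profile.abundances["ORF_16"] == pytest.approx(1.5)
        assert profile.abundances["ORF_34"] == pytest.approx(0.5)
        assert profile.abundances["ORF_56"] == 0.0
        assert profile.cumulative == pytest.approx(2.0)

    def test_no_valid_hits_gives_zero_profile(self, simple_meta):
        hits = [make_hit(identity=20.0)]
        profile = compute_profile(
            HitTable(hits, "read_query"),
            query_lengths={"read1": 100},
            orf_ids=self.ORFS,
            meta=simple_meta,
        )
        assert profile.cumulative == 0.0

    def test_scale_invariance(self):
        hits = [make_hit(query=f"r{i}") for i in range(4)]
        lengths = {h.query_id: 100 for h in hits}
        p1 = compute_profile(HitTable(hits, "read_query"), lengths, self.ORFS,
                             MetagenomeMeta("d", "env_virome", 1e6))
        p2 = compute_profile(HitTable(hits, "read_query"), lengths, self.ORFS,
                             MetagenomeMeta("d", "env_virome", 3e6))
        assert np.allclose(p1.abundances.values, 3.0 * p2.abundances.values)

    def test_duplicate_hsp_collapses(self, simple_meta):
        hit = make_hit()
        weaker = make_hit(evalue=1e-8, bits=50.0)
        once = compute_profile(HitTable([hit], "read_query"), {"read1": 100},
                               self.ORFS, simple_meta)
        dup = compute_profile(HitTable([hit, hit, weaker], "read_query"),
                              {"read1": 100}, self.ORFS, simple_meta)
        pd.testing.assert_series_equal(once.abundances, dup.abundances)

    def test_multi_orf_query_counts_once_per_orf(self, simple_meta):
        hits = [make_hit(orf="ORF_16"), make_hit(orf="ORF_34", bits=90.0)]
        profile = compute_profile(HitTable(hits, "read_query"), {"read1": 100},
                                  self.ORFS, simple_meta)
        assert profile.abundances["ORF_16"] == pytest.approx(0.5)
        assert profile.abundances["ORF_34"] == pytest.approx(0.5)

    def test_best_orf_only_switch(self, simple_meta):
        hits = [make_hit(orf="ORF_16", evalue=1e-30),
                make_hit(orf="ORF_34", evalue=1e-20)]
        profile = compute_profile(HitTable(hits, "read_query"), {"read1": 100},
                                  self.ORFS, simple_meta, best_orf_only=True)
        assert profile.abundances["ORF_16"] == pytest.approx(0.5)
        assert profile.abundances["ORF_34"] == 0.0

    def test_orf_outside_universe_errors(self, simple_meta):
        with pytest.raises(KeyError, match="ORF_99"):
            compute_profile(HitTable([make_hit(orf="ORF_99")], "read_query"),
                            {"read1": 100}, self.ORFS, simple_meta)

    def test_missing_length_errors(self, simple_meta):
        with pytest.raises(KeyError, match="read1"):
            compute_profile(HitTable([make_hit()], "read_query"), {},
                            self.ORFS, simple_meta)

    def test_orf_query_orientation_counts_subjects(self, simple_meta):
        # tBlastn-style: the phage ORF is the query, contigs are subjects
        hits = [
            HitRecord("ORF_16", f"contig{i}", 80.0, 200, 0, 0, 1, 200, 1, 600,
                      1e-30, 300.0)
            for i in range(2)
        ]
        profile = compute_profile(HitTable(hits, "orf_query"), {"ORF_16": 250},
                                  self.ORFS, simple_meta)
        assert profile.abundances["ORF_16"] == pytest.approx(1.0)


class TestCumulativeAndFilter:
    def test_cumulative_subset(self, tiny_matrix):
        p = tiny_matrix.profile("a")
        assert cumulative_abundance(p, ["ORF_1", "ORF_2"]) == pytest.approx(2.0)
        assert cumulative_abundance(p, []) == 0.0
        assert cumulative_abundance(p) == pytest.approx(2.0)

    def test_cumulative_unknown_orf_errors(self, tiny_matrix):
        with pytest.raises(KeyError):
            cumulative_abundance(tiny_matrix.profile("a"), ["ORF_9"])

    def test_min_orf_representation(self, tiny_matrix):
        kept = filter_min_orf_representation(tiny_matrix, 2)
        assert kept.dataset_ids == ["a"]
        kept1 = filter_min_orf_representation(tiny_matrix, 1)
        assert kept1.dataset_ids == ["a", "b", "c"]
        identity = filter_min_orf_representation(tiny_matrix, 0)
        assert identity.dataset_ids == tiny_matrix.dataset_ids

    def test_all_zero_profile_removed(self):
        data = pd.DataFrame({"ORF_1": [0.0, 1.0], "ORF_2": [0.0, 1.0]},
                            index=["z", "ok"])
        kept = filter_min_orf_representation(ProfileMatrix(data), 2)
        assert kept.dataset_ids == ["ok"]


class TestIO:
    def test_lengths_tsv_and_fasta(self, tmp_path):
        tsv = tmp_path / "lengths.tsv"
        tsv.write_text("read1\t100\nread2\t151\n")
        assert read_lengths(tsv) == {"read1": 100, "read2": 151}
        fasta = tmp_path / "orfs.faa"
        fasta.write_text(">ORF_1 desc\nMKV\n>ORF_2\nMKVLNNN\n")
        assert read_lengths(fasta) == {"ORF_1": 3, "ORF_2": 7}

    def test_metadata_roundtrip(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text(
            "dataset_id,habitat_group,total_bp,assembled\n"
            "d1,env_virome,2000000,False\n"
        )
        meta = read_metadata(path)
        assert meta.loc["d1", "total_bp"] == 2000000

    def test_metadata_rejects_duplicates(self, tmp_path):
        path = tmp_path / "meta.csv"
        path.write_text(
            "dataset_id,habitat_group,total_bp\nd1,a,10\nd1,b,20\n"
        )
        with pytest.raises(ValueError):
            read_metadata(path)

    def test_profile_matrix_csv_roundtrip(self, tmp_path, tiny_matrix):
        path = tmp_path / "profiles.csv"
        tiny_matrix.to_csv(path)
        back = ProfileMatrix.read_csv(path)
        pd.testing.assert_frame_equal(back.data, tiny_matrix.data,
                                      check_names=False)
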