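"""I/O round trips, coordinate conventions and validation errors."""

import pytest

from transcurate.seqio import (Contig, SplicedAlignment, read_blast_tab,
                               read_fasta, read_spliced_gff3, read_taxa,
                               revcomp, write_fasta, write_report,
                               write_spliced_gff3)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "a" and recs[0].length == 4

    def test_case_normalization(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacgt\n>b\nNNN\n")
        recs = read_fasta(p)
        assert [r.seq for r in recs] == ["ACGT", "NNN"]

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a desc\nAC\n>a\nGG\n")
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(p)

    def test_non_iupac_character_reports_line(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>b\nAC1T\n")
        with pytest.raises(ValueError, match="line 4"):
            read_fasta(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert read_fasta(p) == []

    def test_round_trip(self, tmp_path):
        recs = [Contig("c1", "ACGTACGT" * 30, description="note"),
                Contig("c2", "NNACGT")]
        p = tmp_path / "out.fasta"
        write_fasta(recs, p, width=17)
        back = read_fasta(p)
        assert [(r.id, r.seq, r.description) for r in back] == \
               [(r.id, r.seq, r.description) for r in recs]

    def test_revcomp(self):
        assert revcomp("ACGTN") == "NACGT"


class TestBlastTab:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("c1\tp1\t70.00\t33\t10\t0\t1\t99\t1\t33\t1e-04\t60.1\n")
        (h,) = read_blast_tab(p)
        assert (h.query_id, h.subject_id) == ("c1", "p1")
        assert h.pct_identity == 70.0 and h.aln_len == 33
        assert h.evalue == 1e-4 and h.strand == "+"

    def test_minus_strand_normalized(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("c1\tp1\t90\t50\t5\t0\t1\t150\t90\t10\t1e-9\t80\n")
        (h,) = read_blast_tab(p)
        assert (h.s_start, h.s_end, h.strand) == (10, 90, "-")

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("c1\tp1\t70\t33\t10\t0\t1\t99\t1\t33\t1e-04\n")
        with pytest.raises(ValueError, match="row 1"):
            read_blast_tab(p)

    def test_unparsable_numeric(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("c1\tp1\tseventy\t33\t10\t0\t1\t99\t1\t33\t1e-4\t60\n")
        with pytest.raises(ValueError, match="row 1"):
            read_blast_tab(p)


GFF = """##gff-version 3
chr1\tgth\tmatch\t1\t300\t.\t+\t.\tID=m1;Target=c1
chr1\tgth\tmatch_part\t1\t100\t.\t+\t.\tParent=m1;Target=c1 1 100
chr1\tgth\tmatch_part\t201\t300\t.\t+\t.\tParent=m1;Target=c1 101 200
"""


class TestSplicedGff3:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "aln.gff3"
        p.write_text(GFF)
        (aln,) = read_spliced_gff3(p)
        assert [(b[0], b[1]) for b in aln.blocks] == [(0, 100), (200, 300)]
        assert [(b[2], b[3]) for b in aln.blocks] == [(0, 100), (100, 200)]
        assert aln.contig_id == "c1" and aln.target_id == "chr1"

    def test_cdna_match_synonym(self, tmp_path):
        p = tmp_path / "aln.gff3"
        p.write_text(GFF.replace("\tmatch\t", "\tcDNA_match\t"))
        (aln,) = read_spliced_gff3(p)
        assert len(aln.blocks) == 2

    def test_match_part_without_target(self, tmp_path):
        p = tmp_path / "aln.gff3"
        p.write_text("chr1\t.\tmatch\t1\t50\t.\t+\t.\tID=m1\n"
                     "chr1\t.\tmatch_part\t1\t50\t.\t+\t.\tParent=m1\n")
        with pytest.raises(ValueError, match="Target"):
            read_spliced_gff3(p)

    def test_child_without_parent(self, tmp_path):
        p = tmp_path / "aln.gff3"
        p.write_text("chr1\t.\tmatch_part\t1\t50\t.\t+\t.\t"
                     "Parent=ghost;Target=c1 1 50\n")
        with pytest.raises(ValueError, match="ghost"):
            read_spliced_gff3(p)

    def test_overlapping_blocks_rejected(self, tmp_path):
        p = tmp_path / "aln.gff3"
        p.write_text("chr1\t.\tmatch\t1\t150\t.\t+\t.\tID=m1;Target=c1\n"
                     "chr1\t.\tmatch_part\t1\t100\t.\t+\t.\t"
                     "Parent=m1;Target=c1 1 100\n"
                     "chr1\t.\tmatch_part\t50\t150\t.\t+\t.\t"
                     "Parent=m1;Target=c1 101 201\n")
        with pytest.raises(ValueError, match="overlap"):
            read_spliced_gff3(p)

    def test_round_trip_preserves_blocks_and_coords(self, tmp_path):
        aln = SplicedAlignment("c9", "chr2", "-",
                               [(10, 110, 0, 100, 98.5),
                                (200, 260, 100, 160, 100.0)])
        p = tmp_path / "out.gff3"
        write_spliced_gff3([aln], p)
        (back,) = read_spliced_gff3(p)
        assert [(b[0], b[1], b[2], b[3]) for b in back.blocks] == \
               [(b[0], b[1], b[2], b[3]) for b in aln.blocks]
        assert back.strand == "-"
        # external serialization is 1-based inclusive
        lines = [l for l in p.read_text().splitlines() if "match_part" in l]
        assert lines[0].split("\t")[3:5] == ["11", "110"]


class TestReport:
    def test_row_count_and_determinism(self, tmp_path):
        rows = [{"id": "b", "x": 1.23456}, {"id": "a", "x": 2.0}]
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_report(rows, p1)
        write_report(list(reversed(rows)), p2)
        assert p1.read_bytes() == p2.read_bytes()
        lines = p1.read_text().splitlines()
        assert len(lines) == 3 and lines[1].startswith("a\t")

    def test_empty_rows_warn(self, tmp_path):
        with pytest.warns(UserWarning):
            write_report([], tmp_path / "r.tsv")


def test_read_taxa(tmp_path):
    p = tmp_path / "taxa.tsv"
    p.write_text("subject_id\ttaxon_class\np1\tant\nv1\tmicroorganism\n")
    assert read_taxa(p) == {"p1": "ant", "v1": "microorganism"}
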