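"""Parsing of annotations, domain/disorder tables and result round-trips."""

import math
import random

import pytest

from xdc import annotation_io as aio
from xdc.models import GenomeSummary, AlignmentCounts

from conftest import gtf_line, make_gtf


class TestReadAnnotation:
    def test_two_exon_plus_strand(self, tmp_path):
        path = make_gtf(
            tmp_path,
            [gtf_line("c1", 1, 99, "+"), gtf_line("c1", 200, 301, "+")],
        )
        (t,) = aio.read_annotation(path, "GTF")
        assert t.cds_exons == [(1, 99), (200, 301)]
        assert t.total_cds_nt == 201
        # 201 nt = 67 codons; final codon is the stop -> 66 residues
        assert t.protein_length == 66

    def test_minus_strand_reverses_exon_order(self, tmp_path):
        path = make_gtf(
            tmp_path,
            [gtf_line("c1", 1, 99, "-"), gtf_line("c1", 200, 301, "-")],
        )
        (t,) = aio.read_annotation(path, "GTF")
        assert t.cds_exons == [(200, 301), (1, 99)]

    def test_stop_not_included(self, tmp_path):
        path = make_gtf(
            tmp_path,
            [gtf_line("c1", 1, 99, "+"), gtf_line("c1", 200, 301, "+")],
        )
        (t,) = aio.read_annotation(path, "GTF", stop_included=False)
        assert t.protein_length == 67

    def test_empty_file(self, tmp_path):
        assert aio.read_annotation(make_gtf(tmp_path, []), "GTF") == []

    def test_non_mod3_transcript_dropped(self, tmp_path, caplog):
        path = make_gtf(
            tmp_path,
            [gtf_line("c1", 1, 100, "+"), gtf_line("c1", 200, 301, "+")],
        )
        assert aio.read_annotation(path, "GTF") == []
        assert "not a multiple of 3" in caplog.text

    def test_missing_protein_id_skips_with_warning(self, tmp_path, caplog):
        line = 'c1\tsynth\tCDS\t1\t102\t.\t+\t0\tgene_id "g"; transcript_id "t9";'
        assert aio.read_annotation(make_gtf(tmp_path, [line]), "GTF") == []
        assert "no protein id" in caplog.text

    def test_unparseable_line_reports_line_number(self, tmp_path):
        path = make_gtf(tmp_path, [gtf_line("c1", 1, 99, "+"), "garbage"])
        with pytest.raises(ValueError, match="line 2"):
            aio.read_annotation(path, "GTF")

    def test_bad_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            aio.read_annotation(make_gtf(tmp_path, []), "BED")

    def test_gff3_dialect(self, tmp_path):
        lines = [
            "c1\tsynth\tCDS\t1\t99\t.\t+\t0\tID=cds1;Parent=t1;protein_id=p1",
            "c1\tsynth\tCDS\t200\t301\t.\t+\t0\tID=cds2;Parent=t1;protein_id=p1",
        ]
        (t,) = aio.read_annotation(make_gtf(tmp_path, lines), "GFF3")
        assert t.protein_id == "p1"
        assert t.cds_exons == [(1, 99), (200, 301)]

    def test_line_order_independence(self, tmp_path):
        lines = [
            gtf_line("c1", 1, 99, "+", tid="tA", pid="pA"),
            gtf_line("c1", 200, 301, "+", tid="tA", pid="pA"),
            gtf_line("c2", 50, 151, "-", tid="tB", pid="pB"),
            gtf_line("c2", 300, 401, "-", tid="tB", pid="pB"),
        ]
        base = aio.read_annotation(make_gtf(tmp_path, lines, "a.gtf"), "GTF",
                                   genome_id="g")
        shuffled = lines[:]
        random.Random(0).shuffle(shuffled)
        other = aio.read_annotation(
            make_gtf(tmp_path, shuffled, "b.gtf"), "GTF", genome_id="g"
        )
        assert base == other

    def test_mirrored_minus_gene_same_exon_lengths(self, tmp_path):
        """A '-' strand annotation of a mirrored '+' gene yields the same
        exon-length sequence 5'->3'."""
        plus = [(1, 99), (200, 301), (400, 459)]
        M = 1000
        minus = [(M - e + 1, M - s + 1) for s, e in plus]
        p_lines = [gtf_line("c1", s, e, "+") for s, e in plus]
        m_lines = [gtf_line("c1", s, e, "-") for s, e in minus]
        (tp,) = aio.read_annotation(make_gtf(tmp_path, p_lines, "p.gtf"), "GTF")
        (tm,) = aio.read_annotation(make_gtf(tmp_path, m_lines, "m.gtf"), "GTF")
        assert tp.exon_nt_lengths == tm.exon_nt_lengths
        assert tp.protein_length == tm.protein_length


class TestDomainTable:
    def test_parse_drop_dedup(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            "protein_id\tdomain_id\tstart\tend\n"
            "P1\td.58.1\t10\t50\n"
            "P1\td.58.1\t10\t50\n"  # duplicate
            "P1\tb.1.1\t60\t150\n"  # beyond length 100
        )
        doms = aio.read_domains(path, protein_lengths={"P1": 100})
        assert len(doms) == 1
        assert (doms[0].domain_id, doms[0].start, doms[0].end) == ("d.58.1", 10, 50)

    def test_non_integer_coordinate_names_row(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("protein_id\tdomain_id\tstart\tend\nP1\tx\tten\t50\n")
        with pytest.raises(ValueError, match="row"):
            aio.read_domains(path)


class TestDisorderTable:
    def test_regions_mode(self, tmp_path):
        path = tmp_path / "dis.tsv"
        path.write_text("protein_id\tstart\tend\nP1\t20\t40\n")
        (r,) = aio.read_disorder(path, "regions")
        assert (r.protein_id, r.start, r.end, r.source) == ("P1", 20, 40, "consensus")

    def test_regions_merged_maximal(self, tmp_path):
        path = tmp_path / "dis.tsv"
        path.write_text("protein_id\tstart\tend\nP1\t20\t40\nP1\t41\t50\n")
        (r,) = aio.read_disorder(path, "regions")
        assert (r.start, r.end) == (20, 50)

    @pytest.mark.parametrize("n_called, expect_region", [(6, True), (5, False)])
    def test_per_predictor_consensus_threshold(self, tmp_path, n_called,
                                               expect_region):
        """6 of 8 predictors is exactly 75% -> disordered; 5 of 8 is not."""
        rows = ["protein_id\tstart\tend\tpredictor"]
        rows += [f"P1\t5\t10\tpred{i}" for i in range(n_called)]
        # remaining predictors appear elsewhere so the denominator is 8
        rows += [f"P2\t1\t3\tpred{i}" for i in range(8)]
        path = tmp_path / "dis.tsv"
        path.write_text("\n".join(rows) + "\n")
        regions = aio.read_disorder(
            path, "per_predictor", protein_lengths={"P1": 50, "P2": 50}
        )
        p1 = [r for r in regions if r.protein_id == "P1"]
        if expect_region:
            assert [(r.start, r.end) for r in p1] == [(5, 10)]
        else:
            assert p1 == []

    def test_per_predictor_call_outside_protein_errors(self, tmp_path):
        path = tmp_path / "dis.tsv"
        path.write_text("protein_id\tstart\tend\tpredictor\nP1\t5\t60\tpredA\n")
        with pytest.raises(ValueError, match="outside protein"):
            aio.read_disorder(path, "per_predictor", protein_lengths={"P1": 50})


class TestSummaryRoundTrip:
    @staticmethod
    def _summary(gid, observed, expected):
        counts = AlignmentCounts(
            scope="genome", cls="domain", observed=observed, expected=expected,
            n_boundaries=1000, n_window_residues=600, n_residues=10000,
            n_proteins=42,
        )
        return GenomeSummary(
            genome_id=gid, cls="domain", counts=counts,
            ratio=observed / expected, chi2=27.7777777778,
            p_value=1.38447939e-7, significant=True,
        )

    def test_ratio_in_file(self, tmp_path):
        path = tmp_path / "s.tsv"
        aio.write_genome_summary([self._summary("G1", 150, 100.0)], path)
        assert "\t1.5\t" in path.read_text()

    def test_empty_summary_header_only(self, tmp_path):
        path = tmp_path / "s.tsv"
        aio.write_genome_summary([], path)
        assert path.read_text().strip() == "\t".join(aio.SUMMARY_COLUMNS)

    def test_round_trip_10_significant_digits(self, tmp_path):
        path = tmp_path / "s.tsv"
        orig = [self._summary("G1", 150, 100.123456789012),
                self._summary("G2", 80, 123.4)]
        aio.write_genome_summary(orig, path)
        back = aio.read_genome_summary(path)
        assert len(back) == 2
        for a, b in zip(orig, back):
            assert a.genome_id == b.genome_id
            assert a.significant == b.significant
            for attr in ("ratio", "chi2", "p_value"):
                x, y = getattr(a, attr), getattr(b, attr)
                assert math.isclose(x, y, rel_tol=1e-10)
            assert math.isclose(a.counts.expected, b.counts.expected,
                                rel_tol=1e-10)
            assert a.counts.observed == b.counts.observed
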