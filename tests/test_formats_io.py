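import pytest

from fusionsieve.formats_io import (
    DialectError, GenomicBreakpoint, GtfParseError, read_caller_calls,
    read_canonical_calls, read_gtf, read_transcript_fasta, write_bedpe,
    write_canonical_calls, write_gtf, write_transcript_fasta,
)
from fusionsieve.consensus import ConsensusEvent

from conftest import make_call


class TestGtf:
    def test_minimal_coding_transcript(self, tmp_path):
        p = tmp_path / "t.gtf"
        attrs = 'gene_id "G1"; transcript_id "T1"; gene_name "G1";'
        p.write_text(
            f"chr1\tx\texon\t100\t200\t.\t+\t.\t{attrs}\n"
            f"chr1\tx\texon\t300\t400\t.\t+\t.\t{attrs}\n"
            f"chr1\tx\tCDS\t150\t200\t.\t+\t.\t{attrs}\n"
        )
        (m,) = read_gtf(p)
        assert m.biotype == "protein_coding"
        assert m.exons == [(100, 200), (300, 400)]
        assert (m.cds_start_genomic, m.cds_end_genomic) == (150, 200)

    def test_exon_only_is_noncoding(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text('chr1\tx\texon\t10\t90\t.\t-\t.\tgene_id "G"; transcript_id "T";\n')
        (m,) = read_gtf(p)
        assert m.biotype == "noncoding" and m.cds_start_genomic is None

    def test_missing_transcript_id_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tx\texon\t10\t90\t.\t+\t.\tgene_id "G";\n')
        with pytest.raises(GtfParseError, match=":1:"):
            read_gtf(p)

    def test_cds_outside_exons_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        attrs = 'gene_id "G"; transcript_id "T";'
        p.write_text(
            f"chr1\tx\texon\t100\t200\t.\t+\t.\t{attrs}\n"
            f"chr1\tx\tCDS\t250\t260\t.\t+\t.\t{attrs}\n"
        )
        with pytest.raises(GtfParseError):
            read_gtf(p)

    def test_generated_annotation_round_trips(self, toy_annotation, tmp_path):
        """Write-then-read yields identical models for the full toy genome."""
        p = tmp_path / "toy.gtf"
        write_gtf(toy_annotation.models, p)
        back = {m.transcript_id: m for m in read_gtf(p)}
        assert len(back) == len(toy_annotation.models)
        for m in toy_annotation.models:
            r = back[m.transcript_id]
            assert (r.gene, r.chrom, r.strand, r.exons, r.biotype,
                    r.cds_start_genomic, r.cds_end_genomic) == \
                   (m.gene, m.chrom, m.strand, m.exons, m.biotype,
                    m.cds_start_genomic, m.cds_end_genomic)


class TestFasta:
    def test_sequences_round_trip_and_match_models(self, toy_annotation, tmp_path):
        p = tmp_path / "tx.fa"
        write_transcript_fasta(toy_annotation.sequences, p)
        back = read_transcript_fasta(p)
        assert back == toy_annotation.sequences
        for m in toy_annotation.models:
            assert len(back[m.transcript_id]) == m.length


class TestDialects:
    def test_generic_row_parses_printed_breakpoints(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "sample_id\tgene5\tgene3\tbreakpoint5\tbreakpoint3\tspanning_reads\tcrossing_reads\n"
            "S1\tGENEA\tGENEB\tchr7:959605:-\tchr12:132635526:+\t6\t0\n"
        )
        calls, skipped = read_caller_calls(p, "generic")
        assert skipped == 0 and len(calls) == 1
        c = calls[0]
        assert c.bp5 == GenomicBreakpoint("chr7", 959605, "-")
        assert c.bp3 == GenomicBreakpoint("chr12", 132635526, "+")
        assert c.spanning_reads == 6

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tgene5\tgene3\tbreakpoint5\tbreakpoint3\t"
                     "spanning_reads\tcrossing_reads\n")
        assert read_caller_calls(p, "generic") == ([], 0)

    def test_unparseable_coordinate_is_skipped_and_counted(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "sample_id\tgene5\tgene3\tbreakpoint5\tbreakpoint3\tspanning_reads\tcrossing_reads\n"
            "S1\tA\tB\tchrX:abc:-\tchr1:10:+\t6\t0\n"
            "S1\tA\tB\tchrX:50:-\tchr1:10:+\t6\t0\n"
        )
        calls, skipped = read_caller_calls(p, "generic")
        assert len(calls) == 1 and skipped == 1

    def test_unknown_dialect_rejected(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("a\tb\n")
        with pytest.raises(DialectError, match="star"):
            read_caller_calls(p, "star")

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("gene1\tgene2\n")
        with pytest.raises(DialectError, match="breakpoint1"):
            read_caller_calls(p, "arriba", sample_id="S1")

    def test_dialect_equivalence(self, tmp_path):
        """The same fusion in every dialect normalizes identically (bar caller)."""
        (tmp_path / "arriba.tsv").write_text(
            "gene1\tgene2\tbreakpoint1\tbreakpoint2\tstrand1\tstrand2\t"
            "split_reads\tdiscordant_mates\nA\tB\tchr7:959605\tchr12:132635526\t-\t+\t6\t2\n")
        (tmp_path / "defuse.tsv").write_text(
            "gene_name1\tgene_name2\tgene_chromosome1\tgenomic_break_pos1\tgenomic_strand1\t"
            "gene_chromosome2\tgenomic_break_pos2\tgenomic_strand2\tsplitr_count\tspan_count\n"
            "A\tB\tchr7\t959605\t-\tchr12\t132635526\t+\t6\t2\n")
        (tmp_path / "soapfuse.tsv").write_text(
            "up_gene\tup_chr\tup_strand\tup_genome_pos\tdn_gene\tdn_chr\tdn_strand\t"
            "dn_genome_pos\tjunc_reads_num\tspan_reads_num\n"
            "A\tchr7\t-\t959605\tB\tchr12\t+\t132635526\t6\t2\n")
        (tmp_path / "clc.tsv").write_text(
            "left_gene\tright_gene\tleft_chr\tleft_pos0\tleft_strand\tright_chr\t"
            "right_pos0\tright_strand\tfusion_reads\tpe_reads\n"
            "A\tB\tchr7\t959604\t-\tchr12\t132635525\t+\t6\t2\n")
        parsed = {}
        for dialect in ("arriba", "defuse", "soapfuse", "clc"):
            (c,), _ = read_caller_calls(tmp_path / f"{dialect}.tsv", dialect, "S1")
            parsed[dialect] = c
        ref = parsed["arriba"]
        for c in parsed.values():
            assert (c.sample_id, c.gene5, c.gene3, c.bp5, c.bp3,
                    c.spanning_reads, c.crossing_reads) == \
                   (ref.sample_id, ref.gene5, ref.gene3, ref.bp5, ref.bp3,
                    ref.spanning_reads, ref.crossing_reads)

    def test_canonical_round_trip(self, tmp_path):
        calls = [make_call(sample=f"S{i}", pos5=1000 + i, spanning=5 + i)
                 for i in range(4)]
        p = tmp_path / "canon.tsv"
        assert write_canonical_calls(calls, p) == 4
        assert read_canonical_calls(p) == calls


class TestBedpe:
    def _event(self):
        ev = ConsensusEvent(
            gene5="ADAP1", gene3="NOC4L",
            bp5=GenomicBreakpoint("chr7", 959605, "-"),
            bp3=GenomicBreakpoint("chr12", 132635526, "+"))
        ev.support_by_sample = {"S1": 8}
        return ev

    def test_one_based_to_zero_based_conversion(self, tmp_path):
        p = tmp_path / "e.bedpe"
        assert write_bedpe([self._event()], p) == 1
        fields = p.read_text().strip().split("\t")
        # independent arithmetic: [pos-1, pos) half-open single-base interval
        assert fields[:6] == ["chr7", "959604", "959605", "chr12", "132635525", "132635526"]
        assert fields[6] == "ADAP1--NOC4L" and fields[7] == "8"
        assert fields[8:] == ["-", "+"]

    def test_empty_event_list(self, tmp_path):
        p = tmp_path / "e.bedpe"
        assert write_bedpe([], p) == 0
        assert p.read_text() == ""
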