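import numpy as np
import pytest

from fusionsieve.chimera_annotation import (ChimericTranscript, NotExonicError,
                                            annotate_chimera, classify_type,
                                            map_breakpoint_to_transcript,
                                            nominate_driver, preserved_domains,
                                            select_transcript)
from fusionsieve.consensus import ConsensusEvent
from fusionsieve.formats_io import DomainRecord, GenomicBreakpoint
from fusionsieve.fixtures import load_table1, synthetic_driver_models
from fusionsieve.synthetic_cohort import _plant_junction

from oracles import chimera_in_frame_by_translation


def bp(chrom, pos, strand="+"):
    return GenomicBreakpoint(chrom, pos, strand)


class TestBreakpointMapping:
    def test_plus_strand_second_exon(self, plus_transcript):
        m = map_breakpoint_to_transcript(bp("chr1", 350), plus_transcript)
        assert (m.exon_ordinal, m.offset) == (2, 150)

    def test_minus_strand_reverses_orientation(self, minus_transcript):
        m = map_breakpoint_to_transcript(bp("chr1", 350, "-"), minus_transcript)
        assert (m.exon_ordinal, m.offset) == (1, 51)

    def test_intronic_position(self, plus_transcript):
        with pytest.raises(NotExonicError):
            map_breakpoint_to_transcript(bp("chr1", 250), plus_transcript)

    def test_chromosome_mismatch(self, plus_transcript):
        with pytest.raises(ValueError, match="chromosome mismatch"):
            map_breakpoint_to_transcript(bp("chr9", 350), plus_transcript)


class TestDriverFixtures:
    """Synthetic stand-in transcript models realizing the published junctions."""

    def test_flagship_interchromosomal_junction_phases(self):
        models, _ = synthetic_driver_models()
        row = next(r for r in load_table1() if r.gene5 == "ADAP1")
        ch = annotate_chimera(row.bp5, row.bp3, models["ADAP1"], models["NOC4L"])
        assert (ch.junction_exon5, ch.junction_exon3) == (4, 10)
        assert (ch.retained_cds5_nt, ch.skipped_cds3_nt) == (146, 233)
        assert (ch.phase5, ch.phase3) == (2, 2)
        assert ch.frame_status == "in_frame"

    def test_flagship_domains_preserved(self):
        models, domains = synthetic_driver_models()
        row = next(r for r in load_table1() if r.gene5 == "ADAP1")
        ch = annotate_chimera(row.bp5, row.bp3, models["ADAP1"], models["NOC4L"])
        names = {d.name for _, d in preserved_domains(ch, domains)}
        assert {"ArfGAP", "CBF"} <= names
        assert "PH" not in names  # PH sits downstream of the junction aa 48

    def test_read_through_utr_fusion(self):
        models, domains = synthetic_driver_models()
        row = next(r for r in load_table1() if r.gene5 == "RNF43")
        ch = annotate_chimera(row.bp5, row.bp3, models["RNF43"], models["SUPT4H1"])
        assert ch.frame_status == "five_prime_utr_fusion"
        assert ch.intact_3p_orf is True
        assert ch.junction_exon3 == 2
        kept = preserved_domains(ch, domains)
        assert [(p, d.name) for p, d in kept] == [("3p", "SPT4")]


class TestFrameRules:
    def _chimera(self, retained, skipped, status=None, intact=None):
        return ChimericTranscript(
            tx5="T5", tx3="T3", junction_exon5=1, junction_exon3=1,
            retained_cds5_nt=retained, skipped_cds3_nt=skipped,
            phase5=retained % 3, phase3=skipped % 3,
            frame_status=status or ("in_frame" if retained % 3 == skipped % 3
                                    else "out_of_frame"),
            intact_3p_orf=intact)

    def test_whole_codon_junction_is_in_frame(self):
        ch = self._chimera(3, 0)
        assert (ch.phase5, ch.phase3) == (0, 0) and ch.frame_status == "in_frame"

    def test_unequal_phases_are_out_of_frame(self):
        assert self._chimera(1, 0).frame_status == "out_of_frame"

    def test_five_prime_domain_preservation_inequality(self):
        ch = self._chimera(146, 233)  # J5 = 48
        dom = DomainRecord("T5", "d", aa_start=10, aa_end=40, oncogenic=False)
        assert preserved_domains(ch, [dom]) == [("5p", dom)]
        dom2 = DomainRecord("T5", "d2", aa_start=10, aa_end=49, oncogenic=False)
        assert preserved_domains(ch, [dom2]) == []

    def test_three_prime_truncated_domain_not_preserved(self):
        ch = self._chimera(146, 104)  # A3 = 35
        dom = DomainRecord("T3", "d", aa_start=30, aa_end=90, oncogenic=False)
        assert preserved_domains(ch, [dom]) == []
        dom2 = DomainRecord("T3", "d2", aa_start=35, aa_end=90, oncogenic=False)
        assert preserved_domains(ch, [dom2]) == [("3p", dom2)]

    def test_out_of_frame_preserves_nothing(self):
        ch = self._chimera(1, 0)
        assert preserved_domains(ch, [DomainRecord("T5", "d", 1, 1)]) == []

    def test_monotone_in_junction_position(self):
        """Moving the 5' junction downstream never loses a preserved 5' domain."""
        dom = DomainRecord("T5", "d", aa_start=5, aa_end=20, oncogenic=False)
        preserved_before = False
        for retained in range(0, 303, 3):
            ch = self._chimera(retained, 0)
            now = preserved_domains(ch, [dom]) != []
            assert now or not preserved_before
            preserved_before = preserved_before or now


class TestTranslationOracle:
    def test_frame_status_agrees_with_translation_on_random_junctions(
            self, toy_annotation):
        """Phase arithmetic vs literal translation of the chimeric cDNA,
        over >= 200 random planted junctions on generated sequences."""
        rng = np.random.default_rng(123)
        coding = [m for m in toy_annotation.models if m.is_coding]
        n_checked = n_inframe = 0
        while n_checked < 220:
            i, j = rng.choice(len(coding), size=2, replace=False)
            tx5, tx3 = coding[i], coding[j]
            truth = "in_frame" if rng.random() < 0.5 else "out_of_frame"
            o5, o3 = _plant_junction(tx5, tx3, truth, rng)
            ch = annotate_chimera(
                GenomicBreakpoint(tx5.chrom, tx5.genomic_position(o5), tx5.strand),
                GenomicBreakpoint(tx3.chrom, tx3.genomic_position(o3), tx3.strand),
                tx5, tx3)
            assert ch.frame_status == truth
            oracle = chimera_in_frame_by_translation(
                toy_annotation.sequences[tx5.transcript_id], tx5, o5,
                toy_annotation.sequences[tx3.transcript_id], tx3, o3)
            assert oracle == (ch.frame_status == "in_frame")
            n_checked += 1
            n_inframe += truth == "in_frame"
        assert 50 < n_inframe < 170  # both classes well represented

    def test_phase_arithmetic_identity(self, toy_annotation):
        """retained + remaining 3' CDS nt is a whole number of codons for
        every in-frame junction between CDS-length-divisible partners."""
        rng = np.random.default_rng(5)
        coding = [m for m in toy_annotation.models if m.is_coding]
        for _ in range(100):
            i, j = rng.choice(len(coding), size=2, replace=False)
            tx5, tx3 = coding[i], coding[j]
            assert tx5.cds_length % 3 == 0 and tx3.cds_length % 3 == 0
            o5, o3 = _plant_junction(tx5, tx3, "in_frame", rng)
            retained = o5 - tx5.cds_start_offset + 1
            skipped = o3 - tx3.cds_start_offset
            assert (retained + (tx3.cds_length - skipped)) % 3 == 0


class TestNomination:
    def _event(self):
        ev = ConsensusEvent(gene5="A", gene3="B",
                            bp5=bp("chr7", 100), bp3=bp("chr12", 200))
        return ev

    def _inframe_chimera(self):
        return ChimericTranscript(tx5="T5", tx3="T3", junction_exon5=1,
                                  junction_exon3=1, retained_cds5_nt=146,
                                  skipped_cds3_nt=233, phase5=2, phase3=2,
                                  frame_status="in_frame")

    def test_oncogenic_domain_with_recurrence_nominates(self):
        dom = DomainRecord("T5", "ArfGAP", 10, 40, oncogenic=True)
        nom = nominate_driver(self._event(), self._inframe_chimera(), [dom],
                              recurrence_mCRC=7)
        assert nom.nominated and any("oncogenic" in r for r in nom.reasons)

    def test_score_route_nominates_without_domains(self):
        nom = nominate_driver(self._event(), self._inframe_chimera(), [],
                              driver_score=0.85, recurrence_mCRC=2)
        assert nom.nominated and any("score" in r for r in nom.reasons)

    def test_score_at_threshold_is_not_enough(self):
        nom = nominate_driver(self._event(), self._inframe_chimera(), [],
                              driver_score=0.8, recurrence_mCRC=5)
        assert not nom.nominated

    def test_recurrence_below_two_blocks_nomination(self):
        nom = nominate_driver(self._event(), self._inframe_chimera(), [],
                              driver_score=0.85, recurrence_mCRC=1)
        assert not nom.nominated

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError, match="driver_score"):
            nominate_driver(self._event(), self._inframe_chimera(), [],
                            driver_score=1.2, recurrence_mCRC=2)


class TestTypeAndSelection:
    def test_interchromosomal(self):
        assert classify_type(bp("chr7", 959605), bp("chr12", 132635526)) == \
            "interchromosomal"

    def test_intrachromosomal(self):
        assert classify_type(bp("chr1", 93029199), bp("chr1", 92944310)) == \
            "intrachromosomal"

    def test_identical_breakpoints_are_intrachromosomal(self):
        assert classify_type(bp("chr1", 5), bp("chr1", 5)) == "intrachromosomal"

    def test_select_transcript_prefers_pinned_then_longest_cds(self, toy_annotation):
        m = toy_annotation.models[0]
        assert select_transcript(toy_annotation.models, m.gene).gene == m.gene
        assert select_transcript(toy_annotation.models, m.gene,
                                 m.transcript_id).transcript_id == m.transcript_id
        assert select_transcript(toy_annotation.models, "NOPE") is None
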