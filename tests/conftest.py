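import numpy as np
import pytest

from fusionsieve.formats_io import GenomicBreakpoint, FusionCall, SampleSheet, TranscriptModel
from fusionsieve.synthetic_cohort import SimulationConfig, build_toy_annotation, simulate_bundle


@pytest.fixture(scope="session")
def toy_annotation():
    """Deterministic toy annotation with sequences (session-wide)."""
    return build_toy_annotation(SimulationConfig(seed=11), np.random.default_rng(11))


@pytest.fixture(scope="session")
def zero_noise_bundle(tmp_path_factory):
    """Full synthetic bundle with perfect callers: truth is exactly recoverable."""
    out = tmp_path_factory.mktemp("zero_noise")
    cfg = SimulationConfig(seed=5).zero_noise()
    ann, truths, sheet = simulate_bundle(cfg, out)
    return cfg, ann, truths, sheet, out


@pytest.fixture
def plus_transcript():
    """'+' strand, exons [101-200],[301-400], CDS 131..330 in transcript coords."""
    return TranscriptModel(
        transcript_id="TXP", gene="GP", chrom="chr1", strand="+",
        exons=[(101, 200), (301, 400)],
        cds_start_genomic=131, cds_end_genomic=400,
    )


@pytest.fixture
def minus_transcript():
    """'-' strand, exons [101-200],[301-400] (transcript starts at 400)."""
    return TranscriptModel(
        transcript_id="TXM", gene="GM", chrom="chr1", strand="-",
        exons=[(101, 200), (301, 400)],
        cds_start_genomic=101, cds_end_genomic=370,
    )


def make_call(sample="S1", caller="arriba", gene5="A", gene3="B",
              pos5=1000, pos3=2000, chrom5="chr1", chrom3="chr2",
              strand5="+", strand3="-", spanning=6, crossing=0):
    return FusionCall(
        sample_id=sample, caller=caller, gene5=gene5, gene3=gene3,
        bp5=GenomicBreakpoint(chrom5, pos5, strand5),
        bp3=GenomicBreakpoint(chrom3, pos3, strand3),
        spanning_reads=spanning, crossing_reads=crossing,
    )


@pytest.fixture
def simple_sheet():
    return SampleSheet(rows=[
        ("S1", "LM", "P1"), ("S2", "LM", "P2"), ("P1T", "pCRC", "P1"),
        ("N1", "N", "P1"),
    ])
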