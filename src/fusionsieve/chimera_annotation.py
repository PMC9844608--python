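"""Reading-frame and domain-retention annotation of chimeric transcripts.

A fusion junction is mapped onto one transcript model per partner gene and
the chimera's coding consequence is derived purely from coordinate
arithmetic on the mature transcripts:

* ``retained_cds5_nt`` — coding nucleotides kept from the 5' partner,
  counted from its CDS start (the A of ATG) through the breakpoint base,
  inclusive.  0 when the 5' breakpoint lies in the 5'UTR.
* ``skipped_cds3_nt`` — coding nucleotides of the 3' partner lying
  strictly upstream of its breakpoint, i.e. lost from the native 3' ORF.
* ``phase5 = retained_cds5_nt mod 3`` and ``phase3 = skipped_cds3_nt mod
  3`` — the codon phase at which each partner meets the junction.

The chimera is **in frame** when the two phases are equal: the 3'
partner's remaining codons are then read in their native frame by the
ribosome entering from the 5' ORF.  A junction upstream of the 5'
partner's CDS start is a **5'UTR (read-through) fusion**; when the 3'
breakpoint also lies at or upstream of the 3' CDS start the downstream ORF
is intact and is translated as wild type.  Either partner lacking a CDS
makes the chimera non-coding.

Domain retention on the predicted fusion protein: with junction amino acid
``J5 = floor(retained_cds5_nt / 3)`` on the 5' partner and first retained
amino acid ``A3 = floor(skipped_cds3_nt / 3) + 1`` on the 3' partner, a 5'
domain is preserved iff it ends at or before J5 and a 3' domain iff it
starts at or after A3.  An intact-ORF read-through preserves every 3'
domain and no 5' domain.

Driver nomination follows the discovery rule: a chimera is nominated when
it retains at least one oncogenic-flagged domain OR an externally supplied
driver score exceeds the threshold (default 0.8), AND it recurs in at
least ``min_recurrence`` (default 2) metastatic samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .consensus import ConsensusEvent
from .formats_io import DomainRecord, GenomicBreakpoint, TranscriptModel

__all__ = [
    "MappedBreakpoint", "JunctionPhases", "ChimericTranscript", "DriverAnnotation",
    "NominationConfig", "map_breakpoint_to_transcript", "junction_phases",
    "frame_status", "annotate_chimera", "preserved_domains", "nominate_driver",
    "classify_type", "select_transcript",
]

FRAME_STATUSES = ("in_frame", "out_of_frame", "five_prime_utr_fusion", "noncoding")


class NotExonicError(ValueError):
    """Breakpoint falls in an intron or outside the transcript."""


@dataclass(frozen=True)
class MappedBreakpoint:
    """A breakpoint located on a mature transcript."""

    transcript_id: str
    exon_ordinal: int      # 1-based, transcript orientation
    offset: int            # 1-based cumulative transcribed position


def map_breakpoint_to_transcript(
    bp: GenomicBreakpoint, tx: TranscriptModel
) -> MappedBreakpoint:
    """Locate a genomic breakpoint on a transcript model.

    Raises ``ValueError`` on chromosome mismatch and
    :class:`NotExonicError` for intronic/intergenic positions.  For ``-``
    strand transcripts the transcript coordinate runs high->low along the
    genome.
    """
    if tx.chrom != bp.chrom:
        raise ValueError(
            f"chromosome mismatch: breakpoint on {bp.chrom}, "
            f"transcript {tx.transcript_id} on {tx.chrom}")
    offset = tx.transcript_offset(bp.pos)
    if offset is None:
        raise NotExonicError(
            f"position {bp.chrom}:{bp.pos} not exonic in {tx.transcript_id}")
    return MappedBreakpoint(tx.transcript_id, tx.exon_ordinal(bp.pos), offset)


@dataclass(frozen=True)
class JunctionPhases:
    retained_cds5_nt: int
    skipped_cds3_nt: int
    phase5: int
    phase3: int
    bp5_in_utr5: bool           # 5' breakpoint upstream of the 5' CDS start
    bp3_at_or_before_cds3: bool  # 3' breakpoint at/upstream of the 3' CDS start


def junction_phases(
    mapped5: MappedBreakpoint, tx5: TranscriptModel,
    mapped3: MappedBreakpoint, tx3: TranscriptModel,
) -> JunctionPhases:
    """Compute retained/skipped coding nucleotides and their mod-3 phases.

    Both transcripts must be protein-coding.  The retained count is capped
    at the 5' CDS length (junctions in the 3'UTR keep the whole ORF); the
    skipped count is clamped to [0, CDS length of the 3' partner].
    """
    for tx in (tx5, tx3):
        if not tx.is_coding:
            raise ValueError(f"{tx.transcript_id} is non-coding; phases undefined")
    cs5, ce5 = tx5.cds_start_offset, tx5.cds_end_offset
    cs3 = tx3.cds_start_offset
    cds3_len = tx3.cds_length

    in_utr5 = mapped5.offset < cs5
    retained = 0 if in_utr5 else min(mapped5.offset, ce5) - cs5 + 1

    at_or_before = mapped3.offset <= cs3
    skipped = 0 if at_or_before else min(mapped3.offset - cs3, cds3_len)

    return JunctionPhases(
        retained_cds5_nt=retained, skipped_cds3_nt=skipped,
        phase5=retained % 3, phase3=skipped % 3,
        bp5_in_utr5=in_utr5, bp3_at_or_before_cds3=at_or_before,
    )


def frame_status(
    phases: Optional[JunctionPhases],
    tx5: TranscriptModel, tx3: TranscriptModel,
) -> tuple[str, Optional[bool]]:
    """Classify the chimera's coding consequence.

    Returns ``(status, intact_3p_orf)``; ``intact_3p_orf`` is defined only
    for ``five_prime_utr_fusion``.
    """
    if not (tx5.is_coding and tx3.is_coding):
        return "noncoding", None
    assert phases is not None
    if phases.bp5_in_utr5:
        return "five_prime_utr_fusion", phases.bp3_at_or_before_cds3
    if phases.phase5 == phases.phase3:
        return "in_frame", None
    return "out_of_frame", None


@dataclass
class ChimericTranscript:
    """A fusion junction mapped onto two transcript models."""

    tx5: str
    tx3: str
    junction_exon5: int
    junction_exon3: int
    retained_cds5_nt: int
    skipped_cds3_nt: int
    phase5: int
    phase3: int
    frame_status: str
    intact_3p_orf: Optional[bool] = None


def annotate_chimera(
    bp5: GenomicBreakpoint, bp3: GenomicBreakpoint,
    tx5: TranscriptModel, tx3: TranscriptModel,
) -> ChimericTranscript:
    """Full junction annotation: mapping, phases, frame status."""
    m5 = map_breakpoint_to_transcript(bp5, tx5)
    m3 = map_breakpoint_to_transcript(bp3, tx3)
    if tx5.is_coding and tx3.is_coding:
        ph = junction_phases(m5, tx5, m3, tx3)
    else:
        ph = None
    status, intact = frame_status(ph, tx5, tx3)
    return ChimericTranscript(
        tx5=tx5.transcript_id, tx3=tx3.transcript_id,
        junction_exon5=m5.exon_ordinal, junction_exon3=m3.exon_ordinal,
        retained_cds5_nt=ph.retained_cds5_nt if ph else 0,
        skipped_cds3_nt=ph.skipped_cds3_nt if ph else 0,
        phase5=ph.phase5 if ph else 0, phase3=ph.phase3 if ph else 0,
        frame_status=status, intact_3p_orf=intact,
    )


def preserved_domains(
    chimera: ChimericTranscript, domains: Iterable[DomainRecord]
) -> list[tuple[str, DomainRecord]]:
    """Domains of either partner carried intact into the fusion protein.

    Returns ``(partner, domain)`` pairs with partner in {"5p", "3p"}.
    Out-of-frame or non-coding chimeras preserve nothing (no ORF reaches
    the 3' partner; the truncated 5' ORF is not scored).
    """
    if chimera.frame_status not in ("in_frame", "five_prime_utr_fusion"):
        return []
    out: list[tuple[str, DomainRecord]] = []
    if chimera.frame_status == "five_prime_utr_fusion":
        if not chimera.intact_3p_orf:
            return []
        for d in domains:
            if d.transcript_id == chimera.tx3:
                out.append(("3p", d))
        return out
    j5 = chimera.retained_cds5_nt // 3
    a3 = chimera.skipped_cds3_nt // 3 + 1
    for d in domains:
        if d.transcript_id == chimera.tx5 and d.aa_end <= j5:
            out.append(("5p", d))
        elif d.transcript_id == chimera.tx3 and d.aa_start >= a3:
            out.append(("3p", d))
    return out


@dataclass
class NominationConfig:
    score_threshold: float = 0.8
    min_recurrence: int = 2


@dataclass
class DriverAnnotation:
    """Driver-nomination decision with the criteria that fired."""

    gene5: str
    gene3: str
    preserved: list[tuple[str, DomainRecord]] = field(default_factory=list)
    driver_score: Optional[float] = None
    recurrence_mCRC: int = 0
    nominated: bool = False
    reasons: list[str] = field(default_factory=list)


def nominate_driver(
    event: ConsensusEvent,
    chimera: ChimericTranscript,
    domains: Iterable[DomainRecord],
    driver_score: Optional[float] = None,
    recurrence_mCRC: int = 0,
    config: NominationConfig = NominationConfig(),
) -> DriverAnnotation:
    """Nominate iff (oncogenic domain retained OR score > threshold) AND
    the fusion recurs in >= min_recurrence metastatic samples."""
    if driver_score is not None and not 0.0 <= driver_score <= 1.0:
        raise ValueError(f"driver_score must be in [0,1], got {driver_score}")
    kept = preserved_domains(chimera, domains)
    reasons: list[str] = []
    onc = [d for _, d in kept if d.oncogenic]
    if onc:
        reasons.append("oncogenic domain preserved: " + ", ".join(sorted(d.name for d in onc)))
    if driver_score is not None and driver_score > config.score_threshold:
        reasons.append(f"driver score {driver_score:.2f} > {config.score_threshold}")
    recurrent = recurrence_mCRC >= config.min_recurrence
    if recurrent:
        reasons.append(f"recurrent in {recurrence_mCRC} mCRC samples")
    nominated = bool((onc or (driver_score is not None and driver_score > config.score_threshold))
                     and recurrent)
    return DriverAnnotation(
        gene5=event.gene5, gene3=event.gene3, preserved=kept,
        driver_score=driver_score, recurrence_mCRC=recurrence_mCRC,
        nominated=nominated, reasons=reasons,
    )


def classify_type(bp5: GenomicBreakpoint, bp3: GenomicBreakpoint) -> str:
    """Intrachromosomal vs interchromosomal by chromosome identity."""
    return "interchromosomal" if bp5.chrom != bp3.chrom else "intrachromosomal"


def select_transcript(
    models: Sequence[TranscriptModel], gene: str, transcript_id: Optional[str] = None
) -> Optional[TranscriptModel]:
    """One transcript per gene: the pinned id if given, else the longest CDS
    (coding preferred), ties broken by transcript id."""
    cands = [m for m in models if m.gene == gene]
    if transcript_id is not None:
        for m in cands:
            if m.transcript_id == transcript_id:
                return m
        return None
    if not cands:
        return None
    return max(cands, key=lambda m: (m.is_coding, m.cds_length or 0,
                                     m.length, m.transcript_id))
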