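"""Domain types and file I/O for the fusion post-processing pipeline.

Conventions
-----------
All genomic coordinates are 1-based, closed intervals internally.  A fusion
breakpoint denotes the last transcribed base of the 5' segment or the first
transcribed base of the 3' segment.  BEDPE export converts to 0-based
half-open single-base intervals.  The minus sign may arrive as ASCII ``-``
or Unicode U+2212 in third-party tables; both are normalized to ``-``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd

__all__ = [
    "GenomicBreakpoint",
    "FusionCall",
    "TranscriptModel",
    "DomainRecord",
    "SampleSheet",
    "CALLER_DIALECTS",
    "read_gtf",
    "write_gtf",
    "read_transcript_fasta",
    "write_transcript_fasta",
    "read_caller_calls",
    "read_canonical_calls",
    "write_canonical_calls",
    "read_domain_table",
    "write_domain_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_bedpe",
    "GtfParseError",
    "DialectError",
]

TISSUE_CLASSES = ("LM", "pCRC", "N")

CALLER_DIALECTS = ("arriba", "defuse", "soapfuse", "clc", "generic")


class GtfParseError(ValueError):
    """Raised when a GTF file violates the expected structure."""


class DialectError(ValueError):
    """Raised for unknown caller dialects or malformed dialect tables."""


def _norm_strand(s: str) -> str:
    s = s.strip().replace("−", "-")
    if s not in ("+", "-"):
        raise ValueError(f"invalid strand {s!r}")
    return s


@dataclass(frozen=True)
class GenomicBreakpoint:
    """A single fusion breakpoint: chromosome, 1-based position, strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if int(self.pos) < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        object.__setattr__(self, "pos", int(self.pos))
        object.__setattr__(self, "strand", _norm_strand(self.strand))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.strand}"


@dataclass(frozen=True)
class FusionCall:
    """One caller's report of a candidate fusion in one sample.

    ``spanning_reads`` counts reads bridging the junction (the read-support
    quantity thresholded downstream); ``crossing_reads`` carries the
    caller's secondary support count and is 0 for dialects lacking it.
    """

    sample_id: str
    caller: str
    gene5: str
    gene3: str
    bp5: GenomicBreakpoint
    bp3: GenomicBreakpoint
    spanning_reads: int
    crossing_reads: int = 0

    def __post_init__(self) -> None:
        if self.caller not in CALLER_DIALECTS:
            raise DialectError(f"unknown caller {self.caller!r}")
        g5 = self.gene5.strip()
        g3 = self.gene3.strip()
        if not g5 or not g3:
            raise ValueError("gene symbols must be non-empty")
        object.__setattr__(self, "gene5", g5)
        object.__setattr__(self, "gene3", g3)
        if int(self.spanning_reads) < 0 or int(self.crossing_reads) < 0:
            raise ValueError("read counts must be non-negative")
        object.__setattr__(self, "spanning_reads", int(self.spanning_reads))
        object.__setattr__(self, "crossing_reads", int(self.crossing_reads))


@dataclass
class TranscriptModel:
    """A transcript: ordered exons plus optional CDS bounds, all genomic.

    ``exons`` are 1-based closed intervals sorted by genomic start and
    non-overlapping.  For ``-`` strand transcripts the mature transcript
    runs from the genomically last exon's end down to the first exon's
    start.  ``cds_start_genomic``/``cds_end_genomic`` are the genomic min
    and max of the coding region (orientation-free); ``None`` for
    non-coding transcripts.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_genomic: Optional[int] = None
    cds_end_genomic: Optional[int] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.strand = _norm_strand(self.strand)
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = 0
        for a, b in self.exons:
            if a > b:
                raise ValueError(f"{self.transcript_id}: exon start > end ({a} > {b})")
            if a <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
            prev_end = b
        if (self.cds_start_genomic is None) != (self.cds_end_genomic is None):
            raise ValueError(f"{self.transcript_id}: half-specified CDS bounds")
        if self.cds_start_genomic is not None:
            if self.transcript_offset(self.cds_start_genomic) is None or \
               self.transcript_offset(self.cds_end_genomic) is None:
                raise ValueError(f"{self.transcript_id}: CDS bounds outside exon union")

    # -- coordinate arithmetic -------------------------------------------

    @property
    def length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic is not None

    def _oriented_exons(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def transcript_offset(self, pos: int) -> Optional[int]:
        """1-based position of a genomic coordinate in the mature transcript.

        Returns ``None`` for intronic/flanking positions.  For ``-`` strand
        transcripts the offset runs high->low along the genome.
        """
        cum = 0
        for a, b in self._oriented_exons():
            if a <= pos <= b:
                return cum + (pos - a + 1 if self.strand == "+" else b - pos + 1)
            cum += b - a + 1
        return None

    def exon_ordinal(self, pos: int) -> Optional[int]:
        """1-based exon number in transcript orientation, or None."""
        for i, (a, b) in enumerate(self._oriented_exons(), start=1):
            if a <= pos <= b:
                return i
        return None

    def genomic_position(self, offset: int) -> int:
        """Inverse of :meth:`transcript_offset` (offset must be in range)."""
        if not 1 <= offset <= self.length:
            raise ValueError(f"offset {offset} outside transcript of length {self.length}")
        cum = 0
        for a, b in self._oriented_exons():
            n = b - a + 1
            if offset <= cum + n:
                k = offset - cum
                return a + k - 1 if self.strand == "+" else b - k + 1
            cum += n
        raise AssertionError("unreachable")

    @property
    def cds_start_offset(self) -> Optional[int]:
        """Transcript offset of the first coding base (the A of ATG)."""
        if not self.is_coding:
            return None
        g = self.cds_start_genomic if self.strand == "+" else self.cds_end_genomic
        return self.transcript_offset(g)

    @property
    def cds_end_offset(self) -> Optional[int]:
        if not self.is_coding:
            return None
        g = self.cds_end_genomic if self.strand == "+" else self.cds_start_genomic
        return self.transcript_offset(g)

    @property
    def cds_length(self) -> Optional[int]:
        if not self.is_coding:
            return None
        return self.cds_end_offset - self.cds_start_offset + 1


@dataclass(frozen=True)
class DomainRecord:
    """A protein domain on a transcript's translation, in aa coordinates."""

    transcript_id: str
    name: str
    aa_start: int
    aa_end: int
    oncogenic: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValueError(f"require 1 <= aa_start <= aa_end, got {self.aa_start}..{self.aa_end}")


@dataclass
class SampleSheet:
    """Sample metadata: tissue class (LM / pCRC / N) and patient pairing."""

    rows: list[tuple[str, str, str]]  # (sample_id, tissue_class, patient_id)

    def __post_init__(self) -> None:
        seen = set()
        for sid, cls, _pid in self.rows:
            if cls not in TISSUE_CLASSES:
                raise ValueError(f"sample {sid}: tissue class {cls!r} not in {TISSUE_CLASSES}")
            if sid in seen:
                raise ValueError(f"duplicate sample_id {sid}")
            seen.add(sid)

    def tissue_class(self, sample_id: str) -> str:
        for sid, cls, _ in self.rows:
            if sid == sample_id:
                return cls
        raise KeyError(f"sample {sample_id!r} absent from sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.rows]

    def samples_of_class(self, cls: str) -> list[str]:
        return [sid for sid, c, _ in self.rows if c == cls]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF into :class:`TranscriptModel`s (exon + CDS features).

    Biotype is inferred from CDS presence.  Raises :class:`GtfParseError`
    naming the line number if an exon/CDS feature lacks a transcript_id
    attribute, and a validation error if CDS bounds fall outside the exon
    union.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            if fields[2] in ("exon", "CDS") and "transcript_id" not in fields[8]:
                raise GtfParseError(f"{path}:{lineno}: feature lacks transcript_id attribute")

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [tid])[0]
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(
            (feat.start, feat.end)
        )
    models = []
    for tid in sorted(exons):
        gene, chrom, strand = meta[tid]
        cds_bounds = cds.get(tid)
        kwargs = {}
        if cds_bounds:
            kwargs = {
                "cds_start_genomic": min(a for a, _ in cds_bounds),
                "cds_end_genomic": max(b for _, b in cds_bounds),
            }
        try:
            model = TranscriptModel(
                transcript_id=tid, gene=gene, chrom=chrom, strand=strand,
                exons=_merge_adjacent(sorted(exons[tid])),
                biotype="protein_coding" if cds_bounds else "noncoding",
                **kwargs,
            )
        except ValueError as exc:
            raise GtfParseError(f"{path}: {exc}") from exc
        models.append(model)
    return models


def _merge_adjacent(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge book-ended/overlapping intervals (duplicate exon lines)."""
    out: list[tuple[int, int]] = []
    for a, b in ivals:
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF exon (+CDS) features."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.exons[0][0], m.transcript_id)):
            attrs = f'gene_id "{m.gene}"; transcript_id "{m.transcript_id}"; gene_name "{m.gene}";'
            for a, b in m.exons:
                fh.write(f"{m.chrom}\ttoy\texon\t{a}\t{b}\t.\t{m.strand}\t.\t{attrs}\n")
            if m.is_coding:
                lo, hi = m.cds_start_genomic, m.cds_end_genomic
                for a, b in m.exons:
                    ca, cb = max(a, lo), min(b, hi)
                    if ca <= cb:
                        fh.write(f"{m.chrom}\ttoy\tCDS\t{ca}\t{cb}\t.\t{m.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# FASTA (mature transcript sequences)
# ---------------------------------------------------------------------------

def read_transcript_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_transcript_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Caller dialects
# ---------------------------------------------------------------------------
#
# The reference ("generic") layout is:
#   sample_id  gene5  gene3  breakpoint5  breakpoint3  spanning_reads  crossing_reads
# with breakpoints as "chrom:pos:strand" (1-based).  The caller-flavoured
# dialects below are deterministic column re-mappings of the same content;
# they carry no sample column (one file per sample), so `sample_id` must be
# supplied by the reader.  The clc-like dialect uses 0-based positions and
# is converted on input.  Exact layouts are documented in docs/methods.md.

_REQUIRED = {
    "generic": ["sample_id", "gene5", "gene3", "breakpoint5", "breakpoint3",
                "spanning_reads", "crossing_reads"],
    "arriba": ["gene1", "gene2", "breakpoint1", "breakpoint2", "strand1",
               "strand2", "split_reads", "discordant_mates"],
    "defuse": ["gene_name1", "gene_name2", "gene_chromosome1", "genomic_break_pos1",
               "genomic_strand1", "gene_chromosome2", "genomic_break_pos2",
               "genomic_strand2", "splitr_count", "span_count"],
    "soapfuse": ["up_gene", "up_chr", "up_strand", "up_genome_pos", "dn_gene",
                 "dn_chr", "dn_strand", "dn_genome_pos", "junc_reads_num",
                 "span_reads_num"],
    "clc": ["left_gene", "right_gene", "left_chr", "left_pos0", "left_strand",
            "right_chr", "right_pos0", "right_strand", "fusion_reads", "pe_reads"],
}


def _parse_pos(text: str) -> int:
    pos = int(str(text).strip())
    if pos < 0:
        raise ValueError(f"negative position {pos}")
    return pos


def read_caller_calls(
    path: str | Path, dialect: str, sample_id: Optional[str] = None
) -> tuple[list[FusionCall], int]:
    """Normalize one caller's TSV into canonical :class:`FusionCall`s.

    Returns ``(calls, n_skipped)`` where skipped rows are those with
    unparseable coordinates.  Non-generic dialects are per-sample files and
    require ``sample_id``.
    """
    if dialect not in CALLER_DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; choose from {CALLER_DIALECTS}")
    if dialect != "generic" and sample_id is None:
        raise DialectError(f"dialect {dialect!r} carries no sample column; pass sample_id")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED[dialect]:
        if col not in df.columns:
            raise DialectError(f"{path}: required column {col!r} absent for dialect {dialect!r}")
    calls: list[FusionCall] = []
    skipped = 0
    for _, row in df.iterrows():
        try:
            calls.append(_row_to_call(row, dialect, sample_id))
        except (ValueError, DialectError):
            skipped += 1
    return calls, skipped


def _row_to_call(row: pd.Series, dialect: str, sample_id: Optional[str]) -> FusionCall:
    if dialect == "generic":
        c5, p5, s5 = row["breakpoint5"].rsplit(":", 2)
        c3, p3, s3 = row["breakpoint3"].rsplit(":", 2)
        return FusionCall(
            sample_id=sample_id or row["sample_id"], caller="generic",
            gene5=row["gene5"], gene3=row["gene3"],
            bp5=GenomicBreakpoint(c5, _parse_pos(p5), s5),
            bp3=GenomicBreakpoint(c3, _parse_pos(p3), s3),
            spanning_reads=int(row["spanning_reads"]),
            crossing_reads=int(row["crossing_reads"]),
        )
    if dialect == "arriba":
        c5, p5 = row["breakpoint1"].rsplit(":", 1)
        c3, p3 = row["breakpoint2"].rsplit(":", 1)
        return FusionCall(
            sample_id=sample_id, caller="arriba",
            gene5=row["gene1"], gene3=row["gene2"],
            bp5=GenomicBreakpoint(c5, _parse_pos(p5), row["strand1"]),
            bp3=GenomicBreakpoint(c3, _parse_pos(p3), row["strand2"]),
            spanning_reads=int(row["split_reads"]),
            crossing_reads=int(row["discordant_mates"]),
        )
    if dialect == "defuse":
        return FusionCall(
            sample_id=sample_id, caller="defuse",
            gene5=row["gene_name1"], gene3=row["gene_name2"],
            bp5=GenomicBreakpoint(row["gene_chromosome1"], _parse_pos(row["genomic_break_pos1"]),
                                  row["genomic_strand1"]),
            bp3=GenomicBreakpoint(row["gene_chromosome2"], _parse_pos(row["genomic_break_pos2"]),
                                  row["genomic_strand2"]),
            spanning_reads=int(row["splitr_count"]),
            crossing_reads=int(row["span_count"]),
        )
    if dialect == "soapfuse":
        return FusionCall(
            sample_id=sample_id, caller="soapfuse",
            gene5=row["up_gene"], gene3=row["dn_gene"],
            bp5=GenomicBreakpoint(row["up_chr"], _parse_pos(row["up_genome_pos"]), row["up_strand"]),
            bp3=GenomicBreakpoint(row["dn_chr"], _parse_pos(row["dn_genome_pos"]), row["dn_strand"]),
            spanning_reads=int(row["junc_reads_num"]),
            crossing_reads=int(row["span_reads_num"]),
        )
    # clc-like: 0-based positions
    return FusionCall(
        sample_id=sample_id, caller="clc",
        gene5=row["left_gene"], gene3=row["right_gene"],
        bp5=GenomicBreakpoint(row["left_chr"], _parse_pos(row["left_pos0"]) + 1, row["left_strand"]),
        bp3=GenomicBreakpoint(row["right_chr"], _parse_pos(row["right_pos0"]) + 1, row["right_strand"]),
        spanning_reads=int(row["fusion_reads"]),
        crossing_reads=int(row["pe_reads"]),
    )


CANONICAL_COLUMNS = [
    "sample_id", "caller", "gene5", "gene3", "chrom5", "pos5", "strand5",
    "chrom3", "pos3", "strand3", "spanning_reads", "crossing_reads",
]


def write_canonical_calls(calls: Sequence[FusionCall], path: str | Path) -> int:
    rows = [
        {
            "sample_id": c.sample_id, "caller": c.caller,
            "gene5": c.gene5, "gene3": c.gene3,
            "chrom5": c.bp5.chrom, "pos5": c.bp5.pos, "strand5": c.bp5.strand,
            "chrom3": c.bp3.chrom, "pos3": c.bp3.pos, "strand3": c.bp3.strand,
            "spanning_reads": c.spanning_reads, "crossing_reads": c.crossing_reads,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)
    return len(rows)


def read_canonical_calls(path: str | Path) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise DialectError(f"{path}: required column {col!r} absent")
    return [
        FusionCall(
            sample_id=r["sample_id"], caller=r["caller"],
            gene5=r["gene5"], gene3=r["gene3"],
            bp5=GenomicBreakpoint(r["chrom5"], int(r["pos5"]), r["strand5"]),
            bp3=GenomicBreakpoint(r["chrom3"], int(r["pos3"]), r["strand3"]),
            spanning_reads=int(r["spanning_reads"]),
            crossing_reads=int(r["crossing_reads"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Domain table / sample sheet
# ---------------------------------------------------------------------------

def read_domain_table(path: str | Path) -> list[DomainRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        DomainRecord(
            transcript_id=r["transcript_id"], name=r["domain_name"],
            aa_start=int(r["aa_start"]), aa_end=int(r["aa_end"]),
            oncogenic=bool(int(r["oncogenic"])),
        )
        for _, r in df.iterrows()
    ]


def write_domain_table(domains: Sequence[DomainRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "domain_name", "aa_start", "aa_end", "oncogenic"])
        for d in domains:
            w.writerow([d.transcript_id, d.name, d.aa_start, d.aa_end, int(d.oncogenic)])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(rows=[(r["sample_id"], r["tissue_class"], r["patient_id"])
                             for _, r in df.iterrows()])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "tissue_class", "patient_id"])
        for row in sheet.rows:
            w.writerow(row)


# ---------------------------------------------------------------------------
# BEDPE export
# ---------------------------------------------------------------------------

def write_bedpe(events, path: str | Path) -> int:
    """Write consensus events as BEDPE (0-based half-open single-base ends).

    Name column is ``gene5--gene3``; score is the max spanning-read support
    over samples; strands go in columns 9-10.  Returns rows written.
    """
    n = 0
    with open(path, "w") as fh:
        for ev in events:
            score = max(ev.support_by_sample.values(), default=0)
            fh.write(
                f"{ev.bp5.chrom}\t{ev.bp5.pos - 1}\t{ev.bp5.pos}\t"
                f"{ev.bp3.chrom}\t{ev.bp3.pos - 1}\t{ev.bp3.pos}\t"
                f"{ev.gene5}--{ev.gene3}\t{score}\t{ev.bp5.strand}\t{ev.bp3.strand}\n"
            )
            n += 1
    return n
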