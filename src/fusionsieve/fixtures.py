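"""Packaged worked-example fixtures.

Two small tables ship with the package: the fourteen recurrent driver
fusions of the metastatic colorectal cohort (gene pairs, breakpoints,
printed frame labels, functional domains, carrier samples, read counts)
and the cohort category counts.  The frame labels are stored verbatim as
printed; all fourteen rows are treated as frame-passing drivers.

Because the real hg19 transcript annotation is not shipped, the two
flagship fusions are additionally backed by *synthetic* transcript models
(:func:`synthetic_driver_models`) — code-constructed stand-ins whose exon
structures realize the published junction geometry: the ArfGAP-partner
junction at exon 4 with 146 retained coding nt meeting the CBF-partner at
exon 10 with 233 skipped coding nt (phases 2 > 2, in frame), and the
5'UTR read-through onto an intact downstream ORF carrying an SPT4-like
domain.  They are stand-ins for phase arithmetic, not real gene models.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .consensus import ConsensusEvent
from .formats_io import DomainRecord, GenomicBreakpoint, SampleSheet, TranscriptModel

__all__ = ["Table1Row", "load_table1", "load_table2_counts", "table1_events",
           "table1_sample_sheet", "synthetic_driver_models"]


@dataclass(frozen=True)
class Table1Row:
    gene5: str
    tx5: str
    bp5: GenomicBreakpoint
    gene3: str
    tx3: str
    bp3: GenomicBreakpoint
    inframe_label: str
    functional_domain: str
    fusion_type: str
    samples: tuple[str, ...]
    read_counts: tuple[int, ...]
    selected: bool


def _fixture_path(name: str):
    return resources.files("fusionsieve") / "fixtures" / name


def load_table1() -> list[Table1Row]:
    """The fourteen recurrent driver fusions, as printed."""
    df = pd.read_csv(_fixture_path("table1_fusions.tsv"), sep="\t", dtype=str)
    rows = []
    for _, r in df.iterrows():
        rows.append(Table1Row(
            gene5=r["gene5"], tx5=r["tx5"],
            bp5=GenomicBreakpoint(r["chrom5"], int(r["pos5"]), r["strand5"]),
            gene3=r["gene3"], tx3=r["tx3"],
            bp3=GenomicBreakpoint(r["chrom3"], int(r["pos3"]), r["strand3"]),
            inframe_label=r["inframe_label"],
            functional_domain=r["functional_domain"],
            fusion_type=r["fusion_type"].lower(),
            samples=tuple(r["samples"].split(";")),
            read_counts=tuple(int(x) for x in r["read_counts"].split(";")),
            selected=bool(int(r["selected"])),
        ))
    return rows


def load_table2_counts() -> dict[str, dict[str, int]]:
    """Cohort category counts keyed by exclusivity class then category."""
    df = pd.read_csv(_fixture_path("table2_counts.tsv"), sep="\t", dtype=str)
    out: dict[str, dict[str, int]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["exclusivity_class"], {})[r["category"]] = int(r["count"])
    return out


def table1_sample_sheet() -> SampleSheet:
    """All carrier samples in the driver table are liver metastases."""
    samples = sorted({s for row in load_table1() for s in row.samples})
    return SampleSheet(rows=[(s, "LM", s) for s in samples])


def table1_events() -> list[ConsensusEvent]:
    """The driver table as cohort-level consensus events."""
    events = []
    for row in load_table1():
        ev = ConsensusEvent(gene5=row.gene5, gene3=row.gene3, bp5=row.bp5, bp3=row.bp3)
        for s, n in zip(row.samples, row.read_counts):
            ev.callers_by_sample[s] = frozenset({"arriba", "defuse"})
            ev.support_by_sample[s] = n
            ev.crossing_by_sample[s] = 0
        ev.samples_by_class = {"LM": frozenset(row.samples),
                               "pCRC": frozenset(), "N": frozenset()}
        events.append(ev)
    return events


def synthetic_driver_models() -> tuple[dict[str, TranscriptModel], list[DomainRecord]]:
    """Synthetic transcript models realizing the flagship junction geometry.

    ADAP1-like (chr7, '-'): 5 exons; junction base chr7:959605 sits in
    exon 4 at transcript offset 176 with the CDS starting at offset 31,
    so 146 coding nt are retained (phase 2).  NOC4L-like (chr12, '+'):
    11 exons; junction base chr12:132635526 sits in exon 10 at offset 254
    with CDS start at offset 21, so 233 coding nt are skipped (phase 2).
    RNF43-like (chr17, '-'): junction chr17:56494378 in the 5'UTR (exon 1).
    SUPT4H1-like (chr17, '-'): junction chr17:56428869 in exon 2 exactly
    at the CDS start, leaving the downstream ORF intact; an SPT4-like
    oncogenic domain sits on its translation.
    """
    adap1 = TranscriptModel(
        transcript_id="ENST00000265846", gene="ADAP1", chrom="chr7", strand="-",
        exons=[(959300, 959399), (959551, 959650), (959700, 959729),
               (959800, 959839), (959900, 959959)],
        cds_start_genomic=959300, cds_end_genomic=959929,
    )
    noc4l = TranscriptModel(
        transcript_id="ENST00000330579", gene="NOC4L", chrom="chr12", strand="+",
        exons=[(132634050 + 50 * i, 132634075 + 50 * i) for i in range(9)]
              + [(132635507, 132635606), (132635700, 132635799)],
        cds_start_genomic=132634070, cds_end_genomic=132635799,
    )
    rnf43 = TranscriptModel(
        transcript_id="ENST00000407977", gene="RNF43", chrom="chr17", strand="-",
        exons=[(56493800, 56493899), (56494000, 56494099), (56494300, 56494399)],
        cds_start_genomic=56493801, cds_end_genomic=56494050,
    )
    supt4h1 = TranscriptModel(
        transcript_id="ENST00000225504", gene="SUPT4H1", chrom="chr17", strand="-",
        exons=[(56428600, 56428699), (56428800, 56428899), (56429000, 56429059)],
        cds_start_genomic=56428650, cds_end_genomic=56428869,
    )
    domains = [
        DomainRecord("ENST00000265846", "ArfGAP", aa_start=10, aa_end=40, oncogenic=True),
        DomainRecord("ENST00000265846", "PH", aa_start=60, aa_end=95, oncogenic=False),
        DomainRecord("ENST00000330579", "CBF", aa_start=90, aa_end=130, oncogenic=True),
        DomainRecord("ENST00000407977", "RING", aa_start=10, aa_end=40, oncogenic=True),
        DomainRecord("ENST00000225504", "SPT4", aa_start=5, aa_end=35, oncogenic=True),
    ]
    models = {m.gene: m for m in (adap1, noc4l, rnf43, supt4h1)}
    return models, domains
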