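"""Synthetic paired-cohort generator with planted ground truth.

Generates every input the pipeline consumes — toy transcript annotation
(GTF + mature-transcript FASTA + protein-domain table), per-sample
per-caller fusion call files in the caller dialects, a sample sheet, a
qPCR Ct table and a survival table — together with a truth table
recording every planted attribute, so the full analysis runs end to end
with no external data.

The default cohort mirrors the discovery design: 24 patients contributing
paired liver-metastasis (LM), primary-tumor (pCRC) and normal (N)
specimens plus 7 unpaired LM samples.  The planted fusion catalog
contains fourteen metastasis-exclusive driver fusions (recurrences 2-8,
including one in-frame flagship in 7 LM samples and one 5'UTR
read-through in 8), plus events designed to exercise every filter:
primary-unique and shared fusions, fusions present in normal tissue,
sub-threshold read support, single-caller calls, and a breakpoint in a
non-coding transcript.

Caller noise model: each caller detects a planted fusion in a carrier
sample with its configured sensitivity, reports breakpoints jittered by a
rounded normal (sd in nt), and adds private false-positive calls at a
Poisson rate per sample.  Read support per carrier sample is drawn as
5 + Poisson(mean - 5) for means >= 5 (so values exactly at the support
threshold are common, exercising the >= comparison) and as
max(1, Poisson(mean)) for sub-threshold means.

Everything is driven by one numpy Generator: a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    DomainRecord, GenomicBreakpoint, SampleSheet, TranscriptModel,
    write_domain_table, write_gtf, write_sample_sheet, write_transcript_fasta,
)

__all__ = ["SimulationConfig", "PlantedFusion", "ToyAnnotation", "default_catalog",
           "build_toy_annotation", "plant_and_emit_calls",
           "emit_expression_and_survival", "simulate_bundle"]

NUCLEOTIDES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}
DOMAIN_NAMES = ["kinase", "zinc_finger", "RING", "proteasome_activator", "SMAD_FHA"]


@dataclass(frozen=True)
class PlantedFusion:
    """One catalog entry: a fusion with known truth attributes."""

    fusion_id: str
    gene5: str
    gene3: str
    exclusivity: str            # LM_unique | pCRC_unique | common | normal_present
    frame_truth: str            # in_frame | out_of_frame | utr | noncoding
    oncogenic_domain: bool      # an oncogenic domain survives the junction
    mean_support: float
    n_LM: int = 0
    n_pCRC: int = 0
    n_N: int = 0
    callers: Optional[frozenset[str]] = None   # None = all callers


@dataclass
class SimulationConfig:
    seed: int = 0
    # cohort structure
    n_paired_patients: int = 24
    n_unpaired_LM: int = 7
    # toy genome
    n_coding_genes: int = 20
    n_noncoding_genes: int = 2
    n_chromosomes: int = 4
    exon_count_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (60, 300)
    intron_length_range: tuple[int, int] = (200, 2000)
    utr5_length_range: tuple[int, int] = (30, 120)
    utr3_length_range: tuple[int, int] = (30, 200)
    cds_codons_range: tuple[int, int] = (80, 300)
    # caller noise
    sensitivity: dict[str, float] = field(default_factory=lambda: {
        "arriba": 0.9, "defuse": 0.85, "soapfuse": 0.8, "clc": 0.8})
    jitter_sd: float = 2.0
    fp_rate: float = 1.0        # expected false positives / caller / sample
    # expression (qPCR) emulation
    fold_change: float = 4.0
    ct_noise_sd: float = 0.4
    baseline_delta_ct: float = 5.0
    ref_ct_mean: float = 20.0
    ref_ct_sd: float = 0.3
    n_expr_mcrc: int = 13
    n_expr_pcrc: int = 8
    # survival emulation
    baseline_hazard: float = 0.03   # per month
    hazard_ratio: float = 3.0
    censoring_fraction: float = 0.2
    n_survival: int = 23
    n_survival_positive: int = 13
    # planted catalog (None -> default_catalog())
    catalog: Optional[list[PlantedFusion]] = None

    def __post_init__(self) -> None:
        for name, p in self.sensitivity.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sensitivity[{name}] must be in [0,1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if not 0.0 <= self.censoring_fraction <= 1.0:
            raise ValueError("censoring_fraction must be in [0,1]")

    def zero_noise(self) -> "SimulationConfig":
        """All sensitivities 1, no jitter, no false positives."""
        return replace(self, sensitivity={k: 1.0 for k in self.sensitivity},
                       jitter_sd=0.0, fp_rate=0.0)


def _gene_pairs(n_genes: int = 20, n_pairs: int = 30) -> list[tuple[str, str]]:
    """Distinct ordered gene pairs spread evenly over the toy gene set."""
    genes = [f"G{i:02d}" for i in range(1, n_genes + 1)]
    out: list[tuple[str, str]] = []
    shift = 1
    while len(out) < n_pairs:
        for i in range(0, n_genes, 2):
            a, b = genes[i], genes[(i + shift) % n_genes]
            if a != b and (a, b) not in out:
                out.append((a, b))
        shift += 1
    return out[:n_pairs]


def default_catalog() -> list[PlantedFusion]:
    """The study-condition catalog: 14 LM-exclusive drivers + stress events."""
    driver_recurrence = [3, 2, 2, 2, 3, 2, 2, 2, 2, 7, 2, 3, 2, 8]
    pairs = _gene_pairs()
    cat: list[PlantedFusion] = []
    k = 0
    for i, rec in enumerate(driver_recurrence):
        frame = "utr" if i == 13 else "in_frame"
        cat.append(PlantedFusion(
            fusion_id=f"DRV{i+1:02d}", gene5=pairs[k][0], gene3=pairs[k][1],
            exclusivity="LM_unique", frame_truth=frame, oncogenic_domain=True,
            mean_support=6.0, n_LM=rec))
        k += 1
    for i in range(3):
        cat.append(PlantedFusion(
            fusion_id=f"OOF{i+1:02d}", gene5=pairs[k][0], gene3=pairs[k][1],
            exclusivity="LM_unique", frame_truth="out_of_frame",
            oncogenic_domain=False, mean_support=6.0, n_LM=2))
        k += 1
    for i in range(2):
        cat.append(PlantedFusion(
            fusion_id=f"PRI{i+1:02d}", gene5=pairs[k][0], gene3=pairs[k][1],
            exclusivity="pCRC_unique", frame_truth="in_frame" if i == 0 else "out_of_frame",
            oncogenic_domain=False, mean_support=6.0, n_pCRC=2 + i))
        k += 1
    for i in range(2):
        cat.append(PlantedFusion(
            fusion_id=f"COM{i+1:02d}", gene5=pairs[k][0], gene3=pairs[k][1],
            exclusivity="common", frame_truth="in_frame" if i == 0 else "out_of_frame",
            oncogenic_domain=False, mean_support=6.5, n_LM=2, n_pCRC=2))
        k += 1
    for i in range(2):
        cat.append(PlantedFusion(
            fusion_id=f"NRM{i+1:02d}", gene5=pairs[k][0], gene3=pairs[k][1],
            exclusivity="normal_present", frame_truth="in_frame",
            oncogenic_domain=False, mean_support=7.0, n_LM=2, n_N=1))
        k += 1
    cat.append(PlantedFusion(
        fusion_id="LOW01", gene5=pairs[k][0], gene3=pairs[k][1],
        exclusivity="LM_unique", frame_truth="in_frame", oncogenic_domain=False,
        mean_support=3.0, n_LM=2))
    k += 1
    cat.append(PlantedFusion(
        fusion_id="ONE01", gene5=pairs[k][0], gene3=pairs[k][1],
        exclusivity="LM_unique", frame_truth="in_frame", oncogenic_domain=False,
        mean_support=6.0, n_LM=2, callers=frozenset({"soapfuse"})))
    k += 1
    cat.append(PlantedFusion(
        fusion_id="NCG01", gene5=pairs[k][0], gene3="NC01",
        exclusivity="LM_unique", frame_truth="noncoding", oncogenic_domain=False,
        mean_support=6.0, n_LM=2))
    return cat


# ---------------------------------------------------------------------------
# Toy annotation
# ---------------------------------------------------------------------------

@dataclass
class ToyAnnotation:
    models: list[TranscriptModel]
    sequences: dict[str, str]           # transcript_id -> mature sequence
    domains: list[DomainRecord]

    def model_for_gene(self, gene: str) -> TranscriptModel:
        for m in self.models:
            if m.gene == gene:
                return m
        raise KeyError(gene)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n sense codons (no in-frame stops)."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(NUCLEOTIDES, size=3))
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=n))


def _partition(rng: np.random.Generator, total: int, k: int, lo: int) -> list[int]:
    """Split `total` into k parts each >= lo (k*lo <= total)."""
    extra = total - k * lo
    cuts = np.sort(rng.integers(0, extra + 1, size=k - 1)) if k > 1 else np.array([], int)
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [lo + int(p) for p in parts]


def build_toy_annotation(cfg: SimulationConfig,
                         rng: Optional[np.random.Generator] = None) -> ToyAnnotation:
    """Generate coding + noncoding toy transcripts across several chromosomes.

    Every CDS begins with ATG, ends with a stop codon, has length
    divisible by 3 and no internal in-frame stop; the mature FASTA
    sequence is consistent with the GTF exon structure by construction.
    """
    lo_e, hi_e = cfg.exon_length_range
    if lo_e < 10 or lo_e > hi_e:
        raise ValueError("infeasible exon length range")
    rng = rng or np.random.default_rng(cfg.seed)
    gene_names = [f"G{i:02d}" for i in range(1, cfg.n_coding_genes + 1)] + \
                 [f"NC{i:02d}" for i in range(1, cfg.n_noncoding_genes + 1)]
    chroms = [f"chr{i:02d}" for i in range(1, cfg.n_chromosomes + 1)]
    cursor = {c: 10_000 for c in chroms}
    models, seqs, domains = [], {}, []
    for gi, gene in enumerate(gene_names):
        coding = gene.startswith("G")
        utr5 = int(rng.integers(*cfg.utr5_length_range))
        utr3 = int(rng.integers(*cfg.utr3_length_range))
        if coding:
            n_codons = int(rng.integers(*cfg.cds_codons_range))
            cds = "ATG" + _random_codons(rng, n_codons - 2) + \
                  str(rng.choice(["TAA", "TAG", "TGA"]))
            seq = _random_nt(rng, utr5) + cds + _random_nt(rng, utr3)
        else:
            seq = _random_nt(rng, utr5 + utr3 + 300)
        L = len(seq)
        k = int(rng.integers(*cfg.exon_count_range))
        k = max(1, min(k, L // lo_e))
        exon_lens = _partition(rng, L, k, lo_e)
        chrom = chroms[gi % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor[chrom]
        for el in exon_lens:
            exons.append((pos, pos + el - 1))
            pos += el + int(rng.integers(*cfg.intron_length_range))
        cursor[chrom] = pos + 5_000
        tid = f"T_{gene}"
        # exon list is in genomic order; for '-' the designed sequence still
        # reads along the transcript, so offsets map via TranscriptModel
        model = TranscriptModel(transcript_id=tid, gene=gene, chrom=chrom,
                                strand=strand, exons=exons,
                                biotype="protein_coding" if coding else "noncoding")
        if coding:
            cs, ce = utr5 + 1, utr5 + len(cds)
            g1, g2 = model.genomic_position(cs), model.genomic_position(ce)
            model.cds_start_genomic, model.cds_end_genomic = min(g1, g2), max(g1, g2)
            model = TranscriptModel(  # revalidate with CDS bounds
                transcript_id=tid, gene=gene, chrom=chrom, strand=strand,
                exons=exons, cds_start_genomic=model.cds_start_genomic,
                cds_end_genomic=model.cds_end_genomic, biotype="protein_coding")
            prot_len = len(cds) // 3 - 1
            for _ in range(int(rng.integers(1, 3))):
                a = int(rng.integers(1, max(2, prot_len - 10)))
                b = min(prot_len, a + int(rng.integers(8, 40)))
                domains.append(DomainRecord(tid, str(rng.choice(DOMAIN_NAMES)),
                                            aa_start=a, aa_end=b, oncogenic=False))
        models.append(model)
        seqs[tid] = seq
    return ToyAnnotation(models=models, sequences=seqs, domains=domains)


# ---------------------------------------------------------------------------
# Junction planting
# ---------------------------------------------------------------------------

_EDGE_MARGIN = 4  # keep junctions this far inside an exon so jitter stays exonic


def _exon_safe(model: TranscriptModel, offset: int) -> bool:
    pos = model.genomic_position(offset)
    for a, b in model.exons:
        if a <= pos <= b:
            return (pos - a) >= _EDGE_MARGIN and (b - pos) >= _EDGE_MARGIN
    return False


def _plant_junction(
    tx5: TranscriptModel, tx3: TranscriptModel, frame_truth: str,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Pick transcript offsets (o5, o3) realizing the requested frame truth."""
    if frame_truth == "noncoding":
        for _ in range(500):
            o5 = int(rng.integers(1, tx5.length + 1))
            o3 = int(rng.integers(1, tx3.length + 1))
            if _exon_safe(tx5, o5) and _exon_safe(tx3, o3):
                return o5, o3
        raise ValueError("could not place noncoding junction")
    cs5, ce5 = tx5.cds_start_offset, tx5.cds_end_offset
    cs3, ce3 = tx3.cds_start_offset, tx3.cds_end_offset
    if frame_truth == "utr":
        for _ in range(500):
            o5 = int(rng.integers(1, cs5))  # strictly upstream of CDS start
            if _exon_safe(tx5, o5) and _exon_safe(tx3, cs3):
                return o5, cs3              # 3' ORF intact
        raise ValueError("could not place 5'UTR junction (5'UTR too short?)")
    for _ in range(500):
        o5 = int(rng.integers(cs5 + 30, ce5 - 10))   # retained >= 31 nt
        o3 = int(rng.integers(cs3 + 1, ce3 - 60))
        retained = o5 - cs5 + 1
        skipped = o3 - cs3
        want = (retained - skipped) % 3 == 0
        have = frame_truth == "in_frame"
        if want != have:
            shift = (retained - skipped) % 3 if have else 1
            o3 += shift
            skipped += shift
        if _exon_safe(tx5, o5) and _exon_safe(tx3, o3) and skipped > 0:
            return o5, o3
    raise ValueError(f"could not place {frame_truth} junction")


@dataclass
class PlantedTruth:
    """Resolved truth for one planted fusion."""

    fusion: PlantedFusion
    bp5: GenomicBreakpoint
    bp3: GenomicBreakpoint
    carriers: dict[str, int]          # sample_id -> drawn support
    retained_cds5_nt: int = 0
    skipped_cds3_nt: int = 0


def _draw_support(mean: float, rng: np.random.Generator) -> int:
    if mean >= 5:
        return 5 + int(rng.poisson(mean - 5))
    return max(1, int(rng.poisson(mean)))


def _make_sheet(cfg: SimulationConfig) -> SampleSheet:
    rows = []
    for p in range(1, cfg.n_paired_patients + 1):
        pid = f"P{p:02d}"
        rows += [(f"{pid}-LM", "LM", pid), (f"{pid}-T", "pCRC", pid), (f"{pid}-N", "N", pid)]
    for u in range(1, cfg.n_unpaired_LM + 1):
        rows.append((f"U{u:02d}-LM", "LM", f"U{u:02d}"))
    return SampleSheet(rows=rows)


def plant_and_emit_calls(
    cfg: SimulationConfig, ann: ToyAnnotation, outdir: str | Path,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PlantedTruth], SampleSheet]:
    """Emit per-sample per-caller dialect call files plus the truth table.

    Oncogenic domains implied by the catalog are appended to the
    annotation's domain table so that driver truth is realizable.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    outdir = Path(outdir)
    (outdir / "calls").mkdir(parents=True, exist_ok=True)
    catalog = cfg.catalog if cfg.catalog is not None else default_catalog()
    sheet = _make_sheet(cfg)

    truths: list[PlantedTruth] = []
    for pf in catalog:
        tx5 = ann.model_for_gene(pf.gene5)
        tx3 = ann.model_for_gene(pf.gene3)
        o5, o3 = _plant_junction(tx5, tx3, pf.frame_truth, rng)
        bp5 = GenomicBreakpoint(tx5.chrom, tx5.genomic_position(o5), tx5.strand)
        bp3 = GenomicBreakpoint(tx3.chrom, tx3.genomic_position(o3), tx3.strand)
        retained = max(0, o5 - (tx5.cds_start_offset or o5 + 1) + 1) if tx5.is_coding else 0
        skipped = max(0, o3 - (tx3.cds_start_offset or o3)) if tx3.is_coding else 0
        carriers: dict[str, int] = {}
        for cls, n in (("LM", pf.n_LM), ("pCRC", pf.n_pCRC), ("N", pf.n_N)):
            pool = sheet.samples_of_class(cls)
            for s in rng.choice(pool, size=n, replace=False):
                carriers[str(s)] = _draw_support(pf.mean_support, rng)
        truths.append(PlantedTruth(pf, bp5, bp3, carriers,
                                   retained_cds5_nt=retained, skipped_cds3_nt=skipped))
        if pf.oncogenic_domain:
            ann.domains.extend(_oncogenic_domains_for(pf, tx5, tx3, retained, skipped))

    _write_caller_files(cfg, ann, truths, sheet, outdir / "calls", rng)
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    _write_truth_table(truths, outdir / "truth_table.tsv")
    return truths, sheet


def _oncogenic_domains_for(pf, tx5, tx3, retained, skipped) -> list[DomainRecord]:
    if pf.frame_truth == "utr":
        prot3 = tx3.cds_length // 3 - 1
        return [DomainRecord(tx3.transcript_id, "SPT4",
                             aa_start=max(1, skipped // 3 + 1),
                             aa_end=min(prot3, skipped // 3 + 20), oncogenic=True)]
    j5 = retained // 3
    out = [DomainRecord(tx5.transcript_id, "ArfGAP",
                        aa_start=max(1, j5 - 8), aa_end=j5, oncogenic=True)]
    a3 = skipped // 3 + 1
    prot3 = tx3.cds_length // 3 - 1
    if a3 + 10 <= prot3:
        out.append(DomainRecord(tx3.transcript_id, "CBF",
                                aa_start=a3 + 1, aa_end=min(prot3, a3 + 15), oncogenic=True))
    return out


def _jitter(pos: int, sd: float, rng: np.random.Generator) -> int:
    if sd <= 0:
        return pos
    return max(1, pos + int(round(rng.normal(0.0, sd))))


def _write_caller_files(cfg, ann, truths, sheet, calls_dir: Path,
                        rng: np.random.Generator) -> None:
    callers = sorted(cfg.sensitivity)
    coding_models = [m for m in ann.models if m.is_coding]
    rows: dict[tuple[str, str], list[dict]] = {
        (s, c): [] for s in sheet.sample_ids for c in callers}

    for t in truths:
        allowed = t.fusion.callers
        for sample in sorted(t.carriers):
            support = t.carriers[sample]
            for caller in callers:
                if allowed is not None and caller not in allowed:
                    continue
                if rng.random() > cfg.sensitivity[caller]:
                    continue
                rows[(sample, caller)].append({
                    "gene5": t.fusion.gene5, "gene3": t.fusion.gene3,
                    "chrom5": t.bp5.chrom, "pos5": _jitter(t.bp5.pos, cfg.jitter_sd, rng),
                    "strand5": t.bp5.strand,
                    "chrom3": t.bp3.chrom, "pos3": _jitter(t.bp3.pos, cfg.jitter_sd, rng),
                    "strand3": t.bp3.strand,
                    "spanning": support, "crossing": int(rng.integers(0, support + 1)),
                })
    # private false positives
    for sample in sheet.sample_ids:
        for caller in callers:
            for _ in range(int(rng.poisson(cfg.fp_rate))):
                m5, m3 = rng.choice(coding_models, size=2, replace=False)
                o5 = int(rng.integers(1, m5.length + 1))
                o3 = int(rng.integers(1, m3.length + 1))
                rows[(sample, caller)].append({
                    "gene5": m5.gene, "gene3": m3.gene,
                    "chrom5": m5.chrom, "pos5": m5.genomic_position(o5),
                    "strand5": m5.strand,
                    "chrom3": m3.chrom, "pos3": m3.genomic_position(o3),
                    "strand3": m3.strand,
                    "spanning": int(rng.integers(1, 10)), "crossing": int(rng.integers(0, 5)),
                })

    for (sample, caller), rws in sorted(rows.items()):
        d = calls_dir / sample
        d.mkdir(parents=True, exist_ok=True)
        _write_dialect_file(d / f"{caller}.tsv", caller, rws)


def _write_dialect_file(path: Path, caller: str, rows: list[dict]) -> None:
    headers = {
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
    }[caller]
    with open(path, "w") as fh:
        fh.write("\t".join(headers) + "\n")
        for r in rows:
            if caller == "arriba":
                vals = [r["gene5"], r["gene3"], f"{r['chrom5']}:{r['pos5']}",
                        f"{r['chrom3']}:{r['pos3']}", r["strand5"], r["strand3"],
                        r["spanning"], r["crossing"]]
            elif caller == "defuse":
                vals = [r["gene5"], r["gene3"], r["chrom5"], r["pos5"], r["strand5"],
                        r["chrom3"], r["pos3"], r["strand3"], r["spanning"], r["crossing"]]
            elif caller == "soapfuse":
                vals = [r["gene5"], r["chrom5"], r["strand5"], r["pos5"], r["gene3"],
                        r["chrom3"], r["strand3"], r["pos3"], r["spanning"], r["crossing"]]
            else:  # clc, 0-based
                vals = [r["gene5"], r["gene3"], r["chrom5"], r["pos5"] - 1, r["strand5"],
                        r["chrom3"], r["pos3"] - 1, r["strand3"], r["spanning"], r["crossing"]]
            fh.write("\t".join(str(v) for v in vals) + "\n")


TRUTH_COLUMNS = ["fusion_id", "gene5", "gene3", "chrom5", "pos5", "strand5",
                 "chrom3", "pos3", "strand3", "exclusivity", "frame_truth",
                 "oncogenic_domain", "retained_cds5_nt", "skipped_cds3_nt", "carriers"]


def _write_truth_table(truths: Sequence[PlantedTruth], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            carriers = ";".join(f"{s}:{n}" for s, n in sorted(t.carriers.items()))
            fh.write("\t".join(str(v) for v in [
                t.fusion.fusion_id, t.fusion.gene5, t.fusion.gene3,
                t.bp5.chrom, t.bp5.pos, t.bp5.strand,
                t.bp3.chrom, t.bp3.pos, t.bp3.strand,
                t.fusion.exclusivity, t.fusion.frame_truth,
                int(t.fusion.oncogenic_domain),
                t.retained_cds5_nt, t.skipped_cds3_nt, carriers]) + "\n")


# ---------------------------------------------------------------------------
# Expression and survival
# ---------------------------------------------------------------------------

def emit_expression_and_survival(
    cfg: SimulationConfig, outdir: str | Path,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Emit the qPCR Ct table and the survival table for the focal fusion.

    The validation cohort is modelled independently of the RNA-seq cohort,
    as in the study design: fusion-positive samples from both tissue
    groups are assayed, with the metastatic group's target Ct lowered by
    log2(fold_change); survival times are exponential with hazard
    h0 * HR^(fusion_positive) and a configurable censored fraction.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    outdir = Path(outdir)
    with open(outdir / "ct_table.csv", "w") as fh:
        fh.write("sample_id,group,target_ct,reference_ct\n")
        for group, n in (("mCRC", cfg.n_expr_mcrc), ("pCRC", cfg.n_expr_pcrc)):
            shift = math.log2(cfg.fold_change) if group == "mCRC" else 0.0
            for i in range(1, n + 1):
                ref = rng.normal(cfg.ref_ct_mean, cfg.ref_ct_sd)
                tgt = ref + cfg.baseline_delta_ct - shift + rng.normal(0.0, cfg.ct_noise_sd)
                fh.write(f"Q-{group}-{i:02d},{group},{tgt:.4f},{ref:.4f}\n")

    n_pos = cfg.n_survival_positive
    n_neg = cfg.n_survival - n_pos
    with open(outdir / "survival_table.csv", "w") as fh:
        fh.write("sample_id,time_months,event,fusion_positive\n")
        rows = []
        for pos, n in ((True, n_pos), (False, n_neg)):
            h = cfg.baseline_hazard * (cfg.hazard_ratio if pos else 1.0)
            for i in range(1, n + 1):
                t = float(rng.exponential(1.0 / h))
                rows.append([f"S-{'pos' if pos else 'neg'}-{i:02d}", t, 1, int(pos)])
        n_cens = int(round(cfg.censoring_fraction * len(rows)))
        if n_cens:
            for idx in rng.choice(len(rows), size=n_cens, replace=False):
                rows[idx][1] = float(rng.uniform(0.0, rows[idx][1]))
                rows[idx][2] = 0
        for sid, t, ev, pos in rows:
            fh.write(f"{sid},{t:.4f},{ev},{pos}\n")


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(cfg: SimulationConfig, outdir: str | Path
                    ) -> tuple[ToyAnnotation, list[PlantedTruth], SampleSheet]:
    """Generate the complete input bundle under ``outdir``.

    Files: annotation.gtf, transcripts.fa, domains.tsv, sample_sheet.tsv,
    truth_table.tsv, ct_table.csv, survival_table.csv, and
    calls/<sample>/<caller>.tsv for every sample and caller.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ann = build_toy_annotation(cfg, rng)
    truths, sheet = plant_and_emit_calls(cfg, ann, outdir, rng)
    emit_expression_and_survival(cfg, outdir, rng)
    write_gtf(ann.models, outdir / "annotation.gtf")
    write_transcript_fasta(ann.sequences, outdir / "transcripts.fa")
    write_domain_table(ann.domains, outdir / "domains.tsv")
    return ann, truths, sheet
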