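"""Cross-caller and cross-sample consensus of fusion calls.

Fusion callers disagree on exact breakpoint coordinates by a few bases
(exon-boundary ambiguity), so calls are matched with a configurable
positional tolerance (default 10 nt) and clustered by single linkage.
Within a sample, a fusion is *cross-validated* when at least ``min_tools``
distinct callers report it (multiple calls from one caller count as one
vote).  Validated per-sample clusters sharing gene pair and coordinates
are then merged across samples into cohort-level events.

All steps are deterministic and invariant to input order: inputs are
canonically sorted before clustering and cluster representatives use the
per-end median position, taking the lower of the two middle values for
even cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import FusionCall, GenomicBreakpoint, SampleSheet, TISSUE_CLASSES

__all__ = ["ValidatedCluster", "ConsensusEvent", "match_calls", "cross_validate",
           "merge_events", "DEFAULT_TOL", "DEFAULT_MIN_TOOLS"]

DEFAULT_TOL = 10
DEFAULT_MIN_TOOLS = 2


def match_calls(a: FusionCall, b: FusionCall, tol: int = DEFAULT_TOL) -> bool:
    """True iff two calls describe the same fusion within ``tol`` nt.

    Requires equal ordered gene pairs, equal chromosomes and strands at
    both ends, and per-end position differences <= tol.  Symmetric.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    return (
        a.gene5 == b.gene5 and a.gene3 == b.gene3
        and a.bp5.chrom == b.bp5.chrom and a.bp3.chrom == b.bp3.chrom
        and a.bp5.strand == b.bp5.strand and a.bp3.strand == b.bp3.strand
        and abs(a.bp5.pos - b.bp5.pos) <= tol
        and abs(a.bp3.pos - b.bp3.pos) <= tol
    )


@dataclass
class ValidatedCluster:
    """A cross-validated fusion within one sample."""

    sample_id: str
    gene5: str
    gene3: str
    bp5: GenomicBreakpoint
    bp3: GenomicBreakpoint
    callers: frozenset[str]
    spanning_reads: int
    crossing_reads: int
    members: tuple[FusionCall, ...] = ()


@dataclass
class ConsensusEvent:
    """A cohort-level fusion event after cross-caller/cross-sample merging."""

    gene5: str
    gene3: str
    bp5: GenomicBreakpoint
    bp3: GenomicBreakpoint
    callers_by_sample: dict[str, frozenset[str]] = field(default_factory=dict)
    support_by_sample: dict[str, int] = field(default_factory=dict)
    crossing_by_sample: dict[str, int] = field(default_factory=dict)
    samples_by_class: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def max_support(self) -> int:
        return max(self.support_by_sample.values(), default=0)

    @property
    def max_callers(self) -> int:
        return max((len(v) for v in self.callers_by_sample.values()), default=0)

    def n_samples(self, cls: str) -> int:
        return len(self.samples_by_class.get(cls, ()))

    @property
    def key(self) -> tuple:
        return (self.gene5, self.gene3, self.bp5.chrom, self.bp5.pos, self.bp5.strand,
                self.bp3.chrom, self.bp3.pos, self.bp3.strand)


def _median_low(values: Sequence[int]) -> int:
    """Median; lower of the two middle values for even counts."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _sort_key(c: FusionCall) -> tuple:
    return (c.sample_id, c.gene5, c.gene3, c.bp5.chrom, c.bp5.pos, c.bp3.chrom,
            c.bp3.pos, c.caller, c.spanning_reads, c.crossing_reads)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _single_linkage(items: list, match) -> list[list]:
    """Transitive clustering; O(n^2) pairwise, adequate at cohort scale
    because items are pre-bucketed by sample/gene pair."""
    uf = _UnionFind(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if match(items[i], items[j]):
                uf.union(i, j)
    groups: dict[int, list] = {}
    for i, it in enumerate(items):
        groups.setdefault(uf.find(i), []).append(it)
    return [groups[k] for k in sorted(groups)]


def cross_validate(
    calls: Iterable[FusionCall],
    min_tools: int = DEFAULT_MIN_TOOLS,
    tol: int = DEFAULT_TOL,
) -> list[ValidatedCluster]:
    """Cluster calls per sample and keep clusters seen by >= min_tools callers."""
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    buckets: dict[tuple, list[FusionCall]] = {}
    for c in sorted(calls, key=_sort_key):
        buckets.setdefault((c.sample_id, c.gene5, c.gene3,
                            c.bp5.chrom, c.bp5.strand, c.bp3.chrom, c.bp3.strand), []).append(c)
    out: list[ValidatedCluster] = []
    for key in sorted(buckets):
        for members in _single_linkage(buckets[key], lambda a, b: match_calls(a, b, tol)):
            callers = frozenset(m.caller for m in members)
            if len(callers) < min_tools:
                continue
            out.append(ValidatedCluster(
                sample_id=members[0].sample_id,
                gene5=members[0].gene5, gene3=members[0].gene3,
                bp5=GenomicBreakpoint(members[0].bp5.chrom,
                                      _median_low([m.bp5.pos for m in members]),
                                      members[0].bp5.strand),
                bp3=GenomicBreakpoint(members[0].bp3.chrom,
                                      _median_low([m.bp3.pos for m in members]),
                                      members[0].bp3.strand),
                callers=callers,
                spanning_reads=max(m.spanning_reads for m in members),
                crossing_reads=max(m.crossing_reads for m in members),
                members=tuple(members),
            ))
    out.sort(key=lambda v: (v.gene5, v.gene3, v.bp5.pos, v.bp3.pos, v.sample_id))
    return out


def merge_events(
    validated: Iterable[ValidatedCluster],
    sheet: SampleSheet,
    tol: int = DEFAULT_TOL,
) -> list[ConsensusEvent]:
    """Merge per-sample validated clusters into cohort-level events.

    Clusters with the same gene pair whose representative breakpoints lie
    within ``tol`` at both ends (single linkage across samples) become one
    event; ``samples_by_class`` is populated from the sample sheet.
    Raises if a sample is absent from the sheet.
    """
    validated = sorted(validated, key=lambda v: (v.gene5, v.gene3, v.bp5.chrom,
                                                 v.bp5.pos, v.bp3.pos, v.sample_id))
    known = set(sheet.sample_ids)
    for v in validated:
        if v.sample_id not in known:
            raise ValueError(f"sample {v.sample_id!r} absent from sample sheet")

    buckets: dict[tuple, list[ValidatedCluster]] = {}
    for v in validated:
        buckets.setdefault((v.gene5, v.gene3, v.bp5.chrom, v.bp5.strand,
                            v.bp3.chrom, v.bp3.strand), []).append(v)

    def near(a: ValidatedCluster, b: ValidatedCluster) -> bool:
        return abs(a.bp5.pos - b.bp5.pos) <= tol and abs(a.bp3.pos - b.bp3.pos) <= tol

    events: list[ConsensusEvent] = []
    for key in sorted(buckets):
        for members in _single_linkage(buckets[key], near):
            ev = ConsensusEvent(
                gene5=members[0].gene5, gene3=members[0].gene3,
                bp5=GenomicBreakpoint(members[0].bp5.chrom,
                                      _median_low([m.bp5.pos for m in members]),
                                      members[0].bp5.strand),
                bp3=GenomicBreakpoint(members[0].bp3.chrom,
                                      _median_low([m.bp3.pos for m in members]),
                                      members[0].bp3.strand),
            )
            callers: dict[str, set[str]] = {}
            for m in members:
                callers.setdefault(m.sample_id, set()).update(m.callers)
                ev.support_by_sample[m.sample_id] = max(
                    ev.support_by_sample.get(m.sample_id, 0), m.spanning_reads)
                ev.crossing_by_sample[m.sample_id] = max(
                    ev.crossing_by_sample.get(m.sample_id, 0), m.crossing_reads)
            ev.callers_by_sample = {s: frozenset(cs) for s, cs in sorted(callers.items())}
            by_class: dict[str, set[str]] = {cls: set() for cls in TISSUE_CLASSES}
            for s in ev.callers_by_sample:
                by_class[sheet.tissue_class(s)].add(s)
            ev.samples_by_class = {cls: frozenset(v) for cls, v in by_class.items()}
            events.append(ev)
    events.sort(key=lambda e: e.key)
    return events
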