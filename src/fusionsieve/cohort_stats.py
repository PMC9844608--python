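"""Cohort-level category tallies and recurrence summaries.

Events that survive normal exclusion fall into three exclusivity classes
(metastasis-unique, primary-unique, shared) and are tallied along three
dichotomies: intra- vs interchromosomal, coding vs non-coding, in-frame vs
out-of-frame.  Percentages are rounded half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .consensus import ConsensusEvent
from .formats_io import SampleSheet

__all__ = ["AnnotatedEvent", "CohortCounts", "tabulate", "percent", "recurrence_table"]

COUNT_CLASSES = ("LM_unique", "pCRC_unique", "common")


@dataclass(frozen=True)
class AnnotatedEvent:
    """Minimal per-event annotation needed for category tallies."""

    gene5: str
    gene3: str
    exclusivity_class: str
    fusion_type: str          # intrachromosomal | interchromosomal
    coding: bool
    in_frame: bool            # True for in_frame / intact-ORF read-through


@dataclass
class CohortCounts:
    """Per-class counts along the three dichotomies."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def total(self, cls: str) -> int:
        c = self.counts[cls]
        return c["intrachromosomal"] + c["interchromosomal"]


def tabulate(events: Iterable[AnnotatedEvent]) -> CohortCounts:
    """Count events by exclusivity class x dichotomy.

    Every event must carry a class from {LM_unique, pCRC_unique, common};
    anything else (e.g. normal_present leaking past the cascade) raises.
    """
    counts = {cls: {"intrachromosomal": 0, "interchromosomal": 0,
                    "coding": 0, "noncoding": 0,
                    "in_frame": 0, "out_of_frame": 0}
              for cls in COUNT_CLASSES}
    for ev in events:
        if ev.exclusivity_class not in COUNT_CLASSES:
            raise ValueError(
                f"event {ev.gene5}--{ev.gene3}: unexpected class {ev.exclusivity_class!r}")
        if ev.fusion_type not in ("intrachromosomal", "interchromosomal"):
            raise ValueError(f"event {ev.gene5}--{ev.gene3}: bad type {ev.fusion_type!r}")
        c = counts[ev.exclusivity_class]
        c[ev.fusion_type] += 1
        c["coding" if ev.coding else "noncoding"] += 1
        c["in_frame" if ev.in_frame else "out_of_frame"] += 1
    return CohortCounts(counts=counts)


def percent(count: int, total: int, dp: int = 1) -> float:
    """100*count/total rounded half-away-from-zero to dp decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError(f"require 0 <= count <= total, got {count}/{total}")
    q = Decimal(1).scaleb(-dp)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def recurrence_table(
    events: Iterable[ConsensusEvent], sheet: Optional[SampleSheet] = None
) -> list[tuple[str, str, int]]:
    """Per-event count of distinct metastatic (LM) samples.

    Sorted descending by count, then lexicographically by gene pair.
    The sample sheet is accepted for interface symmetry; class membership
    already lives on the events.
    """
    rows = [(ev.gene5, ev.gene3, ev.n_samples("LM")) for ev in events]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows
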