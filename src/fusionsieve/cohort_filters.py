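"""The discovery filter cascade and tissue-exclusivity classification.

After cross-caller consensus, candidate fusion events pass through a fixed
sequence of filters before annotation:

1. read support — max spanning reads over samples >= ``min_support``
   (default 5; crossing reads are reported but not thresholded),
2. coding — both partner breakpoints fall inside exons of protein-coding
   transcripts,
3. normal exclusion — events present in any normal-tissue (N) sample are
   discarded,
4. exclusivity — only events of the configured target class (default
   ``LM_unique``: observed in liver-metastasis samples and in no primary
   tumor) are retained.

"Upregulated in metastasis" is operationalized as presence/absence
exclusivity rather than a count-based differential test: per-event
junction-read counts are far too sparse to calibrate one.  Every event
receives a :class:`FilterTrace` recording its exclusivity class and the
first failing stage, so per-stage attrition is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .consensus import ConsensusEvent
from .formats_io import TranscriptModel

__all__ = ["FilterTrace", "CascadeConfig", "EXCLUSIVITY_CLASSES",
           "classify_exclusivity", "filter_read_support", "filter_coding",
           "apply_cascade"]

EXCLUSIVITY_CLASSES = ("LM_unique", "pCRC_unique", "common", "normal_present")

STAGES = ("read_support", "coding", "normal_exclusion", "exclusivity")


@dataclass
class FilterTrace:
    """Per-event record of cascade outcome."""

    gene5: str
    gene3: str
    exclusivity_class: str
    stage_pass: dict[str, bool] = field(default_factory=dict)
    failed_stage: Optional[str] = None
    fail_reason: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.failed_stage is None


@dataclass
class CascadeConfig:
    min_tools: int = 2
    min_support: int = 5
    breakpoint_tol: int = 10
    target_class: str = "LM_unique"

    def __post_init__(self) -> None:
        if self.target_class not in ("LM_unique", "pCRC_unique", "common"):
            raise ValueError(f"unknown target_class {self.target_class!r}")


def classify_exclusivity(event: ConsensusEvent) -> str:
    """Assign exactly one exclusivity class from per-class sample presence.

    Normal presence dominates: an event seen in any N sample is
    ``normal_present`` regardless of tumor-tissue spread.
    """
    n_lm = event.n_samples("LM")
    n_p = event.n_samples("pCRC")
    n_n = event.n_samples("N")
    if n_lm + n_p + n_n == 0:
        raise ValueError(f"event {event.gene5}--{event.gene3} present in no sample")
    if n_n > 0:
        return "normal_present"
    if n_lm > 0 and n_p == 0:
        return "LM_unique"
    if n_p > 0 and n_lm == 0:
        return "pCRC_unique"
    return "common"


def filter_read_support(event: ConsensusEvent, min_support: int = 5) -> bool:
    """True iff max spanning-read support over samples >= min_support."""
    if min_support < 0:
        raise ValueError("min_support must be >= 0")
    return event.max_support >= min_support


def filter_coding(
    event: ConsensusEvent, models: Sequence[TranscriptModel]
) -> tuple[bool, Optional[str]]:
    """Both breakpoints must be exonic in some protein-coding transcript.

    Returns ``(passed, reason)`` with reason ``"unannotated"`` when a
    partner gene has no transcript model and ``"not exonic"`` when no
    coding transcript's exons contain the breakpoint.
    """
    for gene, bp in ((event.gene5, event.bp5), (event.gene3, event.bp3)):
        gene_models = [m for m in models if m.gene == gene]
        if not gene_models:
            return False, "unannotated"
        coding = [m for m in gene_models
                  if m.biotype == "protein_coding" and m.chrom == bp.chrom
                  and m.transcript_offset(bp.pos) is not None]
        if not coding:
            return False, "not exonic"
    return True, None


def apply_cascade(
    events: Iterable[ConsensusEvent],
    models: Sequence[TranscriptModel],
    config: CascadeConfig,
) -> tuple[list[ConsensusEvent], list[FilterTrace]]:
    """Run the fixed filter cascade; every event gets a FilterTrace.

    Stage order: read support -> coding -> normal exclusion -> exclusivity
    (cross-validation happened upstream in consensus).  The final set is
    order-independent; the order matters only for attributing the first
    failing stage in the trace.
    """
    passing: list[ConsensusEvent] = []
    traces: list[FilterTrace] = []
    for ev in events:
        cls = classify_exclusivity(ev)
        trace = FilterTrace(gene5=ev.gene5, gene3=ev.gene3, exclusivity_class=cls)

        ok = filter_read_support(ev, config.min_support)
        trace.stage_pass["read_support"] = ok
        if not ok and trace.failed_stage is None:
            trace.failed_stage, trace.fail_reason = "read_support", (
                f"max support {ev.max_support} < {config.min_support}")

        ok, reason = filter_coding(ev, models)
        trace.stage_pass["coding"] = ok
        if not ok and trace.failed_stage is None:
            trace.failed_stage, trace.fail_reason = "coding", reason

        ok = cls != "normal_present"
        trace.stage_pass["normal_exclusion"] = ok
        if not ok and trace.failed_stage is None:
            trace.failed_stage, trace.fail_reason = "normal_exclusion", "present in normal tissue"

        ok = cls == config.target_class
        trace.stage_pass["exclusivity"] = ok
        if not ok and trace.failed_stage is None:
            trace.failed_stage, trace.fail_reason = "exclusivity", f"class {cls}"

        traces.append(trace)
        if trace.passed:
            passing.append(ev)
    return passing, traces
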