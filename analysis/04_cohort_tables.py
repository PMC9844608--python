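"""Cohort category tables and recurrence summaries.

Tallies non-normal events by exclusivity class along the three
dichotomies (intra/interchromosomal, coding/non-coding, in/out of frame)
and ranks fusions by metastatic recurrence — the synthetic analogue of
the published cohort tables, plus the packaged printed-table worked
example.
"""

import csv
from pathlib import Path

from fusionsieve.chimera_annotation import annotate_chimera, classify_type, select_transcript
from fusionsieve.cohort_filters import classify_exclusivity
from fusionsieve.cohort_stats import AnnotatedEvent, percent, recurrence_table, tabulate
from fusionsieve.consensus import cross_validate, merge_events
from fusionsieve.fixtures import load_table2_counts, table1_events
from fusionsieve.formats_io import read_caller_calls, read_gtf, read_sample_sheet

SIM = Path("results/analysis/sim")
OUT = Path("results/analysis")

calls = []
for sample_dir in sorted((SIM / "calls").iterdir()):
    for f in sorted(sample_dir.glob("*.tsv")):
        calls.extend(read_caller_calls(f, f.stem, sample_id=sample_dir.name)[0])
sheet = read_sample_sheet(SIM / "sample_sheet.tsv")
models = read_gtf(SIM / "annotation.gtf")
events = merge_events(cross_validate(calls, min_tools=2, tol=10), sheet, tol=10)

annotated = []
for ev in events:
    cls = classify_exclusivity(ev)
    if cls == "normal_present":
        continue
    tx5, tx3 = select_transcript(models, ev.gene5), select_transcript(models, ev.gene3)
    coding = in_frame = False
    if tx5 and tx3:
        try:
            ch = annotate_chimera(ev.bp5, ev.bp3, tx5, tx3)
            coding = ch.frame_status != "noncoding"
            in_frame = ch.frame_status == "in_frame" or (
                ch.frame_status == "five_prime_utr_fusion" and bool(ch.intact_3p_orf))
        except ValueError:
            pass
    annotated.append(AnnotatedEvent(ev.gene5, ev.gene3, cls,
                                    classify_type(ev.bp5, ev.bp3), coding, in_frame))

counts = tabulate(annotated)
with open(OUT / "category_counts.tsv", "w", newline="") as fh:
    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
    w.writerow(["exclusivity_class", "category", "count", "pct"])
    for cls, c in counts.counts.items():
        total = counts.total(cls)
        for cat, n in c.items():
            w.writerow([cls, cat, n, percent(n, total) if total else 0.0])
for cls in ("LM_unique", "pCRC_unique", "common"):
    c, total = counts.counts[cls], counts.total(cls)
    if total:
        print(f"{cls}: {total} events, {c['coding']} coding "
              f"({percent(c['coding'], total)}%), {c['in_frame']} frame-preserving")

rec = recurrence_table(events, sheet)
with open(OUT / "recurrence.tsv", "w", newline="") as fh:
    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
    w.writerow(["gene5", "gene3", "n_LM_samples"])
    w.writerows(rec)
top = [r for r in rec if r[2] >= 2][:3]
print("most recurrent LM fusions:", ", ".join(f"{a}--{b} ({n})" for a, b, n in top))

# worked example on the printed driver/count fixtures
fix_rec = {(a, b): n for a, b, n in recurrence_table(table1_events())}
t2 = load_table2_counts()
p_total = t2["pCRC_unique"]["coding"] + t2["pCRC_unique"]["noncoding"]
print(f"printed-table check: flagship recurrences "
      f"{fix_rec[('ADAP1', 'NOC4L')]} and {fix_rec[('RNF43', 'SUPT4H1')]}; "
      f"primary-unique coding share {percent(t2['pCRC_unique']['coding'], p_total)}%")
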