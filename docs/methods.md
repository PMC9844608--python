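# Methods

## Problem and scope

`fusionsieve` post-processes RNA-seq gene-fusion calls from a cohort of
paired liver-metastasis (LM), primary colorectal tumor (pCRC) and normal
(N) specimens to nominate candidate driver chimeras.  It does not call
fusions from reads: caller outputs (or simulated equivalents) are its
input.  The analysis chain is

1. **dialect normalization** — caller-specific TSVs become canonical
   calls (1-based coordinates, ordered 5′→3′ gene pair, spanning and
   crossing read counts);
2. **cross-caller consensus** — within each sample, calls from distinct
   callers that agree on the gene pair, chromosomes, strands and
   breakpoint positions within a tolerance are clustered (single
   linkage); a cluster is *cross-validated* if ≥ `min_tools` distinct
   callers contribute (default 2 of 4).  Validated clusters merge across
   samples into cohort events;
3. **filter cascade** — read support ≥ 5 spanning reads (crossing reads
   are recorded but not thresholded), both breakpoints exonic in
   protein-coding transcripts, absence from all normal samples, and
   metastasis exclusivity (present in ≥ 1 LM sample, 0 pCRC samples);
4. **chimeric-ORF annotation** — junction phases and frame status
   (below), domain retention on the predicted fusion protein;
5. **driver nomination** — (≥ 1 retained oncogenic-flagged domain OR
   external driver score > 0.8) AND recurrence in ≥ 2 metastatic
   samples;
6. **cohort statistics** — category tallies per exclusivity class
   (intra/interchromosomal, coding/non-coding, in/out of frame) and
   recurrence tables;
7. **validation-cohort statistics** — 2^−ΔΔCt relative expression with
   rank-sum comparison, and Kaplan–Meier / log-rank survival
   stratification by fusion positivity.

## Frame model

With one transcript model per partner (the pinned transcript id if
supplied, else the longest CDS), define

    retained5 = coding nt of the 5′ partner from its CDS start (the A of
                ATG) through the breakpoint base, inclusive
    skipped3  = coding nt of the 3′ partner strictly upstream of its
                breakpoint base

and phases `phase5 = retained5 mod 3`, `phase3 = skipped3 mod 3`.  The
chimera is **in frame** iff `phase5 = phase3`: the ribosome entering
from the 5′ ORF then reads the 3′ partner's remaining codons in their
native frame.  A 5′ breakpoint upstream of the CDS start is a **5′UTR
(read-through) fusion**, with the downstream ORF intact iff the 3′
breakpoint lies at or upstream of the 3′ CDS start.  Either partner
lacking a CDS makes the chimera non-coding.  Stop-codon scanning of the
junction is not part of the frame rule; the test suite instead verifies
the rule against a literal-translation oracle (the native 3′-protein
tail must reappear verbatim in the translated chimeric cDNA) on ≥ 200
random junctions over generated sequences.

Domain retention: with junction amino acid `J5 = floor(retained5/3)` and
first intact 3′ residue `A3 = floor(skipped3/3) + 1`, a 5′ domain is
retained iff `aa_end ≤ J5`, a 3′ domain iff `aa_start ≥ A3`; an
intact-ORF read-through retains every 3′ domain and no 5′ domain.
Out-of-frame chimeras retain nothing (the truncated 5′ ORF is not
scored).

## Coordinate and matching conventions

All coordinates are 1-based closed internally; a breakpoint is the last
transcribed base of the 5′ segment / first transcribed base of the 3′
segment.  BEDPE export converts to 0-based half-open single-base
intervals.  Breakpoint matching tolerance defaults to 10 nt (callers
disagree by a few bases at exon boundaries); cluster representatives are
per-end medians, taking the lower middle value on ties, which keeps the
consensus deterministic and order-independent.  Multiple calls by one
caller count as a single cross-validation vote.

The caller dialects (arriba-like, defuse-like, soapfuse-like, clc-like)
are this package's own fixed column layouts — representative
re-mappings of one reference format, not archival copies of any
caller's release format.  The clc-like dialect is 0-based on disk and
converted on input.  Gene symbols match case-sensitively after
whitespace trimming; no alias resolution.

## Statistical procedures

* **2^−ΔΔCt** — ΔCt = Ct_target − Ct_reference per sample; ΔΔCt
  subtracts the calibrator ΔCt; RQ = 2^−ΔΔCt.  Default calibrator is
  the pCRC group mean ΔCt (configurable to a named sample, whose RQ is
  then exactly 1).
* **Rank-sum** — Mann–Whitney U with mid-ranks; exact p by complete
  enumeration of labelings when n₁+n₂ ≤ 12 (valid under ties because
  pooled mid-ranks are fixed under relabeling), else the normal
  approximation with tie and continuity corrections (scipy).  Constant
  pooled data returns p = 1 with a degeneracy warning.
* **Kaplan–Meier / log-rank** — standard product-limit estimator and
  two-group log-rank (observed − expected with hypergeometric variance,
  1 df), implemented directly in numpy so thousands of simulated
  cohorts run in seconds; both are cross-checked against lifelines and
  hand-computed risk tables in the tests.  Ties between deaths and
  censorings at one time keep the censored subject at risk (standard
  convention).  Tests are two-sided at α = 0.05 with no
  multiple-testing correction, matching the discovery design.

## Synthetic cohort

The generator emulates the discovery conditions: 24 patients with
LM/pCRC/N triples plus 7 unpaired LM samples (79 samples).  The toy
genome holds 20 protein-coding and 2 non-coding transcripts over 4
chromosomes; every CDS starts ATG, ends in a stop, is divisible by 3
and stop-free in frame, and the emitted mature-transcript FASTA is
consistent with the GTF by construction.  The planted catalog contains
14 metastasis-exclusive drivers (recurrences 2–8, one flagship
in-frame fusion in 7 LM samples and one 5′UTR read-through in 8, each
with planted oncogenic domains) plus events exercising every filter:
primary-unique, shared, normal-present, sub-threshold support (mean 3),
single-caller, and a non-coding partner.

Noise model: each caller detects a planted fusion per carrier sample
with its sensitivity (defaults 0.8–0.9), jitters each breakpoint by a
rounded Normal(0, sd = 2 nt), and adds Poisson(1) private false
positives per sample.  Read support per carrier is 5 + Poisson(mean−5)
for means ≥ 5 — so support exactly 5 is common, exercising the
inclusive threshold — and max(1, Poisson(mean)) for sub-threshold
means (the 5 + Poisson form is undefined there).  Expression: reference
Ct ~ Normal(20, 0.3); the metastatic group's target Ct is lowered by
log2(fold change) (default fold 4, Ct noise sd 0.4, 13 vs 8 positive
samples).  Survival: exponential times with hazard h₀·HR^positive
(defaults h₀ = 0.03/month, HR = 3, 23 subjects of whom 13 positive),
with a configured fraction (default 0.2) censored uniformly before
their event.

What the generator does **not** emulate: read-level data, splice-motif
sequence content, caller-specific systematic biases (it jitters
symmetrically), expression-dependent detection, and correlated
patient effects.  Passing tests therefore demonstrate correctness of
the post-processing arithmetic and calibration of the statistics under
the stated model, not caller accuracy on real reads.

A consequence of the jitter model worth knowing: consensus junctions
displaced by 1–2 nt flip phase arithmetic, so under default noise some
planted in-frame drivers annotate as out-of-frame and fewer than 14 are
nominated.  This mirrors the real sensitivity of frame annotation to
breakpoint precision.  With noise off (sensitivities 1, jitter 0, no
false positives) cascade output equals the planted truth exactly and
all 14 drivers are nominated; that configuration is the recovery
benchmark in the tests and acceptance script.

## Worked-example fixtures

The packaged driver table (14 recurrent fusions with breakpoints,
domains, carrier samples and read counts) and category-count table are
stored as printed.  Frame labels like "1 > 0" are kept verbatim and all
fourteen rows are treated as frame-passing on the source table's
authority; phase recomputation is asserted only for the flagship
"2 > 2" fusion, on *synthetic* stand-in transcript models constructed
to realize the published junction geometry (exon 4 → exon 10, 146
retained / 233 skipped coding nt; 5′UTR → exon 2 with intact ORF) —
they are not real gene models.  Percentages are rounded
half-away-from-zero to one decimal; only count cells whose printed
percentages are self-consistent under that rule are used in worked
examples.

## Problem sizes and numerical choices

Default runs use the 79-sample cohort (~560 calls, seconds end to end).
Calibration suites use 2000 null cohorts (30 + 30 exponential survival
times) for type-I error, 500 cohorts for log-rank power at HR 3, and
500 simulated 12 vs 12 qPCR experiments at fold 4 for rank-sum power;
all complete in under a minute on one CPU.  Consensus clustering is
O(n²) within (sample × gene pair) buckets, which is ample at cohort
scale.  All randomness flows from one numpy Generator per run; a fixed
seed reproduces every output byte-identically.

## Limitations

* One transcript per gene; alternative isoforms can change frame calls.
* Exclusivity is presence/absence, not a count-based differential test
  (junction read counts are too sparse to calibrate one).
* The driver-score route consumes an external score column; no
  classifier is reimplemented.
* Survival analysis is KM/log-rank only (no Cox regression, no
  covariates); qPCR assumes perfect amplification efficiency.
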