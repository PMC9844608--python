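"""Independent oracles used only by the test suite.

These deliberately avoid the implementation paths they check: frame status
is decided by literally translating the constructed chimeric cDNA and
looking for the native 3'-partner protein tail, and the log-rank statistic
is rebuilt from an explicit risk table.
"""

from Bio.Seq import Seq


def chimera_in_frame_by_translation(seq5, tx5, offset5, seq3, tx3, offset3) -> bool:
    """Translate the chimeric cDNA and test whether the 5' ORF continues
    into the 3' partner's CDS without frameshift.

    The chimera joins the 5' transcript through ``offset5`` (inclusive) to
    the 3' transcript from ``offset3`` onward.  Translation starts at the
    5' partner's ATG; in frame means the native 3' protein tail (from the
    first fully retained codon after the junction codon, through its stop)
    appears verbatim in the chimeric translation.
    """
    cs5 = tx5.cds_start_offset
    cs3, ce3 = tx3.cds_start_offset, tx3.cds_end_offset
    chim_cds = seq5[cs5 - 1:offset5] + seq3[offset3 - 1:]
    prot = str(Seq(chim_cds[: len(chim_cds) // 3 * 3]).translate())
    native3 = str(Seq(seq3[cs3 - 1:ce3]).translate())
    skipped = max(0, offset3 - cs3)
    a_start = skipped // 3 + 2  # first aa fully downstream of the junction codon
    tail = native3[a_start - 1:]
    assert len(tail) >= 5, "fixture junction too close to the 3' stop for the oracle"
    return tail in prot


def logrank_by_risk_table(times, events, positive):
    """Brute-force log-rank chi-square from an explicit risk table."""
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    O = E = V = 0.0
    for t in event_times:
        at_risk = [(ti, pi) for ti, ei, pi in zip(times, events, positive) if ti >= t]
        n = len(at_risk)
        n1 = sum(1 for _, p in at_risk if p)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        d1 = sum(1 for ti, ei, pi in zip(times, events, positive)
                 if ti == t and ei == 1 and pi)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if V == 0 else (O - E) ** 2 / V


def km_by_hand(times, events):
    """Product-limit curve computed step by explicit step."""
    out = []
    s = 1.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        n = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1 - d / n
        out.append((t, s))
    return out
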