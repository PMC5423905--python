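"""Brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with naive per-base set
arithmetic and explicit loops, independent of the package's interval
logic.
"""

from fractions import Fraction


def exon_bases(t):
    bases = set()
    for e in t.exons:
        bases.update(range(e.start, e.end))
    return bases


def intron_list(t):
    """Genomic (start, end) gaps between consecutive exons."""
    ivs = sorted((e.start, e.end) for e in t.exons)
    return [(ivs[k][1], ivs[k + 1][0]) for k in range(len(ivs) - 1)]


def brute_force_events(a, b):
    """Enumerate the five AS event types between two isoforms.

    Returns a set of tuples (type, (start, end), frozenset(on),
    frozenset(off)) for comparison with classify_pair output.
    """
    strand = a.strand
    found = set()
    bases = {a.transcript_id: exon_bases(a), b.transcript_id: exon_bases(b)}
    introns = {a.transcript_id: intron_list(a), b.transcript_id: intron_list(b)}

    # intron retention: every base of the intron, plus one flanking base on
    # each side, is exonic in the other isoform (a contiguous exonic run
    # cannot span two exons, so this is single-exon containment)
    for spliced, retainer in ((a, b), (b, a)):
        for (s, e) in introns[spliced.transcript_id]:
            span = set(range(s - 1, e + 1))
            if span <= bases[retainer.transcript_id]:
                found.add(
                    ("IntronR", (s, e),
                     frozenset([retainer.transcript_id]),
                     frozenset([spliced.transcript_id]))
                )

    # exon skipping
    for skipper, includer in ((a, b), (b, a)):
        inc_introns = set(introns[includer.transcript_id])
        exlist = sorted((e.start, e.end) for e in includer.exons)
        for (s, e) in introns[skipper.transcript_id]:
            for (xs, xe) in exlist[1:-1]:
                if s < xs and xe < e and (s, xs) in inc_introns and (xe, e) in inc_introns:
                    found.add(
                        ("ExonS", (xs, xe),
                         frozenset([includer.transcript_id]),
                         frozenset([skipper.transcript_id]))
                    )

    # alternative donor/acceptor: introns sharing exactly one end; the
    # segment between the competing sites must be exonic in the isoform
    # with the shorter intron
    for (sa, ea) in introns[a.transcript_id]:
        for (sb, eb) in introns[b.transcript_id]:
            if (sa, ea) == (sb, eb):
                continue
            if sa == sb and ea != eb:
                lo, hi = min(ea, eb), max(ea, eb)
                short = a if ea == lo else b
                other = b if short is a else a
                if set(range(lo, hi)) <= bases[short.transcript_id]:
                    etype = "AltA" if strand == "+" else "AltD"
                    found.add((etype, (lo, hi),
                               frozenset([short.transcript_id]),
                               frozenset([other.transcript_id])))
            elif ea == eb and sa != sb:
                lo, hi = min(sa, sb), max(sa, sb)
                short = a if sa == hi else b
                other = b if short is a else a
                if set(range(lo, hi)) <= bases[short.transcript_id]:
                    etype = "AltD" if strand == "+" else "AltA"
                    found.add((etype, (lo, hi),
                               frozenset([short.transcript_id]),
                               frozenset([other.transcript_id])))

    # alternate terminal exon (each genomic end), both isoforms multi-exon
    if len(a.exons) >= 2 and len(b.exons) >= 2:
        ex_a = sorted((e.start, e.end) for e in a.exons)
        ex_b = sorted((e.start, e.end) for e in b.exons)
        for side in (0, -1):
            ta, tb = ex_a[side], ex_b[side]
            ja = (ex_a[0][1], ex_a[1][0]) if side == 0 else (ex_a[-2][1], ex_a[-1][0])
            jb = (ex_b[0][1], ex_b[1][0]) if side == 0 else (ex_b[-2][1], ex_b[-1][0])
            if ja == jb:
                continue
            a_free = not (set(range(*ta)) & bases[b.transcript_id])
            b_free = not (set(range(*tb)) & bases[a.transcript_id])
            if not (a_free or b_free):
                continue
            span = (min(ta[0], tb[0]), max(ta[1], tb[1]))
            if side == 0:
                on = a if ta[0] < tb[0] else b
            else:
                on = a if ta[1] > tb[1] else b
            off = b if on is a else a
            found.add(("AltTE", span,
                       frozenset([on.transcript_id]),
                       frozenset([off.transcript_id])))
    return found


def event_signature(e):
    return (
        e.event_type,
        (e.affected.start, e.affected.end),
        frozenset(e.on_isoforms),
        frozenset(e.off_isoforms),
    )


def fpkm_fraction(read_count, length_nt, library_size):
    """Arbitrary-precision FPKM for cross-checking."""
    return Fraction(10**9) * read_count / (Fraction(library_size) * length_nt)
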