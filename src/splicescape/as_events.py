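"""Alternative-splicing event classification between isoforms of a locus.

Five event types are recognised from exon chains alone:

* ``IntronR`` — an intron of one isoform is fully contained inside an exon
  of the other (the retention isoform is "on").
* ``ExonS``  — an internal exon of one isoform is absent from the other
  while both isoforms share the bounding donor and acceptor (the
  exon-including isoform is "on").
* ``AltA`` / ``AltD`` — two introns share the donor (resp. acceptor) and
  differ at the other end; the alternative segment between the competing
  sites must be fully exonic in the shorter-intron isoform, which
  distinguishes genuine alternative sites from the exon-skipping pattern.
* ``AltTE`` — the terminal exon of one isoform overlaps no exon of the
  other and the two isoforms' terminal junctions at that end differ.

Events are called pairwise and deduplicated by (type, affected interval,
junction keys); on/off isoform sets accumulate across supporting pairs so
that downstream ratio quantification can sum expression over all "on" and
all "off" isoforms.

The module also finds ORFs from the canonical start, applies the 50-nt
rule for nonsense-mediated-decay candidacy, localizes events to
CDS/UTR5/UTR3, and evaluates reading-frame preservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .gene_models import (
    GeneLocus,
    GenomeInterval,
    SpliceJunction,
    TranscriptModel,
    introns_of,
)

EVENT_TYPES = ("IntronR", "AltA", "AltD", "ExonS", "AltTE")

REGION_CDS = "CDS"
REGION_UTR5 = "UTR5"
REGION_UTR3 = "UTR3"
REGION_NONCODING = "noncoding"

FRAME_UNDEFINED = "undefined"


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    event_type: str
    affected: GenomeInterval
    flanking_junctions: tuple
    on_isoforms: frozenset
    off_isoforms: frozenset
    region: str = ""
    frame_preserving: object = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")
        if self.on_isoforms & self.off_isoforms:
            raise ValueError("on/off isoform sets must be disjoint")
        if not self.on_isoforms or not self.off_isoforms:
            raise ValueError("on/off isoform sets must be non-empty")

    @property
    def key(self) -> tuple:
        """Dedup identity: type + affected interval + junction keys."""
        jkeys = tuple(sorted(j.key for j in self.flanking_junctions))
        a = self.affected
        return (self.event_type, a.chrom, a.start, a.end, a.strand, jkeys)


def _exonic_cover(t: TranscriptModel, start: int, end: int) -> bool:
    """True iff [start, end) lies entirely within a single exon of t."""
    return any(e.start <= start and end <= e.end for e in t.exons)


def classify_pair(a: TranscriptModel, b: TranscriptModel) -> list:
    """All AS events of the five types between two isoforms.

    The returned on/off sets contain only the two transcript ids; use
    :func:`detect_gene_events` for locus-level accumulation.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError("isoforms must share chrom and strand")
    if a.gene_id != b.gene_id:
        raise ValueError("isoforms must belong to one gene")
    strand = a.strand
    chrom = a.chrom
    events: list = []

    introns = {a.transcript_id: introns_of(a), b.transcript_id: introns_of(b)}
    intron_ivs = {tid: [j.intron for j in js] for tid, js in introns.items()}

    def emit(etype, affected, junctions, on, off):
        events.append(
            ASEvent(
                event_id="",
                gene_id=a.gene_id,
                event_type=etype,
                affected=affected,
                flanking_junctions=tuple(junctions),
                on_isoforms=frozenset(on),
                off_isoforms=frozenset(off),
            )
        )

    # Intron retention: intron of `spliced` inside an exon of `retainer`.
    for spliced, retainer in ((a, b), (b, a)):
        for j in introns[spliced.transcript_id]:
            iv = j.intron
            if any(e.start < iv.start and iv.end < e.end for e in retainer.exons):
                emit(
                    "IntronR",
                    iv,
                    (j,),
                    {retainer.transcript_id},
                    {spliced.transcript_id},
                )

    # Exon skipping: `skipper` jumps an internal exon of `includer` while
    # sharing the outer donor/acceptor.
    for skipper, includer in ((a, b), (b, a)):
        inc_intron_set = {(iv.start, iv.end) for iv in intron_ivs[includer.transcript_id]}
        inc_junction = {
            (j.intron.start, j.intron.end): j for j in introns[includer.transcript_id]
        }
        for iv in intron_ivs[skipper.transcript_id]:
            for e in includer.exons[1:-1]:
                if (
                    iv.start < e.start
                    and e.end < iv.end
                    and (iv.start, e.start) in inc_intron_set
                    and (e.end, iv.end) in inc_intron_set
                ):
                    emit(
                        "ExonS",
                        e,
                        (
                            inc_junction[(iv.start, e.start)],
                            inc_junction[(e.end, iv.end)],
                        ),
                        {includer.transcript_id},
                        {skipper.transcript_id},
                    )

    # Alternative donor/acceptor: introns sharing one genomic end.  The
    # alternative segment must be exonic in the shorter-intron isoform.
    for ja in introns[a.transcript_id]:
        for jb in introns[b.transcript_id]:
            ia, ib = ja.intron, jb.intron
            if ia.start == ib.start and ia.end != ib.end:
                lo, hi = sorted((ia.end, ib.end))
                shorter = a if ia.end == lo else b
                if not _exonic_cover(shorter, lo, hi):
                    continue
                etype = "AltA" if strand == "+" else "AltD"
                segment = GenomeInterval(chrom, lo, hi, strand)
                longer = b if shorter is a else a
                emit(etype, segment, (ja, jb),
                     {shorter.transcript_id}, {longer.transcript_id})
            elif ia.end == ib.end and ia.start != ib.start:
                lo, hi = sorted((ia.start, ib.start))
                shorter = a if ia.start == hi else b
                if not _exonic_cover(shorter, lo, hi):
                    continue
                etype = "AltD" if strand == "+" else "AltA"
                segment = GenomeInterval(chrom, lo, hi, strand)
                longer = b if shorter is a else a
                emit(etype, segment, (ja, jb),
                     {shorter.transcript_id}, {longer.transcript_id})

    # Alternate terminal exon, each genomic end separately.
    if len(a.exons) >= 2 and len(b.exons) >= 2:
        for side in ("left", "right"):
            if side == "left":
                ea, eb = a.exons[0], b.exons[0]
                ja, jb = (
                    SpliceJunction(GenomeInterval(chrom, a.exons[0].end, a.exons[1].start, strand)),
                    SpliceJunction(GenomeInterval(chrom, b.exons[0].end, b.exons[1].start, strand)),
                )
            else:
                ea, eb = a.exons[-1], b.exons[-1]
                ja, jb = (
                    SpliceJunction(GenomeInterval(chrom, a.exons[-2].end, a.exons[-1].start, strand)),
                    SpliceJunction(GenomeInterval(chrom, b.exons[-2].end, b.exons[-1].start, strand)),
                )
            if ja.key == jb.key:
                continue
            a_disjoint = not any(ea.overlaps(e) for e in b.exons)
            b_disjoint = not any(eb.overlaps(e) for e in a.exons)
            if not (a_disjoint or b_disjoint):
                continue
            span = GenomeInterval(
                chrom, min(ea.start, eb.start), max(ea.end, eb.end), strand
            )
            # "on" = the isoform whose terminal exon extends further outward.
            if side == "left":
                on_t = a if ea.start < eb.start else b
            else:
                on_t = a if ea.end > eb.end else b
            off_t = b if on_t is a else a
            emit("AltTE", span, (ja, jb),
                 {on_t.transcript_id}, {off_t.transcript_id})

    return _dedup(events)


def _dedup(events: Iterable[ASEvent]) -> list:
    """Merge events with identical keys, accumulating on/off sets."""
    merged: dict = {}
    for e in events:
        k = e.key
        if k in merged:
            prev = merged[k]
            merged[k] = replace(
                prev,
                on_isoforms=prev.on_isoforms | e.on_isoforms,
                off_isoforms=prev.off_isoforms | e.off_isoforms,
            )
        else:
            merged[k] = e
    return sorted(merged.values(), key=lambda e: e.key)


def detect_gene_events(locus: GeneLocus) -> list:
    """Union of pairwise events over all isoform pairs, deduplicated.

    On/off sets accumulate every supporting isoform so downstream
    quantification can sum FPKM over full sets.  Event ids are assigned
    as ``<gene_id>.e<i>`` in deterministic key order.
    """
    all_events: list = []
    txs = locus.transcripts
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            all_events.extend(classify_pair(txs[i], txs[j]))
    events = _dedup(all_events)
    for i, e in enumerate(events):
        e.event_id = f"{locus.gene_id}.e{i}"
    return events


# ---------------------------------------------------------------------------
# ORF finding and NMD


@dataclass
class OrfCall:
    transcript_id: str
    cds: Optional[tuple]  # (start, end) in spliced transcript coords, or None
    stop_is_premature: bool = False
    shares_canonical_start: bool = False
    has_stop: bool = False

    @property
    def noncoding(self) -> bool:
        return self.cds is None


_STOPS = {"TAA", "TAG", "TGA"}


def _scan_orf(seq: str, start: int) -> tuple:
    """CDS (start, end) from an ATG at `start` to the first in-frame stop
    (stop codon included) or the last complete codon; returns (cds, has_stop)."""
    for pos in range(start, len(seq) - 2, 3):
        if seq[pos : pos + 3] in _STOPS:
            return (start, pos + 3), True
    end = start + 3 * ((len(seq) - start) // 3)
    return (start, end), False


def find_orf(
    spliced_seq: str,
    canonical_start_offset: Optional[int] = None,
    transcript_id: str = "",
) -> OrfCall:
    """ORF from the canonical start when present there, else the longest
    ATG-initiated ORF; no ATG at all yields a noncoding call."""
    seq = spliced_seq.upper()
    if any(c not in "ACGTN" for c in seq):
        raise ValueError("sequence must be over {A,C,G,T,N}")
    if (
        canonical_start_offset is not None
        and 0 <= canonical_start_offset <= len(seq) - 3
        and seq[canonical_start_offset : canonical_start_offset + 3] == "ATG"
    ):
        cds, has_stop = _scan_orf(seq, canonical_start_offset)
        return OrfCall(transcript_id, cds, shares_canonical_start=True,
                       has_stop=has_stop)
    best: Optional[tuple] = None
    best_has_stop = False
    pos = seq.find("ATG")
    while pos != -1:
        cds, has_stop = _scan_orf(seq, pos)
        if best is None or cds[1] - cds[0] > best[1] - best[0]:
            best, best_has_stop = cds, has_stop
        pos = seq.find("ATG", pos + 1)
    if best is None or best[1] - best[0] < 3:
        return OrfCall(transcript_id, None)
    return OrfCall(transcript_id, best, has_stop=best_has_stop)


def last_junction_transcript_pos(t: TranscriptModel) -> Optional[int]:
    """Spliced coordinate of the last exon-exon junction (start of the
    terminal exon in transcript coordinates); None for single-exon."""
    if len(t.exons) < 2:
        return None
    return t.spliced_length - t.exons_in_transcription_order()[-1].length


def classify_nmd(t: TranscriptModel, orf: OrfCall) -> bool:
    """True iff the stop codon ends more than 50 nt upstream of the last
    exon-exon junction — the canonical NMD substrate rule.  Only isoforms
    whose ORF shares the canonical start are eligible."""
    if not orf.shares_canonical_start or orf.noncoding or not orf.has_stop:
        return False
    lj = last_junction_transcript_pos(t)
    if lj is None:
        return False
    return lj - orf.cds[1] > 50


def annotate_nmd(t: TranscriptModel, orf: OrfCall) -> OrfCall:
    orf.stop_is_premature = classify_nmd(t, orf)
    return orf


def cds_to_genomic(t: TranscriptModel, cds: tuple) -> list:
    """Map a spliced-coordinate CDS (start, end) onto genomic intervals,
    one per overlapped exon, in genomic order."""
    start, end = cds
    if not (0 <= start < end <= t.spliced_length):
        raise ValueError("cds outside transcript")
    out = []
    offset = 0
    for e in t.exons_in_transcription_order():
        lo = max(start, offset)
        hi = min(end, offset + e.length)
        if lo < hi:
            if t.strand == "+":
                out.append(
                    GenomeInterval(e.chrom, e.start + (lo - offset),
                                   e.start + (hi - offset), t.strand)
                )
            else:
                out.append(
                    GenomeInterval(e.chrom, e.end - (hi - offset),
                                   e.end - (lo - offset), t.strand)
                )
        offset += e.length
    return sorted(out, key=lambda iv: iv.start)


# ---------------------------------------------------------------------------
# Event localization and frame


def localize_event(e: ASEvent, canonical_cds_genomic: Sequence[GenomeInterval]) -> str:
    """CDS / UTR5 / UTR3 / noncoding label for an event.

    Any overlap with the genomic span of the CDS counts as CDS (a retained
    intron between two coding exons interrupts the reading frame even
    though it overlaps no coding exon).  UTR side is strand-aware.
    """
    if not canonical_cds_genomic:
        return REGION_NONCODING
    span_start = min(iv.start for iv in canonical_cds_genomic)
    span_end = max(iv.end for iv in canonical_cds_genomic)
    a = e.affected
    if a.start < span_end and span_start < a.end:
        return REGION_CDS
    genomically_upstream = a.end <= span_start
    if a.strand == "+":
        return REGION_UTR5 if genomically_upstream else REGION_UTR3
    return REGION_UTR3 if genomically_upstream else REGION_UTR5


def frame_preserving(e: ASEvent):
    """Length of the affected segment divisible by 3; undefined for AltTE."""
    if e.event_type == "AltTE":
        return FRAME_UNDEFINED
    return e.affected.length % 3 == 0


def annotate_events(
    events: Iterable[ASEvent],
    canonical_cds_genomic: Sequence[GenomeInterval] = (),
) -> list:
    out = []
    for e in events:
        e.region = localize_event(e, canonical_cds_genomic)
        e.frame_preserving = frame_preserving(e)
        out.append(e)
    return out


def events_to_tsv(events: Iterable[ASEvent], path) -> None:
    """One row per event with type, interval, and on/off isoform lists."""
    cols = [
        "event_id", "gene_id", "event_type", "chrom", "start", "end",
        "strand", "region", "frame_preserving", "on_isoforms", "off_isoforms",
    ]
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for e in events:
            a = e.affected
            out.write(
                "\t".join(
                    [
                        e.event_id, e.gene_id, e.event_type, a.chrom,
                        str(a.start), str(a.end), a.strand, e.region or ".",
                        str(e.frame_preserving),
                        ",".join(sorted(e.on_isoforms)),
                        ",".join(sorted(e.off_isoforms)),
                    ]
                )
                + "\n"
            )
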