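"""Cross-genome conservation of AS events via splice anchor sequence tags.

For each AS event a SAST is built: up to 300 nt of genomic sequence on
each side of the event's affected region (truncated at the gene
boundaries, reverse-complemented to transcription orientation on the
minus strand).  SASTs of same-type events from the members of a
maize1/maize2/sorghum ortholog triplet are compared by six-frame
translated local alignment (Smith-Waterman, BLOSUM62, gap open 11 /
extend 1) and scored with a Karlin-Altschul E-value; matches define
conserved events classified into four categories:

1. conserved in maize1, maize2 and sorghum;
2. conserved between maize1 and sorghum, absent from maize2;
3. conserved between maize2 and sorghum, absent from maize1;
4. conserved between the maize homeologs, absent from sorghum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .as_events import ASEvent
from .gene_models import GenomeInterval, GenomeSequence

MAX_ANCHOR_NT = 300
E_VALUE_THRESHOLD = 1e-5
RELAXED_E_THRESHOLD = 1e-2   # when both tags are under SHORT_SAST_NT
SHORT_SAST_NT = 100
MIN_ALIGNED_NT = 30

# Gapped BLOSUM62 Karlin-Altschul constants (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

GENOMES = ("maize1", "maize2", "sorghum")


@dataclass
class OrthologTriplet:
    triplet_id: str
    genes: dict           # genome label -> gene_id
    multi_exon: dict      # genome label -> bool
    expressed: dict       # genome label -> bool

    def __post_init__(self) -> None:
        if set(self.genes) != set(GENOMES):
            raise ValueError("triplet must name maize1, maize2 and sorghum genes")

    @property
    def eligible(self) -> bool:
        """At least two members multi-exon and expressed."""
        ok = sum(
            1 for g in GENOMES if self.multi_exon.get(g) and self.expressed.get(g)
        )
        return ok >= 2


@dataclass
class SAST:
    event_id: str
    genome: str
    event_type: str
    upstream_anchor: str
    downstream_anchor: str

    def __post_init__(self) -> None:
        for side, anchor in (("upstream", self.upstream_anchor),
                             ("downstream", self.downstream_anchor)):
            if not anchor:
                raise ValueError(f"{self.event_id}: empty {side} anchor")
            if len(anchor) > MAX_ANCHOR_NT:
                raise ValueError(f"{self.event_id}: {side} anchor exceeds "
                                 f"{MAX_ANCHOR_NT} nt")

    @property
    def tag(self) -> str:
        """Junction-spanning tag: upstream + downstream anchor."""
        return self.upstream_anchor + self.downstream_anchor


def make_sast(
    e: ASEvent,
    genome,
    gene_span: GenomeInterval,
    genome_label: str = "",
    max_anchor: int = MAX_ANCHOR_NT,
) -> SAST:
    """Anchors flanking the event's defining junction span.

    The junction span is the union of the event's flanking-junction
    introns (for a retained intron, the intron itself; for a skipped exon,
    from the upstream intron's donor to the downstream intron's acceptor).
    Up to `max_anchor` nt of genomic sequence is taken on each side,
    truncated at the gene boundaries; minus-strand anchors are
    reverse-complemented and swapped so both are reported in
    transcription orientation.  `genome` is any accessor with a
    ``fetch(GenomeInterval) -> str`` method.
    """
    if not e.flanking_junctions:
        raise ValueError(f"{e.event_id}: event has no flanking junction")
    chrom = e.affected.chrom
    strand = e.affected.strand
    region_start = min(j.intron.start for j in e.flanking_junctions)
    region_end = max(j.intron.end for j in e.flanking_junctions)
    left_start = max(gene_span.start, region_start - max_anchor)
    right_end = min(gene_span.end, region_end + max_anchor)
    if left_start >= region_start or region_end >= right_end:
        raise ValueError(f"{e.event_id}: anchor would be empty")
    left = genome.fetch(GenomeInterval(chrom, left_start, region_start, "+"))
    right = genome.fetch(GenomeInterval(chrom, region_end, right_end, "+"))
    if strand == "-":
        rc = lambda s: str(Seq(s).reverse_complement())
        upstream, downstream = rc(right), rc(left)
    else:
        upstream, downstream = left, right
    return SAST(e.event_id, genome_label, e.event_type, upstream, downstream)


# ---------------------------------------------------------------------------
# Translated local alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _six_frames(nt: str) -> list:
    """Protein translations of all six reading frames ('*' kept for stops)."""
    seq = Seq(nt)
    frames = []
    for s in (seq, seq.reverse_complement()):
        for off in range(3):
            sub = s[off:]
            sub = sub[: 3 * (len(sub) // 3)]
            if len(sub) >= 3:
                frames.append(str(sub.translate()))
    return frames


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    return k * m * n * math.exp(-lam * score)


@dataclass
class AlignmentResult:
    score: float
    evalue: float
    aligned_nt_a: int
    aligned_nt_b: int


def translated_align(a: SAST, b: SAST) -> AlignmentResult:
    """Best Smith-Waterman score over all 6x6 translated frame pairs of
    the two tags, with a Karlin-Altschul E-value over the nucleotide
    search space m*n (product of tag lengths)."""
    ta, tb = a.tag, b.tag
    if len(ta) < 3 or len(tb) < 3:
        raise ValueError("anchors shorter than one codon cannot be aligned")
    frames_a = _six_frames(ta)
    frames_b = _six_frames(tb)
    best_score = -1.0
    best_pair: Optional[tuple] = None
    for fa, fb in itertools.product(frames_a, frames_b):
        score = _ALIGNER.score(fa, fb)
        if score > best_score:
            best_score = score
            best_pair = (fa, fb)
    fa, fb = best_pair
    aln = _ALIGNER.align(fa, fb)[0]
    span_a = int(aln.aligned[0][-1][1] - aln.aligned[0][0][0]) if len(aln.aligned[0]) else 0
    span_b = int(aln.aligned[1][-1][1] - aln.aligned[1][0][0]) if len(aln.aligned[1]) else 0
    e = karlin_altschul_evalue(best_score, len(ta), len(tb))
    return AlignmentResult(float(best_score), e, 3 * span_a, 3 * span_b)


def is_match(a: SAST, b: SAST, aln: AlignmentResult) -> bool:
    """E-value screen with the short-SAST relaxation and the 30-nt
    aligned-length rule (discard when the aligned span is under 30 nt in
    both aligned members)."""
    threshold = E_VALUE_THRESHOLD
    if len(a.tag) < SHORT_SAST_NT and len(b.tag) < SHORT_SAST_NT:
        threshold = RELAXED_E_THRESHOLD
    if aln.evalue > threshold:
        return False
    if aln.aligned_nt_a < MIN_ALIGNED_NT and aln.aligned_nt_b < MIN_ALIGNED_NT:
        return False
    return True


# ---------------------------------------------------------------------------
# Triplet classification


@dataclass
class ConservationCall:
    triplet_id: str
    event_type: str
    category: int
    matches: list            # (genome_a, event_a, genome_b, event_b, AlignmentResult)
    member_events: dict      # genome -> list of event_ids in the matched cluster


def classify_triplet_events(
    triplet: OrthologTriplet,
    sasts: Mapping[str, Sequence[SAST]],
    event_types: Sequence[str] = ("IntronR", "AltA", "AltD", "ExonS", "AltTE"),
) -> list:
    """Conservation calls per event type for one ortholog triplet.

    `sasts` maps genome label -> SASTs of that member's AS events.  A
    pairwise match is a translated alignment passing :func:`is_match`.
    Category 1 requires maize1<->sorghum and maize2<->sorghum matches;
    2 and 3 require the single maize<->sorghum match and no same-type
    event in the other maize member; 4 requires a maize1<->maize2 match
    and no same-type event in sorghum.
    """
    calls: list = []
    for etype in event_types:
        per_genome = {
            g: [s for s in sasts.get(g, ()) if s.event_type == etype]
            for g in GENOMES
        }
        has_event = {g: bool(per_genome[g]) for g in GENOMES}
        matches: dict = {("maize1", "sorghum"): [], ("maize2", "sorghum"): [],
                         ("maize1", "maize2"): []}
        for ga, gb in matches:
            for sa in per_genome[ga]:
                for sb in per_genome[gb]:
                    aln = translated_align(sa, sb)
                    if is_match(sa, sb, aln):
                        matches[(ga, gb)].append((sa, sb, aln))
        m1s = bool(matches[("maize1", "sorghum")])
        m2s = bool(matches[("maize2", "sorghum")])
        m1m2 = bool(matches[("maize1", "maize2")])
        category = None
        if m1s and m2s:
            category = 1
        elif m1s and not has_event["maize2"]:
            category = 2
        elif m2s and not has_event["maize1"]:
            category = 3
        elif m1m2 and not has_event["sorghum"]:
            category = 4
        if category is None:
            continue
        support = [
            (ga, sa.event_id, gb, sb.event_id, aln)
            for (ga, gb), lst in matches.items()
            for sa, sb, aln in lst
        ]
        member_events: dict = {g: [] for g in GENOMES}
        for ga, ea, gb, eb, _ in support:
            if ea not in member_events[ga]:
                member_events[ga].append(ea)
            if eb not in member_events[gb]:
                member_events[gb].append(eb)
        calls.append(
            ConservationCall(triplet.triplet_id, etype, category, support, member_events)
        )
    return calls


def summarize_conservation(
    calls: Sequence[ConservationCall],
    genes_of_call: Optional[Mapping[str, Mapping[str, str]]] = None,
):
    """Counts of clusters / events / genes per (event_type, category).

    A cluster is a connected component of the SAST match graph within one
    triplet and event type; its events are the member AS events and its
    genes the distinct contributing genes (one per genome member when
    `genes_of_call` maps triplet_id -> genome -> gene_id, else counted as
    genome members).
    """
    import pandas as pd

    rows = []
    for call in calls:
        # union-find over (genome, event_id) nodes joined by match edges
        parent: dict = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            parent[find(x)] = find(y)

        for ga, ea, gb, eb, _ in call.matches:
            union((ga, ea), (gb, eb))
        components = {}
        for node in parent:
            components.setdefault(find(node), set()).add(node)
        n_clusters = len(components)
        n_events = sum(len(c) for c in components.values())
        member_genomes = {g for c in components.values() for (g, _) in c}
        if genes_of_call is not None:
            gene_map = genes_of_call.get(call.triplet_id, {})
            genes = {gene_map.get(g, f"{call.triplet_id}:{g}") for g in member_genomes}
        else:
            genes = {f"{call.triplet_id}:{g}" for g in member_genomes}
        rows.append(
            {
                "event_type": call.event_type,
                "category": call.category,
                "clusters": n_clusters,
                "events": n_events,
                "genes": len(genes),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["event_type", "category", "clusters", "events", "genes"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["event_type", "category"], as_index=False)[
            ["clusters", "events", "genes"]
        ].sum()
    )


def sasts_to_fasta(sasts: Iterable[SAST], path) -> None:
    """FASTA export; id = event_id|genome|side."""
    with open(path, "w") as out:
        for s in sasts:
            out.write(f">{s.event_id}|{s.genome}|up\n{s.upstream_anchor}\n")
            out.write(f">{s.event_id}|{s.genome}|down\n{s.downstream_anchor}\n")
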