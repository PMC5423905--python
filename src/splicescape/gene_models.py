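"""Genomic coordinate primitives, transcript/gene models, and file I/O.

Internal coordinates are 0-based half-open throughout; GTF on disk is
1-based inclusive. A splice junction is identified by its intron interval
``(chrom, start, end, strand)``; donor/acceptor positions are derived from
the strand, never stored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from gffutils.feature import feature_from_line


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; carries the line number."""


class ModelValidationError(ValueError):
    """Raised when a transcript or gene model violates its invariants."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ModelValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ModelValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ModelValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SpliceJunction:
    """An intron; donor/acceptor are strand-aware views of its ends."""

    intron: GenomeInterval

    @property
    def donor_pos(self) -> int:
        """First intron base in transcription order."""
        return self.intron.start if self.intron.strand == "+" else self.intron.end - 1

    @property
    def acceptor_pos(self) -> int:
        """Last intron base in transcription order."""
        return self.intron.end - 1 if self.intron.strand == "+" else self.intron.start

    @property
    def key(self) -> tuple:
        i = self.intron
        return (i.chrom, i.start, i.end, i.strand)


@dataclass
class TranscriptModel:
    """Ordered exon chain of one isoform on a single chrom/strand."""

    transcript_id: str
    gene_id: str
    exons: tuple

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ModelValidationError(f"{self.transcript_id}: no exons")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ModelValidationError(
                f"{self.transcript_id}: exons span multiple chroms/strands"
            )
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start <= prev.end - 1:
                raise ModelValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
            if nxt.start - prev.end < 1:
                raise ModelValidationError(
                    f"{self.transcript_id}: intron shorter than 1 nt"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    def exons_in_transcription_order(self) -> tuple:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position (must be exonic) to spliced coordinates."""
        offset = 0
        for e in self.exons_in_transcription_order():
            if e.contains_pos(pos):
                if self.strand == "+":
                    return offset + (pos - e.start)
                return offset + (e.end - 1 - pos)
            offset += e.length
        raise ValueError(f"position {pos} is not exonic in {self.transcript_id}")


def introns_of(t: TranscriptModel) -> list:
    """Splice junctions of a transcript, in transcription order."""
    gaps = [
        GenomeInterval(t.chrom, prev.end, nxt.start, t.strand)
        for prev, nxt in zip(t.exons, t.exons[1:])
    ]
    if t.strand == "-":
        gaps.reverse()
    return [SpliceJunction(g) for g in gaps]


@dataclass
class GeneLocus:
    """All isoforms of one gene plus the annotation's canonical transcript."""

    gene_id: str
    transcripts: list
    canonical_id: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelValidationError(f"{self.gene_id}: no transcripts")
        if len({t.gene_id for t in self.transcripts}) != 1:
            raise ModelValidationError(f"{self.gene_id}: mixed gene_ids")
        if len({t.chrom for t in self.transcripts}) != 1:
            raise ModelValidationError(f"{self.gene_id}: transcripts on multiple chroms")
        if not self.canonical_id:
            self.canonical_id = pick_canonical(self.transcripts)
        elif self.canonical_id not in {t.transcript_id for t in self.transcripts}:
            raise ModelValidationError(
                f"{self.gene_id}: canonical {self.canonical_id} not a member"
            )

    @property
    def canonical(self) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == self.canonical_id:
                return t
        raise KeyError(self.canonical_id)

    @property
    def span(self) -> GenomeInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomeInterval(self.transcripts[0].chrom, start, end,
                              self.transcripts[0].strand)


def pick_canonical(transcripts: Sequence[TranscriptModel]) -> str:
    """Longest spliced length; ties broken by lexicographic transcript_id."""
    return min(transcripts, key=lambda t: (-t.spliced_length, t.transcript_id)).transcript_id


# ---------------------------------------------------------------------------
# GTF I/O

def read_gtf(path) -> list:
    """Parse exon features of a GTF file into GeneLocus objects.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    exons_by_tx: dict = {}
    gene_of_tx: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
                raise GtfParseError(f"line {lineno}: not a 9-column GTF record")
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"line {lineno}: cannot parse GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except (KeyError, IndexError):
                raise GtfParseError(
                    f"line {lineno}: exon lacks gene_id/transcript_id"
                )
            iv = GenomeInterval(feat.seqid, feat.start - 1, feat.end,
                                feat.strand if feat.strand in "+-" else "+")
            exons_by_tx.setdefault(tx_id, []).append(iv)
            gene_of_tx[tx_id] = gene_id

    tx_by_gene: dict = {}
    for tx_id, exons in exons_by_tx.items():
        t = TranscriptModel(tx_id, gene_of_tx[tx_id], tuple(exons))
        tx_by_gene.setdefault(t.gene_id, []).append(t)

    loci = []
    for gene_id in sorted(tx_by_gene):
        txs = sorted(tx_by_gene[gene_id], key=lambda t: t.transcript_id)
        loci.append(GeneLocus(gene_id, txs))
    return loci


def write_gtf(loci: Iterable[GeneLocus], path, source: str = "splicescape") -> None:
    """Write exon features; 0-based half-open back to 1-based inclusive."""
    with open(path, "w") as out:
        for locus in loci:
            for t in locus.transcripts:
                for e in t.exons:
                    attrs = (
                        f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                    )
                    out.write(
                        "\t".join(
                            [
                                e.chrom,
                                source,
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                e.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def junctions_to_bed(junctions: Iterable[SpliceJunction], path) -> None:
    """BED6 export; chromStart is the intron start."""
    with open(path, "w") as out:
        for j in junctions:
            i = j.intron
            name = f"{i.chrom}:{i.start}-{i.end}"
            out.write(f"{i.chrom}\t{i.start}\t{i.end}\t{name}\t0\t{i.strand}\n")


# ---------------------------------------------------------------------------
# Sequence access

class GenomeSequence:
    """Strand-aware FASTA accessor backed by pyfaidx."""

    _COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

    def __init__(self, fasta_path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(fasta_path))

    def fetch(self, iv: GenomeInterval) -> str:
        seq = str(self._fa[iv.chrom][iv.start:iv.end]).upper()
        if iv.strand == "-":
            seq = seq.translate(self._COMP)[::-1]
        return seq

    def spliced_sequence(self, t: TranscriptModel) -> str:
        """mRNA sequence in transcription order."""
        parts = [
            self.fetch(dataclasses.replace(e, strand=t.strand))
            for e in t.exons_in_transcription_order()
        ]
        return "".join(parts)


def counts_to_fpkm(read_count: int, transcript_length_nt: int, library_size: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if transcript_length_nt <= 0:
        raise ValueError("transcript length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if read_count == 0:
        return 0.0
    return 1e9 * read_count / (library_size * transcript_length_nt)
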