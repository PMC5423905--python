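"""Isoform-acceptance filters: junction entropy, retained-intron coverage,
and expression / isoform-fraction thresholds.

Junction entropy is the Shannon entropy (bits) of the distribution of
read alignment offsets across a junction; pile-ups of reads at a single
offset are characteristic of alignment artifacts and score 0 bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .gene_models import SpliceJunction

ENTROPY_THRESHOLD = 2.0
MIN_MEDIAN_DEPTH = 10
MIN_COVERED_FRACTION = 0.90
MIN_IR_PERCENT = 10.0
MIN_FPKM = 1.0
MIN_ISOFORM_FRACTION = 0.05


@dataclass
class JunctionEvidence:
    junction: SpliceJunction
    offset_counts: dict  # alignment offset (nt) -> read count

    @property
    def total_reads(self) -> int:
        return sum(self.offset_counts.values())


@dataclass
class IntronSupport:
    junction: SpliceJunction
    per_base_depth: Sequence[int]
    boundary_reads: int
    spliced_reads: int

    def __post_init__(self) -> None:
        if len(self.per_base_depth) != self.junction.intron.length:
            raise ValueError("depth vector length must equal intron length")


def junction_entropy(ev: JunctionEvidence) -> float:
    """Shannon entropy (bits) of the offset distribution."""
    counts = np.array([c for c in ev.offset_counts.values() if c > 0], dtype=float)
    if counts.sum() < 1:
        raise ValueError("junction has zero reads")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def pass_junction_filter(ev: JunctionEvidence, threshold: float = ENTROPY_THRESHOLD) -> bool:
    """Strict: entropy must exceed the threshold ("above 2")."""
    return junction_entropy(ev) > threshold


@dataclass
class IntronRetentionMetrics:
    covered_fraction: float          # bases with depth >= 1
    median_depth: float
    deep_fraction: float             # bases with depth >= MIN_MEDIAN_DEPTH
    depth_rule_pass: bool
    ir_percent: float


def intron_retention_metrics(
    s: IntronSupport,
    min_depth: int = MIN_MEDIAN_DEPTH,
    min_covered: float = MIN_COVERED_FRACTION,
) -> IntronRetentionMetrics:
    """Coverage metrics for a candidate retained intron.

    The published rule — median coverage of `min_depth` over at least
    `min_covered` of the intron — is ambiguous; both readings are applied
    (median depth >= min_depth AND fraction of bases at depth >= min_depth
    is >= min_covered) and reported separately so either can be relaxed.
    ir_percent = 100*b/(b+s) with b boundary-spanning and s spliced reads.
    """
    depth = np.asarray(s.per_base_depth, dtype=float)
    covered = float((depth >= 1).mean())
    med = float(np.median(depth))
    deep = float((depth >= min_depth).mean())
    depth_ok = (med >= min_depth) and (deep >= min_covered)
    b, sp = s.boundary_reads, s.spliced_reads
    ir = 100.0 * b / (b + sp) if (b + sp) > 0 else 0.0
    return IntronRetentionMetrics(covered, med, deep, depth_ok, ir)


def pass_ir_filter(
    s: IntronSupport,
    min_depth: int = MIN_MEDIAN_DEPTH,
    min_covered: float = MIN_COVERED_FRACTION,
    min_ir_percent: float = MIN_IR_PERCENT,
) -> bool:
    m = intron_retention_metrics(s, min_depth, min_covered)
    return m.depth_rule_pass and m.ir_percent >= min_ir_percent


def pass_expression_filter(
    fpkm_by_sample: Mapping[str, float],
    sibling_fpkm: Mapping[str, float],
    min_fpkm: float = MIN_FPKM,
    min_fraction: float = MIN_ISOFORM_FRACTION,
) -> bool:
    """Isoform accepted iff in some sample its FPKM >= min_fpkm AND it is
    at least min_fraction of the gene's total isoform expression there."""
    for sample, fpkm in fpkm_by_sample.items():
        total = sibling_fpkm.get(sample, 0.0)
        if total <= 0:
            continue
        if fpkm >= min_fpkm and fpkm / total >= min_fraction:
            return True
    return False
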