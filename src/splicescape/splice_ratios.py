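"""IRR/PSI splicing-ratio quantification and downstream selection.

The splicing ratio of an event is

    ratio = sum(FPKM_on) / (sum(FPKM_on) + sum(FPKM_off))

summed over all isoforms supporting the "on" and "off" modes.  For an
intron-retention event the retaining isoforms are "on" (the ratio is the
intron retention ratio, IRR); for exon skipping the exon-including
isoforms are "on" (percent spliced in, PSI).

Ratio matrices keep only events with total on+off FPKM >= 1 in every
sample and ratios inside (0.05, 0.95) bounds in every sample.  Seed-
development profiling selects events with a ratio increase > 0.15 between
two stages; differential splicing between conditions is scored with the
square-root Jensen-Shannon divergence of isoform-fraction vectors plus a
seeded permutation test, then post-filtered on per-condition expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import jensenshannon
from scipy import stats

from .as_events import ASEvent

LOG_EPS = 1e-6
RATIO_BOUNDS = (0.05, 0.95)
MIN_EVENT_FPKM = 1.0
DELTA_RATIO_THRESHOLD = 0.15
DIFF_MIN_FPKM = 5.0
PAV_HIGH = 2.0
PAV_LOW = 0.1


@dataclass
class RatioRecord:
    event_id: str
    sample_id: str
    ratio: Optional[float]  # None when on+off == 0
    on_fpkm: float
    off_fpkm: float

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def event_ratio(e: ASEvent, fpkm: Mapping[str, float], sample_id: str = "") -> RatioRecord:
    """IRR (IntronR) or PSI (ExonS) of one event in one sample."""
    if e.event_type not in ("IntronR", "ExonS"):
        raise ValueError(f"ratio defined only for IntronR/ExonS, got {e.event_type}")
    missing = (e.on_isoforms | e.off_isoforms) - set(fpkm)
    if missing:
        raise KeyError(f"missing FPKM for isoform(s): {', '.join(sorted(missing))}")
    on = float(sum(fpkm[t] for t in e.on_isoforms))
    off = float(sum(fpkm[t] for t in e.off_isoforms))
    total = on + off
    ratio = on / total if total > 0 else None
    return RatioRecord(e.event_id, sample_id, ratio, on, off)


@dataclass
class RatioMatrix:
    values: pd.DataFrame          # events x samples
    dropped: pd.DataFrame         # event_id, reason
    min_fpkm: float
    bounds: tuple


def build_ratio_matrix(
    events: Sequence[ASEvent],
    fpkm_table: pd.DataFrame,
    min_fpkm: float = MIN_EVENT_FPKM,
    bounds: tuple = RATIO_BOUNDS,
) -> RatioMatrix:
    """Ratio matrix over events x samples with the acceptance filters.

    `fpkm_table` is isoforms x samples.  An event is dropped when its
    on+off FPKM falls below `min_fpkm` in any sample or any of its ratios
    leaves [bounds[0], bounds[1]]; the reason is logged per event.
    """
    lo, hi = bounds
    rows, kept_ids, dropped = [], [], []
    for e in events:
        ratios = []
        reason = None
        for sample in fpkm_table.columns:
            rec = event_ratio(e, fpkm_table[sample].to_dict(), sample)
            if rec.on_fpkm + rec.off_fpkm < min_fpkm:
                reason = f"fpkm<{min_fpkm} in {sample}"
                break
            if rec.ratio is None or not (lo <= rec.ratio <= hi):
                reason = f"ratio outside [{lo},{hi}] in {sample}"
                break
            ratios.append(rec.ratio)
        if reason is None:
            rows.append(ratios)
            kept_ids.append(e.event_id)
        else:
            dropped.append((e.event_id, reason))
    values = pd.DataFrame(rows, index=kept_ids, columns=list(fpkm_table.columns))
    drop_df = pd.DataFrame(dropped, columns=["event_id", "reason"])
    return RatioMatrix(values, drop_df, min_fpkm, bounds)


# ---------------------------------------------------------------------------
# Clustering


def ward_order(m: RatioMatrix | pd.DataFrame, log_transform: bool = True):
    """Ward (minimum-variance) hierarchical clustering of matrix rows.

    Returns (linkage matrix in scipy format, leaf order as row indices).
    The log transform is log(x + 1e-6), applied before Euclidean
    distances, matching clustering of ratio/expression heatmaps.
    """
    df = m.values if isinstance(m, RatioMatrix) else m
    X = np.asarray(df, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    if log_transform:
        X = np.log(X + LOG_EPS)
    Z = sch.linkage(X, method="ward", metric="euclidean")
    order = list(sch.leaves_list(Z))
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(Z):
        i, j = int(i), int(j)
        bi = h - heights[i]
        bj = h - heights[j]
        nodes[n + k] = f"({nodes[i]}:{bi:.6g},{nodes[j]}:{bj:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


# ---------------------------------------------------------------------------
# Stage profiling


def delta_ratio_select(
    m: RatioMatrix | pd.DataFrame,
    stage_a: str,
    stage_b: str,
    threshold: float = DELTA_RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Events whose ratio increases by strictly more than `threshold`
    from stage_a to stage_b (delta = ratio_b - ratio_a)."""
    df = m.values if isinstance(m, RatioMatrix) else m
    delta = df[stage_b] - df[stage_a]
    out = pd.DataFrame({"delta": delta[delta > threshold]})
    out.index.name = "event_id"
    return out.sort_values("delta", ascending=False)


def expression_shift_test(
    expr_a: Sequence[float], expr_b: Sequence[float], log: bool = True
):
    """Two-sided equal-variance Student's t-test between two groups of
    expression values, on log(FPKM + 1e-6) by default."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if log:
        a = np.log(a + LOG_EPS)
        b = np.log(b + LOG_EPS)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Differential splicing (isoform-fraction divergence)


def jsd_splice_divergence(frac_a: Sequence[float], frac_b: Sequence[float]) -> float:
    """Square root of the Jensen-Shannon divergence (log base 2) between
    two isoform-fraction vectors; a metric on [0, 1]."""
    a = np.asarray(frac_a, dtype=float)
    b = np.asarray(frac_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("fraction vectors must have equal length >= 2")
    for v in (a, b):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("fraction vectors must sum to 1")
    return float(jensenshannon(a, b, base=2))


def diff_splice_test(
    fpkm_a: np.ndarray,
    fpkm_b: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """sqrt-JSD between mean isoform fractions of two replicate groups,
    with a label-permutation p-value.

    `fpkm_a`, `fpkm_b`: isoforms x replicates arrays for one gene.
    """
    rng = np.random.default_rng(seed)

    def fractions(mat):
        mean = np.asarray(mat, dtype=float).mean(axis=1)
        tot = mean.sum()
        if tot <= 0:
            return None
        return mean / tot

    fa, fb = fractions(fpkm_a), fractions(fpkm_b)
    if fa is None or fb is None:
        return np.nan, np.nan
    observed = jsd_splice_divergence(fa, fb)
    pooled = np.concatenate([np.asarray(fpkm_a, float), np.asarray(fpkm_b, float)], axis=1)
    na = np.asarray(fpkm_a).shape[1]
    n_total = pooled.shape[1]
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        pa = fractions(pooled[:, perm[:na]])
        pb = fractions(pooled[:, perm[na:]])
        if pa is None or pb is None:
            hits += 1
            continue
        if jsd_splice_divergence(pa, pb) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return observed, float(p)


def diff_splice_postfilter(
    gene_fpkm: Mapping[str, tuple],
    min_fpkm: float = DIFF_MIN_FPKM,
) -> list:
    """Keep genes where (i) at least one isoform reaches `min_fpkm` FPKM in
    EACH condition and (ii) each condition has at least one isoform more
    highly expressed in it than in the other condition.

    `gene_fpkm` maps gene_id -> (fpkm_vector_cond_a, fpkm_vector_cond_b),
    vectors indexed by isoform.
    """
    kept = []
    for gene_id, (fa, fb) in gene_fpkm.items():
        a = np.asarray(fa, dtype=float)
        b = np.asarray(fb, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"{gene_id}: condition vectors differ in length")
        if a.max() < min_fpkm or b.max() < min_fpkm:
            continue
        if not ((a > b).any() and (b > a).any()):
            continue
        kept.append(gene_id)
    return kept


def pav_isoforms(
    fpkm_a: Mapping[str, float],
    fpkm_b: Mapping[str, float],
    high: float = PAV_HIGH,
    low: float = PAV_LOW,
) -> dict:
    """Presence/absence-variation labels per isoform between two samples:
    'PAV-in-A' (> high in A and < low in B), 'PAV-in-B', or 'none'.
    Strict inequalities on both thresholds."""
    labels = {}
    for iso in set(fpkm_a) | set(fpkm_b):
        a = fpkm_a.get(iso, 0.0)
        b = fpkm_b.get(iso, 0.0)
        if a > high and b < low:
            labels[iso] = "PAV-in-A"
        elif b > high and a < low:
            labels[iso] = "PAV-in-B"
        else:
            labels[iso] = "none"
    return labels
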