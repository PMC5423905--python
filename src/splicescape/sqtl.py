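"""Junction-based splicing-QTL mapping on a biparental RIL panel.

For each splice junction the splicing frequency in line *i* is
y_i / (y_i + r_i), with y_i junction-spanning reads and r_i the other
reads on the same gene (correcting for gene expression differences and
reference-allele alignment bias).  Genotype effects on the splicing odds
are tested with a quasi-binomial GLM: a logit-link binomial fit whose
coefficient variance is scaled by the Pearson-chi-square dispersion
phi = X^2/(N-k), with t-tests on N-k df — the standard overdispersion
control for proportion regression (R's ``glm(family=quasibinomial)``).

The cis scan tests the genotype of the segment containing the junction,
controls FDR by Benjamini-Hochberg across junctions, and optionally
requires a two-fold change in splicing odds.  The trans scan tests every
marker on other chromosomes with a cis x trans interaction term; its
significance cutoff is a modified Bonferroni, dividing alpha by an
effective test count obtained after merging markers within 100 equal-bp
regions per chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .gene_models import GenomeInterval, SpliceJunction

MIN_SPANNING_READS = 20
MIN_MEAN_READS_PER_LINE = 5.0
CIS_FDR = 0.05
MIN_ODDS_FOLD = 2.0
REGIONS_PER_CHROM = 100
TRANS_ALPHA = 0.05

GENO_B = "B"
GENO_M = "M"


@dataclass
class Marker:
    marker_id: str
    segment: GenomeInterval


@dataclass
class RilPanel:
    """Line ids, marker segments, and a line x marker genotype table with
    values in {B, M} or NaN for missing."""

    line_ids: list
    markers: list            # list[Marker]
    genotypes: pd.DataFrame  # lines x marker_ids

    def __post_init__(self) -> None:
        by_chrom: dict = {}
        for m in self.markers:
            by_chrom.setdefault(m.segment.chrom, []).append(m.segment)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping marker segments on {chrom}")

    def marker_containing(self, chrom: str, pos: int) -> Optional[Marker]:
        for m in self.markers:
            if m.segment.chrom == chrom and m.segment.contains_pos(pos):
                return m
        return None

    def genotype_vector(self, marker_id: str) -> pd.Series:
        """Numeric coding B=0, M=1, NaN for missing."""
        g = self.genotypes[marker_id]
        return g.map({GENO_B: 0.0, GENO_M: 1.0})


@dataclass
class JunctionCountSet:
    junction: SpliceJunction
    junction_reads: np.ndarray    # y_i per line, aligned to panel.line_ids
    gene_other_reads: np.ndarray  # r_i per line

    def __post_init__(self) -> None:
        y = np.asarray(self.junction_reads)
        r = np.asarray(self.gene_other_reads)
        if y.shape != r.shape:
            raise ValueError("junction and gene read vectors differ in length")
        if (y < 0).any() or (r < 0).any():
            raise ValueError("read counts must be non-negative")


@dataclass
class SQTLTest:
    junction_key: tuple
    marker_id: str
    scope: str                      # cis | trans
    beta_genotype: float
    p_genotype: float
    dispersion: float
    beta_interaction: Optional[float] = None
    p_interaction: Optional[float] = None
    q: Optional[float] = None
    separated: bool = False

    @property
    def odds_fold_change(self) -> float:
        return float(np.exp(abs(self.beta_genotype)))

    @property
    def direction(self) -> str:
        """Sign convention: beta>0 means splicing odds up in the M parent."""
        return "up-in-M" if self.beta_genotype > 0 else "up-in-B"


def splicing_frequency(y: int, r: int) -> float:
    """Proportion of junction-spanning reads among all gene reads."""
    if y + r <= 0:
        return float("nan")
    return y / (y + r)


def eligible_junctions(
    counts: Sequence[JunctionCountSet],
    min_spanning: int = MIN_SPANNING_READS,
    min_mean_per_line: float = MIN_MEAN_READS_PER_LINE,
) -> list:
    """Junctions with >= min_spanning total spanning reads and a mean of
    >= min_mean_per_line spanning reads per line."""
    kept = []
    for c in counts:
        total = int(np.sum(c.junction_reads))
        if total >= min_spanning and total / len(c.junction_reads) >= min_mean_per_line:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Quasi-binomial GLM


@dataclass
class QuasiBinomialFit:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    dispersion: float
    df_resid: int
    separated: bool = False


def quasibinomial_fit(
    y: np.ndarray, n: np.ndarray, design: np.ndarray, maxiter: int = 100
) -> QuasiBinomialFit:
    """Logit-link binomial GLM with Pearson-chi-square dispersion and
    t-tests on the coefficients (quasi-likelihood overdispersion control).

    Complete separation (fitted proportions pinned to 0/1 with exploding
    coefficients) is handled by a Haldane-style refit that adds half a
    success and half a failure to every observation; the result is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(design, dtype=float)
    if (n < y).any():
        raise ValueError("n must be >= y")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    def _fit(yv, nv):
        endog = np.column_stack([yv, nv - yv])
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        res = model.fit(maxiter=maxiter)
        if not res.converged:
            raise RuntimeError("IRLS did not converge")
        return res

    res = _fit(y, n)
    mu = res.fittedvalues
    separated = bool(
        np.abs(res.params).max() > 15
        or np.any(mu < 1e-8)
        or np.any(mu > 1 - 1e-8)
    ) and res.bse.max() > 50
    if separated:
        res = _fit(y + 0.5, n + 1.0)

    df_resid = int(res.df_resid)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    # Pearson dispersion over the grouped counts, then t-tests on the
    # phi-scaled standard errors (R's summary.glm quasibinomial path).
    phi = float(res.pearson_chi2) / df_resid
    phi = max(phi, 1e-12)
    bse = np.asarray(res.bse) * math.sqrt(phi)
    tvals = np.asarray(res.params) / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return QuasiBinomialFit(
        params=np.asarray(res.params),
        bse=bse,
        pvalues=pvals,
        dispersion=phi,
        df_resid=df_resid,
        separated=separated,
    )


def _complete_cases(g_vectors: Sequence[np.ndarray], y: np.ndarray, r: np.ndarray):
    """Drop lines with missing genotype or zero total reads."""
    n = y + r
    mask = n > 0
    for g in g_vectors:
        mask &= ~np.isnan(g)
    return mask


def cis_scan(
    panel: RilPanel,
    counts: Sequence[JunctionCountSet],
    fdr: float = CIS_FDR,
    fold: float = MIN_ODDS_FOLD,
    apply_fold_filter: bool = False,
) -> list:
    """Single-factor genotype test per junction at its containing segment,
    with BH FDR across junctions.

    Returns one SQTLTest per testable junction; `q` holds the BH-adjusted
    p-value.  When `apply_fold_filter` is set, tests that are significant
    at `fdr` but below a `fold` change in splicing odds are kept in the
    output with `q` intact — use :func:`significant_cis` to subset.
    """
    tests: list = []
    for c in counts:
        iv = c.junction.intron
        marker = panel.marker_containing(iv.chrom, iv.start)
        if marker is None:
            continue
        g = panel.genotype_vector(marker.marker_id).to_numpy()
        y = np.asarray(c.junction_reads, dtype=float)
        r = np.asarray(c.gene_other_reads, dtype=float)
        mask = _complete_cases([g], y, r)
        if mask.sum() < 3 or len(np.unique(g[mask])) < 2:
            continue
        X = np.column_stack([np.ones(mask.sum()), g[mask]])
        fit = quasibinomial_fit(y[mask], (y + r)[mask], X)
        tests.append(
            SQTLTest(
                junction_key=c.junction.key,
                marker_id=marker.marker_id,
                scope="cis",
                beta_genotype=float(fit.params[1]),
                p_genotype=float(fit.pvalues[1]),
                dispersion=fit.dispersion,
                separated=fit.separated,
            )
        )
    if tests:
        pvals = np.array([t.p_genotype for t in tests])
        _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for t, q in zip(tests, qvals):
            t.q = float(q)
    if apply_fold_filter:
        return significant_cis(tests, fdr=fdr, fold=fold)
    return tests


def significant_cis(tests: Iterable[SQTLTest], fdr: float = CIS_FDR,
                    fold: Optional[float] = MIN_ODDS_FOLD) -> list:
    out = [t for t in tests if t.q is not None and t.q <= fdr]
    if fold is not None:
        out = [t for t in out if t.odds_fold_change >= fold]
    return out


def trans_scan(
    panel: RilPanel,
    c: JunctionCountSet,
    include_interaction: bool = True,
) -> list:
    """Test every marker on a chromosome other than the junction's, in a
    model with the cis genotype and (optionally) a cis x trans interaction:
    logit(p) = b0 + b1*G_cis + b2*G_trans + b3*G_cis*G_trans."""
    iv = c.junction.intron
    cis_marker = panel.marker_containing(iv.chrom, iv.start)
    y = np.asarray(c.junction_reads, dtype=float)
    r = np.asarray(c.gene_other_reads, dtype=float)
    g_cis = (
        panel.genotype_vector(cis_marker.marker_id).to_numpy()
        if cis_marker is not None
        else None
    )
    tests: list = []
    for marker in panel.markers:
        if marker.segment.chrom == iv.chrom:
            continue
        g_t = panel.genotype_vector(marker.marker_id).to_numpy()
        gvs = [g_t] if g_cis is None else [g_cis, g_t]
        mask = _complete_cases(gvs, y, r)
        if mask.sum() < 4 or len(np.unique(g_t[mask])) < 2:
            continue
        cols = [np.ones(mask.sum())]
        if g_cis is not None:
            cols.append(g_cis[mask])
        cols.append(g_t[mask])
        with_inter = include_interaction and g_cis is not None
        if with_inter:
            inter = g_cis[mask] * g_t[mask]
            # the interaction column can be collinear in small panels
            trial = np.column_stack(cols + [inter])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(inter)
            else:
                with_inter = False
        X = np.column_stack(cols)
        fit = quasibinomial_fit(y[mask], (y + r)[mask], X)
        i_trans = 2 if g_cis is not None else 1
        tests.append(
            SQTLTest(
                junction_key=c.junction.key,
                marker_id=marker.marker_id,
                scope="trans",
                beta_genotype=float(fit.params[i_trans]),
                p_genotype=float(fit.pvalues[i_trans]),
                dispersion=fit.dispersion,
                beta_interaction=float(fit.params[-1]) if with_inter else None,
                p_interaction=float(fit.pvalues[-1]) if with_inter else None,
                separated=fit.separated,
            )
        )
    return tests


def trans_cutoff(
    panel: RilPanel,
    junction_chroms: Sequence[str],
    chrom_lengths: Mapping[str, int],
    regions_per_chrom: int = REGIONS_PER_CHROM,
    alpha: float = TRANS_ALPHA,
) -> float:
    """Modified-Bonferroni p-value cutoff for the trans scan.

    Each chromosome is split into `regions_per_chrom` equal-bp regions;
    markers within a region count as one effective marker.  The total
    test count is the sum, over junctions, of effective markers on the
    other chromosomes, and the cutoff is alpha / total.
    """
    occupied: dict = {}
    for chrom, length in chrom_lengths.items():
        width = length / regions_per_chrom
        regions = set()
        for m in panel.markers:
            if m.segment.chrom != chrom:
                continue
            mid = (m.segment.start + m.segment.end) // 2
            regions.add(min(int(mid // width), regions_per_chrom - 1))
        occupied[chrom] = len(regions)
    total = 0
    for jc in junction_chroms:
        total += sum(n for chrom, n in occupied.items() if chrom != jc)
    if total == 0:
        raise ValueError("no trans markers available for any junction")
    return alpha / total


# ---------------------------------------------------------------------------
# Splice-site SNP windows and enrichment


def splice_site_windows(j: SpliceJunction) -> tuple:
    """The 9-bp donor and 3-bp acceptor windows around a junction (12 bp).

    Donor window: last 3 exonic + first 6 intronic bases (CAG|GURAGU
    consensus); acceptor window: last 2 intronic + first exonic base
    (AG|G).  Strand-aware.
    """
    iv = j.intron
    if iv.strand == "+":
        donor = GenomeInterval(iv.chrom, iv.start - 3, iv.start + 6, iv.strand)
        acceptor = GenomeInterval(iv.chrom, iv.end - 2, iv.end + 1, iv.strand)
    else:
        donor = GenomeInterval(iv.chrom, iv.end - 6, iv.end + 3, iv.strand)
        acceptor = GenomeInterval(iv.chrom, iv.start - 1, iv.start + 2, iv.strand)
    return donor, acceptor


def yates_chi2(table: np.ndarray) -> tuple:
    """Yates-corrected chi-square on a 2x2 table; returns (chi2, p)."""
    t = np.asarray(table, dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(chi2), float(p)


def _has_window_snp(j: SpliceJunction, snp_positions: Mapping[str, np.ndarray]) -> bool:
    pos = snp_positions.get(j.intron.chrom)
    if pos is None or len(pos) == 0:
        return False
    pos = np.asarray(pos)
    for w in splice_site_windows(j):
        if ((pos >= w.start) & (pos < w.end)).any():
            return True
    return False


def snp_enrichment(
    sig_junctions: Sequence[SpliceJunction],
    all_junctions: Sequence[SpliceJunction],
    snp_positions: Mapping[str, np.ndarray],
) -> tuple:
    """2x2 enrichment of splice-site-window SNPs in significant junctions
    versus the remaining junctions; Yates-corrected chi-square.

    Returns (table, chi2, p) with table rows (sig, other) and columns
    (has SNP, no SNP).
    """
    sig_keys = {j.key for j in sig_junctions}
    a = b = c = d = 0
    for j in all_junctions:
        hit = _has_window_snp(j, snp_positions)
        if j.key in sig_keys:
            a += hit
            b += not hit
        else:
            c += hit
            d += not hit
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p = yates_chi2(table)
    return table, chi2, p


def proximity_overlap(
    sqtl_positions: Sequence[tuple],
    gene_intervals: Sequence[GenomeInterval],
    window_bp: int,
) -> float:
    """Fraction of sQTL positions with at least one gene within window_bp.

    `sqtl_positions` is a sequence of (chrom, pos).
    """
    if not sqtl_positions:
        return 0.0
    by_chrom: dict = {}
    for g in gene_intervals:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    hits = 0
    for chrom, pos in sqtl_positions:
        lo, hi = pos - window_bp, pos + window_bp
        for gs, ge in by_chrom.get(chrom, ()):  # interval [lo, hi] vs gene
            if gs <= hi and lo <= ge:
                hits += 1
                break
    return hits / len(sqtl_positions)
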