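"""Seeded synthetic-data generators for every input the pipeline consumes.

Every generator is a pure function of its configuration and seed and
returns the planted ground truth alongside the data, so recovery of the
truth is testable end to end:

* :func:`make_genome_and_genes` — random chromosomes with multi-exon gene
  models; alternative isoforms each carry one planted AS event of the
  five types, with type proportions defaulting to the rank order seen in
  maize (intron retention dominant, exon skipping rare).
* :func:`simulate_expression`  — FPKM tables over developmental stages
  with planted intron-retention-ratio trajectories.
* :func:`simulate_junction_evidence` — junction offset histograms and
  intron per-base coverage for the entropy/coverage filters.
* :func:`simulate_ril_panel` — a biparental RIL panel with segment
  genotypes and beta-binomially overdispersed junction counts carrying
  planted cis/trans log-odds effects, plus a SNP position table.
* :func:`simulate_triplets` — diverged maize1/maize2/sorghum gene
  triplets with planted 4-way conservation categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .as_events import detect_gene_events
from .evidence_filters import IntronSupport, JunctionEvidence
from .gene_models import (
    GeneLocus,
    GenomeInterval,
    SpliceJunction,
    TranscriptModel,
    introns_of,
    write_gtf,
)
from .sqtl import JunctionCountSet, Marker, RilPanel

# Study-condition defaults: AS type proportions mirror the observed rank
# order (intron retention most common, exon skipping rarest).
EVENT_TYPE_PROPORTIONS = {
    "IntronR": 0.47,
    "AltA": 0.20,
    "AltTE": 0.15,
    "AltD": 0.13,
    "ExonS": 0.05,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


class DictGenome:
    """In-memory genome accessor with the GenomeSequence fetch interface."""

    _COMP = str.maketrans("ACGTN", "TGCAN")

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = dict(seqs)

    def fetch(self, iv: GenomeInterval) -> str:
        seq = self.seqs[iv.chrom][iv.start : iv.end].upper()
        if iv.strand == "-":
            seq = seq.translate(self._COMP)[::-1]
        return seq

    def spliced_sequence(self, t: TranscriptModel) -> str:
        parts = [
            self.fetch(GenomeInterval(e.chrom, e.start, e.end, t.strand))
            for e in t.exons_in_transcription_order()
        ]
        return "".join(parts)

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as out:
            for name in sorted(self.seqs):
                out.write(f">{name}\n")
                seq = self.seqs[name]
                for i in range(0, len(seq), width):
                    out.write(seq[i : i + width] + "\n")


@dataclass
class PlantedEvent:
    gene_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    strand: str
    on_isoforms: list
    off_isoforms: list

    @property
    def interval_key(self) -> tuple:
        return (self.event_type, self.chrom, self.start, self.end, self.strand)


@dataclass
class TruthSet:
    """Serializable record of everything the generators planted."""

    seed: int
    params: dict = field(default_factory=dict)
    events: list = field(default_factory=list)          # PlantedEvent
    trajectories: dict = field(default_factory=dict)    # event key str -> list of ratios
    sqtl_effects: list = field(default_factory=list)
    triplet_categories: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "events": [asdict(e) for e in self.events],
            "trajectories": self.trajectories,
            "sqtl_effects": self.sqtl_effects,
            "triplet_categories": self.triplet_categories,
        }
        with open(path, "w") as out:
            json.dump(payload, out, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Gene models with planted events


def _plant_event(
    rng: np.random.Generator,
    exons: list,
    etype: str,
    strand: str,
    chrom: str,
    used_introns: set,
) -> Optional[tuple]:
    """Derive an alternative exon chain carrying one event of `etype`.

    Returns (alt_exons, affected_interval, touched_intron_indices) or
    None when no placement satisfies the separation constraints (planted
    features must not touch adjacent introns of other isoforms, so that
    pairwise classification between alternative isoforms never yields an
    event outside the planted truth set).
    """
    n_introns = len(exons) - 1

    def free(idxs):
        return all(
            abs(i - u) >= 2 for i in idxs for u in used_introns
        ) and not (set(idxs) & used_introns)

    candidates = list(range(n_introns))
    rng.shuffle(candidates)

    if etype == "IntronR":
        for i in candidates:
            if not free([i]):
                continue
            merged = GenomeInterval(chrom, exons[i].start, exons[i + 1].end, strand)
            alt = exons[: i] + [merged] + exons[i + 2 :]
            affected = GenomeInterval(chrom, exons[i].end, exons[i + 1].start, strand)
            return alt, affected, {i}
        return None

    if etype in ("AltA", "AltD"):
        # shared genomic start (shift the intron end) gives AltA on '+',
        # AltD on '-'; shared genomic end (shift the start) the reverse.
        shift_end = (etype == "AltA") == (strand == "+")
        for i in candidates:
            if not free([i]):
                continue
            if shift_end:
                room = exons[i + 1].length - 10
                if room < 3:
                    continue
                d = int(rng.integers(3, min(60, room) + 1))
                new_exon = GenomeInterval(
                    chrom, exons[i + 1].start + d, exons[i + 1].end, strand
                )
                alt = exons[: i + 1] + [new_exon] + exons[i + 2 :]
                affected = GenomeInterval(
                    chrom, exons[i + 1].start, exons[i + 1].start + d, strand
                )
            else:
                room = exons[i].length - 10
                if room < 3:
                    continue
                d = int(rng.integers(3, min(60, room) + 1))
                new_exon = GenomeInterval(
                    chrom, exons[i].start, exons[i].end - d, strand
                )
                alt = exons[:i] + [new_exon] + exons[i + 1 :]
                affected = GenomeInterval(
                    chrom, exons[i].end - d, exons[i].end, strand
                )
            return alt, affected, {i}
        return None

    if etype == "ExonS":
        order = list(range(1, len(exons) - 1))
        rng.shuffle(order)
        for j in order:
            if not free([j - 1, j]):
                continue
            alt = exons[:j] + exons[j + 1 :]
            return alt, exons[j], {j - 1, j}
        return None

    if etype == "AltTE":
        # replace the first genomic exon by one inside the first intron
        if not free([0]):
            return None
        intron_len = exons[1].start - exons[0].end
        margin = 20
        alt_len = int(rng.integers(50, 151))
        if intron_len < alt_len + 2 * margin:
            return None
        lo = exons[0].end + margin
        hi = exons[1].start - margin - alt_len
        start = int(rng.integers(lo, hi + 1))
        alt_first = GenomeInterval(chrom, start, start + alt_len, strand)
        alt = [alt_first] + exons[1:]
        affected = GenomeInterval(chrom, exons[0].start, alt_first.end, strand)
        return alt, affected, {0}

    raise ValueError(etype)


@dataclass
class SyntheticAnnotation:
    genome: DictGenome
    loci: list
    truth: TruthSet

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.genome.write_fasta(os.path.join(outdir, "genome.fa"))
        write_gtf(self.loci, os.path.join(outdir, "genes.gtf"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))


def make_genome_and_genes(
    n_genes: int = 50,
    seed: int = 0,
    n_chroms: int = 2,
    exon_range: tuple = (50, 400),
    intron_range: tuple = (60, 3000),
    exons_per_gene: tuple = (2, 12),
    event_proportions: Optional[Mapping[str, float]] = None,
    max_alt_isoforms: int = 3,
    intergenic_bp: int = 2000,
) -> SyntheticAnnotation:
    """Random chromosomes and gene models with planted AS events."""
    rng = np.random.default_rng(seed)
    props = dict(event_proportions or EVENT_TYPE_PROPORTIONS)
    types = list(props)
    probs = np.array([props[t] for t in types], dtype=float)
    probs /= probs.sum()

    chrom_parts: dict = {f"chr{c + 1}": [] for c in range(n_chroms)}
    chrom_cursor = {name: 0 for name in chrom_parts}
    loci: list = []
    truth = TruthSet(
        seed=seed,
        params={
            "n_genes": n_genes,
            "exon_range": list(exon_range),
            "intron_range": list(intron_range),
            "exons_per_gene": list(exons_per_gene),
            "event_proportions": props,
        },
    )

    for gi in range(n_genes):
        chrom = f"chr{(gi % n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{gi:04d}"
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        pos = chrom_cursor[chrom] + intergenic_bp
        exons = []
        for k in range(n_exons):
            length = int(rng.integers(exon_range[0], exon_range[1] + 1))
            exons.append(GenomeInterval(chrom, pos, pos + length, strand))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
        chrom_cursor[chrom] = pos

        canonical = TranscriptModel(f"{gene_id}.T0", gene_id, tuple(exons))
        transcripts = [canonical]
        n_alt = int(rng.choice(4, p=[0.15, 0.40, 0.30, 0.15]))
        n_alt = min(n_alt, max_alt_isoforms)
        used: set = set()
        for ai in range(n_alt):
            etype = str(rng.choice(types, p=probs))
            planted = _plant_event(rng, list(exons), etype, strand, chrom, used)
            if planted is None:
                continue
            alt_exons, affected, touched = planted
            used |= touched
            tid = f"{gene_id}.T{len(transcripts)}"
            transcripts.append(TranscriptModel(tid, gene_id, tuple(alt_exons)))
            truth.events.append(
                PlantedEvent(
                    gene_id=gene_id,
                    event_type=etype,
                    chrom=chrom,
                    start=affected.start,
                    end=affected.end,
                    strand=strand,
                    on_isoforms=[],
                    off_isoforms=[],
                )
            )
        loci.append(GeneLocus(gene_id, transcripts))

    _fill_truth_on_off(loci, truth)

    for name in chrom_parts:
        total = chrom_cursor[name] + intergenic_bp
        chrom_parts[name] = _random_seq(rng, total)
    return SyntheticAnnotation(DictGenome(chrom_parts), loci, truth)


def _fill_truth_on_off(loci: Sequence[GeneLocus], truth: TruthSet) -> None:
    """Determine on/off isoform membership structurally for each planted
    event (independent of the classifier)."""
    by_gene = {l.gene_id: l for l in loci}
    for ev in truth.events:
        locus = by_gene[ev.gene_id]
        on, off = [], []
        for t in locus.transcripts:
            if ev.event_type == "IntronR":
                has_intron = any(
                    j.intron.start == ev.start and j.intron.end == ev.end
                    for j in introns_of(t)
                )
                retains = any(
                    e.start < ev.start and ev.end < e.end for e in t.exons
                )
                if retains:
                    on.append(t.transcript_id)
                elif has_intron:
                    off.append(t.transcript_id)
            elif ev.event_type == "ExonS":
                has_exon = any(
                    e.start == ev.start and e.end == ev.end for e in t.exons
                )
                skips = any(
                    j.intron.start < ev.start and ev.end < j.intron.end
                    for j in introns_of(t)
                )
                if has_exon:
                    on.append(t.transcript_id)
                elif skips:
                    off.append(t.transcript_id)
            elif ev.event_type in ("AltA", "AltD"):
                # "on" isoforms carry the affected segment as exon sequence
                exonic = any(
                    e.start <= ev.start and ev.end <= e.end for e in t.exons
                )
                intronic = any(
                    j.intron.start <= ev.start and ev.end <= j.intron.end
                    for j in introns_of(t)
                )
                if exonic:
                    on.append(t.transcript_id)
                elif intronic:
                    off.append(t.transcript_id)
            else:  # AltTE: "on" = terminal exon starting at the outer edge
                first = min(t.exons, key=lambda e: e.start)
                if first.start == ev.start:
                    on.append(t.transcript_id)
                elif ev.start < first.start <= ev.end:
                    off.append(t.transcript_id)
        ev.on_isoforms = sorted(on)
        ev.off_isoforms = sorted(off)


# ---------------------------------------------------------------------------
# Expression tables with planted ratio trajectories

DEFAULT_STAGES = ("day0", "day8", "day16", "day24", "day32", "day38")


def _logistic_trajectory(r0: float, delta: float, n: int) -> np.ndarray:
    x = np.linspace(-3, 3, n)
    return r0 + delta / (1.0 + np.exp(-x))


def simulate_expression(
    ann: SyntheticAnnotation,
    stages: Sequence[str] = DEFAULT_STAGES,
    seed: int = 0,
    noise_sigma: float = 0.0,
    delta: float = 0.3,
    rising_fraction: float = 0.5,
    base_log_mean: float = 2.0,
    base_log_sigma: float = 1.0,
) -> pd.DataFrame:
    """Per-isoform FPKM = gene-level lognormal base x isoform fraction.

    In genes carrying exactly one planted IntronR or ExonS event, the
    "on" fraction follows either a rising logistic trajectory (r0 ->
    r0 + delta across stages) or a flat trajectory, each planted into
    ``ann.truth.trajectories``.  With ``noise_sigma`` = 0 the realized
    event ratios equal the planted values exactly.
    """
    rng = np.random.default_rng(seed)
    truth = ann.truth
    events_by_gene: dict = {}
    for ev in truth.events:
        events_by_gene.setdefault(ev.gene_id, []).append(ev)

    rows: dict = {}
    for locus in ann.loci:
        base = float(np.exp(rng.normal(base_log_mean, base_log_sigma)))
        tx_ids = [t.transcript_id for t in locus.transcripts]
        gene_events = events_by_gene.get(locus.gene_id, [])
        ratio_events = [
            e for e in gene_events if e.event_type in ("IntronR", "ExonS")
        ]
        single_ratio = (
            len(locus.transcripts) == 2 and len(ratio_events) == 1
        )
        if single_ratio:
            ev = ratio_events[0]
            rising = rng.random() < rising_fraction
            if rising:
                r0 = float(rng.uniform(0.10, 0.90 - delta))
                traj = _logistic_trajectory(r0, delta, len(stages))
            else:
                r = float(rng.uniform(0.15, 0.85))
                traj = np.full(len(stages), r)
            traj = np.clip(traj, 0.06, 0.94)
            truth.trajectories["|".join(map(str, ev.interval_key))] = [
                float(x) for x in traj
            ]
            on_set = set(ev.on_isoforms)
            for si, stage in enumerate(stages):
                r = traj[si]
                for tid in tx_ids:
                    frac = r if tid in on_set else (1.0 - r)
                    rows.setdefault(tid, {})[stage] = base * frac
        else:
            fracs = rng.dirichlet(np.full(len(tx_ids), 2.0))
            for stage in stages:
                for tid, f in zip(tx_ids, fracs):
                    rows.setdefault(tid, {})[stage] = base * float(f)

    df = pd.DataFrame(rows).T
    df = df[list(stages)]
    df.index.name = "transcript_id"
    if noise_sigma > 0:
        noise = rng.lognormal(0.0, noise_sigma, size=df.shape)
        df = df * noise
    return df


# ---------------------------------------------------------------------------
# Junction evidence


def simulate_junction_evidence(
    ann: SyntheticAnnotation,
    depth: int = 50,
    seed: int = 0,
    n_offsets: int = 40,
    n_artifacts: int = 20,
    retained_depth: int = 15,
    retained_ir_percent: float = 30.0,
    spurious_depth: float = 0.5,
) -> tuple:
    """Offset histograms for true and artifact junctions plus per-base
    intron coverage for retained and non-retained introns.

    Returns (junction_evidence, intron_support) where each element is a
    list of (object, is_true_label) pairs.
    """
    rng = np.random.default_rng(seed)
    junction_evidence: list = []
    intron_support: list = []
    retained = {
        (ev.chrom, ev.start, ev.end)
        for ev in ann.truth.events
        if ev.event_type == "IntronR"
    }
    for locus in ann.loci:
        seen: set = set()
        junctions = []
        for t in locus.transcripts:
            for j in introns_of(t):
                if j.key not in seen:
                    seen.add(j.key)
                    junctions.append(j)
        for j in junctions:
            counts = rng.multinomial(depth, np.full(n_offsets, 1.0 / n_offsets))
            offsets = {o: int(c) for o, c in enumerate(counts) if c > 0}
            junction_evidence.append((JunctionEvidence(j, offsets), True))

            iv = j.intron
            is_retained = (iv.chrom, iv.start, iv.end) in retained
            if is_retained:
                per_base = rng.poisson(retained_depth, size=iv.length)
                flank = 2 * depth
                b = int(rng.binomial(flank, retained_ir_percent / 100.0))
                s = flank - b
            else:
                per_base = rng.poisson(spurious_depth, size=iv.length)
                flank = 2 * depth
                b = int(rng.binomial(flank, 0.02))
                s = flank - b
            intron_support.append(
                (IntronSupport(j, per_base.tolist(), b, s), is_retained)
            )
    # artifact junctions: single-offset pile-ups on random coordinates
    chroms = sorted(ann.genome.seqs)
    for k in range(n_artifacts):
        chrom = chroms[k % len(chroms)]
        start = int(rng.integers(0, max(1, len(ann.genome.seqs[chrom]) - 500)))
        iv = GenomeInterval(chrom, start, start + int(rng.integers(60, 500)), "+")
        ev = JunctionEvidence(SpliceJunction(iv), {0: depth})
        junction_evidence.append((ev, False))
    return junction_evidence, intron_support


# ---------------------------------------------------------------------------
# RIL panel


@dataclass
class PlantedSqtlEffect:
    junction_index: int
    scope: str                 # cis | trans | interaction
    marker_id: Optional[str]
    log_odds: float


@dataclass
class RilSimulation:
    panel: RilPanel
    counts: list               # JunctionCountSet per junction
    effects: list              # PlantedSqtlEffect
    snp_positions: dict        # chrom -> np.ndarray of positions
    junction_has_window_snp: list
    chrom_lengths: dict
    baseline_logit: float


def _beta_binomial(rng, n, p, rho):
    """Beta-binomial draws; rho=0 degenerates to plain binomial."""
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if rho <= 0:
        return rng.binomial(n, p)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    pp = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))
    return rng.binomial(n, pp)


def simulate_ril_panel(
    n_lines: int = 100,
    n_junctions: int = 30,
    planted: Sequence[tuple] = (),
    rho: float = 0.05,
    depth: int = 50,
    seed: int = 0,
    n_chroms: int = 2,
    markers_per_chrom: int = 20,
    chrom_length: int = 100_000_000,
    baseline_logit: float = -1.4,
    switch_prob: float = 0.1,
    snp_window_prob_flagged: float = 0.5,
    snp_window_prob_background: float = 0.03,
) -> RilSimulation:
    """Biparental RIL panel with overdispersed junction counts.

    `planted` is a sequence of (junction_index, scope, log_odds[,
    marker_id]) tuples; scope is 'cis' (effect at the containing
    segment), 'trans' (at a marker on the other chromosome) or
    'interaction' (effect only when both cis and trans alleles are M).
    Junction counts per line are BetaBinomial(n_i, p_i, rho) with
    n_i ~ 1 + Poisson(depth - 1) gene reads and logit(p_i) the baseline
    plus planted effects.  SNPs are planted inside the 12-bp splice-site
    windows of junctions flagged by planted cis effects at
    `snp_window_prob_flagged` and elsewhere at the background rate.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{c + 1}" for c in range(n_chroms)]
    seg_len = chrom_length // markers_per_chrom
    markers, marker_ids = [], []
    for chrom in chrom_names:
        for k in range(markers_per_chrom):
            mid = f"{chrom}_m{k:03d}"
            markers.append(
                Marker(mid, GenomeInterval(chrom, k * seg_len, (k + 1) * seg_len))
            )
            marker_ids.append(mid)

    line_ids = [f"RIL{i:03d}" for i in range(n_lines)]
    geno = np.empty((n_lines, len(markers)), dtype=object)
    col = 0
    for chrom in chrom_names:
        for k in range(markers_per_chrom):
            if k == 0:
                g = rng.random(n_lines) < 0.5
            else:
                flip = rng.random(n_lines) < switch_prob
                g = np.where(flip, ~prev, prev)
            geno[:, col] = np.where(g, "M", "B")
            prev = g
            col += 1
    genotypes = pd.DataFrame(geno, index=line_ids, columns=marker_ids)
    panel = RilPanel(line_ids, markers, genotypes)

    # junction placement: round-robin across chromosomes, random position
    junction_meta = []
    for ji in range(n_junctions):
        chrom = chrom_names[ji % n_chroms]
        start = int(rng.integers(1000, chrom_length - 10_000))
        intron_len = int(rng.integers(80, 2000))
        iv = GenomeInterval(chrom, start, start + intron_len, "+")
        junction_meta.append(SpliceJunction(iv))

    effects = []
    effect_map: dict = {}
    for spec_tuple in planted:
        ji, scope, log_odds = spec_tuple[0], spec_tuple[1], float(spec_tuple[2])
        marker_id = spec_tuple[3] if len(spec_tuple) > 3 else None
        j = junction_meta[ji]
        if scope == "cis":
            m = panel.marker_containing(j.intron.chrom, j.intron.start)
            marker_id = m.marker_id
        elif marker_id is None:
            other = [m for m in markers if m.segment.chrom != j.intron.chrom]
            marker_id = other[int(rng.integers(len(other)))].marker_id
        effects.append(PlantedSqtlEffect(ji, scope, marker_id, log_odds))
        effect_map.setdefault(ji, []).append(effects[-1])

    counts = []
    for ji, j in enumerate(junction_meta):
        n_i = 1 + rng.poisson(depth - 1, size=n_lines)
        logit = np.full(n_lines, baseline_logit, dtype=float)
        for eff in effect_map.get(ji, []):
            g_eff = (genotypes[eff.marker_id] == "M").to_numpy().astype(float)
            if eff.scope == "interaction":
                cis_m = panel.marker_containing(j.intron.chrom, j.intron.start)
                g_cis = (genotypes[cis_m.marker_id] == "M").to_numpy().astype(float)
                logit += eff.log_odds * g_eff * g_cis
            else:
                logit += eff.log_odds * g_eff
        p = 1.0 / (1.0 + np.exp(-logit))
        y = _beta_binomial(rng, n_i, p, rho)
        counts.append(JunctionCountSet(j, y, n_i - y))

    # SNP table
    flagged = {e.junction_index for e in effects if e.scope == "cis"}
    snp_pos: dict = {c: [] for c in chrom_names}
    has_window_snp = []
    from .sqtl import splice_site_windows

    for ji, j in enumerate(junction_meta):
        prob = snp_window_prob_flagged if ji in flagged else snp_window_prob_background
        hit = bool(rng.random() < prob)
        has_window_snp.append(hit)
        if hit:
            donor, acceptor = splice_site_windows(j)
            w = donor if rng.random() < 0.75 else acceptor
            snp_pos[j.intron.chrom].append(int(rng.integers(w.start, w.end)))
    # background SNPs away from junctions
    for chrom in chrom_names:
        snp_pos[chrom].extend(
            int(x) for x in rng.integers(0, chrom_length, size=200)
        )
        snp_pos[chrom] = np.array(sorted(snp_pos[chrom]))

    return RilSimulation(
        panel=panel,
        counts=counts,
        effects=effects,
        snp_positions=snp_pos,
        junction_has_window_snp=has_window_snp,
        chrom_lengths={c: chrom_length for c in chrom_names},
        baseline_logit=baseline_logit,
    )


# ---------------------------------------------------------------------------
# Ortholog triplets


@dataclass
class TripletSimulation:
    genomes: dict        # genome label -> DictGenome
    loci: dict           # genome label -> list of GeneLocus
    triplets: list       # OrthologTriplet
    truth: TruthSet


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = rng.binomial(len(arr), rate)
    if n_mut == 0:
        return seq
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        cur = arr[p]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != cur]
        arr[p] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_triplets(
    n_triplets: int = 200,
    divergence: float = 0.02,
    category_mix: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    exon_range: tuple = (80, 250),
    intron_range: tuple = (250, 500),
    exons_per_gene: tuple = (3, 6),
) -> TripletSimulation:
    """Diverged maize1/maize2/sorghum gene triplets with one planted AS
    event per triplet and a planted 4-way conservation category.

    Category 1 keeps the alternative isoform in all three members; 2
    deletes it from maize2; 3 from maize1; 4 from sorghum.  Member
    sequences are independent point-mutated copies of the ancestral gene
    at the given per-site divergence; gene structure is shared.
    """
    from .conservation import GENOMES, OrthologTriplet

    rng = np.random.default_rng(seed)
    mix = np.asarray(category_mix, dtype=float)
    mix = mix / mix.sum()
    types = list(EVENT_TYPE_PROPORTIONS)
    probs = np.array([EVENT_TYPE_PROPORTIONS[t] for t in types])
    probs /= probs.sum()

    seqs: dict = {g: {} for g in GENOMES}
    loci: dict = {g: [] for g in GENOMES}
    triplets: list = []
    truth = TruthSet(
        seed=seed,
        params={
            "n_triplets": n_triplets,
            "divergence": divergence,
            "category_mix": [float(x) for x in mix],
        },
    )

    for ti in range(n_triplets):
        category = int(rng.choice(4, p=mix)) + 1
        strand = "+" if rng.random() < 0.5 else "-"
        pad = 400
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        pos = pad
        exons = []
        for k in range(n_exons):
            length = int(rng.integers(exon_range[0], exon_range[1] + 1))
            exons.append(("exon", pos, pos + length))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
        total_len = pos + pad
        ancestral = _random_seq(rng, total_len)

        # plant one AS event on the ancestral structure
        planted = None
        order = rng.permutation(len(types))
        for idx in order:
            etype = types[idx]
            chrom_tmp = "anc"
            ivs = [GenomeInterval(chrom_tmp, s, e, strand) for _, s, e in exons]
            planted = _plant_event(rng, ivs, etype, strand, chrom_tmp, set())
            if planted is not None:
                planted_type = etype
                break
        alt_exons, affected, _ = planted

        keep_alt = {
            1: {"maize1", "maize2", "sorghum"},
            2: {"maize1", "sorghum"},
            3: {"maize2", "sorghum"},
            4: {"maize1", "maize2"},
        }[category]

        triplet_id = f"T{ti:04d}"
        genes = {}
        for g in GENOMES:
            chrom = f"{g}_{triplet_id}"
            seqs[g][chrom] = _mutate(rng, ancestral, divergence)
            gene_id = f"{g}_{triplet_id}_g"
            can_exons = tuple(
                GenomeInterval(chrom, s, e, strand) for _, s, e in exons
            )
            txs = [TranscriptModel(f"{gene_id}.T0", gene_id, can_exons)]
            if g in keep_alt:
                alt = tuple(
                    GenomeInterval(chrom, iv.start, iv.end, strand)
                    for iv in alt_exons
                )
                txs.append(TranscriptModel(f"{gene_id}.T1", gene_id, alt))
            loci[g].append(GeneLocus(gene_id, txs))
            genes[g] = gene_id
        triplets.append(
            OrthologTriplet(
                triplet_id,
                genes,
                multi_exon={g: True for g in GENOMES},
                expressed={g: True for g in GENOMES},
            )
        )
        truth.triplet_categories[triplet_id] = {
            "category": category,
            "event_type": planted_type,
        }

    genomes = {g: DictGenome(seqs[g]) for g in GENOMES}
    return TripletSimulation(genomes, loci, triplets, truth)


# ---------------------------------------------------------------------------
# Study-level evaluation helpers (shared by tests and reproduction script)


def ratio_thinning_correlation(
    n_events: int = 500,
    mean_reads: int = 200,
    thin: float = 0.5,
    seed: int = 0,
) -> float:
    """Pearson correlation between event ratios computed at full depth and
    after binomial thinning of the underlying read counts.

    Each event draws a true ratio uniform on (0.05, 0.95) and a total
    read count Poisson(mean_reads); "on" reads are binomial.  Thinning
    keeps each read independently with probability `thin`.
    """
    rng = np.random.default_rng(seed)
    full, thinned = [], []
    for _ in range(n_events):
        u = rng.uniform(0.05, 0.95)
        total = max(int(rng.poisson(mean_reads)), 1)
        on = int(rng.binomial(total, u))
        off = total - on
        on2 = int(rng.binomial(on, thin))
        off2 = int(rng.binomial(off, thin))
        if on2 + off2 == 0:
            continue
        full.append(on / total)
        thinned.append(on2 / (on2 + off2))
    return float(np.corrcoef(full, thinned)[0, 1])


def sqtl_calibration_study(
    n_replicates: int = 200,
    n_lines: int = 100,
    n_null: int = 12,
    n_planted: int = 3,
    effect_fold: float = 2.5,
    rho: float = 0.05,
    depth: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Operating characteristics of the cis scan over replicate panels.

    Each replicate simulates a RIL panel with `n_null` unaffected
    junctions and `n_planted` junctions carrying a cis log-odds effect of
    log(effect_fold), then runs the quasi-binomial cis scan with BH FDR.
    Returns pooled type-I error (raw p < alpha on null junctions),
    empirical FDR (mean per-replicate false-discovery proportion, the
    quantity Benjamini-Hochberg controls; 0 when nothing is discovered),
    power (planted junctions discovered), and the median absolute error
    of the planted log-odds.
    """
    from .sqtl import cis_scan, significant_cis

    effect = float(np.log(effect_fold))
    n_junctions = n_null + n_planted
    planted = [(i, "cis", effect) for i in range(n_planted)]
    null_p, errs, fdps = [], [], []
    n_true_disc = 0
    for rep in range(n_replicates):
        sim = simulate_ril_panel(
            n_lines=n_lines,
            n_junctions=n_junctions,
            planted=planted,
            rho=rho,
            depth=depth,
            seed=seed + rep,
        )
        tests = cis_scan(sim.panel, sim.counts)
        planted_keys = {
            sim.counts[e.junction_index].junction.key for e in sim.effects
        }
        sig_keys = {t.junction_key for t in significant_cis(tests, fdr=alpha, fold=None)}
        for t in tests:
            if t.junction_key in planted_keys:
                errs.append(abs(t.beta_genotype - effect))
            else:
                null_p.append(t.p_genotype)
        n_true_disc += len(sig_keys & planted_keys)
        n_false = len(sig_keys - planted_keys)
        fdps.append(n_false / len(sig_keys) if sig_keys else 0.0)
    return {
        "type_i_error": float(np.mean(np.asarray(null_p) < alpha)),
        "empirical_fdr": float(np.mean(fdps)),
        "power": n_true_disc / (n_replicates * n_planted),
        "median_abs_effect_error": float(np.median(errs)),
        "n_null_tests": len(null_p),
    }


def classify_simulated_triplets(tsim: TripletSimulation) -> dict:
    """Run SAST construction + triplet classification on a simulation and
    score it against the planted categories.

    Returns {'n': ..., 'n_correct': ..., 'accuracy': ..., 'calls': ...};
    a triplet is correct when exactly one call is produced and both its
    category and event type match the planted truth.
    """
    from .conservation import GENOMES, classify_triplet_events, make_sast

    loci = {g: {l.gene_id: l for l in tsim.loci[g]} for g in GENOMES}
    n_correct = 0
    all_calls = []
    for trip in tsim.triplets:
        sasts = {}
        for g in GENOMES:
            locus = loci[g][trip.genes[g]]
            evs = detect_gene_events(locus) if len(locus.transcripts) > 1 else []
            sasts[g] = [
                make_sast(e, tsim.genomes[g], locus.span, genome_label=g)
                for e in evs
            ]
        calls = classify_triplet_events(trip, sasts)
        all_calls.extend(calls)
        truth = tsim.truth.triplet_categories[trip.triplet_id]
        if (
            len(calls) == 1
            and calls[0].category == truth["category"]
            and calls[0].event_type == truth["event_type"]
        ):
            n_correct += 1
    n = len(tsim.triplets)
    return {
        "n": n,
        "n_correct": n_correct,
        "accuracy": n_correct / n if n else 0.0,
        "calls": all_calls,
    }
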