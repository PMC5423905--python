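# Methods

## Coordinates and gene models

All internal coordinates are 0-based half-open; GTF I/O converts to and
from the on-disk 1-based inclusive convention.  A transcript is an
ordered chain of non-overlapping exons on one chromosome and strand with
inter-exon gaps (introns) of at least 1 nt — the parser enforces only
structural validity and leaves biological minimum-length decisions to
the filters.  A splice junction is identified by its intron interval
`(chrom, start, end, strand)`; donor and acceptor positions are derived
from the strand on demand and never stored.  The canonical transcript
of a gene is the longest spliced form, ties broken lexicographically by
transcript id.  Note that for an intron-retention gene the retention
isoform is often the longest and therefore canonical; "canonical" here
means reference form for ORF/NMD anchoring, not "fully spliced".

## Event classification

Events are called pairwise between isoforms and deduplicated by
(type, affected interval, junction keys); on/off isoform sets accumulate
across supporting pairs, so downstream quantification can sum expression
over all "on" and all "off" isoforms.  Definitions, decidable from exon
chains alone:

* **IntronR** — an intron of one isoform strictly inside an exon of the
  other.  The retention isoform is "on".  The event's defining junction
  is the spliced form's intron; it is stored as the single flanking
  junction.
* **ExonS** — an intron of the skipping isoform spans an internal exon
  of the inclusion isoform whose bounding introns share the outer donor
  and acceptor with it.  The inclusion isoform is "on"; both bounding
  junctions are stored.
* **AltA / AltD** — two introns share one genomic end and differ at the
  other; which label applies depends on the strand (a shared genomic
  start is a shared donor on `+`).  The alternative segment between the
  competing sites must be fully exonic in the shorter-intron isoform —
  without this condition every exon-skipping event would additionally
  surface as a spurious pair of alternative-site events.  The
  shorter-intron isoform (segment exonic) is "on".
* **AltTE** — at either transcript end, the terminal exon of one isoform
  overlaps no exon of the other and the two terminal junctions differ.
  Both ends are eligible; single-exon isoforms have no terminal junction
  and are excluded.  The isoform whose terminal exon extends further
  outward is "on".  The affected interval is the union span of the two
  terminal exons.

The on/off orientation for AltA/AltD/AltTE is a package convention
(ratios are only computed for IntronR/ExonS, where the orientation is
the standard one).

## ORFs, NMD, localization, frame

ORFs are found from the canonical start codon when an ATG is present at
the given offset (translating to the first in-frame stop or the last
complete codon), otherwise the longest ATG-initiated ORF is used.  An
isoform is an NMD candidate when its ORF shares the canonical start and
its stop codon ends more than 50 nt upstream of the last exon–exon
junction in transcript coordinates (strictly greater; single-exon
transcripts are never candidates).

Events are localized against the canonical CDS: any overlap with the
genomic span of the CDS (first to last coding base) counts as CDS — this
deliberately includes retained introns that sit between two coding exons
and interrupt the reading frame while overlapping no coding exon
interval.  Otherwise the label is UTR5/UTR3 by strand-aware position,
or noncoding when no ORF exists.  Frame preservation is length of the
affected segment mod 3 = 0; it is undefined for AltTE (no single
affected segment inside a shared transcript frame) and reported as a
sentinel.

## Evidence filters

* Junction entropy: Shannon entropy (bits) of the distribution of read
  alignment offsets; the acceptance threshold is strictly above 2 bits.
  The offset-distribution variant is used (entropy of read counts per
  distinct offset).
* Retained-intron coverage: the published rule "median coverage of 10
  over ≥ 90 % of the intron" admits two readings; both are enforced
  (median depth ≥ 10 AND ≥ 90 % of bases at depth ≥ 10) and reported
  separately so either can be relaxed.  The intron-retention percentage
  is 100·b/(b+s) with b boundary-spanning and s spliced-junction reads;
  this ratio definition is isolated in one function.
* Expression: an isoform passes when some sample has FPKM ≥ 1 and
  isoform fraction ≥ 5 % of the gene total.

## Splicing ratios

The ratio of an event in a sample is ΣFPKM_on/(ΣFPKM_on+ΣFPKM_off) over
the full supporting sets; undefined (and excluded) when the denominator
is 0.  Ratio matrices drop an event when any sample has on+off FPKM
below 1 or a ratio outside [0.05, 0.95]; drop reasons are logged.  Ward
clustering uses scipy's minimum-variance linkage on Euclidean distances
after log(x + 1e-6) — the ε is a package choice for zero-safe logs and
also applies to the equal-variance two-sided t-test on log FPKM used for
stage-wise expression shifts (testing on the log scale is a documented
choice; raw-scale testing is available via a flag).

Differential splicing between two replicate groups is scored by the
square root of the Jensen–Shannon divergence (log base 2) between mean
isoform-fraction vectors — a metric on [0, 1] — with a seeded
label-permutation p-value (default 1000 permutations, add-one
estimator).  Post-filters keep genes with at least one isoform at
FPKM ≥ 5 in each condition and at least one isoform more highly
expressed in each condition.  PAV labels use strict inequalities
(> 2 FPKM in one sample and < 0.1 in the other).

## Splicing-QTL mapping

For junction i in line j the splicing frequency is y/(y+r): junction
reads over junction reads plus other reads on the same gene, which
normalizes out gene-expression differences and reference-allele
alignment bias.  Junctions enter the scan with ≥ 20 total spanning reads
and ≥ 5 spanning reads per line on average.

Genotype effects are estimated by a binomial GLM with logit link; the
coefficient covariance is scaled by the Pearson dispersion
φ = X²/(N−k) and coefficients are tested with t-statistics on N−k df —
the quasi-binomial path of R's `glm`.  (The fit is delegated to
statsmodels; the dispersion scaling is applied explicitly on the grouped
counts because statsmodels' built-in `scale="X2"` computes the Pearson
scale on the proportion residuals without the trial-count weights.)
Complete separation triggers a flagged Haldane-style refit (half a
success and half a failure added to every observation).  Missing
genotypes and zero-count lines are dropped per test.  Genotype coding is
B=0, M=1, so β > 0 means splicing odds up in the M parent.

The cis scan uses the genotype of the segment containing the junction,
BH FDR at 5 % across junctions, and an optional two-fold splicing-odds
filter (|β| ≥ ln 2) with direction reported.  The trans scan fits
logit(p) = β₀ + β₁G_cis + β₂G_trans + β₃G_cis·G_trans for every marker
on other chromosomes (the interaction column is dropped when collinear
in small panels).  Every marker is tested; the significance cutoff is a
modified Bonferroni derived from merged markers: each chromosome is
split into 100 equal-bp regions, the effective marker count is the
number of occupied regions, and the cutoff is α divided by the summed
effective other-chromosome marker counts over junctions.  "Equal sized"
is interpreted as equal base pairs.

Splice-site windows are 12 bp per junction: 9 bp at the donor (3 exonic
+ 6 intronic, CAG|GURAGU consensus) and 3 bp at the acceptor (2 intronic
+ 1 exonic, AG|G), strand-aware; the exact anchoring of the consensus to
the exon/intron boundary is a documented convention.  SNP enrichment in
these windows between significant and remaining junctions uses the
Yates-corrected χ² on the 2×2 table.  Proximity of sQTL positions to
known splicing-related genes is the fraction with at least one gene
within a ±1 Mb or ±10 Mb window.

## Conservation across genomes

A SAST takes up to 300 nt of genomic sequence on each side of the
event's junction span (the union of its flanking-junction introns),
truncated at the gene boundaries and reported in transcription
orientation.  The two anchors are concatenated into one
junction-spanning tag for alignment, and the E-value search space m·n is
the product of total tag lengths — a simplification of per-frame search
spaces, with Karlin–Altschul constants fixed at the gapped BLOSUM62
defaults (λ = 0.267, K = 0.041).  Alignment is local Smith–Waterman over
all 6×6 translated frame pairs (BLOSUM62, gap open 11, extend 1; stop
codons translate to `*` and score against the matrix).  A pairwise match
requires E ≤ 1e-5, relaxed to E ≤ 1e-2 when both tags are under 100 nt
(the relaxation value is a package constant; only "relaxed" is
prescribed).  An alignment is discarded when its aligned span is under
30 nt in both aligned members.

Within a maize1/maize2/sorghum triplet and one event type, categories
are: (1) maize1↔sorghum and maize2↔sorghum matches; (2) maize1↔sorghum
only and no same-type event in maize2; (3) the mirror image; (4)
maize1↔maize2 and no same-type event in sorghum.  Category 1 does not
additionally require a maize1↔maize2 match.  Summaries count clusters
(connected components of the SAST match graph within a triplet and event
type), member events, and distinct contributing genes.

## Synthetic data

Generators are pure functions of configuration and seed (numpy
`default_rng`), and every output ships with its planted truth.

* Gene models: 2–12 exons of 50–400 nt, introns 60–3000 nt, 0–3
  alternative isoforms per gene, each carrying exactly one planted event
  with type proportions defaulting to the observed rank order in maize
  (IntronR 0.47, AltA 0.20, AltTE 0.15, AltD 0.13, ExonS 0.05).
  Planted features of different isoforms are kept at least two introns
  apart; this separation guarantees that pairwise classification
  between alternative isoforms reproduces exactly the planted event set
  (verified by the truth-recovery tests).
* Expression: gene-level lognormal base expression times isoform
  fractions over six seed-development stages (day 0–38); genes with a
  single ratio-type event receive either a rising logistic IRR
  trajectory (Δ = 0.3 by default) or a flat one, planted in the truth
  set; optional lognormal replicate noise (σ = 0 recovers the planted
  ratios exactly).
* Junction evidence: true junctions draw offsets from a uniform
  multinomial over 40 positions (entropy far above 2 bits at depth 20);
  artifact junctions are single-offset pile-ups (0 bits).  Planted
  retained introns get Poisson(15) per-base depth and 30 % intron
  retention; background introns Poisson(0.5) and 2 %.
* RIL panel: 100 lines by default over 2 chromosomes with 20 equal
  segments each; genotypes follow a per-chromosome Markov chain (10 %
  switch probability).  Junction counts are BetaBinomial(n, p, ρ) with
  ρ = 0.05 by default — beta-binomial is the simulation truth while the
  quasi-binomial is the analysis model, mimicking realistic model
  mis-specification.  Planted effects are cis, trans, or M-only
  interaction log-odds shifts on a logit baseline of −1.4 (baseline
  splicing frequency ≈ 0.20).  SNPs are planted inside the 12-bp
  windows of cis-flagged junctions at a configurable rate.
* Triplets: an ancestral gene (3–6 exons) with one planted event is
  copied to maize1/maize2/sorghum with independent per-site point
  mutations at the stated divergence; the planted category deletes the
  alternative isoform from the appropriate member.  Gene structure is
  shared across members — real homeologs also diverge structurally, so
  recovery rates here bound the idealized, not the real, setting.

What the generators do not emulate: read-level alignment artifacts,
expression-dependent coverage biases along introns, linkage between
events in one gene, structural divergence between orthologs, and
real marker ascertainment.  Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
assumptions, not performance on real libraries.

## Numerical and design notes

* Strict inequalities everywhere a threshold is phrased as "above" /
  "more than" (entropy > 2, ΔIRR > 0.15, NMD > 50 nt, PAV > 2 / < 0.1);
  inclusive elsewhere (IR % ≥ 10, FPKM ≥ 1/5, fraction ≥ 5 %, ratio
  bounds 0.05–0.95, spanning reads ≥ 20, mean/line ≥ 5, fold ≥ 2,
  aligned length ≥ 30).
* The BH step-up q-values are monotone by construction; empirical FDR in
  the calibration study is the mean per-replicate false-discovery
  proportion (0 when nothing is discovered), the quantity BH controls.
* Ward leaf order is scipy's deterministic dendrogram order; dendrograms
  export to Newick with merge heights as branch lengths.
* Degenerate inputs: constant ratio matrices cluster into a valid
  zero-height tree; zero-read junctions raise; zero-total lines are
  excluded from GLM fits; empty anchor extraction raises.
* Problem sizes in the reproduction script (100k frame draws, 80/60-gene
  annotations, 200 replicate panels, 200 triplets per divergence) were
  chosen to keep every Monte-Carlo standard error well below the
  decision margins while completing in about a minute on one CPU.

## Known limitations

* AltA/AltD events sharing one site among three or more acceptors are
  emitted pairwise-deduplicated; an event graph could merge them and
  would count differently.
* The NMD rule uses only the 50-nt heuristic; uORFs, long 3'UTRs and
  other NMD triggers are out of scope.
* The translated aligner reports the best single frame pair; chimeric
  tags whose two anchors align in different frames score conservatively.
* The quasi-binomial model treats lines as independent; family structure
  in real RIL panels would require a mixed model.
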