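# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical details a user re-deriving results would need.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`. BED input is
taken as-is; GTF gene features (1-based inclusive) are converted at the
reader. "Overlap" always means ≥ 1 shared base under half-open arithmetic,
so bookended intervals (`[a,b)`, `[b,c)`) do **not** overlap — this matters
for consensus merging and TSS-window annotation, and the test-suite oracles
encode the same convention (at doubled base-pair resolution, so bookends
stay distinguishable in a coverage vector).

## Consensus regions

Per-sample peaks shorter than 2 kb are stretched symmetrically about their
midpoint (odd deficits give the extra base to the right; clipping at
coordinate 0 pushes the excess rightward so the minimum length always
holds). Stretched peaks from all samples are merged on their outmost
coordinates wherever chains of pairwise overlaps connect them; a merged
region's support is the number of distinct contributing samples, not
peaks. Regions with support ≥ 2 survive. Occupancy is the count of
deduplicated reads (one per (chrom, start, strand)) overlapping the region
by ≥ 1 bp; reads outside the configured autosome set (default chr1–chr22,
overridable for synthetic genomes) are excluded from counts *and* library
sizes. Because merged regions are disjoint, a read can at most straddle two
regions; such reads count once in each and are logged.

## Differential test

The per-region model is NB(μ = s_j·m_g, α) with a log link and a group
effect. Size factors are DESeq2-convention median-of-ratios against the
per-region geometric mean, computed over regions with all-positive counts
and reported unscaled; the median is taken in linear space.

Dispersion: the method-of-moments estimate removes the size-factor-weighted
Poisson part from the pooled within-group variance of normalized counts,
`α̂ᵢ = (v_w − mean_j(m_g/s_j)) / mean_j(m_g²)`. A trend `α(μ) = a₀ + a₁/μ`
is fitted by least squares with one outlier-discarding pass, and the final
dispersion mixes MoM and trend on the log scale with weight 0.1 on the MoM
part. The light weight is deliberate: at 5–25 samples the MoM estimate is
noisy, and correlation between estimated dispersion and observed variance
makes a heavier weight anti-conservative. Regions whose MoM estimate
exceeds 4× the trend keep it (variance outliers must not be shrunk into
false positives). Group means solve the NB score equation by safeguarded
Newton iteration (the ratio-of-sums start is exact at α = 0; an all-zero
group gets a half-read floor). The Wald statistic on ln(m₁/m₀) uses the
Fisher information Σ μ/(1+αμ) per group and a normal reference; under null
simulations at the design sample sizes the 5% level is held within
[0.035, 0.065]. p-values are BH step-up adjusted over testable regions
(all-zero regions are excluded from m and reported with missing p).

The clustering matrix chain is RPKM → quantile normalization across samples
(ties receive the mean of their quantile targets) → add 1 RPKM → log2 →
per-region median centering.

## TRCDs

Eligible regions have |log2FC| strictly above 0.4 and, by default, adjusted
p < 0.05 (`require_significant` exposes the laxer reading where only the
fold-change filter applies). Pairs are consecutive eligible regions per
chromosome; distance is midpoint-to-midpoint (configurable to edge-gap),
classified short = [5 kb, 100 kb], long = (100 kb, 1 Mb]. Runs are maximal
same-direction chains of ≥ 2 regions whose consecutive gaps all fall in one
class; the same regions may appear in runs of both classes, mirroring
separate short/long tallies.

The shuffle null permutes the (log2FC, significance) tuples uniformly over
the fixed positions of the *full* tested region list and recomputes
eligibility and pair counts, so coordinates, inter-region distances and the
fold-change multiset are preserved exactly. Two p-values are reported: the
empirical `(1 + #{null ≥ obs}) / (1 + n_shuffles)` — whose resolution is
bounded by the shuffle count — and an upper-tail binomial with
`p₀ = f_up² + f_down²` from the marginal direction frequencies of eligible
regions, which is the headline number because only a parametric tail can
express the extreme significance levels this statistic reaches on real
cohorts. The binomial p is computed in log space to survive underflow.

## Annotation and windowed signal

One canonical TSS per gene. Three window kinds: ±5 kb around the TSS
(annotation), ±2.5 kb (promoter signal), and a strand-aware 2.5 kb
upstream window (marker panels); upstream extends against the direction of
transcription and windows clip at 0. Window signal attributes each
overlapping region's reads pro-rata to the overlapped fraction of the
region and scales to window RPKM (or RPM), so a window fully inside one
region reproduces that region's RPKM exactly.

## Motif enrichment

PWM site score per column: `p'(b) = (p(b) + 0.25·bg(b)) / 1.25`,
contribution `log2(p'(b)/bg(b))` with uniform background 0.25; N scores 0.
The per-sequence statistic is the maximum site score over all offsets on
both strands (other AME statistics are not implemented). Controls are
per-sequence mononucleotide shuffles (dinucleotide shuffling is not
implemented; the mononucleotide null matches the i.i.d. background of the
synthetic sequences). The one-sided rank-sum test uses exact enumeration
when both sides have ≤ 8 tie-free observations, otherwise the normal
approximation with tie and continuity correction; Bonferroni multiplies by
#motifs × #partitions (partitions default to 1). Motif scoring is
vectorized across equal-length sequences.

## Integration

Correlations are computed on log2(x + 1); Spearman is the headline,
Pearson co-reported. The GSEA running sum uses weight 1: hits add
`|metric|/Σ_hits|metric|`, misses subtract `1/(N − n_hits)`; ES is the
signed maximum deviation; with every gene a hit the miss term is degenerate
and ES is the hit-only maximum. NES divides ES by the mean |null ES| of the
matching sign under gene-set permutation (size-matched random sets —
appropriate for pre-ranked input); FDR follows the positive/negative-tail
convention with null NES pooled across queried sets. The expression DE call
deliberately uses **raw** p < 0.05 while the acetylome uses adjusted
p < 0.05 — the asymmetry reflects the different conventions of the two
assays and is preserved, not reconciled. Marker panels report group means
(all/patient/control) of promoter acetylation and expression per cell type,
flag markers whose 2.5 kb upstream window overlaps a DAR (our
operationalization of "significantly different acetylation at the
upstream window"), and carry the DE flag with fold change.

## Synthetic generator

One global seed fans out to named child streams (`regions`, `counts`,
`peaks`, `reads`, `genes`, `motifs`, `markers`) via CRC32-salted seed
sequences, so changing one component's draws never shifts another's.

Defaults encode the study conditions: 20 patients vs 5 controls; NB counts
with dispersion 0.1 and log2-normal baseline (mean 6, sd 1); 30% of regions
planted at |log2FC| = 1.5 with direction persistence 0.8 along each
chromosome (a two-state Markov chain emulating tandem domains); size
factors log-uniform in [0.5, 2]. Regions are 2–4 kb with gaps from a 70/30
mixture of short (5–90 kb) and long (100–400 kb) draws so both adjacency
classes occur; a minimum gap of 5 kb keeps "adjacent" well defined.
Validation bounds the expected footprint (plus a 6σ margin) against the
chromosome length and placement aborts on overflow. Reads realize the
simulated counts exactly (distinct (start, strand) slots inside each
region, so duplicate collapsing is a no-op) plus background reads in gaps
up to the library size (in-region total inflated by the 20% background
fraction). Gene TSSs sit inside their driving regions; per sample,
log2(expression RPKM + 1) = slope·log2(acetylation RPKM + 1) + Gaussian
noise (`calibrate_noise_sd` converts a target Pearson r into a noise SD);
expression counts are Poisson around the implied mean at a 5e6 library.
Sequences are i.i.d. uniform ACGT, 500 bp, one per region; the first
library motif is planted (exact consensus, random offset) into
hyperacetylated sequences at the plant rate; 20 decoy motifs are never
planted.

The generator emulates the *statistical* structure only: no real genome
sequence, GC or mappability structure, no read-level errors or fragment
lengths, no peak-caller artifacts, no batch effects or covariates. Passing
tests therefore demonstrate correctness and calibration of the methods
under their own model assumptions, not robustness to the full messiness of
real ChIP-seq.

## Problem sizes and numerics

Test and demonstration runs use scaled problem sizes chosen to make the
statistical checks well-powered while staying quick: 5,000 null regions for
calibration, 3,000 regions for recovery and TRCD power (≥ 2,000 planted
DARs), 200 replicates for the TRCD null-uniformity check (199 shuffles
each; the `(1+k)/(1+n)` estimator is slightly super-uniform under ties,
which the KS tolerance absorbs), 25 replicates × 21 motifs for motif
power/FPR, and a 600-region demo cohort for the end-to-end run. Floating
point output is written with `%.6g` so reruns are byte-identical; every
stochastic stage requires an explicit seed and the manifest records all of
them.

## Known limitations

- No numeric parity with DESeq2/limma/GSEA/AME is claimed; conventions are
  re-implemented and validated by oracle equivalence and simulation
  (pydeseq2 serves as an independent cross-check in one test).
- Single-TSS gene models; transcript-level annotation is out of scope.
- Permutation resolution bounds the empirical TRCD p at 1/(n_shuffles+1);
  use the binomial form for tail magnitudes.
- The expression DE test reuses the acetylome NB machinery; paired designs
  and batch correction are unsupported.
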