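# acetylome

Differential histone-acetylome analysis for two-group ChIP-seq cohorts —
built around the H3K27ac design of a small patient cohort (n≈20) compared
against scarce healthy controls (n≈5), where the questions are: which
regulatory regions gain or lose acetylation, whether co-directional changes
cluster into chromatin domains, and how the chromatin changes propagate to
the transcriptome.

The package is a library first (importable modules plus `examples/`), with a
thin `acetylome` command-line wrapper for file-driven runs.

## What it computes

1. **Consensus regions** — per-sample peak calls are stretched to ≥ 2 kb,
   pooled, merged on their outmost coordinates wherever they overlap, and
   kept when supported by ≥ 2 independent samples; per-sample occupancy is
   the number of deduplicated autosomal reads overlapping each region.
2. **Differential acetylation** — a negative-binomial Wald test per region:
   median-of-ratios size factors `s_j = median_i (k_ij / (∏_j k_ij)^{1/n})`,
   method-of-moments dispersions shrunk toward a fitted mean–dispersion
   trend `α(μ) = a₀ + a₁/μ`, group means from the NB score equation, and a
   Wald test on `log2FC` with Benjamini–Hochberg adjustment. Regions with
   adjusted p < 0.05 are DARs (hyper- or hypoacetylated by fold-change sign).
3. **Tandem regulated chromatin domains (TRCDs)** — among regions with
   |log2FC| > 0.4, adjacent same-direction pairs are tallied in short
   (5–100 kb) and long (100 kb–1 Mb) midpoint-distance classes and tested
   against (a) a shuffle null that permutes the (fold change, significance)
   tuples over the fixed region positions and (b) an upper-tail binomial
   with `p₀ = f_up² + f_down²`.
4. **Gene annotation** — regions link to genes whose ±5 kb TSS window they
   overlap; promoter (±2.5 kb) and upstream (2.5 kb) windows quantify
   signal pro-rata from overlapping regions.
5. **Motif enrichment** — AME-style: per-sequence best PWM log-odds site
   (both strands; uniform 0.25 background, 0.25 total pseudocount per
   column), one-sided Wilcoxon rank-sum against mononucleotide-shuffled
   controls, Bonferroni correction by #motifs × #partitions, and
   motif-to-TF set algebra (exclusive/shared Venn partition).
6. **Transcriptome integration** — expressed-gene filter (mean RPKM > 0.5),
   per-sample Spearman/Pearson correlation of promoter acetylation with
   expression on the log2(x+1) scale, a classic weighted Kolmogorov–Smirnov
   running enrichment score with gene-set-permutation NES/FDR, cell-type
   marker panels, and concordant-TF calling against the expression DE test
   (raw p < 0.05).
7. **Synthetic data** — a generator that emulates the assumed statistics
   (NB counts, spatially persistent DAR directions via a two-state Markov
   chain, promoter–expression coupling, planted motif sites) and writes
   every input format the pipeline reads, with ground-truth tables.

## Worked example

`examples/02_differential_acetylation.py` simulates 1,500 regions (25%
carrying a planted |log2FC| = 1.5) for 20 patients vs 5 controls and calls
DARs:

```
1500 regions tested (20 patients vs 5 controls)
DARs at adjusted p < 0.05: 193 hyper + 184 hypo
planted effects: 370; recovered: 370 (100% sensitivity)
false discoveries among calls: 7 (1.9%)
```

All planted effects are recovered and the empirical false-discovery rate
stays below the nominal 5%. `examples/03_trcd_detection.py` continues with
domain detection on a genome with direction persistence 0.85:

```
461 significant regions with |log2FC| > 0.4
short: 87/119 same-direction pairs (null p0 = 0.501); binomial p = 10^-6.6,
       empirical p = 0.0020 (500 shuffles); 67 runs (>= 2 members)
long:  261/310 same-direction pairs (null p0 = 0.501); binomial p = 10^-35.6,
       empirical p = 0.0020 (500 shuffles); 98 runs (>= 2 members)
```

Same-direction pairs far exceed the ~50% expected under independence —
the planted tandem-domain structure is detected in both distance classes.
The other examples cover consensus construction, annotation/integration,
motif enrichment, and the one-command full pipeline.

## Command line

```bash
acetylome config --demo-dir demo          # write demo config pair
acetylome simulate --config demo/simulation.yaml --outdir demo/inputs
acetylome run-all --config demo/pipeline.yaml
```

Stages can also run individually (`consensus`, `diff`, `trcd`, `annotate`,
`motifs`, `integrate`). Every run writes a `manifest.json` with parameters,
seeds and sha256 digests of all outputs; reruns with the same config and
seed are byte-identical.

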