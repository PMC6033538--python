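# clipshift

From RNA-binding-protein CLIP maps to their regulatory consequences:
`clipshift` is a reusable pipeline for the integrative analysis that links
HITS-CLIP binding sites of an AU-rich-element binding protein (the
ZFP36/tristetraprolin family is the motivating case) to changes in mRNA
abundance, translation efficiency, ribosome occupancy, and activation
kinetics between a knockout (KO) and wild-type (WT) genotype.

It is written for computational biologists who have aligned CLIP tags,
RNA-seq and ribosome-profiling count matrices, and gene models, and want
the downstream analysis — binding-site definition through enrichment
statistics — as tested, scriptable components rather than a chain of
one-off notebooks. A bundled synthetic-data generator produces full input
bundles with known ground truth, so every stage is testable without any
external download.

## What it computes

* **Robust binding sites** — per-gene CLIP tag pileups over a genic
  background model (transcript + 10 kb downstream extension), candidate
  peaks split at coverage valleys, and a permutation FDR:
  FDR(h) = E[null candidates with PH ≥ h] / #{observed candidates with
  PH ≥ h}, where PH (peak height) is the maximum pileup depth. Sites are
  kept when PH > 5 with support from ≥ 3 biological replicates and 2
  different antisera (thresholds configurable; a pooled-replicate preset
  uses > 5 replicates). Sites are stratified into the top 20% vs bulk by
  PH, and cross-link-induced truncation sites (CITS) are called inside
  peaks by a binomial excess of read 5' ends.
* **Target classes and CDF shifts** — genes classified by site region
  (3'UTR / CDS / intron, non-exclusive or precedence-resolved), and each
  class's log2(KO/WT) distribution compared against genes with no site by
  the two-sided two-sample Kolmogorov–Smirnov test,
  `D = sup_t |F̂_class(t) − F̂_background(t)|`.
* **ΔTE enrichment** — per-gene ΔTE = log2FC(ribosome profiling) −
  log2FC(RNA-seq); target sets are tested for concentration at the top of
  the ΔTE ranking with a weighted running-sum statistic (pre-ranked
  GSEA-style), random-set permutation null, sign-matched NES, and an
  NES-based FDR.
* **Coverage decomposition** — per-transcript footprint profiles
  (20-nt sliding windows, depth-normalized), a per-transcript exact
  binomial test of the KO read share against the library-depth
  expectation, and a metagene profile of mean per-position read
  proportions anchored to the coding region.
* **Time-course cluster enrichment** — k-means partitioning (k = 20
  default) of an activation time course and per-cluster Fisher exact
  enrichment of binding targets.

## Worked example

The one-command demo simulates a 300-gene bundle (45 3'UTR targets, 24
CDS targets, 18 intron targets planted with known effect sizes), runs
every stage, and prints the headline tables:

```bash
clipshift pipeline demo --seed 1 --outdir demo_out
```

```
{
 "robust_sites": 87,
 "genes_passing_filter": 300,
 "target_genes": 87
}
   class  n_class  n_background        D  p_value  q_value  median_shift  low_power
    UTR3       45           213 0.302660 0.001623 0.004057      0.160442      False
UTR3_top        9           213 0.244131 0.601353 0.601353      0.045485       True
     CDS       24           213 0.397300 0.001411 0.004057      0.203894      False
 CDS_top        5           213 0.692019 0.007504 0.009381      0.303497       True
  intron       18           213 0.396714 0.007273 0.009381      0.224383      False
gene_set        ES       NES   p_perm      FDR  n_permutations       seed
    UTR3  0.658983  2.215613 0.000999 0.000000            1000 1406115012
UTR3_top  0.653510  1.585379 0.042957 0.035294            1000 1406115012
     CDS  0.762887  2.319781 0.000999 0.000000            1000 1406115012
  intron -0.425306 -1.229046 0.177822 0.196911            1000 1406115012
```

Reading the output: all 87 planted target genes were recovered as robust
binding sites. The 3'UTR and CDS target classes show right-shifted
log2(KO/WT) abundance distributions against the 213 no-site background
genes (KS p ≈ 0.002 each, positive median shifts) — loss of the repressor
de-represses its targets — while the top-PH-quintile 3'UTR subset shows no
abundance shift (p = 0.60), the blunted-top-tier behaviour the generator
plants. In the ΔTE ranking, 3'UTR and CDS target sets are enriched for
increased translation efficiency (NES 2.2 and 2.3, FDR < 0.001, CDS
stronger) while the intron set is not (FDR 0.20). At this small demo
scale, chance shifts in small classes are visible (the 18-gene intron
class happens to reach p = 0.007 here); the full-scale defaults used for
validation are 1,000 genes with 20 independent seeds.

Everything the demo writes — robust-site table, CDF tables, enrichment
results, coverage tests, metagene and cluster tables, plus a
`manifest.json` with the effective config, per-stage seeds, and file
checksums — lands under `demo_out/`.

Stage-level commands (`clipshift clip call-peaks`, `clip kmers`,
`expr quantify`, `shift run`, `te enrich`, `cov test|metagene`,
`clusters run`) expose each step on files; the library API
(`clipshift.simulate_dataset`, `clipshift.analyze_bundle`, and the
per-stage modules) is the programmatic surface.

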