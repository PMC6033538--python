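# Methods

This note documents the models and procedures `clipshift` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Coordinate and data conventions

All genomic intervals are 0-based half-open on both strands (BED
convention); GTF input (1-based inclusive) is converted on read. A gene
model is the union of its transcripts' exons, with the CDS taken from the
longest coding transcript; 5'UTR/CDS/3'UTR assignment respects strand, so
the 3'UTR of a minus-strand gene occupies the lowest genomic coordinates.
Every gene carries a downstream extension (default 10,000 nt past the
annotated 3' end) that is part of the "genic background" span: CLIP signal
from non-annotated 3'UTR variants falls there and should count as genic,
not intergenic. In exclusive annotation mode, region precedence is
UTR3 > CDS > UTR5 > intron > downstream, chosen to match the analytic
emphasis on 3'UTR and CDS binding; non-exclusive mode (the default)
returns every overlapped region.

All fold changes are oriented log2(KO/WT).

## Peak calling and robust sites

**Pileup and candidates.** Per-base depth is accumulated over the extended
gene span. Candidate peaks are maximal runs of positive depth, split at
internal valleys: a position splits a run when its depth is strictly below
half the smaller of the maximum depths to its left and right within the
run, with one split per contiguous below-threshold stretch at the leftmost
position of its minimum. The rule is single-pass and order-independent,
which makes the observed path and the permutation kernel provably
identical (they are property-tested against each other).

**Permutation FDR.** The null hypothesis is that a gene's tags are placed
uniformly over its extended span. For `n_perm` permutations the tag
intervals (lengths preserved) are re-placed uniformly and candidates
re-detected; FDR(h) = E[null candidates with PH ≥ h] / #{observed
candidates with PH ≥ h}, monotonized to be non-increasing in peak height
h, and candidates with FDR ≤ α (default 0.01) become peaks. `n_perm < 20`
is rejected as unstably resolved; the pipeline default is 100 (50 in the
multi-seed validation runs, where the FDR decisions are far from the
boundary). All permutations for one gene run in a single compiled pass by
offsetting each permutation into its own coordinate block.

**Robust sites.** Peaks called per replicate are merged across replicates
at ≥ 1 bp overlap into union intervals; the merged PH is the maximum
constituent PH. A site is retained when PH > 5 (strict), ≥ 3 biological
replicates, and ≥ 2 distinct antisera support it. The pooled preset calls
peaks on pooled tags and requires support recorded from member tags in
more than 5 replicates — read strictly as ≥ 6 — and 2 antisera; the
per-replicate and pooled rules are both exposed because different
stringencies suit different depths. Sites are ranked by PH (ties by tag
count, then site id, so the top set is reproducible) and the top 20%
labelled "top" tier, by default within each region separately (ranking
scope is configurable to global).

**CITS.** Within each peak of width w containing m truncation events
(read 5' ends), a position with c events is tested against the upper tail
of Binomial(m, 1/w); Benjamini–Hochberg is applied over all tested
positions and q ≤ 0.05 retained.

**k-mer enrichment.** As a deliberately simple stand-in for de novo motif
discovery, 30-nt windows around sites are compared with ≥ 100
dinucleotide-preserving shuffles (Altschul–Erikson); each observed k-mer
gets z = (obs − null mean)/null sd with the sd floored at one count so
k-mers absent from every shuffle get a finite, count-resolution z.

## Expression quantification and fold changes

RPKM = count/((length/10³)(library/10⁶)); cpm = count/(library/10⁶).
Genes enter the shift and ΔTE analyses only if mean RPKM > 3 in WT or KO
RNA-seq replicates **and** ribosome-profiling cpm > 1 in at least two
replicates of one genotype.

log2FC is estimated as log2((mean_KO + pc)/(mean_WT + pc)) on
size-factor-normalized counts with pseudocount 0.5 — a deliberate
substitution of a fully specified, deterministic estimator for a
dispersion-modelled GLM, justified because every downstream consumer uses
only the log2FC values and their ranking. Size factors are DESeq-style
median-of-ratios. When a substantial fraction of genes is regulated in
one direction, the unrestricted ratio median is measurably pulled toward
the regulated genes (their per-sample ratios blur into the null
distribution at realistic dispersions); the pipeline therefore computes
size factors on a control-gene reference — the genes without any robust
CLIP site — once sites have been called. This is the control-genes idea
familiar from DESeq2 and reduces the planted-effect recovery bias from
≈ 0.05 to ≤ 0.02 log2 units under the default simulation.

## CDF shift tests

Each target class (UTR3, CDS, intron; plus top-tier subsets of UTR3 and
CDS) is compared with the background of filtered genes carrying no robust
site anywhere, using the two-sided two-sample KS test. The exact p-value
is used when n_class · n_background ≤ 10⁴ and the asymptotic Kolmogorov
distribution otherwise. Raw p-values are reported; BH q-values across the
family of class tests are added alongside, never replacing raw p. Classes
with n < 10 are flagged low-power rather than suppressed. An optional
CITS-stringent mode restricts classification to sites overlapping a
significant CITS.

## ΔTE and pre-ranked enrichment

ΔTE = log2FC(ribosome profiling) − log2FC(RNA-seq), computed only for
genes passing both filters; genes are ranked by ΔTE descending with
lexicographic tie-breaking. Each target set is ranked against the
no-binding background only (set ∪ background universe): the comparison of
interest is "targets vs unbound genes", and a shared universe would let
one class's strong signal masquerade as another class's depletion.

The running sum increments |score|^p / Σ_hits|score|^p at set members
(p = 1 default, the classic weighting; p = 0 supported) and decrements
1/(N − N_hits) at non-members; ES is the signed maximum deviation, with
|max| = |min| ties resolved to the earlier extremum, which preserves
ES(set) = −ES(complement) exactly at p = 0. The null re-draws the set
uniformly at random (pre-ranked convention); NES divides ES by the mean
|null ES| of matching sign, p = (1 + #{|null ES| ≥ |ES|})/(n_perm + 1),
and FDR follows the standard NES-based pooling across the reported family,
sign-restricted and capped at 1. The leading edge comprises set members at
or before the maximum for positive ES and at or after the minimum for
negative ES.

## Coverage

"Coverage" counts read centers (footprint midpoints), applied uniformly to
window profiles and the metagene so the two views agree. Window profiles
are 20-nt sliding sums per million mapped reads, step 1. The per-transcript
genotype test is exact binomial: of n = x_KO + x_WT reads on a transcript,
x_KO is tested against p₀ = depth_KO/(depth_KO + depth_WT), two-sided by
the minimum-likelihood method, BH-corrected across transcripts. The
transcript, not the window, is the test unit.

The metagene averages per-transcript read-proportion vectors (each sums
to 1 over the transcript before any mapping) over transcripts with ≥ 10
reads in the region of interest (default: the CDS, configurable). The
default grid anchors 50 nt at the CDS start and stop and rescales the
middle to 100 mass-conserving bins; single-anchor start/stop grids are
available. Each grid position averages only over the transcripts that
contribute there.

## Time-course clustering

Genes are z-scored across timepoints (constant genes map to zero) and
partitioned by Lloyd's k-means with k-means++ initialization, best of
`n_init` seeded starts — a seedable, behaviourally equivalent replacement
for legacy clustering tools at the level used (pattern partitioning).
k = 20 by default. Per-cluster 2×2 tables (in-cluster × target) are tested
two-sided by Fisher's exact test with BH across the k clusters; summaries
report the three most enriched and three most depleted clusters (by p,
ties by |log OR| then cluster id) with their mean standardized profiles.

## The synthetic-data generator

The generator emulates the statistical structure the analyses are designed
to detect, with every parameter in one seeded config:

* **Gene models**: two-exon coding genes (5'UTR 100–300 nt, CDS
  900–1,500 nt, 3'UTR 400–800 nt, intron 500–2,000 nt), strands random,
  spaced so extended spans never overlap.
* **CLIP tags**: per target gene one planted site at the center of its
  designated region; per replicate the site receives Poisson(λ) tags
  (λ = 12 bulk tier, 30 top tier) with lognormal per-replicate rate jitter
  (σ = 0.2), tag 5' ends (truncations) normally concentrated at the site
  center (σ = 2 nt); background tags fall uniformly over the extended span
  at 0.2/kb/replicate. Five replicates across two antisera (3 + 2).
* **Counts**: NB with variance μ + φμ², φ = 0.05, chosen as realistic for
  biological replicates of primary cells from inbred littermates; per-gene
  abundances lognormal (σ = 1) scaled to 10⁶ expected reads per sample,
  4 replicates per genotype per assay. KO means are scaled by
  2^δ_abund(class, tier) in RNA-seq and 2^(δ_abund + δ_TE) in ribosome
  profiling.
* **Effect sizes** (free parameters of the generator — the motivating
  study reports CDF curves and p-values, not magnitudes): δ_abund = 0.2
  for 3'UTR-bulk and CDS, **0 for 3'UTR-top**; δ_TE = 0.3 for 3'UTR
  (both tiers), 0.5 for CDS; intron targets all zero. This plants the
  qualitative structure the analyses should recover: abundance and
  translation shifts for 3'UTR/CDS but not intron, a stronger translation
  effect for CDS, and a top-PH tier whose abundance effect is blunted
  while its translation effect persists. The default plan is 150 UTR3,
  80 CDS, and 60 intron targets among 1,000 genes.
* **Coverage**: per-transcript shape vectors with the dynamic range of
  real footprint profiles (lognormal of smoothed noise, an initiation
  peak at the CDS start, down-weighted UTRs), shared between genotypes;
  read counts Poisson around 2,000 per transcript (lognormal per-gene
  rate, σ = 0.5) with the KO rate scaled by 2^δ_TE.
* **Time course**: eight timepoints, six pattern archetypes; 3'UTR/CDS
  targets receive the rapid-induction archetype with probability 0.6,
  other genes a uniform archetype; Gaussian noise σ = 0.3.
* **Sequence**: 30-nt site windows of uniform random RNA bases with the
  consensus-like 8-mer UAUUUAUU (configurable) embedded centrally.

Each output artifact draws from its own stream seeded by (seed, artifact
offset), so identical seeds give byte-identical outputs and enabling one
artifact never perturbs another.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: read-level sequence/alignment artifacts,
PCR duplicates and UMI structure, isoform mixtures and alternative
polyadenylation, correlated gene-gene expression, batch effects,
overdispersion heterogeneity across genes, CLIP cross-link sequence bias
beyond the planted motif, and genuinely overlapping genes. Results on
synthetic bundles demonstrate correctness and calibration of the
statistics under the stated model, not robustness to those artifacts.

## Validation scale and determinism

The packaged validation (test suite and `scripts/acceptance.py`) runs the
full pipeline on 1,000-gene bundles across 10–20 independent seeds with
50 peak-caller permutations and 500 enrichment permutations, and the
peak-caller calibration on 200 null genes at 100 permutations — sizes at
which every check completes in minutes on one CPU while leaving the
measured quantities far from their decision boundaries. All randomness in
the pipeline flows from one global seed through fixed per-stage
derivations recorded in the run manifest, so reruns with the same config
reproduce identical output checksums.

## Known limitations

* The permutation null models background tags as uniform over the
  extended gene span; structured background (e.g. expression-dependent
  3' bias) would require a more detailed null.
* The log2FC estimator reports no per-gene significance — by design; the
  downstream analyses are distributional.
* Normalization relies on the no-site background being predominantly
  unregulated; a regulator with genome-wide indirect effects would bias
  the control-gene size factors.
* The metagene's rescaled-middle grid assumes CDS length ≥ ~102 nt
  (2 × edge + 2); shorter CDSs are excluded from the "both"-anchored
  profile.
* Pre-ranked enrichment p-values are bounded below by 1/(n_perm + 1).
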