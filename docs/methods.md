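# Methods

## Chromogroup assignment

A sample's profile is the categorical state (gain / disomy / loss) of its
autosomal chromosome arms. Group membership is a pure rule match on the
four arms 1p, 1q, 16p, 16q (table in the README); "no filter" arms are
ignored entirely, so a sample can match several rules. The algebra that
follows from the rules — A, B, D and CTRL pairwise disjoint, D the
disjoint union of D1 and D2, B ∩ C = B2 — is asserted by exhaustive
enumeration of all 3⁴ = 81 state combinations in the test suite.
Samples matching no rule (e.g. 1p-loss with disomic 1q) receive the
empty label set; they stay in cohort-wide summaries but not in group
statistics.

The **aneuploidy score** is the number of non-disomic arms in a
configurable universe, by default the 39 autosomal arms that carry genes
(the acrocentric p-arms 13p/14p/15p/21p/22p are excluded). Arms missing
from a profile count as disomic.

Cohort summaries report each group's size, its share of the union of
A∪B∪C∪D (unique samples; percentages rounded to the nearest integer,
half away from zero) and aneuploidy-score mean/SD/median/IQR.

## Differential-expression engine

The engine is a deterministic, self-contained NB workflow:

1. **Pre-filter.** A gene is removed when at least 70% of samples have a
   zero count (the `zero_fraction` boundary is inclusive for removal).
2. **TMM normalization.** Per-sample factors are precision-weighted,
   doubly trimmed means of M-values against a reference library (trim
   30% per M tail, 5% per A tail); the automatic reference is the sample
   whose upper-quartile relative abundance is closest to the cohort
   mean; factors are rescaled to geometric mean 1. The implementation
   was checked against an independent transcription of the definition
   (tolerance 1e-6) and, during development, reproduced
   edgeR::calcNormFactors to all printed digits on a seeded NB matrix.
3. **Dispersion.** Counts are scaled to the geometric-mean effective
   library; per gene, the pooled within-group method-of-moments estimate
   φ̂ = Σ(n_j−1)(s²_j−m_j) / Σ(n_j−1)m_j² (clamped at 0) is shrunk toward
   the median estimate with weight n0/(n0 + residual df), n0 = 10, and
   floored at 1e-6. With no replicated group the common dispersion falls
   back to 0.1 with a warning.
4. **Exact test.** Counts are linearly scaled to the geometric-mean
   effective library ("library equalization"; a deliberate, simpler
   alternative to quantile mapping) and summed per group. Under a shared
   per-sample NB(μ, φ) model, the split of the total between groups of
   sizes n_A, n_B follows a conditional law that depends only on
   r_A = n_A/φ and r_B = n_B/φ; for φ < 1e-10 it reduces to
   binomial(t, n_A/(n_A+n_B)). Two-sided p-values use the
   minimum-likelihood convention (sum of probabilities of outcomes no
   more probable than the observed one). The support is enumerated fully
   for totals ≤ 50 000 and otherwise restricted to a ±40 SD window
   around the conditional mean, extended to the observation; the
   conditional pmf is log-concave, so the mass outside is negligible.
5. **Fold-change.** Group means on the CPM scale with a 0.5 pseudo-count
   per mean; the ratio r is reported as r when r ≥ 1 and −1/r otherwise,
   so |FC| ≥ 1 always and "FC < −1.3" means the reference is more than
   1.3-fold higher. The modified FC (FC−1 for FC>1, FC+1 for FC<−1)
   removes the (−1, 1) gap for clustering.
6. **Multiplicity.** Benjamini–Hochberg step-up, verified against a
   brute-force transcription of the definition.

All taxonomy thresholds are strict inequalities on the signed linear FC
(FC = 1.3 exactly is not OverT).

### Known limitation: one-sided composition shifts

TMM assumes most genes are not differentially expressed *symmetrically*.
When a large one-sided block of genes shifts (e.g. ~9% of the
transcriptome up two-fold in one group only), the trimmed mean
under-corrects the composition change and null genes inherit a small
apparent fold-change; in a simulation with 200 same-direction two-fold
effects among 2000 nulls the empirical FDR of BH calls rose to ~0.18.
With balanced effects the FDR stays within 1.5× nominal. This is a
property of TMM itself, not of the exact test, and matters for cohorts
dominated by a single gained arm; arm-level dosage effects in these
data are partially balanced (1q up, 16q down), which mitigates it.

## NCDI

NCDI_n = (x_n/X_n) / Σ(x_i/X_i) × 100 over a region system (all arms, or
the cytobands of one arm). Regions encoding no transcripts are dropped
before normalization — the density is undefined there. The AllT baseline
sets x_n = X_n. The statistic is scale-invariant, sums to 100 exactly,
is zero iff the region is empty of the class, and is strictly monotone
in each region's count. Denominators use the post-filter gene universe
by default (the universe actually tested), configurable by passing a
different annotation subset.

## Clustering

The strict-DEG matrix (|FCvsCTRL| > 1.3, adjp < 0.001, chromosomes 1 and
16) holds modified fold-changes per chromogroup; genes missing from some
group's contrast are filled with 0 (no evidence of change) to keep the
matrix dense. Rows are centered/scaled to SD 1 (constant rows zeroed
with a warning); linkage is UPGMA on Euclidean distance via scipy
(`method="average"`), validated against a naive O(n³) agglomeration in
the tests; k-cut labels default to 5 row clusters. On dosage-dominated
synthetic cohorts the two 1q-gain/16q-loss groups (A, B1) pair by
cophenetic distance, as do the 1q-gain-only and 16q-loss-only pairs.

## GSEA

Genes are ranked by Signal2Noise s = (μ_A−μ_B)/(σ_A+σ_B), each σ floored
at max(0.2|μ|, 0.2) (the conventional guard; it also makes the metric
finite for constant genes). The absolute-value variant ranks by |s| so
dosage-increased and dosage-decreased genes reach the top together —
that is what lets one mixed 1q+16q set score as a block. The running sum
increments by |s|^p (p = 1) normalized over hits and decrements by
1/(N−N_hit); ES is the extremum of largest magnitude; when every hit has
zero weight the walk degrades to the unweighted KS form. NES divides ES
by the mean magnitude of same-sign permuted scores; nominal p is the
same-sign exceedance fraction; FDR q follows the ratio-of-tails scheme
over the pooled sign-matched null. Phenotype permutation is the default
and requires ≥7 samples per side, otherwise the run switches to gene-set
permutation with a warning; ties in the metric break by gene id; runs
are bit-reproducible given a seed. Set-size filter: 15–500. The
hypergeometric over-representation test (upper tail, BH across sets) is
provided for threshold-selected lists.

## Synthetic cohorts

The generator emits annotation, arm calls, NB counts and metadata with
the structure the analysis assumes.

* **Arms and genes.** Default 39 autosomal arms × `genes_per_arm` genes;
  each arm carries four synthetic cytobands; coordinates are schematic
  (equal-length arms). The desk-scale config uses 8 arms × 25 genes.
* **Copy number.** Constrained arms follow the truth group's rule (16p
  stays disomic except in D2 where the rule requires a gain);
  unconstrained arms gain or lose (50/50) independently at a per-group
  rate chosen to reproduce the cohort's aneuploidy-score ordering:
  CTRL 0.05 < A = D1 0.10 < D2 0.15 < C 0.25 < B2 0.30 < B1 0.40.
  With 35 free arms this puts the median score near 2 for CTRL, 6 for A
  and 17 for B1, matching the observed low-AS der(1;16) group versus the
  high-AS i(1q)+del(16q) group.
* **Counts.** Gene baselines are log-normal (μ = 4, σ = 1 on the natural
  log, normalized to proportions); expected counts are
  L·p_g·(copies/2)^β·t_g·h_g with library size L = 500 000 (200 000 at
  desk scale), dosage exponent β = 1 (β < 1 models compensation; the
  analytic `expected_fold_change` oracle returns (copies/2)^β ratios),
  tumor-dysregulation multipliers t_g (5% of genes ×2, 5% ×0.5 in all
  tumors vs normals) and a lobular marker h_g (one 16q gene at ×1/3 in
  lobular samples, the CDH1-like pattern). Sampling is gamma–Poisson
  with common dispersion φ = 0.1.
* **Histotypes.** Lobular fractions are enriched in 16q-loss groups
  (A 0.30, D1 0.25, D2 0.20, CTRL 0.20, B1 0.15, C 0.01, B2 0) —
  mirroring the observed association — and 0 for B2/C means those
  groups legitimately error out of histotype contrasts.
* **Group sizes.** Defaults are the cohort's RNA-seq group sizes
  (A 175, B1 98, B2 17, C 89, D1 27, D2 45, CTRL 68, 99 normals). The
  desk-scale config keeps the D1:D2 imbalance (16:24) so histotype
  contrasts retain lobular samples.
* **Streams.** Each consumer (baselines, arm calls, histotypes, counts,
  dysregulation choice) draws from its own child of the master seed, so
  enabling one feature never perturbs another's draws.

What the generator does **not** emulate: gene–gene expression
covariance, tumor purity and subclonality, allele-specific copy number,
length-biased FPKM artifacts, point mutations. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under clean
dosage signals, not performance on real cohorts — in particular,
real-data fold-changes are attenuated (β < 1) and noisier.

## Pipeline and problem sizes

`run_pipeline` executes assignment → summaries → per-group contrasts
(vs CTRL and vs normals; groups with fewer than 3 usable samples are
skipped with a logged reason, not errored) → taxonomy → region summaries
→ NCDI → strict-DEG clustering → Venn/core sets → GSEA (both metrics) →
lobular-vs-ductal DEGs. One shared pre-filter across all samples fixes a
common gene universe, so filtered analyses operate on subsets of it.
Report tables have fixed schemas; reruns with the same config and seed
are byte-identical.

The shipped test and acceptance workloads use desk-scale cohorts
(hundreds of samples, a few thousand genes, 200–1000 permutations),
chosen so the full suite runs in a few minutes on one CPU; all
statistical checks are calibrated to these sizes. The parameter-recovery
suite runs five seeds at β = 1, φ = 0.1, 40 samples/group and 200
genes/arm and requires ≥70% OverT sensitivity on the gained arm, ≤10%
on disomic arms, the NCDI(OverT) maximum on 1q, and the A–B1 cophenetic
pairing.
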