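# Methods

## The DMR model

MeDIP-seq enriches methylated DNA fragments, so the read depth observed at
a CpG site is a monotone proxy of that site's methylation level. The study
design is paired: each animal contributes one superficial-backfat (sBF)
and one deep-backfat (dBF) sample, and all tests operate on within-pair
contrasts of depth. A DMR is a run of nearby CpGs whose depth differs
consistently between the two depots.

### Test routing

Count coverage is heteroskedastic, so each tested unit — a single CpG, or
a candidate region summarised by its per-sample average depth — is first
screened with Bartlett's homogeneity-of-variance test between the two
groups. Units passing (Bartlett p > 0.05) go to the two-sided paired
Student's t-test on within-pair differences; units failing go to the
two-sided Wilcoxon rank-sum test. Degenerate case: when both groups have
zero variance the homoscedasticity premise holds trivially and the unit is
routed parametric with Bartlett p recorded as 1; when exactly one variance
is zero the statistic is infinite and the unit routes non-parametric.

The rank-sum branch is exact for combined n ≤ 20, including ties: the null
distribution of the midrank sum over all C(N, n1) label assignments is
computed by a subset-sum dynamic program over the (doubled, hence integer)
midrank multiset, and the two-sided p is the probability of a rank sum at
least as far from its mean as observed. Above N = 20 the tie-corrected
normal approximation is used (no continuity correction, matching the
large-sample permutation limit). The paired-t branch reports p = 1 for
all-zero differences and the smallest representable double (with a
warning) for constant non-zero differences, where the t statistic is off
the scale.

### Seed and extend

1. **Seeds.** Every CpG with routed test p < 0.01 seeds a candidate
   region. The genome-wide scan is vectorised: row-wise closed-form
   Bartlett and paired-t computations, with only rank-sum rows falling
   back to per-row evaluation.
2. **Extension.** From each seed, the next CpG in increasing genomic
   coordinate is incorporated one at a time. Extension stops when the gap
   to the next CpG exceeds 200 bp, the chromosome ends, or including the
   next CpG would lift the routed test on the region's per-sample average
   depth to p ≥ 0.01 (that CpG is excluded). Extension is strand-agnostic
   — CpG methylation is strand-symmetric and regions are genomic
   intervals — and proceeds toward increasing coordinates only; leftward
   growth is recovered because every significant CpG seeds its own region
   and overlapping candidates merge.
3. **Merging.** Candidates sharing at least one member CpG are unioned and
   the union retested; output regions are disjoint in member CpGs.
4. **Permutation significance.** Each region's p-value comes from
   re-computing its test statistic under 1,000 random within-pair label
   swaps (sign flips of paired differences) for the parametric branch, or
   full group-label permutations of the samples for the rank-sum branch,
   using the +1/+1 estimator p = (1 + #extreme)/(1 + n_perm) so p is never
   zero. When fewer than 10 distinct permutations exist — e.g. 2³ = 8 sign
   flips at three pairs — the analytic routed-test p is reported instead
   and flagged in the output.
5. **FDR and the 5-CpG rule.** Region p-values are Benjamini–Hochberg
   corrected; a region is a DMR when q < 0.01 and at least five member
   CpGs are individually significant at the seed threshold. Direction is
   the group with the higher mean region depth.

A companion statistic, `cpg_chain_coverage`, reports the fraction of CpGs
whose nearest neighbour lies within the 200-bp chaining distance, i.e. the
fraction of the map reachable by the extension rule.

### Choices made where the procedure is under-determined

- **Extension stop rule.** Repeated region testing needs a termination
  criterion; the greedy rule — stop at the first CpG whose inclusion makes
  the region test non-significant — is the minimal one consistent with
  significance-guarded growth.
- **Region p into BH.** The permutation p (analytic only as the flagged
  small-n fallback) is what enters the BH correction.
- **Permutation scheme.** Within-pair label swaps respect the pairing for
  the paired-t branch; the rank-sum branch, being an unpaired test, uses
  full group-label permutations.
- **Small-n caveat.** At three pairs the rank-sum branch cannot reach
  p < 0.01 (its smallest two-sided p is 0.1) and 1,000 distinct
  permutations do not exist; the `study-n3` preset therefore exercises the
  analytic fallback, and method evaluation uses ten pairs (`eval-n10`),
  where both branches and the permutation test are fully operative.
- **Coordinates.** 0-based half-open throughout; a DMR spans its first
  member CpG's C to its last member's G (end = last position + 2).

## Feature annotation

Each gene's 2,700-bp promoter is split, in transcription orientation
around the TSS, into proximal (−200..+500), intermediate (−1000..−200) and
distal (−2200..−1000) sub-regions; on the minus strand the offsets are
mirrored. First/last exons are taken in transcription order, remaining
exons are internal; introns are the gaps between consecutive exons, the
first intron being the one after the first exon. The downstream feature is
the 2 kb past the TES in transcription direction. All intervals are
clipped to chromosome bounds; intergenic is the per-chromosome complement
of the union of every gene-linked interval. A single-exon gene contributes
a first exon but no last exon. Feature classes are deliberately
non-exclusive — the proximal promoter overlaps the first 500 bp of the
gene body, and a DMR overlapping several classes by ≥ 1 bp counts in each;
the per-feature CpG percentage is 100 × (CpGs in the class that lie in any
DMR) / (CpGs in the class), undefined for empty classes.

## Expression integration

Probes are kept only if they have exactly one genomic hit and that hit
overlaps an exon of exactly one gene; genes represented by more than one
surviving probe are then dropped, leaving a one-probe-one-gene table. The
filter is idempotent and its stage counts are reported as percentages of
the initial probe count (two decimals).

For a gene with at least one DMR overlapping the requested promoter
sub-region, the methylation change is log2((m̄_A + 0.5)/(m̄_B + 0.5)) with
m̄ the group mean depth over the qualifying CpGs — by default only CpGs
inside DMRs that overlap the sub-region, since the quantity being
correlated is the *detected* methylation change; `dmr_restricted=False`
instead averages every sub-region CpG. The 0.5 pseudocount per mean is the
standard log-ratio guard against zero coverage. Correlation is the Pearson
product-moment r with the two-sided p from the t transform on n − 2
degrees of freedom, plus the least-squares line for plotting.

## Phenotypes

Mean adipocyte volume is V = (π/6)·Σ(f_i·D_i³)/Σf_i (μm³), with D_i the
geometric mean of a cell's maximum and minimum diameter (μm) and f_i the
class count; raw per-cell diameters are the f_i = 1 special case, and the
formula is homogeneous of degree 3 in diameters and invariant to uniform
count rescaling. Group contrasts are two-sided paired t-tests, summarised
as mean ± sample SD (n − 1).

## Enrichment

The EASE score is the hypergeometric upper tail of the 2×2
study-versus-term table with the observed overlap reduced by one (floored
at zero) — a conservative variant of the one-tailed Fisher exact test that
penalises single-gene support (overlap ≤ 1 ⇒ p = 1); scores are BH
corrected across terms. The term map and universe are caller-supplied, so
the statistic is testable without an external annotation database. The
bundled 13-gene cytokine-production panel records 11 genes hypermethylated
in the superficial layer (84.62%); which two genes are the exceptions is a
synthetic choice — only the count is load-bearing.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, not
the sequencing chemistry:

- **CpG map.** Clusters of 1–15 CpGs spaced uniformly 20–150 bp apart,
  separated by 300–2,000 bp gaps, so both ≤ 200 bp chains and > 200 bp
  breaks occur (~99% of sites fall in chains under the defaults).
  Degenerate ranges give deterministic geometry for tests.
- **Depth.** Negative binomial with mean μ = 30 and dispersion (NB size)
  k = 5 — the standard overdispersed count model for enrichment
  coverage — scaled by a per-sample log-normal size factor (σ = 0.02;
  libraries sequenced to near-equal depth, so the unnormalised depths the
  caller consumes are comparable across samples) and a per-pair log-normal
  random effect (σ = 0.1) shared by both samples of an animal.
- **Planted windows.** 20 windows of 6–10 CpGs by default, placed only
  inside ≤ 200 bp CpG runs so the extension rule can in principle recover
  them — separating algorithmic failure from placement artifact — with a
  3-fold multiplicative depth shift alternating between the two groups.
  Effect size 1 means a pure null: nothing is planted and the truth set is
  empty.
- **Genes, expression, phenotypes.** Non-overlapping gene models on both
  strands (always including a 2-exon and a ≥ 4-exon gene, so every feature
  class is populated); per-gene log2 expression ratios equal to
  −β·(promoter methylation delta) plus Gaussian noise; gamma-distributed
  adipocyte diameters (100 cells per sample, superficial mean 90 μm vs
  deep 80 μm, SD 15) and fatty-acid compositions drawn around the measured
  depot means (SFA 35.63 ± 2.09 vs 37.39 ± 2.19, MUFA 44.92 ± 0.80 vs
  43.54 ± 1.27, PUFA 19.45 ± 1.31 vs 19.06 ± 0.97) and renormalised to sum
  to 100.

What the generator does **not** model: read-level artifacts (duplicates,
mapping bias), CpG-density-dependent MeDIP efficiency, input-DNA
normalisation tracks, spatial autocorrelation of methylation beyond the
planted windows, and real genome sequence. Passing tests therefore show
that the algorithms are correct under the stated generative model, not
that the pipeline is robust to every artifact of real MeDIP-seq data.

## Evaluation conditions and problem sizes

Method evaluation uses ten pairs, 5,000 clustered CpGs, 20 planted 3-fold
windows and the caller's defaults. Under these conditions, the 50-replicate
study run by `scripts/acceptance.py` measures a mean empirical FDR of 0 at
the nominal 0.01 (a called region must survive BH at 0.01 *and* carry five
independently significant CpGs, a conjunction that makes null calls rare)
with mean sensitivity ≈ 0.98. The null-calibration suite (50 no-effect
replicates) checks that seed-test p-values are near-uniform
(Kolmogorov–Smirnov at the 1% level in ≥ 90% of replicates); the power
suite checks sensitivity is non-decreasing over 1.5×/2×/3× effects. The
analysis drivers use a single 8,000-CpG study with 60 windows and 60 genes
so that enough promoters intersect planted windows for the correlation and
enrichment steps to have material to work with.

## Known limitations

- The ±1 bp endpoint convention at promoter boundaries (half-open
  intervals) may differ from inclusive biological notation at each edge.
- One transcript model per gene; alternative promoters/isoforms are out of
  scope.
- The caller performs no coverage normalisation; it assumes depth is
  comparable across samples (near-equal library sizes), as the paired
  design and the generator's defaults reflect.
- At three pairs the non-parametric branch cannot produce seeds at the
  0.01 threshold and region significance falls back to analytic p-values;
  results at that scale rest on the parametric branch.
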