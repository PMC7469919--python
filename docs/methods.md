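# Methods

## Model and procedure

`tdfe` implements unsupervised gene selection by tensor decomposition for
expression studies laid out as *genes × tissues × treatments × replicates*.
The motivating design is the GSE142068 resource: 24 mouse tissues, each
profiled under 18 treatment conditions (15 drugs plus control/vehicle
conditions) with 2 replicates.

The analysis proceeds in five stages.

1. **Tensor assembly.** Per-tissue count tables are restricted to the shared
   gene set and placed into a 4-way array `x[i,j,k,m]` (gene, tissue,
   treatment, replicate) by axis label, so input file order is irrelevant.

2. **Standardization.** Each sample's gene fiber (fixed `j,k,m`) is
   transformed to `log2(count + 1)` (configurable), centered to mean 0 and
   scaled so its sum of squares equals the gene count `N`. The scaling uses
   the population (1/N) variance so the sum-of-squares constraint holds
   exactly. A zero-variance fiber is an error, not a silent skip, because
   the scaling is undefined there. With this convention the Frobenius norm
   of the standardized tensor is `sqrt(N·24·18·2)` by construction.

3. **Higher-order SVD.** For each mode, the factor matrix is the left
   singular matrix of that mode's unfolding (economy form), and the core
   tensor `G(ℓ1,ℓ2,ℓ3,ℓ4)` is the projection of the data onto all four
   factors, so that

   ```
   x[i,j,k,m] = Σ G(ℓ1,ℓ2,ℓ3,ℓ4) · u_ℓ1(j) · u_ℓ2(k) · u_ℓ3(m) · u_ℓ4(i)
   ```

   exactly at full ranks. The gene-mode factor is economy-sized
   (`N × 864` for the study design), never `N × N`: the unfolding's rank
   cannot exceed the product of the other modes' sizes, so the full square
   factor would be redundant. Because each sample fiber is centered over
   genes, the leading tissue-, treatment- and replicate-mode vectors are
   near-uniform (they carry the shared expression profile) and express no
   contrast; interpretation starts at the second vector of each mode.

4. **Interpretation and gene selection.** Tissue-mode vectors whose
   large-magnitude loadings concentrate on a few tissues define tissue
   groups (loading magnitude ≥ `dominance` × max, default 0.5). Treatments
   are split into a control-like and a treated side by exact 2-means on the
   plane of treatment-mode vectors 2 and 3. For a chosen tissue vector ℓ1,
   the gene-mode vectors with the largest `|G(ℓ1, ℓ2∈{2,3}, 1, ℓ4)|` carry
   the matching gene weights (replicate vector 1 is used because the two
   replicates load identically on it; gene vector 1 is excluded by default
   as the contrast-free direction). Gene loadings are treated as zero-mean
   Gaussian with standard deviation `σ = sqrt(mean(u²))`; each gene's
   statistic is the sum of squared standardized loadings over the selected
   vectors, referred to a χ² distribution with one degree of freedom per
   vector. P-values are Benjamini–Hochberg adjusted and genes with adjusted
   P strictly below 0.01 are selected. For multi-vector contexts the χ²
   combination (df = number of vectors) is the default; a union-of-df-1
   rule is available via `combine="union"`.

5. **Validation.** Selected genes are confirmed by pooling every
   standardized value with the gene in the selection and the tissue (or
   treatment) on one side of the split versus the other side, compared with
   a Welch two-sided t-test and a Wilcoxon rank-sum test (normal
   approximation, tie-corrected). Every `(i,j,k,m)` value counts once; no
   per-gene averaging. Overlap between contexts is reported as exact Venn
   region counts plus pairwise Jaccard indices.

## Synthetic data: what it emulates and what it does not

The generator plants known structure so that every downstream stage is
scoreable against ground truth:

```
count = round(2^(b_i + tissue_effect·[planted, group tissue]
                  + drug_effect·[planted, group tissue, treated] + ε))
b_i ~ Normal(baseline_log_mean, baseline_log_sd),  ε ~ Normal(0, noise_sd)
```

Defaults: `N = 2000` genes, the 24-tissue/18-treatment/2-replicate study
layout, three disjoint planted groups of 50 genes — neuron
{Brain, Eye, PituitaryG, Testis}, muscle {Heart, SkMuscle}, gastro
{Pancreas, Stomach} — with `tissue_effect = 3`, `drug_effect = 2` (log2
units) and `noise_sd = 0.5`. The control-like treatment side is
{APAP, FivePercentSucrose, Sofosbuvir, WT.No.treated}, matching the
observed grouping of acetaminophen and sofosbuvir with the two untreated
conditions in the motivating study. Baseline parameters
(`baseline_log_mean = 8`, `baseline_log_sd = 2`) give median counts near
256 with a heavy right tail, a plausible bulk RNA-seq profile.

A log-normal-with-rounding model is used instead of a negative binomial
because the pipeline standardizes per sample and never evaluates count
likelihoods; only the relative log-scale structure matters. The generator
does **not** emulate real library sizes, per-drug effect heterogeneity,
gene–gene correlation, or the true gene count of the deposited data, so
passing recovery tests demonstrates the machinery is correct under the
assumed signal model, not that the method's power on real data matches the
simulation.

The deposited study's tissue list names Spleen twice and omits Testis while
its tissue-group figure includes Testis; the default roster resolves the
duplicate in favour of Testis.

## Degenerate group pairs and signed contexts

Two planted groups of *equal* signal strength (muscle and gastro: both two
tissues × 50 genes with identical effects) span a two-dimensional tissue
subspace with equal singular values. The factorization therefore returns
their **sum and difference vectors**, not one vector per group: one vector
loads on all four tissues with one sign, the other splits the pair by sign.
The magnitude-based grouping rule then reports the 4-tissue union for both
vectors. This is not an artifact of the simulation — the motivating study's
own data shows two tissue-mode vectors loading on the same Pancreas/Stomach
pair, yielding two heavily overlapping gene sets.

The package handles the situation in two complementary ways:

- `identify_tissue_groups(..., side="positive"/"negative")` reads one sign
  of a difference vector, separating the paired groups exactly; signed
  contexts additionally restrict the significant genes to those
  over-expressed (in standardized units) in the member tissues, which
  resolves the gene sets of the two groups.
- The pipeline's auto-scan (`signed_split`, default on) detects a
  sign-mixed dominant group and analyses the two sign sides as separate
  contexts, while a sign-pure group is analysed with the plain magnitude
  rule.

Defaults for single-vector contexts are unchanged: `side="abs"` reproduces
the magnitude-only reading.

## Numerical choices

- **Sign convention.** Each singular vector is flipped so its
  largest-magnitude entry is positive; the decomposition is sign-ambiguous
  per vector/core pair and a fixed convention makes runs deterministic.
  Core values are therefore compared externally by absolute value.
- **Treatment split.** The within-cluster sum of squares of the 2-means
  split is minimized *exactly* by vectorized enumeration of all
  bipartitions for ≤ 20 treatments (Lloyd iteration from the farthest pair
  is the fallback above that). Local-search 2-means can be trapped by the
  perpendicular diversity axis — when treatment vector 3 is noise-dominated
  the farthest pair of points lies *within* one cluster — whereas the exact
  optimum is the control/treated partition whenever that partition explains
  the most between-cluster variance. The smaller cluster is labelled the
  control-like side (controls are the minority in the study design); the
  full coordinate table is exported for manual override.
- **BH adjustment** delegates to `statsmodels.stats.multitest`
  (`fdr_bh`), with input validation and an independent step-up oracle in
  the test suite.
- **Ties in singular values** inherit LAPACK's deterministic ordering plus
  the sign convention; exact ties are measure-zero for the data this
  pipeline targets.
- **Degenerate inputs.** Zero-variance fibers, non-finite entries,
  unstandardized input to the decomposition, empty gene pools and empty
  candidate lists all raise errors naming the offending cell or parameter.

## Problem sizes

Tests and the acceptance script run the full study-shaped simulation at
`N = 2000` genes (tensor `2000 × 24 × 18 × 2`, a ~2 s fit), decomposition
exactness checks on random tensors up to `50 × 8 × 6 × 2`, a quadruple-loop
core oracle at `6 × 4 × 3 × 2`, and calibration at 2000 genes over 20
replicates. These sizes exercise every code path at full statistical
fidelity for the planted-signal design.

## Known limitations

- Recovery guarantees are relative to the planted log-linear signal model;
  correlated noise or library-size artifacts are not simulated.
- The dominance rule is a threshold heuristic for what the original
  workflow did by eye; the loading tables are always exported so a user can
  override the grouping.
- Exact-enumeration 2-means is exponential in the number of treatments and
  falls back to a heuristic beyond 20; treatment designs that large should
  be split by the user.
- P-values from the pooled two-group tests treat all values as independent
  observations, ignoring replicate correlation — they are confirmatory
  effect summaries, not calibrated inference.
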