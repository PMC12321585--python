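# Methods

## Scope and data model

`clonodyn` operates downstream of trajectory inference: cluster labels, branch
(tip) assignments and pseudotime are taken as inputs, never recomputed. The
in-memory containers are an `anndata.AnnData` (cells × genes) with layers
`counts`, `normalized`, `scaled`, and plain pandas DataFrames for cell
metadata, clone membership, guide assignments, proportion tables and genomic
intervals (0-based half-open). All tabular artifacts are TSV; matrices are
MatrixMarket (genes × cells with sidecar index files); intervals are
BED/bedGraph.

## Expression layers

* `normalized = log1p(counts · target / depth)`, target defaulting to the
  median cell depth. Cells with zero depth are excluded with a warning, never
  imputed. The resolved target is stored so the layer is exactly recomputable.
* `scaled` is the per-gene z-score of `normalized` with the **population SD
  (denominator n)** and clipping at ±10. Zero-variance genes map to zero. The
  population-SD convention and the clip value are deliberate, documented
  choices; the expressed-cell rule used by the dynamic screen ("scaled value
  \> 0.5") depends on them.
* log2 fold changes are computed on group means of `expm1(normalized)` with a
  pseudocount of 1e-9, the common single-cell convention; this makes fold
  changes comparable to what Seurat-style tooling reports.
* Unwanted-variation regression (counts, gene counts, mitochondrial fraction,
  cell cycle) during scaling is **omitted**: whether the screen's 0.5
  scaled-expression cutoff should be applied before or after such regression is
  not determined, and the synthetic data plants none of those nuisances.

## Rank-sum differential expression

Per-gene two-sided Wilcoxon rank-sum tests use the normal approximation with
midrank tie correction and continuity correction (vectorized
`scipy.stats.mannwhitneyu`). Adjustment is Bonferroni (default for DE
significance calls) or Benjamini–Hochberg. The approximation agrees with exact
enumeration to within 0.02 for continuous expression values at group sizes
6–8; for smaller groups, or data with heavy ties (many zero counts at equal
depths), the discrepancy can exceed that — an intrinsic property of the
normal approximation, stated here rather than patched over. Group-size
preconditions (≥ 3 cells) are enforced.

## Clones and fate coupling

Clones are connected components of the cell–barcode bipartite graph
(`scipy.sparse.csgraph`); a clone spanning several barcodes through shared
cells is merged, and clone ids are deterministic (smallest member cell id).
The coupling statistic for cluster pair (i, j) counts **multicellular clones**
with at least one cell in each (the diagonal counts clones with ≥ 2 cells in
the cluster). The permutation null shuffles the cell→cluster labels of all
barcoded cells, preserving cluster sizes and clone membership — the clone-size
and cluster-size marginals of the data. z = (obs − mean)/SD over ≥ 100
permutations (default 10,000); when the null SD is zero the pair is flagged
and z set to 0. Empirical P values are one-sided per direction with an add-one
pseudocount (they can never be exactly zero) and BH-corrected separately for
the coupled and anticoupled families, mirroring the two one-sided null
hypotheses. On instances small enough to enumerate (≤ 9 barcoded cells) the
Monte-Carlo estimates agree with exhaustive enumeration (p within 0.02, z
within 0.05 at 10,000 permutations); the enumeration routine is kept in the
package as `enumerate_coupling_null` for audits.

The progenitor→progeny test groups nondispersing clones by their postmitotic
tip, computes all pairwise Pearson correlations (over 500 highly variable
genes) between clonal mitotic cells and the group's postmitotic reference, and
the same for size-matched random mitotic draws. The **returned distributions**
are those all-pairs correlations; the **significance test** compares
per-mitotic-cell mean correlations (one value per cell) with a two-sided
rank-sum test. The all-pairs sets share reference cells, so ranking them
directly is anticonservative; collapsing to per-cell means restores a unit
that is exchangeable under the null (verified by simulation).

## Dynamic-gene screen

Per stage and per branch (a branch is the root-to-tip path, so trunk cells
participate in every branch's run): cells are binned into `n_bins = 10`
equal-width pseudotime sections ("sections" reads as width, not occupancy;
quantile bins are available); per bin and gene, the expression change is the
log2 ratio of in-bin to out-bin mean `expm1(normalized)` and the abundance
change the in-minus-out difference of expressed fractions (scaled > 0.5). A
normal distribution is ML-fitted to each change's across-gene values, and a
gene is selected when **both** changes exceed their mean + k·SD (k = 2; the
conjunctive reading of "high expression and high gene abundance" — a
disjunctive mode is available). Branch sets are unions over bins; a stage
keeps genes present in ≥ 2 of 5 branches; the final set is the union across
stages. Bins with < 3 cells are flagged and skipped; branches with fewer cells
than bins are excluded from the ≥2-of-5 denominator with a warning.

**Calibration.** The mean + k·SD rule is scale-free: whatever the noise level,
roughly the upper tail of the across-gene change distribution is selected, so
a null dataset (no dynamic genes) still yields a nonzero per-bin selection
rate (~0.1–0.6% per gene after the conjunction, measured on the generator at
2,000 genes × 6,000 cells). Because trunk bins contain the same cells in every
branch's run, their selections recur across branches and survive the
≥2-branches filter; the final set on null data therefore stabilizes at a
small but nonzero size (≈ 10 genes of 2,000, i.e. a per-gene false-positive
rate of ~0.5%, well below a nominal 5% α but not zero). Sensitivity for
planted bump/sigmoid programs with peak amplitude 2× baseline in ≥ 3 of 5
branches is ≥ 0.9 with false-discovery proportion ≤ 0.2 at that problem size;
both are recomputed by `scripts/acceptance.py`. Users should treat the final
set as high-precision-not-perfect and filter by effect size where purity
matters.

## Maturation and perturbation statistics

* Cohort pseudotime shift: two-sided rank-sum (exact for tiny groups via
  scipy's method selection), optional equal-size subsampling (n = 2,000
  mirrors the figure convention); medians and direction reported.
* Weighted maturation score: `Σ_c p_c · s_c`. The cluster summary `s_c` is the
  **median** per-cluster pseudotime by default with the mean as an option (the
  two summaries differ and both are legitimate; the median is the default
  because it is robust to the skewed within-cluster pseudotime distributions
  the generator produces). Proportions must sum to 1 within 1e-6.
* Condition assignment from guides: perturbed ⇔ ≥ 1 perturbed-class guide and
  no control-class guide; control conversely; cells carrying both classes, or
  none, are excluded.
* Proportion change: within-condition cluster **fractions** (invariant to
  condition capture depth; raw counts behind a flag), per replicate:
  `log10(f_pert + pc) − log10(f_ctrl + pc)` with default pseudocount
  `1/(2·min(n_pert, n_ctrl))`, then mean ± SD across replicates. Swapping
  condition labels negates every ratio exactly. Note the closure effect:
  depleting one population necessarily inflates the fractions of the others
  (by −log10(1 − removed share)), which is a property of compositional data,
  not an artifact.
* Per-state pseudotime comparisons are uncorrected across states by default
  (localized effects are read per state); a correction flag exists.
* DE counts per cluster run the rank-sum test within each cluster between
  conditions and count genes with adjusted p < 0.01.

## Peak-set utilities

Interval overlap uses interval trees with an any-overlap ≥ 1 bp rule
(configurable); classification of two stage peak sets is symmetric and
partitions each input exactly. Summit windows are [summit − 500, summit + 500)
with the interval midpoint substituting a missing summit and truncation at
position 0 flagged; the signal is the mean per-base coverage scaled as
`rpkm = mean_cov · 1e9 / library_size` (coverage values are read counts per
base). FRiP is the fraction of fragments overlapping ≥ 1 bp of any peak. All
three agree exactly with quadratic all-pairs oracles in the test suite.

## Synthetic data: what it emulates and what it does not

The generator plants: a five-tip bifurcating topology (2 IN-like + 3 PN-like
tips) over pseudotime [0, 1] with a mitotic cutoff at 0.35 and deterministic
cluster labels (AP/BP split of the trunk, tip × tertile past it); cohorts with
truncated-normal or uniform pseudotime and planted location shifts;
negative-binomial counts, NB(μ, θ) with var = μ + μ²/θ, log-normal library
sizes (log-SD 0.35), and a heterogeneous panel (log-normal baselines across
~2 orders of magnitude, θ ∈ [0.5, 3], 15% single-tip markers with fold 2–6,
10% stage-boosted genes, configurable dynamic genes — bump or sigmoid,
amplitude 2× baseline; branch-restricted programs are postmitotic by
construction since trunk cells belong to no specific branch); disjoint
multicellular clones with controllable dispersion probability, optional
fate-restricted tip sets, optional mitotic members and optional progenitor
priming (weak pre-expression of the progeny tip's markers); perturbation
replicates with per-cluster survival factors, AP pseudotime shifts and
dual-guide cells; bulk mixtures of cluster pseudobulks with multiplicative
noise; and peak/fragment/coverage sets with planted overlap and FRiP. A
master seed expands to per-stage child seeds via sha256(seed:stage) mod 2³¹,
and every routine regenerates bit-identically from its seed.

Deliberately **not** emulated: gene–gene correlation beyond the planted
programs, ambient RNA, doublets, batch effects, cell-cycle structure,
chromatin fragments with motif content, or spatial effects. Passing recovery
tests on this generator shows the statistics are implemented correctly and
calibrated under their stated assumptions; it does not show robustness to the
real-data nuisances listed above, which upstream preprocessing is assumed to
have handled.

## Problem sizes

Recovery experiments run at: coupling oracle, 20 instances of ≤ 8 barcoded
cells at 10,000 permutations; dispersion grid, 500 clones per probability;
dynamic screen, one stage of 6,000 cells × 2,000 genes with near-uniform
pseudotime occupancy (the cross-stage union is exercised separately by unit
tests and the pipeline); maturation ordering, 100 replicate pairs at
composition bias ±0.6 and Dirichlet concentration 50; proportion change,
40,000 cells in 4 replicates (≈ 5,000 cells per condition and replicate) with
one branch population halved; rank-sum calibration, 2,000 genes × 200 cells.
The default pipeline configuration (4,000 cells, 600 genes) is a desk-scale
setting of the same machinery.

## Known limitations

* The screen's mean + 2·SD rule cannot produce an exactly empty selection on
  null data (see Calibration above); its false positives concentrate in
  trunk bins shared across branches.
* The rank-sum normal approximation degrades below ~6 cells per group with
  heavy ties.
* Empirical coupling P values are bounded below by 1/(1 + N_perm); strongly
  significant pairs need permutation counts to match.
* The weighted maturation score inherits any bias in the upstream proportion
  estimates; it is a linear functional of them.
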