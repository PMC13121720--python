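# Methods

## Model and procedure

`qnetcoloc` measures the convergence of two gene sets on a shared
neighborhood of an undirected interaction network. The pipeline is:

1. **Seeding.** Binary mode assigns initial heat 1 to every in-network
   member of a gene set; quantitative mode assigns −log₁₀(p) to genes with
   association p < θ and normalizes the vector to sum to 1, so that the most
   confident associations carry the most heat. Sets with fewer than three
   in-network genes are refused (study-inclusion floor). p-values at or
   below 1e−300 are floored before the log so weights stay finite while
   preserving order.
2. **Propagation.** Random walk with restart in closed form,
   F = (I − αW)⁻¹(1 − α)Y₀, with W the column-normalized adjacency and
   α ∈ (0,1) the dissipation constant (default 0.5). Column stochasticity
   makes the walk conserve total heat (ΣF = ΣY₀), which the test suite
   asserts to 1e−9. The kernel (1 − α)(I − αW)⁻¹ is computed densely once
   per network and cached, so each additional propagation is one
   matrix–vector product; a fixed-point iteration is kept alongside as an
   independent oracle (agreement < 1e−8 enforced in tests). The network is
   restricted to its largest connected component by default, since an
   isolated node has a zero column in W and would leak heat.
3. **Degree-matched standardization.** Genes are sorted by (degree,
   identifier) and grouped greedily into bins of at least β = 20 genes
   (an undersized trailing bin merges into its predecessor; the identifier
   tie-break makes binning deterministic). The per-gene null is built from
   n_null randomized seedings — binary: each seed gene replaced by a random
   same-bin gene, without replacement within a replicate; quantitative: the
   full weight vector permuted within each bin (preserving the degree–score
   correlation and the per-bin weight multiset) and renormalized. The
   network proximity score is the Z of log observed heat against the log
   null heats (natural log — any base cancels in a Z-score — and sample
   n−1 standard deviation; both fixed for determinism). Genes with
   numerically zero null variance, possible only on degenerate toy graphs,
   score 0 rather than ±∞. Default n_null = 1000, exposed prominently
   because it is a convention, not a derived value.
4. **Trait network and COLOC.** G_trait collects genes with NPS_C > τ,
   NPS_R > τ and NPS_C·NPS_R > τ* (strict inequalities; defaults τ = 1,
   τ* = 3, with τ* ≥ τ enforced). The null permutes NPS_C labels n_perm
   times (default 1000): genes shared by both input sets are shuffled as
   their own stratum — their scores run higher by construction — and all
   other genes as a second stratum; the permutation is realized as two
   independent within-stratum shuffles. COLOC score = observed size /
   mean permuted size; significance is a Z-test of the observed size
   against the permuted sizes, one-sided upper tail by default (convergence
   is directional; a flag selects two-sided). Permuted size distributions
   are close to normal for non-trivial traits (QQ correlation > 0.95
   asserted in tests). Batch runs are corrected with Benjamini–Hochberg,
   and the best study combination per trait is the one with the highest
   COLOC score.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.5 | restart/dissipation constant of the walk |
| β | 20 | minimum genes per degree bin |
| τ, τ* | 1, 3 | individual and combined NPS thresholds |
| θ_common, θ_rare | 1e−5, 1e−4 | association p-value thresholds (Q-mode) |
| n_null | 1000 | NPS null ensemble size |
| n_perm | 1000 | NPS_C label permutations |
| background | 19,000 | gene universe for the hypergeometric overlap test |

## Synthetic data: what it emulates, what it does not

The generator produces (i) a preferential-attachment backbone — chosen so
the degree distribution is heavy-tailed and degree binning is actually
exercised — with planted disjoint modules whose internal edge density is
raised to a target (default 60 genes at 0.25–0.3, standing in for
trait-relevant pathways); (ii) study pairs whose signal genes are drawn
from a module with −log₁₀p = −log₁₀θ + Exp(1) (a GWAS-like right-skewed
tail) and whose noise genes are degree-matched to module genes with p just
below θ, so that every emitted gene passes its threshold and degree alone
cannot separate related from unrelated pairs; (iii) unrelated control
pairs drawing signal from two disjoint modules.

Default study scale: 4000-node networks with mean degree 20 and 30-gene
(or 75-gene partitioned) sets. Real interactomes are an order of magnitude
larger and denser (~19k genes, mean degree in the hundreds), and the seed
footprint matters: on much smaller graphs the hot zones of the two NPS
fields compete for the same limited neighborhoods, which biases the COLOC
score of *independent* random pairs below 1 (we measured ≈0.88 at 2000
nodes vs ≈1.0 at 4000 nodes with identical code). The 4000-node default is
the smallest scale at which the permutation null is calibrated the way it
is on a full-size interactome; calibration results on synthetic data
therefore support, but do not replace, calibration on a real network.
Other real-data features deliberately not emulated: edge noise and
ascertainment bias of interactomes, linkage disequilibrium between
associated genes, and gene-length confounding of burden tests.

Unrelated-module control pairs are genuinely *anti*-convergent here
(COLOC well below 1): a gene's proximity to one module's seeds trades off
against proximity to the other's. They are used for the AUROC benchmark.
Calibration claims (mean COLOC ≈ 1, uniform p) are checked on pairs with
no planted relationship — degree-matched random sets, equivalently the
100%-dilution condition.

## Numerical choices

- Dense LU solve for the kernel (float64); exactness is guarded by the
  iterative oracle rather than by tolerance tuning.
- Degree-bin ties split deterministically by identifier; bins are
  contiguous in the degree ordering.
- Edge canonicalization (min, max) and a sorted edge-list writer make
  network outputs diffable; degree-preserving randomization counts
  *attempted* swaps (n_swap_multiplier × |E|) and measures the achieved
  dilution 1 − J afterwards, stepping the budget by (target − achieved)/4
  since k successful swaps move the Jaccard dilution by ≈ 4k/|E|.
- Gene-set dilution replaces ⌊fn⌉ genes (ties away from zero) with
  same-bin genes, transfers the replaced gene's p-value, excludes both
  current members and all original genes from the replacement pool (so
  fraction 1 retains nothing), and widens to adjacent bins on exhaustion.
- COLOC with a zero-mean null reports NaN score with p = 1 and a warning;
  a zero-variance null maps to z = 0 (observed at mean) or ±∞.
- Seeds for every stochastic stage derive from the run seed plus a CRC of
  the gene-set content, so NPS vectors cached across study combinations
  are bit-identical to cold runs.

## Feature regression

Per study pair: population sizes N_C/N_R, gene counts g_C/g_R, Jaccard
J_CR, induced-subnetwork densities ρ_C/ρ_R, binary-label assortativity
A_CR averaged over the two labelings ({common} vs {rare-only} and {rare}
vs {common-only}; computed once when the sets are disjoint, 0 with a
warning when the induced subgraph has no edges), and per gene property the
weighted mean μ_CR = (g_Cμ_C + g_Rμ_R)/(g_C + g_R) and normalized
difference δ = 2(μ_R − μ_C)/(μ_R + μ_C) ∈ [−2, 2]. Property tables are
caller-supplied. Transforms: Gaussian quantile transform (quantiles =
sample size) for population sizes, A_CR, property means (except
μ_nTissues) and all δ; Yeo–Johnson power transform for counts, densities,
J_CR and μ_nTissues; one-hot flags pass through; everything is then
standardized (flags included — unconventional but kept for comparability
of coefficients).

The elastic net is selected by 5-fold CV (shuffled folds, fixed seed) over
20 log-spaced penalties in [1e−5, 10] and l1 ratios
{0.1, 0.25, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1}, minimizing
out-of-fold MSE, then refit on all rows. Coefficient uncertainty comes
from bootstrap resampling (default 2000 replicates) with percentile 95%
CIs and empirical sign-based p-values
p = 2·min((r₊+1)/(B+1), (r₋+1)/(B+1)), capped at 1 (the formula can
exceed 1 for balanced signs), Bonferroni-corrected over features.

Two caveats, verified empirically and reflected in the tests: (1) the
percentile CI covers the *penalized* population coefficient, so coverage
of a generative β is only meaningful at a negligible penalty (the grid
minimum) — at CV-scale penalties the shrinkage bias of large coefficients
exceeds their standard error and coverage of β degrades by design;
(2) the sign-based p-value is anti-conservative under lasso-dominant
penalties, because exact zeros deplete both sign counts (a feature zeroed
in every replicate gets p = 2/(B+1)); at the ridge-dominant configuration
the CV selects in practice (l1 ratio 0.1) it is calibrated.

## Problem sizes used by the test suite and acceptance script

Closed-vs-iterative and conservation checks: 20 random graphs of ≤ 200
nodes. NPS self-calibration: 500-node network, 20 repetitions, n_null =
200. Calibration, recovery, AUROC and gene-set dilution: one 4000-node
network (mean degree 20, three 60-gene modules at density 0.3), 20 planted
pairs, 20 unrelated-module controls, 30–40 random pairs, 20 partitioned
pairs per seeding mode at 100% dilution, n_null = 200 and n_perm = 500
throughout. Network dilution: a 2000-node network rewired to measured
dilutions ≈ {0.3, 0.6, 0.9}. Regression: n = 1000 rows, 10 features,
3 nonzero coefficients, noise sd 0.5, 200–500 bootstrap replicates.

## Known limitations

- Dense kernels scale as O(n²) memory and O(n³) setup; beyond ~2×10⁴
  nodes an iterative solver per seed batch would be preferable.
- The Z-test for colocalization leans on approximate normality of permuted
  sizes; tiny trait networks (observed size < ~10) make the COLOC ratio
  noisy and its p-value lumpy.
- The sign-based bootstrap p-values are not valid under strong
  sparsity (see above); CIs are percentile, not bias-corrected.
- Control pairs built from planted disjoint modules are more strongly
  anti-convergent than typical real unrelated studies, which makes the
  synthetic AUROC benchmark easier than the real one.
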