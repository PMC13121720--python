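# qnetcoloc

Quantitative network colocalization of two weighted gene sets on a
molecular-interaction network.

Complex traits are shaped both by common variants found in GWAS and by rare
variants found in gene-based burden tests, yet the two study designs often
implicate almost disjoint gene sets. `qnetcoloc` asks whether the two sets
nevertheless converge on the same *network neighborhood* of an interactome:
it propagates each set over the network with a random walk with restart,
scores every gene's proximity to each set against a degree-matched null,
extracts the subnetwork of genes proximal to both sets, and tests whether
that subnetwork is larger than expected by chance. The package is aimed at
statistical geneticists and network biologists who have, per trait, a set of
common-variant-associated genes (CVGs), a set of rare-variant-associated
genes (RVGs), and an undirected interactome edge list.

## Method

Each gene set is encoded as an initial heat vector **Y₀** — binary
membership (B-mode) or association weights −log₁₀(p) for genes with
p < θ, normalized to sum to 1 (Q-mode) — and diffused in closed form:

```
F = (I − αW)⁻¹ (1 − α) Y₀
```

where **W** is the column-normalized adjacency matrix and α = 0.5 the
dissipation constant. Because heat at a gene depends strongly on degree,
the observed heat is standardized per gene against a null ensemble built by
degree-matched randomization (random same-bin gene sets in B-mode; within-bin
score shuffles in Q-mode, bins of ≥ β = 20 genes):

```
NPS_g,S = ( log F_g,S − ⟨log F_g,rand⟩ ) / σ(log F_g,rand)
```

With NPS_C and NPS_R computed for the common and rare sets, the combined
score is the product NPS_CR = NPS_C × NPS_R, and the trait-specific network
is

```
G_trait = { g : NPS_C > τ,  NPS_R > τ,  NPS_CR > τ* },   τ = 1, τ* = 3.
```

Significance comes from permuting the NPS_C labels (1000×, genes shared by
both input sets permuted as their own stratum) and a Z-test of the observed
|G_trait| against the permuted sizes; the **COLOC score** is observed size
over expected size — 1 means no convergence beyond chance.

Around the core method the package provides the evaluation machinery:
partitioned test/control pairs with AUROC, gene-set dilution (replacing a
fraction of genes with degree-matched random genes) and degree-preserving
network rewiring for calibration, a hypergeometric shared-gene test
(background 19,000), cosine similarity of trait networks, per-pair gene-set
features (Jaccard, subnetwork densities, assortativity, weighted property
means μ_CR and normalized differences δ), and an elastic-net bootstrap
regression of COLOC scores on those features with sign-based empirical
p-values. A synthetic-data module generates degree-heterogeneous networks
with planted modules and paired gene-score sets so everything is testable
without downloads.

## Worked example

```python
import qnetcoloc as q

# synthetic interactome with one planted 60-gene module
net, modules = q.generate_network(
    2000, attachment_edges=10,
    module_specs=[q.ModuleSpec("pathway", 60, 0.3)], rng_seed=7,
)
# two studies whose signal genes are drawn from the shared module
common, rare = q.generate_study_pair(net, modules["pathway"],
                                     size_a=30, size_b=30,
                                     signal_fraction=0.7, rng_seed=100)
run = q.colocalize(net, common, rare,
                   params=q.ColocParams(n_null=200, n_perm=500), rng_seed=200)
r = run.result
print(f"observed={r.observed_size} expected={r.expected_size:.1f} "
      f"COLOC={r.coloc_score:.2f} z={r.z:.1f} p={r.p:.2e}")
print(f"prioritized common genes: {len(run.prioritized.common)}/30")
```

Output:

```
observed=35 expected=20.3 COLOC=1.72 z=4.9 p=6.13e-07
prioritized common genes: 13/30
```

The trait network holds 35 genes against an expected 20.3 under label
permutation (COLOC = 1.72, p ≈ 6e−7): the two gene sets converge well
beyond chance, as they should when 70% of each set is drawn from the same
planted module. 13 of the 30 common-set genes are carried into the trait
network (prioritized).

The same pipeline is exposed as a CLI for file-based runs:

```
qnetcoloc simulate --n-nodes 2000 --module pathway:60:0.3 \
    --study pathway:30:30:0.7 --seed 7 --outdir demo/
qnetcoloc coloc --network demo/network.tsv --common demo/study0.common.tsv \
    --rare demo/study0.rare.tsv --outdir demo/out --seed 1
```

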