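"""Network proximity scores: degree-matched null ensembles and per-gene Z-scores.

The propagated heat at a gene depends strongly on the gene's degree and on
the degrees of the seeds. To correct for this, the observed heat at every
gene is compared against a null ensemble built from degree-matched random
seedings:

* binary mode — each replicate replaces every seed gene with a uniformly
  random gene drawn from the same degree bin (without replacement within a
  replicate);
* quantitative mode — each replicate permutes the full per-gene weight
  vector (zeros included) within each degree bin, preserving the
  degree–score correlation, then renormalizes to sum one.

The network proximity score of gene g for seed set S is the Z-score

    NPS_{g,S} = (log F_{g,S} − ⟨log F_{g,rand}⟩) / σ(log F_{g,rand}),

using the natural log (any base cancels in a Z-score) and the sample (n−1)
standard deviation. Scores from the common and rare seedings combine as the
elementwise product NPS_CR = NPS_C × NPS_R; genes scoring high on both are
the shared network neighborhood of the two gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import DegreeBins, Network
from .propagation import HeatVector, SeedVector, propagate_matrix

__all__ = [
    "NullHeatEnsemble",
    "NPSVector",
    "CombinedNPS",
    "null_ensemble_binary",
    "null_ensemble_quantitative",
    "compute_nps",
    "combine_nps",
    "write_nps_table",
]

#: Default number of null replicates for the NPS ensemble.
DEFAULT_N_NULL = 1000


@dataclass(frozen=True)
class NullHeatEnsemble:
    """Per-gene null heats from randomized seedings.

    ``heats`` has shape (n_genes, n_null), rows aligned to ``genes``.
    """

    genes: tuple[str, ...]
    heats: np.ndarray
    n_null: int
    mode: str

    def __post_init__(self):
        if self.heats.shape != (len(self.genes), self.n_null):
            raise ValueError("ensemble heats shape mismatch")


@dataclass(frozen=True)
class NPSVector:
    """Per-gene network proximity score (Z of log heat vs the null)."""

    score: pd.Series
    source_label: str | None = None


@dataclass(frozen=True)
class CombinedNPS:
    """Elementwise product of the common- and rare-seeding NPS vectors."""

    score: pd.Series


def _permutation_block(rng: np.random.Generator, n_rep: int, size: int) -> np.ndarray:
    """(n_rep, size) array of independent permutations of range(size)."""
    return np.argsort(rng.random((n_rep, size)), axis=1)


# ---------------------------------------------------------------------------
# Null ensembles
# ---------------------------------------------------------------------------


def null_ensemble_binary(
    net: Network,
    seed_genes,
    bins: DegreeBins,
    n_null: int = DEFAULT_N_NULL,
    alpha: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
) -> NullHeatEnsemble:
    """Degree-matched random gene sets of equal size, propagated.

    For every replicate, each seed gene is replaced by a random gene from its
    own degree bin; draws within one bin and replicate are without
    replacement. If a bin holds fewer genes than seeds mapped to it, draws
    fall back to sampling with replacement (with a warning) — only possible
    on tiny graphs given the minimum bin size.
    """
    rng = np.random.default_rng(rng_seed)
    seed_genes = sorted(set(map(str, seed_genes)))
    missing = [g for g in seed_genes if g not in net.node_index]
    if missing:
        raise ValueError(f"seed genes not in network: {missing[:10]}")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    n = net.n_nodes
    Y = np.zeros((n, n_null))
    # group seeds by bin; sample per bin for all replicates at once
    by_bin: dict[int, int] = {}
    for g in seed_genes:
        b = bins.bin_of[g]
        by_bin[b] = by_bin.get(b, 0) + 1
    for b, k in sorted(by_bin.items()):
        members = np.array([net.node_index[g] for g in bins.bins[b]])
        s = len(members)
        if k > s:
            warnings.warn(
                f"degree bin {b} holds {s} gene(s) but {k} seed(s); "
                "sampling with replacement"
            )
            picks = members[rng.integers(0, s, size=(n_null, k))]
        else:
            picks = members[_permutation_block(rng, n_null, s)[:, :k]]
        for r in range(n_null):
            Y[picks[r], r] = 1.0
    F = propagate_matrix(net, Y, alpha)
    return NullHeatEnsemble(genes=net.nodes, heats=F, n_null=n_null, mode="binary")


def null_ensemble_quantitative(
    net: Network,
    seed: SeedVector,
    bins: DegreeBins,
    n_null: int = DEFAULT_N_NULL,
    alpha: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
) -> NullHeatEnsemble:
    """Within-bin score shuffles preserving the degree–score correlation.

    Each replicate permutes the full weight vector (zeros included) within
    every degree bin — the multiset of weights per bin is preserved exactly —
    renormalizes columns to sum one, and propagates.
    """
    if seed.mode != "quantitative":
        raise ValueError("quantitative null requires a quantitative seed")
    rng = np.random.default_rng(rng_seed)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    w = seed.values()
    n = net.n_nodes
    Y = np.empty((n, n_null))
    for b, bin_genes in enumerate(bins.bins):
        idx = np.array([net.node_index[g] for g in bin_genes])
        vals = w[idx]
        perms = _permutation_block(rng, n_null, len(idx))
        Y[idx, :] = vals[perms].T
    totals = Y.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("null seed columns must have positive total weight")
    Y /= totals
    F = propagate_matrix(net, Y, alpha)
    return NullHeatEnsemble(
        genes=net.nodes, heats=F, n_null=n_null, mode="quantitative"
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def compute_nps(
    observed: HeatVector,
    ensemble: NullHeatEnsemble,
    source_label: str | None = None,
) -> NPSVector:
    """Per-gene Z-score of log observed heat against the log null heats.

    Natural log; sample (n−1) standard deviation. A gene whose null heats
    have numerically zero variance (possible only on degenerate toy graphs)
    scores 0 rather than ±∞, with a warning.
    """
    if tuple(observed.heat.index) != ensemble.genes:
        raise ValueError("observed heat and ensemble cover different gene universes")
    f = observed.values()
    if (f <= 0).any() or (ensemble.heats <= 0).any():
        raise ValueError("all heats must be positive to take logs")
    logs = np.log(ensemble.heats)
    mu = logs.mean(axis=1)
    sd = logs.std(axis=1, ddof=1) if ensemble.n_null > 1 else np.zeros_like(mu)
    z = np.zeros_like(mu)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} gene(s) have zero null variance; NPS set to 0"
        )
    z[ok] = (np.log(f[ok]) - mu[ok]) / sd[ok]
    return NPSVector(
        score=pd.Series(z, index=list(ensemble.genes)), source_label=source_label
    )


def combine_nps(nps_c: NPSVector, nps_r: NPSVector) -> CombinedNPS:
    """NPS_CR = NPS_C × NPS_R, elementwise over the shared gene universe."""
    if not nps_c.score.index.equals(nps_r.score.index):
        raise ValueError("NPS vectors cover different gene universes")
    return CombinedNPS(score=nps_c.score * nps_r.score)


def write_nps_table(
    path, nps_c: NPSVector, nps_r: NPSVector, combined: CombinedNPS | None = None
) -> None:
    """Write a per-gene score table: gene, nps_common, nps_rare, nps_combined."""
    if combined is None:
        combined = combine_nps(nps_c, nps_r)
    df = pd.DataFrame(
        {
            "gene": nps_c.score.index,
            "nps_common": nps_c.score.to_numpy(),
            "nps_rare": nps_r.score.to_numpy(),
            "nps_combined": combined.score.to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)
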