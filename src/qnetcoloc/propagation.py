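"""Seed-vector construction and random walk with restart (RWR) propagation.

Association evidence enters the model as an initial heat vector Y₀ over the
network genes: either binary membership (1 for every gene in the input set)
or quantitative weights −log10(p) for genes passing the association p-value
threshold θ, normalized to sum to one. Heat then diffuses by a random walk
with restart and the stable heat is obtained in closed form,

    F = (I − αW)⁻¹ (1 − α) Y₀,

with W the column-normalized adjacency and α ∈ (0,1) the dissipation
constant (default 0.5). Because W is column-stochastic the walk conserves
total heat: ΣF = ΣY₀.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import Network, column_normalized_adjacency

__all__ = [
    "SeedVector",
    "HeatVector",
    "build_binary_seed",
    "build_quantitative_seed",
    "propagate",
    "propagate_matrix",
    "propagate_iterative",
    "read_gene_scores",
    "read_gmt",
]

#: p-values at or below this are floored before −log10 to avoid infinite
#: weights while preserving the ordering of everything else.
P_VALUE_FLOOR = 1e-300

#: Study-inclusion floor: a gene set must leave at least this many genes in
#: the network to be propagated.
MIN_SEED_GENES = 3


@dataclass(frozen=True)
class SeedVector:
    """Initial heat Y₀ aligned to the network node order.

    ``heat`` is indexed by every network gene (zeros for non-members);
    ``dropped`` lists input genes absent from the network.
    """

    heat: pd.Series
    mode: str  # "binary" | "quantitative"
    theta: float | None = None
    dropped: tuple[str, ...] = ()

    @property
    def genes(self) -> tuple[str, ...]:
        """Genes carrying non-zero initial heat."""
        return tuple(self.heat.index[self.heat.values > 0])

    def values(self) -> np.ndarray:
        return self.heat.to_numpy(dtype=float)


@dataclass(frozen=True)
class HeatVector:
    """Stable propagated heat F, aligned to the network node order."""

    heat: pd.Series
    alpha: float

    def values(self) -> np.ndarray:
        return self.heat.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Seed construction
# ---------------------------------------------------------------------------


def build_binary_seed(
    genes, net: Network, min_genes: int = MIN_SEED_GENES
) -> SeedVector:
    """Binary seeding: heat 1 for every in-network member of ``genes``.

    Genes absent from the network are dropped (and reported on the returned
    seed); if fewer than ``min_genes`` remain the set is refused, mirroring
    the exclusion of studies with fewer than three distinct gene associations.
    """
    genes = set(map(str, genes))
    members = sorted(genes & set(net.nodes))
    dropped = tuple(sorted(genes - set(members)))
    if len(members) < min_genes:
        raise ValueError(
            f"only {len(members)} input gene(s) are in the network "
            f"(minimum {min_genes}); dropped: {list(dropped)[:10]}"
        )
    heat = pd.Series(0.0, index=list(net.nodes))
    heat.loc[members] = 1.0
    return SeedVector(heat=heat, mode="binary", theta=None, dropped=dropped)


def build_quantitative_seed(
    scores, theta: float, net: Network, min_genes: int = 1
) -> SeedVector:
    """Quantitative seeding: weight −log10(p) for genes with p < θ, sum-normalized.

    ``scores`` maps gene → association p-value (one entry per gene; duplicate
    gene identifiers are an upstream curation problem and are rejected).
    p-values must be positive; values below 1e−300 are floored. Genes failing
    θ or absent from the network get zero weight; if no in-network gene passes
    θ the set is refused.
    """
    if not 0 < theta <= 1:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    s = pd.Series(dict(scores) if not isinstance(scores, pd.Series) else scores)
    s.index = s.index.map(str)
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in scores: {dup[:10]}")
    vals = s.to_numpy(dtype=float)
    if (vals <= 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    vals = np.maximum(vals, P_VALUE_FLOOR)
    passing = s.index[vals < theta]
    in_net = [g for g in passing if g in net.node_index]
    dropped = tuple(sorted(set(passing) - set(in_net)))
    if len(in_net) < max(min_genes, 1):
        raise ValueError(
            f"no gene passes theta={theta} within the network "
            f"({len(passing)} passed theta overall)"
        )
    heat = pd.Series(0.0, index=list(net.nodes))
    weights = -np.log10(np.maximum(s.loc[in_net].to_numpy(dtype=float), P_VALUE_FLOOR))
    heat.loc[in_net] = weights
    total = heat.sum()
    heat = heat / total
    return SeedVector(heat=heat, mode="quantitative", theta=theta, dropped=dropped)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------


def propagate(net: Network, seed: SeedVector, alpha: float = 0.5) -> HeatVector:
    """Closed-form RWR: F = (I − αW)⁻¹(1 − α)Y₀.

    Uses the network's cached dense kernel so repeated propagations (null
    ensembles) cost one matrix–vector product each.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    _check_alignment(net, seed)
    K = net.rwr_kernel(alpha)
    f = K @ seed.values()
    return HeatVector(heat=pd.Series(f, index=list(net.nodes)), alpha=alpha)


def propagate_matrix(net: Network, Y: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Propagate many seed columns at once: returns K @ Y for Y of shape (n, k)."""
    if Y.shape[0] != net.n_nodes:
        raise ValueError("seed matrix rows must match network node count")
    return net.rwr_kernel(alpha) @ Y


def propagate_iterative(
    net: Network,
    seed: SeedVector,
    alpha: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> HeatVector:
    """Fixed-point RWR iteration F ← αWF + (1−α)Y₀ — the independent oracle
    for the closed form (guaranteed to converge for α < 1)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    _check_alignment(net, seed)
    W = column_normalized_adjacency(net)
    y0 = seed.values()
    f = y0.copy()
    base = (1.0 - alpha) * y0
    for _ in range(max_iter):
        f_next = alpha * (W @ f) + base
        if np.max(np.abs(f_next - f)) < tol:
            return HeatVector(heat=pd.Series(f_next, index=list(net.nodes)), alpha=alpha)
        f = f_next
    raise RuntimeError(f"propagation did not converge within {max_iter} iterations")


def _check_alignment(net: Network, seed: SeedVector) -> None:
    if len(seed.heat) != net.n_nodes or tuple(seed.heat.index) != net.nodes:
        raise ValueError("seed vector is not aligned to the network node order")


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------


def read_gene_scores(path, delimiter: str = "\t") -> pd.Series:
    """Read a gene association table with columns ``gene`` and ``p_value``.

    Extra columns are ignored. Returns a Series gene → p-value; duplicate
    genes are rejected (curation keeps one p-value per gene upstream).
    """
    df = pd.read_csv(path, sep=delimiter)
    missing = {"gene", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    s = pd.Series(df["p_value"].to_numpy(dtype=float), index=df["gene"].astype(str))
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers: {dup[:10]}")
    return s


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read unweighted gene sets in GMT format: name, description, genes...."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    "and at least one gene"
                )
            sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    return sets
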