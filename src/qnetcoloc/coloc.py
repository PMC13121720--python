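"""Colocalized trait-specific networks and the COLOC score.

Genes proximal to *both* seed sets form the trait-specific network

    G_trait = { g : NPS_C(g) > τ,  NPS_R(g) > τ,  NPS_C(g)·NPS_R(g) > τ* },

with τ the individual threshold and τ* ≥ τ the stricter combined threshold
(defaults 1 and 3). Whether the two gene sets converge beyond chance is
judged by permuting the NPS_C labels: genes shared between the two input
sets are permuted as their own stratum (their scores are expected to run
higher), all other genes as a second stratum. The COLOC score is the
observed size of G_trait over its expected (mean permuted) size — 1 means
no convergence beyond chance — and significance comes from a Z-test of the
observed size against the permuted null, which is approximately normal.

Also here: the hypergeometric shared-gene overlap test, Benjamini–Hochberg
batch correction, input-gene prioritization, and the cosine similarity of
combined proximity scores between two trait networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nps import CombinedNPS, NPSVector

__all__ = [
    "TraitNetwork",
    "ColocResult",
    "PrioritizedGenes",
    "extract_trait_network",
    "permutation_null_sizes",
    "trait_network_size",
    "coloc_statistics",
    "bh_correct",
    "shared_gene_test",
    "prioritized_genes",
    "trait_similarity",
    "write_coloc_json",
]

DEFAULT_TAU = 1.0
DEFAULT_TAU_STAR = 3.0
DEFAULT_N_PERM = 1000
#: Approximate number of human protein-coding genes, the default background
#: universe for the shared-gene overlap test.
DEFAULT_BACKGROUND = 19_000


@dataclass(frozen=True)
class TraitNetwork:
    """Genes passing both individual thresholds and the combined threshold."""

    members: frozenset[str]
    tau: float
    tau_star: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ColocResult:
    """Observed vs permuted trait-network size and derived statistics.

    ``coloc_score`` is observed/expected size; ``z`` and ``p`` come from a
    one-sided (upper-tail) Z-test of the observed size against the permuted
    null; ``q`` is filled in by batch-level BH correction.
    """

    observed_size: int
    null_sizes: np.ndarray
    coloc_score: float
    z: float
    p: float
    q: float | None = None

    @property
    def expected_size(self) -> float:
        return float(np.mean(self.null_sizes))


@dataclass(frozen=True)
class PrioritizedGenes:
    """Input genes carried into the trait-specific network."""

    common: frozenset[str]
    rare: frozenset[str]
    common_disjoint: frozenset[str]
    rare_disjoint: frozenset[str]


# ---------------------------------------------------------------------------
# Trait network extraction
# ---------------------------------------------------------------------------


def _aligned_scores(nps_c: NPSVector, nps_r: NPSVector) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    if not nps_c.score.index.equals(nps_r.score.index):
        raise ValueError("NPS vectors cover different gene universes")
    return nps_c.score.index, nps_c.score.to_numpy(), nps_r.score.to_numpy()


def _size_given(c: np.ndarray, r: np.ndarray, tau: float, tau_star: float) -> np.ndarray:
    """Trait-network membership mask for score arrays (strict inequalities)."""
    return (c > tau) & (r > tau) & (c * r > tau_star)


def extract_trait_network(
    nps_c: NPSVector,
    nps_r: NPSVector,
    tau: float = DEFAULT_TAU,
    tau_star: float = DEFAULT_TAU_STAR,
) -> TraitNetwork:
    """Extract G_trait with strict thresholds NPS_C > τ, NPS_R > τ, NPS_CR > τ*."""
    if tau_star < tau:
        raise ValueError(f"tau_star ({tau_star}) must be >= tau ({tau})")
    genes, c, r = _aligned_scores(nps_c, nps_r)
    mask = _size_given(c, r, tau, tau_star)
    return TraitNetwork(
        members=frozenset(genes[mask]), tau=float(tau), tau_star=float(tau_star)
    )


def trait_network_size(
    nps_c: NPSVector, nps_r: NPSVector, tau: float, tau_star: float
) -> int:
    """Size of G_trait without materializing the member set."""
    _, c, r = _aligned_scores(nps_c, nps_r)
    return int(_size_given(c, r, tau, tau_star).sum())


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def permutation_null_sizes(
    nps_c: NPSVector,
    nps_r: NPSVector,
    shared_genes,
    tau: float = DEFAULT_TAU,
    tau_star: float = DEFAULT_TAU_STAR,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null trait-network sizes from stratified label permutation of NPS_C.

    Genes shared between the common and rare input sets are shuffled among
    themselves, all other genes among themselves (two independent
    within-stratum shuffles), keeping the higher expected score distribution
    of shared genes intact. NPS_R stays fixed. Returns one trait-network size
    per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes, c, r = _aligned_scores(nps_c, nps_r)
    shared_genes = set(map(str, shared_genes))
    unknown = shared_genes - set(genes)
    if unknown:
        raise ValueError(f"shared genes outside the gene universe: {sorted(unknown)[:10]}")
    rng = np.random.default_rng(rng_seed)
    shared_mask = np.asarray(genes.isin(shared_genes))
    perm_c = np.tile(c, (n_perm, 1))
    for mask in (shared_mask, ~shared_mask):
        idx = np.flatnonzero(mask)
        if idx.size > 1:
            order = np.argsort(rng.random((n_perm, idx.size)), axis=1)
            perm_c[:, idx] = perm_c[:, idx][np.arange(n_perm)[:, None], order]
    sizes = _size_given(perm_c, r[None, :], tau, tau_star).sum(axis=1)
    return sizes.astype(int)


def coloc_statistics(
    observed_size: int,
    null_sizes,
    alternative: str = "greater",
) -> ColocResult:
    """COLOC score (observed/expected size) and Z-test significance.

    The test is one-sided upper tail by default (convergence means a larger
    than expected network); ``alternative="two-sided"`` is available.
    """
    null_sizes = np.asarray(null_sizes, dtype=float)
    if null_sizes.size == 0:
        raise ValueError("null_sizes must be non-empty")
    mean = float(null_sizes.mean())
    sd = float(null_sizes.std(ddof=1)) if null_sizes.size > 1 else 0.0
    if mean == 0:
        warnings.warn("expected trait-network size is 0; COLOC score undefined")
        return ColocResult(
            observed_size=int(observed_size),
            null_sizes=null_sizes.astype(int),
            coloc_score=float("nan"),
            z=float("nan"),
            p=1.0,
        )
    score = observed_size / mean
    if sd > 0:
        z = (observed_size - mean) / sd
    else:
        z = 0.0 if observed_size == mean else float(np.sign(observed_size - mean)) * np.inf
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return ColocResult(
        observed_size=int(observed_size),
        null_sizes=null_sizes.astype(int),
        coloc_score=float(score),
        z=float(z),
        p=p,
    )


# ---------------------------------------------------------------------------
# Supporting statistics
# ---------------------------------------------------------------------------


def bh_correct(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def shared_gene_test(
    n_common: int,
    n_rare: int,
    n_overlap: int,
    background: int = DEFAULT_BACKGROUND,
) -> float:
    """Upper-tail hypergeometric P(X ≥ n_overlap) for the gene-set overlap.

    ``background`` defaults to 19,000, approximating the number of human
    protein-coding genes.
    """
    if not (0 <= n_overlap <= min(n_common, n_rare) <= max(n_common, n_rare) <= background):
        raise ValueError(
            "inconsistent counts: need 0 <= overlap <= min(sets) <= background"
        )
    # X ~ Hypergeom(M=background, n=n_common, N=n_rare)
    return float(stats.hypergeom.sf(n_overlap - 1, background, n_common, n_rare))


def prioritized_genes(cvgs, rvgs, trait_net: TraitNetwork) -> PrioritizedGenes:
    """Input genes meeting the trait-network inclusion criteria.

    Returns both the plain intersections with the trait network and the
    disjoint-only variants (input genes not shared between the two sets).
    """
    cvgs = frozenset(map(str, cvgs))
    rvgs = frozenset(map(str, rvgs))
    members = trait_net.members
    return PrioritizedGenes(
        common=cvgs & members,
        rare=rvgs & members,
        common_disjoint=(cvgs - rvgs) & members,
        rare_disjoint=(rvgs - cvgs) & members,
    )


def trait_similarity(
    nps_cr_1: CombinedNPS,
    members_1,
    nps_cr_2: CombinedNPS,
    members_2,
) -> float:
    """Cosine similarity of combined proximity scores over the member union."""
    union = sorted(set(map(str, members_1)) | set(map(str, members_2)))
    if not union:
        raise ValueError("union of trait-network members is empty")
    try:
        v1 = nps_cr_1.score.loc[union].to_numpy(dtype=float)
        v2 = nps_cr_2.score.loc[union].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError("combined NPS must be defined on the member union") from exc
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        warnings.warn("zero-norm NPS vector; cosine similarity set to 0")
        return 0.0
    return float(np.dot(v1, v2) / (n1 * n2))


# ---------------------------------------------------------------------------
# Result writer
# ---------------------------------------------------------------------------


def write_coloc_json(
    path,
    result: ColocResult,
    trait_net: TraitNetwork,
    prioritized: PrioritizedGenes | None = None,
) -> None:
    """Write the colocalization result as JSON (sorted member lists)."""
    payload = {
        "observed_size": result.observed_size,
        "expected_size": result.expected_size,
        "coloc_score": result.coloc_score,
        "z": result.z,
        "p": result.p,
        "q": result.q,
        "tau": trait_net.tau,
        "tau_star": trait_net.tau_star,
        "members": sorted(trait_net.members),
    }
    if prioritized is not None:
        payload["prioritized_common"] = sorted(prioritized.common)
        payload["prioritized_rare"] = sorted(prioritized.rare)
        payload["prioritized_common_disjoint"] = sorted(prioritized.common_disjoint)
        payload["prioritized_rare_disjoint"] = sorted(prioritized.rare_disjoint)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
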