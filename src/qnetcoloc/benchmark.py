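"""Evaluation machinery: partitioned test/control pairs, AUROC, dilution series.

The method is benchmarked without ground-truth labels by partitioning a
study's gene set into two non-overlapping halves: the two halves of one
study form a *test* pair (they should colocalize), halves from studies of
unrelated traits form *control* pairs. AUROC over COLOC scores measures the
separation.

Calibration is probed by dilution: replacing a fraction of a gene set with
degree-matched random genes (each replacement inherits the replaced gene's
p-value) should decay the COLOC score toward the chance value of 1 at 100%
dilution; degree-preserving edge rewiring of the network itself should have
the same effect, showing that the signal lives in the edges rather than the
degree sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .graph import DegreeBins, Network, edge_jaccard_dilution, shuffle_network
from .pipeline import ColocParams, colocalize

__all__ = [
    "LabeledPair",
    "DilutionPoint",
    "partition_gene_set",
    "make_control_pairs",
    "auroc",
    "dilute_gene_set",
    "dilution_curve",
    "calibration_ttest",
    "network_dilution_series",
]

DEFAULT_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class LabeledPair:
    """Two gene-score halves with a test/control label and trait provenance."""

    set_a: dict[str, float]
    set_b: dict[str, float]
    label: str  # "test" | "control"
    trait_a: str = ""
    trait_b: str = ""


@dataclass(frozen=True)
class DilutionPoint:
    """One colocalization outcome at a given dilution fraction and replicate."""

    fraction: float
    replicate: int
    coloc_score: float
    coloc_p: float


# ---------------------------------------------------------------------------
# Partitioned pairs
# ---------------------------------------------------------------------------


def partition_gene_set(
    scores, rng_seed: int | np.random.Generator = 0
) -> tuple[dict[str, float], dict[str, float]]:
    """Uniform random split into two disjoint halves (scores carried along).

    An odd gene count puts the extra gene in the first half. Needs at least
    six genes so each half clears the three-gene inclusion floor.
    """
    scores = dict(scores) if not isinstance(scores, dict) else scores
    genes = sorted(scores)
    if len(genes) < 6:
        raise ValueError(f"need >= 6 genes to partition, got {len(genes)}")
    rng = np.random.default_rng(rng_seed)
    order = [genes[i] for i in rng.permutation(len(genes))]
    cut = (len(order) + 1) // 2  # odd count: extra gene in half_a
    half_a = {g: scores[g] for g in order[:cut]}
    half_b = {g: scores[g] for g in order[cut:]}
    return half_a, half_b


def make_control_pairs(
    partitions: dict[str, tuple[dict, dict]],
    trait_relatedness=(),
    rng_seed: int | np.random.Generator = 0,
    n_pairs: int | None = None,
) -> list[LabeledPair]:
    """Control pairs: one half from trait i matched with one half from trait j ≠ i.

    ``trait_relatedness`` is a blacklist of related trait pairs (any iterable
    of 2-element collections) to exclude. The number of controls defaults to
    the number of test pairs (one per trait); an impossible matching errors.
    """
    traits = sorted(partitions)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits to form control pairs")
    blacklist = {frozenset(map(str, pair)) for pair in trait_relatedness}
    candidates = [
        (i, j)
        for i in traits
        for j in traits
        if i != j and frozenset((i, j)) not in blacklist
    ]
    if n_pairs is None:
        n_pairs = len(traits)
    if len(candidates) < n_pairs:
        raise ValueError(
            f"only {len(candidates)} admissible cross-trait pairings for "
            f"{n_pairs} requested control pairs"
        )
    rng = np.random.default_rng(rng_seed)
    picks = rng.choice(len(candidates), size=n_pairs, replace=False)
    out = []
    for k in picks:
        i, j = candidates[k]
        out.append(
            LabeledPair(
                set_a=dict(partitions[i][0]),
                set_b=dict(partitions[j][1]),
                label="control",
                trait_a=i,
                trait_b=j,
            )
        )
    return out


def auroc(labels, scores) -> float:
    """Probability a random positive outscores a random negative (ties ½)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Gene-set dilution
# ---------------------------------------------------------------------------


def dilute_gene_set(
    scores,
    fraction: float,
    bins: DegreeBins,
    rng_seed: int | np.random.Generator = 0,
):
    """Replace a fraction of genes with degree-matched random genes.

    ``round(fraction × n)`` genes (nearest integer, ties away from zero),
    chosen uniformly, are each replaced by a random gene from the same degree
    bin not already in the set; the replaced gene's association p-value
    transfers to its replacement, and the set size is unchanged. An exhausted
    bin widens to adjacent bins with a warning. Accepts a score mapping (dict
    returned) or a plain gene set (set returned).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    as_set = not isinstance(scores, dict)
    mapping = {g: None for g in scores} if as_set else dict(scores)
    genes = sorted(mapping)
    missing = [g for g in genes if g not in bins.bin_of]
    if missing:
        raise ValueError(f"genes not in the network/bins: {missing[:10]}")
    rng = np.random.default_rng(rng_seed)
    n = len(genes)
    n_replace = int(np.floor(fraction * n + 0.5))  # ties away from zero
    if n_replace == 0:
        return set(mapping) if as_set else mapping
    replace = [genes[i] for i in rng.choice(n, size=n_replace, replace=False)]
    current = set(mapping)
    original = set(genes)  # replaced originals never re-enter
    n_bins = len(bins.bins)
    warned = False
    for g in replace:
        b = bins.bin_of[g]
        pick = None
        for width in range(n_bins + 1):
            lo, hi = max(0, b - width), min(n_bins - 1, b + width)
            pool = [
                x
                for bb in range(lo, hi + 1)
                for x in bins.bins[bb]
                if x not in current and x not in original
            ]
            if pool:
                if width > 0 and not warned:
                    warnings.warn("degree bin exhausted; widening to adjacent bins")
                    warned = True
                pick = pool[rng.integers(0, len(pool))]
                break
        if pick is None:
            raise ValueError("network exhausted during dilution")
        mapping[pick] = mapping.pop(g)
        current.discard(g)
        current.add(pick)
    return set(mapping) if as_set else mapping


def dilution_curve(
    pair: LabeledPair,
    fractions=DEFAULT_FRACTIONS,
    n_reps: int = 3,
    coloc_config: ColocParams = ColocParams(),
    rng_seed: int = 0,
    *,
    net: Network,
    bins: DegreeBins,
    nps_cache: dict | None = None,
) -> list[DilutionPoint]:
    """Full colocalization at every dilution fraction × replicate.

    Both halves of the pair are diluted independently per replicate. Callers
    should pre-filter to pairs with significant baseline colocalization, as
    the decay is only meaningful from a significant start.
    """
    points = []
    for fi, fraction in enumerate(fractions):
        for rep in range(n_reps):
            rng = np.random.default_rng([rng_seed, fi, rep])
            a = dilute_gene_set(pair.set_a, fraction, bins, rng_seed=rng)
            b = dilute_gene_set(pair.set_b, fraction, bins, rng_seed=rng)
            run = colocalize(
                net, a, b, params=coloc_config,
                rng_seed=int(np.random.default_rng([rng_seed, fi, rep, 3]).integers(2**31 - 1)),
                nps_cache=nps_cache,
            )
            points.append(
                DilutionPoint(
                    fraction=float(fraction),
                    replicate=rep,
                    coloc_score=run.result.coloc_score,
                    coloc_p=run.result.p,
                )
            )
    return points


def calibration_ttest(scores_at_full_dilution) -> tuple[float, float, float]:
    """One-sample two-sided t-test of the mean COLOC score against 1.

    Returns (mean, t, p). A well-calibrated null gives a mean near 1 and a
    non-significant test.
    """
    x = np.asarray(list(scores_at_full_dilution), dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 scores")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance; t-test undefined")
    t, p = stats.ttest_1samp(x, popmean=1.0)
    return float(x.mean()), float(t), float(p)


# ---------------------------------------------------------------------------
# Network dilution
# ---------------------------------------------------------------------------


def network_dilution_series(
    net: Network,
    target_dilutions,
    n_series: int = 1,
    rng_seed: int = 0,
    max_multiplier: float = 32.0,
) -> list[list[tuple[Network, float]]]:
    """Progressively randomized networks with measured dilution 1 − J.

    For each series, swap budgets grow until the achieved dilution reaches
    each increasing target (or the budget cap ``max_multiplier × |E|`` is
    hit, with a warning — edge swaps cannot reach arbitrary dilution on small
    graphs). Every returned network has the original degree sequence; the
    achieved dilutions are non-decreasing along a series.
    """
    targets = list(target_dilutions)
    if any(t2 <= t1 for t1, t2 in zip(targets, targets[1:])) or not targets:
        raise ValueError("target dilutions must be increasing and non-empty")
    if any(not 0 < t <= 1 for t in targets):
        raise ValueError("target dilutions must lie in (0, 1]")
    out: list[list[tuple[Network, float]]] = []
    for s in range(n_series):
        series: list[tuple[Network, float]] = []
        current = net
        total = 0.0
        for target in targets:
            achieved = edge_jaccard_dilution(net, current)
            while achieved < target and total < max_multiplier:
                # k successful swaps rewire 2k edges, moving the Jaccard
                # dilution by ≈ 4k/|E|; step the attempt budget accordingly
                step = min(max((target - achieved) / 4, 0.01), 1.0)
                current = shuffle_network(
                    current, step,
                    rng_seed=np.random.default_rng([rng_seed, s, int(total * 1000)]),
                )
                total += step
                achieved = edge_jaccard_dilution(net, current)
            if achieved < target:
                warnings.warn(
                    f"series {s}: target dilution {target} unreachable; "
                    f"achieved {achieved:.3f}"
                )
            series.append((current, achieved))
        out.append(series)
    return out
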