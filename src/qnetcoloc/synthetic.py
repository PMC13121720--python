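"""Synthetic networks and gene-score sets with the structure the method assumes.

The generator emulates the statistical shape of real inputs without any
downloads: a degree-heterogeneous interactome (preferential-attachment
backbone, so degree binning is actually exercised) with planted dense
modules standing in for trait-relevant pathways, and pairs of gene-score
sets whose signal genes are drawn from a shared module with association
p-values below the threshold θ, and whose noise genes are degree-matched to
the module genes (so degree alone cannot separate related from unrelated
pairs) with p-values just below θ.

Signal strength follows a GWAS-like right-skewed tail:
−log10 p = −log10 θ + Exponential(λ) with λ = 1 by default; noise genes get
−log10 p = −log10 θ + Uniform(0.01, noise_margin], i.e. barely past the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import DegreeBins, Network, make_degree_bins

__all__ = [
    "ModuleSpec",
    "StudySpec",
    "SyntheticScenario",
    "generate_network",
    "generate_study_pair",
    "generate_unrelated_pair",
]

#: Default association p-value thresholds for the two study types (lenient
#: GWAS-style for the common set, gene-based rare-variant style for the rare
#: set).
DEFAULT_THETA_COMMON = 1e-5
DEFAULT_THETA_RARE = 1e-4


@dataclass(frozen=True)
class ModuleSpec:
    """A planted module: ``size`` genes with internal edge density ``density``."""

    name: str
    size: int
    density: float = 0.25


@dataclass(frozen=True)
class StudySpec:
    """One simulated study pair drawing signal from a named module."""

    module: str
    size_a: int = 30
    size_b: int = 30
    signal_fraction: float = 0.7
    theta_a: float = DEFAULT_THETA_COMMON
    theta_b: float = DEFAULT_THETA_RARE


@dataclass(frozen=True)
class SyntheticScenario:
    """A reproducible test bed: network, planted modules and study pairs."""

    n_nodes: int = 2000
    attachment_edges: int = 2
    modules: tuple[ModuleSpec, ...] = ()
    studies: tuple[StudySpec, ...] = ()
    rng_seed: int = 0

    def build(self):
        """Returns (net, module assignments, list of (scores_a, scores_b))."""
        net, assignments = generate_network(
            self.n_nodes, self.attachment_edges, self.modules, self.rng_seed
        )
        rng = np.random.default_rng([self.rng_seed, 1])
        pairs = []
        for spec in self.studies:
            pairs.append(
                generate_study_pair(
                    net,
                    assignments[spec.module],
                    size_a=spec.size_a,
                    size_b=spec.size_b,
                    signal_fraction=spec.signal_fraction,
                    theta_a=spec.theta_a,
                    theta_b=spec.theta_b,
                    rng_seed=rng,
                )
            )
        return net, assignments, pairs


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(
    n_nodes: int,
    attachment_edges: int = 2,
    module_specs=(),
    rng_seed: int | np.random.Generator = 0,
) -> tuple[Network, dict[str, frozenset[str]]]:
    """Preferential-attachment backbone with planted dense modules.

    Modules are disjoint random node groups whose internal edge count is
    raised to ``density × C(size, 2)`` by adding random absent intra-module
    edges. Returns the network and the module assignments.
    """
    if n_nodes < 50:
        raise ValueError("n_nodes must be >= 50")
    total = sum(m.size for m in module_specs)
    if total > n_nodes:
        raise ValueError(
            f"modules require {total} nodes but the graph has only {n_nodes}"
        )
    rng = np.random.default_rng(rng_seed)
    # networkx BA generator needs an int seed; derive one below 2**31
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(n_nodes, attachment_edges, seed=ba_seed)
    g = nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes})

    assignments: dict[str, frozenset[str]] = {}
    available = sorted(g.nodes)
    for spec in module_specs:
        if isinstance(spec, (tuple, list)):
            spec = ModuleSpec(*spec)
        members = [
            available[i]
            for i in rng.choice(len(available), size=spec.size, replace=False)
        ]
        available = [n for n in available if n not in set(members)]
        target_edges = int(round(spec.density * spec.size * (spec.size - 1) / 2))
        existing = {
            frozenset(e) for e in g.subgraph(members).edges
        }
        candidates = [
            (members[i], members[j])
            for i in range(spec.size)
            for j in range(i + 1, spec.size)
            if frozenset((members[i], members[j])) not in existing
        ]
        n_add = max(0, target_edges - len(existing))
        if n_add > 0:
            picks = rng.choice(len(candidates), size=min(n_add, len(candidates)), replace=False)
            g.add_edges_from(candidates[i] for i in picks)
        assignments[spec.name] = frozenset(members)
    return Network(g), assignments


# ---------------------------------------------------------------------------
# Study-pair generation
# ---------------------------------------------------------------------------


def _signal_p(rng: np.random.Generator, theta: float, n: int, rate: float = 1.0) -> np.ndarray:
    """GWAS-like significant p-values: −log10 p = −log10 θ + Exp(rate)."""
    return theta * 10.0 ** (-rng.exponential(1.0 / rate, size=n))


def _noise_p(rng: np.random.Generator, theta: float, n: int, margin: float = 0.3) -> np.ndarray:
    """Barely significant p-values just below θ (all pass the threshold)."""
    return theta * 10.0 ** (-rng.uniform(0.01, margin, size=n))


def _degree_matched_draw(
    rng: np.random.Generator,
    bins: DegreeBins,
    templates: list[str],
    n: int,
    excluded: set[str],
) -> list[str]:
    """Draw ``n`` genes degree-matched to ``templates``, avoiding ``excluded``.

    Each draw picks a random template gene and samples uniformly from its
    degree bin; if the bin is exhausted the search widens to adjacent bins.
    """
    chosen: list[str] = []
    taken = set(excluded)
    n_bins = len(bins.bins)
    for _ in range(n):
        template = templates[rng.integers(0, len(templates))]
        b = bins.bin_of[template]
        pick = None
        for width in range(n_bins + 1):
            lo, hi = max(0, b - width), min(n_bins - 1, b + width)
            pool = [
                g
                for bb in range(lo, hi + 1)
                for g in bins.bins[bb]
                if g not in taken
            ]
            if pool:
                pick = pool[rng.integers(0, len(pool))]
                break
        if pick is None:
            raise ValueError("network exhausted while drawing degree-matched genes")
        chosen.append(pick)
        taken.add(pick)
    return chosen


def generate_study_pair(
    net: Network,
    module,
    size_a: int = 30,
    size_b: int = 30,
    signal_fraction: float = 0.7,
    p_model: tuple[float, float] = (1.0, 0.3),
    theta_a: float = DEFAULT_THETA_COMMON,
    theta_b: float = DEFAULT_THETA_RARE,
    rng_seed: int | np.random.Generator = 0,
    beta: int = 20,
    bins: DegreeBins | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """A related pair: both sets draw their signal genes from one module.

    ``signal_fraction`` of each set comes from ``module`` (sampled without
    replacement per set, so the two sets overlap by chance); the rest are
    degree-matched noise genes from outside the module. ``p_model`` is
    (signal exponential rate λ, noise uniform margin). Every emitted gene
    passes its θ.
    """
    if not 0 <= signal_fraction <= 1:
        raise ValueError("signal_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    module = sorted({g for g in map(str, module) if g in net.node_index})
    if not module:
        raise ValueError("module has no genes in the network")
    if bins is None:
        bins = make_degree_bins(net, beta)
    rate, margin = p_model

    def one_set(size: int, theta: float) -> dict[str, float]:
        n_sig = int(round(signal_fraction * size))
        n_sig = min(n_sig, size)
        if n_sig > len(module):
            raise ValueError(
                f"module holds {len(module)} genes but {n_sig} signal draws requested"
            )
        sig = [module[i] for i in rng.choice(len(module), size=n_sig, replace=False)]
        noise = _degree_matched_draw(
            rng, bins, templates=module, n=size - n_sig,
            excluded=set(module) | set(sig),
        )
        scores: dict[str, float] = {}
        for g, p in zip(sig, _signal_p(rng, theta, n_sig, rate)):
            scores[g] = float(p)
        for g, p in zip(noise, _noise_p(rng, theta, len(noise), margin)):
            scores[g] = float(p)
        return scores

    return one_set(size_a, theta_a), one_set(size_b, theta_b)


def generate_unrelated_pair(
    net: Network,
    module_1,
    module_2,
    size_a: int = 30,
    size_b: int = 30,
    signal_fraction: float = 0.7,
    p_model: tuple[float, float] = (1.0, 0.3),
    theta_a: float = DEFAULT_THETA_COMMON,
    theta_b: float = DEFAULT_THETA_RARE,
    rng_seed: int | np.random.Generator = 0,
    beta: int = 20,
    bins: DegreeBins | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """A control pair: set a signals from module 1, set b from module 2.

    The modules must be disjoint; noise draws for both sets avoid both
    modules, so disjoint modules yield non-overlapping gene sets.
    """
    m1 = {g for g in map(str, module_1) if g in net.node_index}
    m2 = {g for g in map(str, module_2) if g in net.node_index}
    if m1 & m2:
        raise ValueError("modules must be disjoint for an unrelated pair")
    rng = np.random.default_rng(rng_seed)
    if bins is None:
        bins = make_degree_bins(net, beta)
    rate, margin = p_model
    both = m1 | m2

    def one_set(module: list[str], size: int, theta: float, taken: set[str]) -> dict[str, float]:
        n_sig = min(int(round(signal_fraction * size)), size)
        if n_sig > len(module):
            raise ValueError("module too small for requested signal draws")
        sig = [module[i] for i in rng.choice(len(module), size=n_sig, replace=False)]
        noise = _degree_matched_draw(
            rng, bins, templates=module, n=size - n_sig, excluded=both | set(sig) | taken
        )
        scores: dict[str, float] = {}
        for g, p in zip(sig, _signal_p(rng, theta, n_sig, rate)):
            scores[g] = float(p)
        for g, p in zip(noise, _noise_p(rng, theta, len(noise), margin)):
            scores[g] = float(p)
        return scores

    scores_a = one_set(sorted(m1), size_a, theta_a, set())
    scores_b = one_set(sorted(m2), size_b, theta_b, set(scores_a))
    return scores_a, scores_b
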