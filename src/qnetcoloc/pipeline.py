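"""End-to-end colocalization runs: load → seed → propagate → NPS → extract → permute.

:func:`colocalize` is the library entry point operating on in-memory
objects; :func:`run_coloc` wraps it with file I/O, logging and artifact
writing for one configured run; :func:`run_batch` executes many runs and
applies batch-level Benjamini–Hochberg correction, with per-trait selection
of the best-scoring study combination.

NPS vectors depend only on the network, one gene set and the method
parameters, so they are cached and reused across study combinations of the
same set. Seeds for each stochastic stage derive deterministically from the
run seed and the content of the gene set(s), which makes cached and cold
runs bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as _coloc
from .graph import Network, load_edge_list, make_degree_bins
from .nps import (
    CombinedNPS,
    NPSVector,
    combine_nps,
    compute_nps,
    null_ensemble_binary,
    null_ensemble_quantitative,
    write_nps_table,
)
from .propagation import (
    MIN_SEED_GENES,
    build_binary_seed,
    build_quantitative_seed,
    propagate,
    read_gene_scores,
    read_gmt,
)

logger = logging.getLogger("qnetcoloc")

__all__ = ["ColocParams", "RunConfig", "ColocRun", "colocalize", "run_coloc", "run_batch"]


@dataclass(frozen=True)
class ColocParams:
    """Method parameters with the reference defaults.

    α is the random-walk dissipation constant, β the minimum degree-bin
    size, τ/τ* the trait-network thresholds, θ the association p-value
    thresholds for the common and rare sets (quantitative mode), n_null the
    NPS null ensemble size and n_perm the label-permutation count.
    """

    mode: str = "quantitative"  # "binary" | "quantitative"
    alpha: float = 0.5
    beta: int = 20
    tau: float = 1.0
    tau_star: float = 3.0
    theta_common: float = 1e-5
    theta_rare: float = 1e-4
    n_null: int = 1000
    n_perm: int = 1000

    def __post_init__(self):
        if self.mode not in ("binary", "quantitative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tau_star < self.tau:
            raise ValueError("tau_star must be >= tau")
        for name in ("theta_common", "theta_rare"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class RunConfig:
    """One configured colocalization run (file-based interface)."""

    network_path: str
    common_path: str
    rare_path: str
    output_dir: str
    params: ColocParams = field(default_factory=ColocParams)
    rng_seed: int = 0
    label: str = "run"
    trait: str | None = None
    gmt_set_common: str | None = None  # set names when inputs are GMT files
    gmt_set_rare: str | None = None
    restrict_to_lcc: bool = True


@dataclass
class ColocRun:
    """Full result of one colocalization: scores, trait network, statistics."""

    nps_common: NPSVector
    nps_rare: NPSVector
    nps_combined: CombinedNPS
    trait_network: _coloc.TraitNetwork
    result: _coloc.ColocResult
    prioritized: _coloc.PrioritizedGenes
    shared_genes: frozenset[str]
    params: ColocParams
    rng_seed: int


def _set_token(obj) -> int:
    """Stable 31-bit token of a gene set / score map's content."""
    if isinstance(obj, dict):
        items = sorted((str(g), float(p)) for g, p in obj.items())
        text = "\n".join(f"{g}\t{p:.17g}" for g, p in items)
    else:
        text = "\n".join(sorted(map(str, obj)))
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def _nps_for_set(
    net: Network,
    bins,
    data,
    theta: float,
    params: ColocParams,
    rng_seed: int,
    label: str,
    cache: dict | None,
) -> tuple[NPSVector, frozenset[str]]:
    """NPS vector for one gene set (cached); returns (scores, seed genes)."""
    token = _set_token(data)
    key = (token, params.mode, params.alpha, params.beta, params.n_null, theta, rng_seed)
    if cache is not None and key in cache:
        nps, genes = cache[key]
        return NPSVector(score=nps.score, source_label=label), genes
    rng = np.random.default_rng([rng_seed, token])
    if params.mode == "binary":
        genes = set(data) if not isinstance(data, dict) else set(data)
        seed = build_binary_seed(genes, net)
        ensemble = null_ensemble_binary(
            net, seed.genes, bins, n_null=params.n_null, alpha=params.alpha, rng_seed=rng
        )
    else:
        if not isinstance(data, dict):
            raise ValueError("quantitative mode needs gene → p-value scores")
        seed = build_quantitative_seed(data, theta, net, min_genes=MIN_SEED_GENES)
        ensemble = null_ensemble_quantitative(
            net, seed, bins, n_null=params.n_null, alpha=params.alpha, rng_seed=rng
        )
    observed = propagate(net, seed, params.alpha)
    nps = compute_nps(observed, ensemble, source_label=label)
    seed_genes = frozenset(seed.genes)
    if cache is not None:
        cache[key] = (nps, seed_genes)
    return nps, seed_genes


def colocalize(
    net: Network,
    common,
    rare,
    params: ColocParams = ColocParams(),
    rng_seed: int = 0,
    nps_cache: dict | None = None,
) -> ColocRun:
    """Run the full colocalization of two gene sets on one network.

    ``common`` and ``rare`` are gene → p-value mappings (quantitative mode)
    or plain gene collections (binary mode). The shared-gene stratum for the
    permutation null is the intersection of the in-network seed genes.
    """
    bins = make_degree_bins(net, params.beta)
    nps_c, genes_c = _nps_for_set(
        net, bins, common, params.theta_common, params, rng_seed, "common", nps_cache
    )
    nps_r, genes_r = _nps_for_set(
        net, bins, rare, params.theta_rare, params, rng_seed, "rare", nps_cache
    )
    combined = combine_nps(nps_c, nps_r)
    trait_net = _coloc.extract_trait_network(nps_c, nps_r, params.tau, params.tau_star)
    shared = frozenset(genes_c & genes_r)
    perm_rng = np.random.default_rng(
        [rng_seed, _set_token(common), _set_token(rare), 2]
    )
    null_sizes = _coloc.permutation_null_sizes(
        nps_c,
        nps_r,
        shared,
        tau=params.tau,
        tau_star=params.tau_star,
        n_perm=params.n_perm,
        rng_seed=perm_rng,
    )
    result = _coloc.coloc_statistics(trait_net.size, null_sizes)
    prioritized = _coloc.prioritized_genes(genes_c, genes_r, trait_net)
    return ColocRun(
        nps_common=nps_c,
        nps_rare=nps_r,
        nps_combined=combined,
        trait_network=trait_net,
        result=result,
        prioritized=prioritized,
        shared_genes=shared,
        params=params,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# File-based runs
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_set(path: str, mode: str, gmt_set: str | None):
    if gmt_set is not None or str(path).endswith(".gmt"):
        sets = read_gmt(path)
        if gmt_set is None:
            if len(sets) != 1:
                raise ValueError(f"{path}: GMT holds {len(sets)} sets; name one")
            return next(iter(sets.values()))
        if gmt_set not in sets:
            raise ValueError(f"{path}: no GMT set named {gmt_set!r}")
        return sets[gmt_set]
    scores = read_gene_scores(path)
    if mode == "binary":
        return set(scores.index)
    return scores.to_dict()


def run_coloc(config: RunConfig, nps_cache: dict | None = None) -> ColocRun:
    """Execute one configured run and write its artifacts.

    Writes ``<label>.coloc.json`` (result + members + prioritized genes) and
    ``<label>.nps.tsv`` (per-gene scores) into the output directory, plus a
    ``<label>.manifest.json`` recording input hashes, parameters and seed.
    """
    p = config.params
    logger.info(
        "run %s: mode=%s alpha=%s beta=%s tau=%s tau_star=%s theta_common=%s "
        "theta_rare=%s n_null=%s n_perm=%s seed=%s",
        config.label, p.mode, p.alpha, p.beta, p.tau, p.tau_star,
        p.theta_common, p.theta_rare, p.n_null, p.n_perm, config.rng_seed,
    )
    net = load_edge_list(config.network_path, restrict_to_lcc=config.restrict_to_lcc)
    common = _load_set(config.common_path, p.mode, config.gmt_set_common)
    rare = _load_set(config.rare_path, p.mode, config.gmt_set_rare)
    run = colocalize(net, common, rare, params=p, rng_seed=config.rng_seed, nps_cache=nps_cache)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _coloc.write_coloc_json(
        outdir / f"{config.label}.coloc.json",
        run.result,
        run.trait_network,
        run.prioritized,
    )
    write_nps_table(
        outdir / f"{config.label}.nps.tsv", run.nps_common, run.nps_rare, run.nps_combined
    )
    manifest = {
        "label": config.label,
        "trait": config.trait,
        "rng_seed": config.rng_seed,
        "params": asdict(p),
        "inputs": {
            "network": {"path": str(config.network_path), "sha256": _sha256(config.network_path)},
            "common": {"path": str(config.common_path), "sha256": _sha256(config.common_path)},
            "rare": {"path": str(config.rare_path), "sha256": _sha256(config.rare_path)},
        },
        "n_dropped_common": len(set(map(str, common)) - set(net.nodes))
        if not isinstance(common, dict)
        else len(set(common) - set(net.nodes)),
        "observed_size": run.result.observed_size,
    }
    with open(outdir / f"{config.label}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return run


def run_batch(
    configs, nps_cache: dict | None = None, summary_path=None
) -> pd.DataFrame:
    """Run many configurations; BH-correct p-values across the batch.

    Failures are recorded (``error`` column) and the batch continues. When
    trait labels are present, the best study combination per trait (highest
    COLOC score) is flagged. Returns the summary table (also written as TSV
    when ``summary_path`` is given).
    """
    if not configs:
        raise ValueError("run_batch needs at least one configuration")
    if nps_cache is None:
        nps_cache = {}
    rows = []
    for cfg in configs:
        try:
            run = run_coloc(cfg, nps_cache=nps_cache)
            rows.append(
                {
                    "label": cfg.label,
                    "trait": cfg.trait,
                    "observed_size": run.result.observed_size,
                    "expected_size": run.result.expected_size,
                    "coloc_score": run.result.coloc_score,
                    "z": run.result.z,
                    "p": run.result.p,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - batch keeps going
            logger.warning("run %s failed: %s", cfg.label, exc)
            rows.append(
                {
                    "label": cfg.label,
                    "trait": cfg.trait,
                    "observed_size": np.nan,
                    "expected_size": np.nan,
                    "coloc_score": np.nan,
                    "z": np.nan,
                    "p": np.nan,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = _coloc.bh_correct(df.loc[ok, "p"].to_numpy())
    df["best_for_trait"] = False
    with_trait = df["trait"].notna() & ok
    if with_trait.any():
        idx = df[with_trait].groupby("trait")["coloc_score"].idxmax()
        df.loc[idx, "best_for_trait"] = True
    if summary_path is not None:
        df.to_csv(summary_path, sep="\t", index=False)
    return df
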