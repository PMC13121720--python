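"""Study-pair features and elastic-net regression on colocalization strength.

For each pair of gene sets (common-variant genes C and rare-variant genes R)
a handful of scalar features summarize the pair: study population sizes
(N_C, N_R), gene counts (g_C, g_R), Jaccard overlap J_CR, induced-subnetwork
densities ρ_C and ρ_R, the label assortativity A_CR of the induced union
subgraph, and — for each externally supplied per-gene property — the
weighted mean μ_CR = (g_C μ_C + g_R μ_R)/(g_C + g_R) and the normalized
difference of means δ = 2(μ_R − μ_C)/(μ_R + μ_C) ∈ [−2, 2].

Features are transformed to comparable scales (Gaussian quantile transform
or Yeo–Johnson power transform per feature, one-hot flags passed through,
everything standardized), an elastic net is fit with 5-fold cross-validated
selection of penalty and l1-ratio, and coefficient confidence comes from
bootstrap resampling with empirical sign-based p-values

    p = 2 · min((r₊ + 1)/(B + 1), (r₋ + 1)/(B + 1)),  capped at 1,

where r₊/r₋ count positive/negative coefficient estimates over B bootstrap
replicates, followed by Bonferroni correction over features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.metrics import explained_variance_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import PowerTransformer, QuantileTransformer, StandardScaler

from .graph import Network

__all__ = [
    "StudyPairFeatures",
    "BootstrapSummary",
    "ElasticNetFit",
    "jaccard_similarity",
    "subnetwork_density",
    "pair_assortativity",
    "weighted_mean_and_delta",
    "compute_pair_features",
    "features_frame",
    "default_transform_scheme",
    "transform_features",
    "quantile_normalize_response",
    "fit_elastic_net_cv",
    "bootstrap_coefficients",
]

#: Gene properties summarized by μ/δ in the reference feature set.
PROPERTY_NAMES = ("Constraint", "GeneSize", "mRNA", "nTissues", "GO")

DEFAULT_ALPHA_GRID = tuple(np.logspace(-5, 1, 20))
DEFAULT_L1_RATIOS = (0.1, 0.25, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0)
DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class StudyPairFeatures:
    """Scalar features for one common/rare study pair."""

    n_common_pop: int
    n_rare_pop: int
    g_common: int
    g_rare: int
    jaccard: float
    density_common: float
    density_rare: float
    assortativity: float
    mu: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)
    is_categorical: bool = False

    @property
    def jaccard_zero(self) -> bool:
        return self.jaccard == 0.0

    def as_row(self) -> dict[str, float]:
        row = {
            "N_C": self.n_common_pop,
            "N_R": self.n_rare_pop,
            "g_C": self.g_common,
            "g_R": self.g_rare,
            "J_CR": self.jaccard,
            "rho_C": self.density_common,
            "rho_R": self.density_rare,
            "A_CR": self.assortativity,
        }
        for name, val in self.mu.items():
            row[f"mu_{name}"] = val
        for name, val in self.delta.items():
            row[f"delta_{name}"] = val
        row["binary"] = float(self.is_categorical)
        row["jaccard_zero"] = float(self.jaccard_zero)
        return row


# ---------------------------------------------------------------------------
# Elementary features
# ---------------------------------------------------------------------------


def jaccard_similarity(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for gene sets (error when both are empty)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(union)


def subnetwork_density(net: Network, genes) -> float:
    """Edge density 2E/(n(n−1)) of the subgraph induced by in-network genes.

    Genes absent from the network are ignored; fewer than two in-network
    genes gives density 0.
    """
    members = [g for g in set(map(str, genes)) if g in net.node_index]
    n = len(members)
    if n < 2:
        return 0.0
    e = net.graph.subgraph(members).number_of_edges()
    return 2.0 * e / (n * (n - 1))


def _attribute_assortativity(sub: nx.Graph, labels: dict[str, str]) -> float:
    nx.set_node_attributes(sub, labels, name="_role")
    return float(nx.attribute_assortativity_coefficient(sub, "_role"))


def pair_assortativity(net: Network, cvgs, rvgs) -> float:
    """Mean label assortativity of the union-induced subgraph.

    Computed twice on the subgraph induced by CVGs ∪ RVGs — once labeling
    {common} vs {rare-only}, once {rare} vs {common-only} — and averaged:
    A_CR = (A_{C,R−C} + A_{R,C−R})/2. With no shared genes the two labelings
    coincide and the single value is returned. A subgraph with no edges (or a
    degenerate single-label mixing matrix) yields 0 with a warning.
    """
    cvgs = {g for g in map(str, cvgs) if g in net.node_index}
    rvgs = {g for g in map(str, rvgs) if g in net.node_index}
    union = cvgs | rvgs
    if not union:
        raise ValueError("no input genes present in the network")
    sub = nx.Graph(net.graph.subgraph(union))
    if sub.number_of_edges() == 0:
        warnings.warn("induced subgraph has no edges; assortativity set to 0")
        return 0.0

    def one(first: set[str], first_name: str, other_name: str) -> float:
        labels = {g: (first_name if g in first else other_name) for g in union}
        with np.errstate(invalid="ignore", divide="ignore"):
            val = _attribute_assortativity(sub, labels)
        if not np.isfinite(val):
            warnings.warn("degenerate label mixing; assortativity term set to 0")
            return 0.0
        return val

    a_c = one(cvgs, "common", "rare_only")
    if not (cvgs & rvgs):
        return a_c  # the two labelings coincide when J_CR = 0
    a_r = one(rvgs, "rare", "common_only")
    return 0.5 * (a_c + a_r)


def weighted_mean_and_delta(
    mu_c: float, g_c: int, mu_r: float, g_r: int
) -> tuple[float, float]:
    """μ_CR = (g_C μ_C + g_R μ_R)/(g_C + g_R) and δ = 2(μ_R − μ_C)/(μ_R + μ_C)."""
    if g_c < 1 or g_r < 1:
        raise ValueError("gene counts must be >= 1")
    if mu_r + mu_c == 0:
        raise ValueError("delta undefined when the property means sum to 0")
    mu_cr = (g_c * mu_c + g_r * mu_r) / (g_c + g_r)
    delta = 2.0 * (mu_r - mu_c) / (mu_r + mu_c)
    return mu_cr, delta


def compute_pair_features(
    net: Network,
    cvgs,
    rvgs,
    n_common_pop: int,
    n_rare_pop: int,
    properties: dict[str, dict[str, float]] | None = None,
    is_categorical: bool = False,
) -> StudyPairFeatures:
    """Assemble the full feature record for one study pair.

    ``properties`` maps property name → (gene → value); per-set property
    means are taken over the genes with a value available.
    """
    cvgs, rvgs = set(map(str, cvgs)), set(map(str, rvgs))
    mu: dict[str, float] = {}
    delta: dict[str, float] = {}
    for name, table in (properties or {}).items():
        vc = [table[g] for g in cvgs if g in table]
        vr = [table[g] for g in rvgs if g in table]
        if not vc or not vr:
            raise ValueError(f"property {name!r} has no values for one gene set")
        mu_c, mu_r = float(np.mean(vc)), float(np.mean(vr))
        mu[name], delta[name] = weighted_mean_and_delta(mu_c, len(cvgs), mu_r, len(rvgs))
    return StudyPairFeatures(
        n_common_pop=int(n_common_pop),
        n_rare_pop=int(n_rare_pop),
        g_common=len(cvgs),
        g_rare=len(rvgs),
        jaccard=jaccard_similarity(cvgs, rvgs),
        density_common=subnetwork_density(net, cvgs),
        density_rare=subnetwork_density(net, rvgs),
        assortativity=pair_assortativity(net, cvgs, rvgs),
        mu=mu,
        delta=delta,
        is_categorical=is_categorical,
    )


def features_frame(pairs) -> pd.DataFrame:
    """Stack StudyPairFeatures records into a feature table (one row per pair)."""
    return pd.DataFrame([p.as_row() for p in pairs])


# ---------------------------------------------------------------------------
# Feature transforms
# ---------------------------------------------------------------------------


def default_transform_scheme(columns) -> dict[str, str]:
    """Per-feature transform assignment used by the reference analysis.

    Population sizes, assortativity, the property means (except μ_nTissues)
    and all δ features get the Gaussian quantile transform; gene counts,
    densities, Jaccard and μ_nTissues get the power transform; the binary
    flags are one-hot passthrough. Everything is standardized afterwards.
    """
    scheme: dict[str, str] = {}
    for col in columns:
        if col in ("binary", "jaccard_zero"):
            scheme[col] = "one-hot"
        elif col in ("g_C", "g_R", "rho_C", "rho_R", "J_CR", "mu_nTissues"):
            scheme[col] = "power"
        elif col in ("N_C", "N_R", "A_CR") or col.startswith(("mu_", "delta_")):
            scheme[col] = "quantile"
        else:
            raise ValueError(
                f"no default transform for feature {col!r}; pass an explicit scheme"
            )
    return scheme


def transform_features(
    table: pd.DataFrame, scheme: dict[str, str] | None = None
) -> pd.DataFrame:
    """Transform and standardize a feature table.

    Each column gets exactly one of {"quantile", "power", "one-hot"}; the
    quantile transform targets a Gaussian with as many quantiles as samples,
    the power transform is Yeo–Johnson, and one-hot columns pass through.
    All columns are then rescaled to mean 0, sd 1. Constant columns cannot be
    standardized and are rejected.
    """
    if scheme is None:
        scheme = default_transform_scheme(table.columns)
    unknown = set(scheme) - set(table.columns)
    if unknown:
        raise ValueError(f"scheme names absent columns: {sorted(unknown)}")
    missing = set(table.columns) - set(scheme)
    if missing:
        raise ValueError(f"columns without a transform: {sorted(missing)}")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant feature column(s) cannot be standardized: {constant}")
    n = len(table)
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float).reshape(-1, 1)
        kind = scheme[col]
        if kind == "quantile":
            qt = QuantileTransformer(
                n_quantiles=n, output_distribution="normal", random_state=0
            )
            x = qt.fit_transform(x)
        elif kind == "power":
            x = PowerTransformer(method="yeo-johnson", standardize=False).fit_transform(x)
        elif kind == "one-hot":
            pass
        else:
            raise ValueError(f"unknown transform {kind!r} for column {col!r}")
        out[col] = x.ravel()
    df = pd.DataFrame(out, index=table.index)
    scaled = StandardScaler().fit_transform(df.to_numpy())
    return pd.DataFrame(scaled, columns=df.columns, index=df.index)


def quantile_normalize_response(y) -> np.ndarray:
    """Quantile-normalize the regression target to a Gaussian (quantiles = n)."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    qt = QuantileTransformer(
        n_quantiles=len(y), output_distribution="normal", random_state=0
    )
    return qt.fit_transform(y).ravel()


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------


@dataclass
class ElasticNetFit:
    """Cross-validated elastic-net fit refit on the full data."""

    penalty: float
    l1_ratio: float
    coefficients: pd.Series
    intercept: float
    explained_variance: float
    residuals: np.ndarray


@dataclass
class BootstrapSummary:
    """Bootstrap coefficient table: mean, percentile CI, empirical p, q."""

    table: pd.DataFrame
    n_boot: int


def fit_elastic_net_cv(
    X: pd.DataFrame,
    y,
    penalty_grid=DEFAULT_ALPHA_GRID,
    l1_grid=DEFAULT_L1_RATIOS,
    k: int = 5,
    rng_seed: int = 0,
) -> ElasticNetFit:
    """Select (penalty, l1_ratio) by k-fold CV mean squared error; refit on all data.

    The response is expected to be quantile-normalized upstream. Residuals
    are actual − predicted on the full data.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for {k}-fold CV")
    if np.linalg.matrix_rank(X.to_numpy()) == 0:
        raise ValueError("feature matrix has rank 0")
    cv = KFold(n_splits=k, shuffle=True, random_state=rng_seed)
    model = ElasticNetCV(
        alphas=list(penalty_grid),
        l1_ratio=list(l1_grid),
        cv=cv,
        max_iter=50_000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny penalties
        model.fit(X.to_numpy(), y)
    pred = model.predict(X.to_numpy())
    return ElasticNetFit(
        penalty=float(model.alpha_),
        l1_ratio=float(model.l1_ratio_),
        coefficients=pd.Series(model.coef_, index=X.columns),
        intercept=float(model.intercept_),
        explained_variance=float(explained_variance_score(y, pred)),
        residuals=y - pred,
    )


def _empirical_p(r_plus: int, r_minus: int, n_boot: int) -> float:
    """Sign-based bootstrap p-value, capped at 1."""
    p = 2.0 * min((r_plus + 1) / (n_boot + 1), (r_minus + 1) / (n_boot + 1))
    return min(p, 1.0)


def bootstrap_coefficients(
    X: pd.DataFrame,
    y,
    penalty: float,
    l1_ratio: float,
    n_boot: int = DEFAULT_N_BOOT,
    rng_seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap the elastic-net coefficients by resampling rows with replacement.

    Per feature: mean coefficient, 2.5/97.5 percentile CI, empirical p from
    the sign counts r₊/r₋, and Bonferroni q over the number of features.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n, p = X.shape
    Xv = X.to_numpy()
    coefs = np.empty((n_boot, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            m = ElasticNet(alpha=penalty, l1_ratio=l1_ratio, max_iter=50_000)
            m.fit(Xv[idx], y[idx])
            coefs[b] = m.coef_
    r_plus = (coefs > 0).sum(axis=0)
    r_minus = (coefs < 0).sum(axis=0)
    pvals = np.array([_empirical_p(rp, rm, n_boot) for rp, rm in zip(r_plus, r_minus)])
    table = pd.DataFrame(
        {
            "coef_mean": coefs.mean(axis=0),
            "ci_low": np.percentile(coefs, 2.5, axis=0),
            "ci_high": np.percentile(coefs, 97.5, axis=0),
            "r_plus": r_plus,
            "r_minus": r_minus,
            "p": pvals,
            "q": np.minimum(pvals * p, 1.0),
        },
        index=X.columns,
    )
    return BootstrapSummary(table=table, n_boot=n_boot)
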