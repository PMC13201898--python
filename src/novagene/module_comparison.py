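"""Cross-condition module comparison via hub-gene PCA1 signatures.

Each module is summarized by the first principal component of its most
influential (eigenvector-central) genes' expression, evaluated over the
pooled samples of both conditions so that signatures from different
conditions share an index and can be Pearson-correlated.  A module pair is
called significant when the two-sided p-value of that correlation falls
below the configured alpha; +1 indicates matched hub activity across
conditions, -1 a complete inversion.

Centrality is computed on each module's induced weighted subgraph, which is
well-defined even when the pruned network is disconnected.  The PCA sign
indeterminacy is resolved by requiring a non-negative mean correlation
between the score vector and the standardized hub profiles, making
signatures bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalysisConfig, ConditionDesign, ExpressionMatrix
from .module_detection import ModulePartition
from .network_builder import ConditionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubSignature:
    """A module's hub genes and oriented PCA1 score vector."""

    condition_label: str
    module_label: str
    hub_genes: tuple[str, ...]
    sample_ids: tuple[str, ...]
    pca1_scores: np.ndarray
    variance_explained: float
    orientation_sign: int


@dataclass(frozen=True)
class ModuleComparisonResult:
    """Module x module Pearson correlations of hub-PCA1 signatures."""

    modules_a: tuple[str, ...]
    modules_b: tuple[str, ...]
    pearson_r: pd.DataFrame
    p_value: pd.DataFrame
    significant: pd.DataFrame

    def significant_pairs(self) -> list[tuple[str, str]]:
        out = []
        for ma in self.modules_a:
            for mb in self.modules_b:
                if bool(self.significant.loc[ma, mb]):
                    out.append((ma, mb))
        return out


def module_centrality(
    network: ConditionNetwork, module_genes: Sequence[str]
) -> dict[str, float]:
    """Eigenvector centrality on the module's induced weighted subgraph.

    Power iteration on the induced adjacency to tolerance 1e-10 (max 1000
    iterations); the result is the dominant eigenvector with non-negative
    entries and unit Euclidean norm.
    """
    genes = list(module_genes)
    if not genes:
        raise ValueError("module must contain at least one gene")
    lookup = {g: i for i, g in enumerate(network.gene_ids)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise KeyError(f"module genes absent from network: {missing}")
    idx = np.array([lookup[g] for g in genes], dtype=int)
    sub = network.adjacency[np.ix_(idx, idx)]
    m = len(genes)
    if m == 1:
        return {genes[0]: 1.0}
    if sub.max() <= 0:
        warnings.warn("induced subgraph has no edges; uniform centralities")
        u = 1.0 / np.sqrt(m)
        return {g: u for g in genes}
    v = np.full(m, 1.0 / np.sqrt(m))
    for _ in range(1000):
        # identity shift keeps the dominant eigenvector but damps the
        # period-2 oscillation of plain iteration on bipartite graphs
        w = sub @ v + v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.linalg.norm(w - v) < 1e-10:
            v = w
            break
        v = w
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return {g: float(c) for g, c in zip(genes, v)}


def select_hubs(
    centrality: dict[str, float], config: AnalysisConfig | None = None
) -> tuple[str, ...]:
    """Top hub genes by centrality (ties broken by gene id), up to n_hubs.

    Modules smaller than n_hubs contribute all of their genes.
    """
    config = config or AnalysisConfig()
    if not centrality:
        raise ValueError("centrality mapping is empty")
    ordered = sorted(centrality, key=lambda g: (-centrality[g], g))
    return tuple(ordered[: config.n_hubs])


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    ok = sd.ravel() > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    return z, ok


def _pca1(z: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component scores over samples of a genes x samples
    standardized matrix, via SVD of the sample x gene view."""
    x = z.T  # samples x genes, columns already mean-zero
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, 0] * s[0]
    total = float((s**2).sum())
    var_exp = float(s[0] ** 2 / total) if total > 0 else 0.0
    return scores, var_exp


def hub_signature(
    expr: ExpressionMatrix,
    hubs: Sequence[str],
    pooled_samples: Sequence[str],
    condition_label: str = "",
    module_label: str = "",
) -> HubSignature:
    """PCA1 of the standardized hub-gene expression over pooled samples.

    Hub profiles are restricted to ``pooled_samples`` and standardized per
    gene; the first principal component score vector is oriented so its
    mean Pearson correlation with the standardized hub profiles is
    non-negative.
    """
    hubs = list(hubs)
    if not hubs:
        raise ValueError("hub list is empty")
    if len(pooled_samples) < 3:
        raise ValueError("need at least 3 pooled samples")
    sub = expr.subset_genes(hubs).subset_samples(pooled_samples)
    z, ok = _standardize_rows(sub.values)
    if not ok.all():
        dropped = [g for g, o in zip(hubs, ok) if not o]
        warnings.warn(f"dropping constant hub genes: {dropped}")
        hubs = [g for g, o in zip(hubs, ok) if o]
        z = z[ok]
    if not hubs:
        raise ValueError("all hub genes constant over pooled samples")
    scores, var_exp = _pca1(z)
    # orientation: scores should on average co-vary with the hub profiles
    score_sd = scores.std(ddof=1)
    sign = 1
    if score_sd > 0:
        zs = (scores - scores.mean()) / score_sd
        mean_corr = float(np.mean(z @ zs) / (len(zs) - 1))
        if mean_corr < 0:
            sign = -1
            scores = -scores
    return HubSignature(
        condition_label=condition_label,
        module_label=module_label,
        hub_genes=tuple(hubs),
        sample_ids=tuple(pooled_samples),
        pca1_scores=scores,
        variance_explained=var_exp,
        orientation_sign=sign,
    )


def correlate_signatures(
    sig_a: HubSignature, sig_b: HubSignature
) -> tuple[float, float]:
    """Pearson correlation of two signatures with a two-sided t-test p-value.

    Both signatures must be indexed by the identical pooled sample list; the
    p-value uses t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom,
    and |r| = 1 maps to p = 0.
    """
    if sig_a.sample_ids != sig_b.sample_ids:
        raise ValueError("signatures are indexed by different sample lists")
    n = len(sig_a.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples to correlate signatures")
    da = sig_a.pca1_scores - sig_a.pca1_scores.mean()
    db = sig_b.pca1_scores - sig_b.pca1_scores.mean()
    denom = np.sqrt(float(da @ da) * float(db @ db))
    if denom == 0.0:
        raise ValueError("a signature has zero variance")
    r = float(da @ db) / denom  # argument-order symmetric by construction
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def comparison_matrix(
    net_a: ConditionNetwork,
    net_b: ConditionNetwork,
    partition_a: ModulePartition,
    partition_b: ModulePartition,
    expr: ExpressionMatrix,
    design: ConditionDesign,
    config: AnalysisConfig | None = None,
) -> ModuleComparisonResult:
    """Correlate every non-grey module pair across two condition networks.

    Signatures are evaluated over the pooled union of both conditions'
    samples (condition A's samples first, in design order) so the two PCA1
    vectors share length and indexing.  Significance is the uncorrected
    two-sided p < alpha.
    """
    config = config or AnalysisConfig()
    modules_a = partition_a.module_labels
    modules_b = partition_b.module_labels
    if not modules_a and not modules_b:
        raise ValueError("no non-grey modules in either network")
    if not modules_a or not modules_b:
        raise ValueError(
            f"no non-grey modules in condition "
            f"{net_a.condition_label if not modules_a else net_b.condition_label!r}"
        )
    samples_a = list(design.samples_for(net_a.condition_label))
    seen = set(samples_a)
    pooled = samples_a + [
        s for s in design.samples_for(net_b.condition_label) if s not in seen
    ]

    def _signature(net, partition, module):
        genes = partition.genes_in(module)
        cent = module_centrality(net, genes)
        hubs = select_hubs(cent, config)
        return hub_signature(expr, hubs, pooled, net.condition_label, module)

    sigs_a = {m: _signature(net_a, partition_a, m) for m in modules_a}
    sigs_b = {m: _signature(net_b, partition_b, m) for m in modules_b}

    r = pd.DataFrame(index=list(modules_a), columns=list(modules_b), dtype=float)
    p = pd.DataFrame(index=list(modules_a), columns=list(modules_b), dtype=float)
    for ma in modules_a:
        for mb in modules_b:
            rv, pv = correlate_signatures(sigs_a[ma], sigs_b[mb])
            r.loc[ma, mb] = rv
            p.loc[ma, mb] = pv
    sig = p < config.alpha_significance
    logger.info(
        "comparison %s vs %s: %d x %d modules, %d significant pairs",
        net_a.condition_label, net_b.condition_label,
        len(modules_a), len(modules_b), int(sig.to_numpy().sum()),
    )
    return ModuleComparisonResult(
        modules_a=modules_a, modules_b=modules_b,
        pearson_r=r, p_value=p, significant=sig,
    )


def write_comparison(result: ModuleComparisonResult, path: str | Path) -> None:
    rows = []
    for ma in result.modules_a:
        for mb in result.modules_b:
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "pearson_r": result.pearson_r.loc[ma, mb],
                    "p_value": result.p_value.loc[ma, mb],
                    "significant": bool(result.significant.loc[ma, mb]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
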