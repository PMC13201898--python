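"""Pooled single-network baselines (standard and distance-correlation WGCNA).

Both comparison conditions' samples are pooled into one network: a
correlation matrix (Pearson, or distance correlation for the nonlinear
variant), soft-thresholded adjacency, topological overlap, hierarchical
modules, then a module eigengene (first principal component of the module's
standardized expression) correlated against binary traits such as the
condition indicator.  No power-law pruning is applied here — pruning
belongs to the per-condition pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    AnalysisConfig,
    ConditionDesign,
    ExpressionMatrix,
    filter_zero_variance,
)
from .module_detection import ModulePartition, cluster_modules, topological_overlap
from .module_comparison import _pca1, _standardize_rows
from .network_builder import adjacency_from_correlation, pick_soft_threshold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleEigengene:
    module_label: str
    sample_ids: tuple[str, ...]
    scores: np.ndarray
    variance_explained: float


@dataclass(frozen=True)
class TraitAssociation:
    module_label: str
    trait: str
    pearson_r: float
    p_value: float
    significant: bool


def pearson_matrix(
    expr: ExpressionMatrix, samples: Sequence[str] | None = None
) -> np.ndarray:
    """Gene x gene Pearson correlation over a sample subset."""
    if samples is None:
        samples = expr.sample_ids
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    idx = expr.sample_index(samples)
    sub = expr.values[:, idx]
    if np.any(np.ptp(sub, axis=1) == 0):
        const = [g for g, c in zip(expr.gene_ids, np.ptp(sub, axis=1) == 0) if c]
        raise ValueError(f"constant genes in scope: {const}")
    corr = np.corrcoef(sub)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def module_eigengene(
    expr: ExpressionMatrix,
    module_genes: Sequence[str],
    samples: Sequence[str],
    module_label: str = "",
) -> ModuleEigengene:
    """First principal component of the module's standardized expression.

    Oriented so the mean correlation with the module's gene profiles is
    non-negative, as for hub signatures.
    """
    genes = list(module_genes)
    if not genes:
        raise ValueError("module is empty")
    sub = expr.subset_genes(genes).subset_samples(samples)
    z, ok = _standardize_rows(sub.values)
    if not ok.any():
        raise ValueError("all module genes constant over the samples")
    z = z[ok]
    scores, var_exp = _pca1(z)
    sd = scores.std(ddof=1)
    if sd > 0:
        zs = (scores - scores.mean()) / sd
        if float(np.mean(z @ zs) / (len(zs) - 1)) < 0:
            scores = -scores
    return ModuleEigengene(
        module_label=module_label,
        sample_ids=tuple(samples),
        scores=scores,
        variance_explained=var_exp,
    )


def module_trait_correlation(
    me: ModuleEigengene,
    trait: Sequence[float],
    trait_name: str = "trait",
    alpha: float = 0.05,
) -> TraitAssociation:
    """Pearson correlation of a module eigengene with a binary trait."""
    trait = np.asarray(trait, dtype=float).ravel()
    if trait.size != me.scores.size:
        raise ValueError("trait length does not match eigengene length")
    if np.ptp(trait) == 0:
        raise ValueError("trait is constant")
    if me.scores.std() == 0:
        raise ValueError("eigengene is constant")
    n = trait.size
    r = float(np.corrcoef(me.scores, trait)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return TraitAssociation(
        module_label=me.module_label,
        trait=trait_name,
        pearson_r=r,
        p_value=p,
        significant=p < alpha,
    )


def run_pooled_pipeline(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    mode: str = "pearson",
    config: AnalysisConfig | None = None,
) -> tuple[ModulePartition, list[ModuleEigengene], list[TraitAssociation]]:
    """Pooled-sample network analysis with module-trait associations.

    All design samples form one network; the only mode-dependent stage is
    the correlation matrix (Pearson vs distance correlation).  Every
    non-grey module yields an eigengene and one association per design
    trait, flagged at the configured alpha without multiplicity correction.
    """
    from .network_builder import correlation_matrix_for

    config = (config or AnalysisConfig()).with_mode(mode)
    if design.traits.empty:
        raise ValueError("design must provide at least one binary trait")
    design.validate_against(expr)
    samples = list(design.sample_ids)
    filtered = filter_zero_variance(expr, samples)
    corr = correlation_matrix_for(filtered, samples, mode)
    soft = pick_soft_threshold(corr, config)
    adj = adjacency_from_correlation(corr, soft.beta)
    tom = topological_overlap(adj, filtered.gene_ids)
    partition = cluster_modules(tom, config)
    eigengenes: list[ModuleEigengene] = []
    associations: list[TraitAssociation] = []
    for module in partition.module_labels:
        me = module_eigengene(filtered, partition.genes_in(module), samples, module)
        eigengenes.append(me)
        for trait_name in design.traits.columns:
            trait = design.trait_vector(trait_name, samples)
            associations.append(
                module_trait_correlation(
                    me, trait, trait_name, config.alpha_significance
                )
            )
    logger.info(
        "pooled %s pipeline: beta=%d fit=%.3f modules=%d significant=%d",
        mode, soft.beta, soft.fit_index, len(partition.module_labels),
        sum(a.significant for a in associations),
    )
    return partition, eigengenes, associations


def write_eigengenes(
    eigengenes: Sequence[ModuleEigengene], path: str | Path
) -> None:
    if not eigengenes:
        return
    df = pd.DataFrame(
        {me.module_label: me.scores for me in eigengenes},
        index=list(eigengenes[0].sample_ids),
    )
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_trait_associations(
    associations: Sequence[TraitAssociation], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "module_label": a.module_label,
                "trait": a.trait,
                "pearson_r": a.pearson_r,
                "p_value": a.p_value,
                "significant": a.significant,
            }
            for a in associations
        ]
    ).to_csv(path, sep="\t", index=False)
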