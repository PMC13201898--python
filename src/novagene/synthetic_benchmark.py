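"""Synthetic differential co-expression benchmark with known ground truth.

The generator emulates a two-condition expression study: 300 genes over 100
samples (50 healthy, 50 diseased), with 150 genes co-expressing
predominantly within the diseased group and the remaining 150 within the
healthy group.  Each module is driven by a per-sample latent activity with
a cubic nonlinearity, and gene values are produced on the log-intensity
scale (so the implied raw intensities are heavy-tailed log-normal):

    x_gs = mu_g + b_g * w_c(s) * (delta + z_cs + gamma * z_cs^3) + sigma * eps_gs

where z_cs ~ N(0,1) is the condition-c driver at sample s, delta is the
mean activation level of an engaged module (so module genes are induced,
not merely covarying, when their module is active), and the coupling
weight w_c(s) is 1 when sample s belongs to the module's condition and
(1 - p) otherwise.  Loadings b_g follow a Pareto law, giving each module a
hub structure: a few strongly-coupled driver genes and many peripheral
ones, so node strengths of the resulting co-expression networks are
heavy-tailed the way biological networks are.  The variability parameter
p in [0, 1] controls how condition-specific the true modules are: low p
lets both modules co-express in both conditions (high overlap — the hard,
sepsis-like case), high p makes co-expression nearly exclusive to the
module's own condition.

Detection methods are scored against the ground truth by micro-averaged
precision and recall over the two conditions; precision is reported as NA
when a method predicts nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisConfig, ConditionDesign, ExpressionMatrix
from .module_comparison import ModuleComparisonResult, comparison_matrix
from .module_detection import cluster_modules, topological_overlap
from .network_builder import ConditionNetwork, build_condition_network
from .baseline_linear import TraitAssociation, run_pooled_pipeline

logger = logging.getLogger(__name__)

HEALTHY = "healthy"
DISEASED = "diseased"
TRAIT = "diseased"  # binary indicator: 1 = diseased


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic two-condition generator.

    ``activation_mean`` (delta) is the latent activity level of an engaged
    module in units of the driver's scale; the default 2.0 is one standard
    deviation of the nonlinear activity ``z + gamma z^3`` (sd ~ 2.04 at
    gamma = 0.3), i.e. activation signal-to-fluctuation of one.
    ``loading_scale``/``loading_tail_exponent`` set the Pareto law of gene
    loadings (minimum coupling 0.5, tail exponent 2.5 in the range reported
    for biological degree distributions).
    """

    n_genes: int = 300
    n_samples_per_condition: int = 50
    n_module_genes_per_condition: int = 150
    p: float = 0.5
    cubic_coefficient: float = 0.3
    activation_mean: float = 2.0
    loading_scale: float = 0.5
    loading_tail_exponent: float = 2.5
    mu_sd: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.n_genes < 2 or self.n_samples_per_condition < 3:
            raise ValueError("need at least 2 genes and 3 samples per condition")
        if 2 * self.n_module_genes_per_condition > self.n_genes:
            raise ValueError("module genes exceed total genes")


@dataclass(frozen=True)
class SyntheticDataset:
    expr: ExpressionMatrix
    design: ConditionDesign
    truth: dict[str, str]  # gene -> 'healthy_module' | 'diseased_module'
    config: SyntheticConfig

    def truth_genes(self, condition: str) -> frozenset[str]:
        label = f"{condition}_module"
        return frozenset(g for g, t in self.truth.items() if t == label)


@dataclass(frozen=True)
class BenchmarkScores:
    """Replicate-averaged precision/recall of one method at one p setting."""

    method: str
    p: float
    precision: float | None  # mean over defined replicates, None if all NA
    recall: float
    replicate_seeds: tuple[int, ...]
    per_replicate: tuple[tuple[float | None, float], ...]
    n_na_precision: int
    n_failed: int = 0


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic dataset; fully deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_per = cfg.n_samples_per_condition
    n_samples = 2 * n_per
    samples = tuple(
        [f"H{i+1:03d}" for i in range(n_per)] + [f"D{i+1:03d}" for i in range(n_per)]
    )
    conditions = (HEALTHY,) * n_per + (DISEASED,) * n_per
    is_diseased = np.array([c == DISEASED for c in conditions])

    gamma = cfg.cubic_coefficient
    drivers = {
        HEALTHY: rng.standard_normal(n_samples),
        DISEASED: rng.standard_normal(n_samples),
    }
    gene_ids = tuple(f"gene{i+1:04d}" for i in range(cfg.n_genes))
    n_mod = cfg.n_module_genes_per_condition
    truth = {}
    for i, g in enumerate(gene_ids):
        if i < n_mod:
            truth[g] = f"{DISEASED}_module"
        elif i < 2 * n_mod:
            truth[g] = f"{HEALTHY}_module"
        else:
            truth[g] = "background"

    values = np.empty((cfg.n_genes, n_samples))
    for i, g in enumerate(gene_ids):
        mu = rng.normal(0.0, cfg.mu_sd)
        # Pareto(scale, tail exponent) loading: hub-dominated coupling
        b = cfg.loading_scale * (1.0 - rng.random()) ** (
            -1.0 / cfg.loading_tail_exponent
        )
        eps = rng.standard_normal(n_samples)
        if truth[g] == f"{DISEASED}_module":
            z = drivers[DISEASED]
            w = np.where(is_diseased, 1.0, 1.0 - cfg.p)
        elif truth[g] == f"{HEALTHY}_module":
            z = drivers[HEALTHY]
            w = np.where(is_diseased, 1.0 - cfg.p, 1.0)
        else:
            z = np.zeros(n_samples)
            w = np.zeros(n_samples)
        activity = cfg.activation_mean + z + gamma * z**3
        values[i] = mu + b * w * activity + cfg.noise_sd * eps

    expr = ExpressionMatrix(gene_ids, samples, values)
    traits = pd.DataFrame({TRAIT: is_diseased.astype(int)}, index=list(samples))
    design = ConditionDesign(samples, conditions, traits)
    return SyntheticDataset(expr=expr, design=design, truth=truth, config=cfg)


def evaluate_detection(
    predicted: Mapping[str, Iterable[str]], dataset: SyntheticDataset
) -> tuple[float | None, float]:
    """Micro-averaged (precision, recall) of per-condition predictions.

    ``predicted`` maps condition label -> predicted-positive gene set.
    Precision is None (NA) when nothing is predicted in either condition.
    """
    universe = set(dataset.expr.gene_ids)
    tp = fp = fn = 0
    for condition in (HEALTHY, DISEASED):
        pred = set(predicted.get(condition, ()))
        unknown = pred - universe
        if unknown:
            raise ValueError(f"predicted genes not in dataset: {sorted(unknown)[:5]}")
        true = set(dataset.truth_genes(condition))
        tp += len(pred & true)
        fp += len(pred - true)
        fn += len(true - pred)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return precision, recall


def predicted_positives_novagene(
    comparison: ModuleComparisonResult,
    partition_a,
    partition_b,
    condition_a: str,
    condition_b: str,
) -> dict[str, set[str]]:
    """Genes of modules participating in at least one significant cell."""
    sig = comparison.significant
    mods_a = {m for m in comparison.modules_a if sig.loc[m].any()}
    mods_b = {
        m for m in comparison.modules_b if sig[m].any()
    }
    pred_a: set[str] = set()
    for m in mods_a:
        pred_a.update(partition_a.genes_in(m))
    pred_b: set[str] = set()
    for m in mods_b:
        pred_b.update(partition_b.genes_in(m))
    return {condition_a: pred_a, condition_b: pred_b}


def predicted_positives_baseline(
    partition, associations: Sequence[TraitAssociation], trait: str = TRAIT
) -> dict[str, set[str]]:
    """Split significantly trait-associated module genes by correlation sign.

    With the diseased indicator as trait (1 = diseased), a significant
    positive correlation marks a module's genes as diseased-predicted and a
    significant negative one as healthy-predicted.
    """
    pred: dict[str, set[str]] = {HEALTHY: set(), DISEASED: set()}
    for a in associations:
        if a.trait != trait or not a.significant:
            continue
        target = DISEASED if a.pearson_r > 0 else HEALTHY
        pred[target].update(partition.genes_in(a.module_label))
    return pred


def run_novagene_on(
    dataset: SyntheticDataset, config: AnalysisConfig | None = None
) -> dict[str, set[str]]:
    """Full per-condition pipeline on a synthetic dataset -> predictions."""
    config = (config or AnalysisConfig()).with_mode("dcor")
    nets: dict[str, ConditionNetwork] = {}
    partitions = {}
    for condition in (HEALTHY, DISEASED):
        net = build_condition_network(dataset.expr, dataset.design, condition, config)
        tom = topological_overlap(net.adjacency, net.gene_ids)
        nets[condition] = net
        partitions[condition] = cluster_modules(tom, config)
    if not partitions[HEALTHY].module_labels or not partitions[DISEASED].module_labels:
        # a network without modules is a legitimate zero-detection outcome
        logger.info("no modules in at least one condition network; nothing detected")
        return {HEALTHY: set(), DISEASED: set()}
    comparison = comparison_matrix(
        nets[HEALTHY], nets[DISEASED],
        partitions[HEALTHY], partitions[DISEASED],
        dataset.expr, dataset.design, config,
    )
    return predicted_positives_novagene(
        comparison, partitions[HEALTHY], partitions[DISEASED], HEALTHY, DISEASED
    )


def run_baseline_on(
    dataset: SyntheticDataset, mode: str, config: AnalysisConfig | None = None
) -> dict[str, set[str]]:
    """Pooled baseline pipeline on a synthetic dataset -> predictions."""
    partition, _, associations = run_pooled_pipeline(
        dataset.expr, dataset.design, mode, config
    )
    return predicted_positives_baseline(partition, associations)


METHOD_RUNNERS = {
    "novagene": lambda ds, cfg: run_novagene_on(ds, cfg),
    "wgcna_pearson": lambda ds, cfg: run_baseline_on(ds, "pearson", cfg),
    "wgcna_dcor": lambda ds, cfg: run_baseline_on(ds, "dcor", cfg),
}


def run_benchmark(
    methods: Sequence[str],
    p_values: Sequence[float],
    n_replicates: int = 20,
    base_seed: int = 1,
    synth: SyntheticConfig | None = None,
    config: AnalysisConfig | None = None,
) -> list[BenchmarkScores]:
    """Replicate benchmark of detection methods across variability settings.

    Replicate r uses generator seed ``base_seed + r``; each method is run on
    the same replicate datasets.  Precision means exclude NA replicates,
    whose count is reported; replicate failures are logged and skipped.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    unknown = [m for m in methods if m not in METHOD_RUNNERS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    synth = synth or SyntheticConfig()
    results: list[BenchmarkScores] = []
    for p in p_values:
        seeds = tuple(base_seed + r for r in range(n_replicates))
        datasets = [
            generate_dataset(replace(synth, p=p, seed=s)) for s in seeds
        ]
        for method in methods:
            per_rep: list[tuple[float | None, float]] = []
            n_failed = 0
            for ds in datasets:
                try:
                    predicted = METHOD_RUNNERS[method](ds, config)
                    per_rep.append(evaluate_detection(predicted, ds))
                except Exception:
                    logger.exception(
                        "replicate seed=%d failed for %s at p=%.2f",
                        ds.config.seed, method, p,
                    )
                    n_failed += 1
            precisions = [pr for pr, _ in per_rep if pr is not None]
            recalls = [rc for _, rc in per_rep]
            results.append(
                BenchmarkScores(
                    method=method,
                    p=float(p),
                    precision=float(np.mean(precisions)) if precisions else None,
                    recall=float(np.mean(recalls)) if recalls else 0.0,
                    replicate_seeds=seeds,
                    per_replicate=tuple(per_rep),
                    n_na_precision=len(per_rep) - len(precisions),
                    n_failed=n_failed,
                )
            )
    return results


def scores_table(results: Sequence[BenchmarkScores]) -> pd.DataFrame:
    """Summary table with precision/recall on the percent scale."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "p": r.p,
                "mean_precision_pct": (
                    np.nan if r.precision is None else 100.0 * r.precision
                ),
                "mean_recall_pct": 100.0 * r.recall,
                "n_replicates": len(r.per_replicate),
                "n_na_precision": r.n_na_precision,
                "n_failed": r.n_failed,
            }
        )
    return pd.DataFrame(rows)
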