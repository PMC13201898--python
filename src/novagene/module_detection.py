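"""Topological overlap and hierarchical module detection.

The topological overlap matrix (TOM) augments direct adjacency with shared
neighborhood: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
l_ij = sum_u a_iu a_uj, the unsigned Zhang-Horvath formulation.  Modules
are branches of an average-linkage tree on the dissimilarity 1 - TOM, cut
at a fixed quantile of the merge heights; branches below the minimum size
fall into the grey background.  Module labels are color names assigned in
decreasing size order (turquoise, blue, brown, ...), matching the naming
convention of the weighted co-expression analysis ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_model import AnalysisConfig

GREY = "grey"

# WGCNA-style palette, grey reserved for background; recycled with numeric
# suffixes if more modules than colors arise.
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass(frozen=True)
class TopologicalOverlap:
    gene_ids: tuple[str, ...]
    values: np.ndarray


@dataclass(frozen=True)
class ModulePartition:
    """Gene -> module-color assignment with a grey background label."""

    assignments: dict[str, str]
    sizes: dict[str, int]

    def genes_in(self, module: str) -> tuple[str, ...]:
        return tuple(g for g, m in self.assignments.items() if m == module)

    @property
    def module_labels(self) -> tuple[str, ...]:
        """Non-grey module labels in decreasing size order."""
        return tuple(
            sorted((m for m in self.sizes if m != GREY), key=lambda m: -self.sizes[m])
        )


def topological_overlap(
    adjacency: np.ndarray, gene_ids: Sequence[str] | None = None
) -> TopologicalOverlap:
    """Unsigned topological overlap of a weighted adjacency matrix."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(a.shape[0]))
    return TopologicalOverlap(gene_ids=tuple(gene_ids), values=tom)


def _color_labels(n: int) -> list[str]:
    labels = list(MODULE_COLORS)
    cycle = 2
    while len(labels) < n:
        labels.extend(f"{c}{cycle}" for c in MODULE_COLORS)
        cycle += 1
    return labels[:n]


def cluster_modules(
    tom: TopologicalOverlap, config: AnalysisConfig | None = None
) -> ModulePartition:
    """Detect modules by average-linkage clustering of 1 - TOM.

    The tree is cut at the configured quantile of the merge heights
    (default 0.99); clusters of at least ``min_module_size`` genes become
    modules, everything else is grey.
    """
    config = config or AnalysisConfig()
    values = np.asarray(tom.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("TOM must be square")
    genes = list(tom.gene_ids)
    n = len(genes)
    if n < config.min_module_size:
        return ModulePartition(
            assignments={g: GREY for g in genes}, sizes={GREY: n}
        )
    dissim = 1.0 - values
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    np.fill_diagonal(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False),
                             method=config.linkage_method)
    heights = link[:, 2]
    cut = float(np.quantile(heights, config.cut_quantile))
    flat = hierarchy.fcluster(link, t=cut, criterion="distance")

    cluster_sizes = pd.Series(flat).value_counts()
    big = [int(c) for c in cluster_sizes.index if
           cluster_sizes[c] >= config.min_module_size]
    # deterministic label order: size desc, then smallest member gene id
    def _first_gene(c: int) -> str:
        return min(genes[i] for i in range(n) if flat[i] == c)

    big.sort(key=lambda c: (-int(cluster_sizes[c]), _first_gene(c)))
    colors = _color_labels(len(big))
    color_of = {c: colors[i] for i, c in enumerate(big)}
    assignments = {
        g: color_of.get(int(c), GREY) for g, c in zip(genes, flat)
    }
    sizes: dict[str, int] = {}
    for m in assignments.values():
        sizes[m] = sizes.get(m, 0) + 1
    return ModulePartition(assignments=assignments, sizes=sizes)


def write_partition(partition: ModulePartition, path: str | Path) -> None:
    """Export gene -> module assignment as TSV."""
    rows = [
        {"gene_id": g, "module_label": m, "module_size": partition.sizes[m]}
        for g, m in partition.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
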