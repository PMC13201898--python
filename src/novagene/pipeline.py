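"""End-to-end orchestration of the per-condition comparison run.

``run_novagene`` builds a pruned nonlinear network for each of two
conditions, detects modules in both, computes the cross-condition module
comparison matrix, and writes every artifact (edge lists, metadata,
partitions, hub lists, comparison table, run summary) into an output
directory with a checksummed manifest so a run is reproducible from its
config echo alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .data_model import AnalysisConfig, ConditionDesign, ExpressionMatrix
from .module_comparison import (
    ModuleComparisonResult,
    comparison_matrix,
    module_centrality,
    select_hubs,
    write_comparison,
)
from .module_detection import (
    ModulePartition,
    cluster_modules,
    topological_overlap,
    write_partition,
)
from .network_builder import ConditionNetwork, build_condition_network, export_network

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunBundle:
    networks: dict[str, ConditionNetwork]
    partitions: dict[str, ModulePartition]
    comparison: ModuleComparisonResult
    out_dir: Path | None
    manifest: dict[str, str]
    config: AnalysisConfig


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_novagene(
    expr: ExpressionMatrix,
    design: ConditionDesign,
    condition_pair: tuple[str, str],
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunBundle:
    """Per-condition network comparison between two conditions.

    Raises before any computation if a named condition is absent from the
    design.  Fully deterministic given the configuration.
    """
    config = config or AnalysisConfig()
    cond_a, cond_b = condition_pair
    labels = design.condition_labels
    for c in (cond_a, cond_b):
        if c not in labels:
            raise KeyError(f"condition {c!r} not present in design {labels}")
    design.validate_against(expr)

    networks: dict[str, ConditionNetwork] = {}
    partitions: dict[str, ModulePartition] = {}
    written: list[Path] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    stage = "network construction"
    try:
        for c in (cond_a, cond_b):
            net = build_condition_network(expr, design, c, config)
            networks[c] = net
            tom = topological_overlap(net.adjacency, net.gene_ids)
            partitions[c] = cluster_modules(tom, config)
            if out_path is not None:
                written.extend(export_network(net, out_path))
                ppath = out_path / f"modules_{c}.tsv"
                write_partition(partitions[c], ppath)
                written.append(ppath)
        stage = "module comparison"
        comparison = comparison_matrix(
            networks[cond_a], networks[cond_b],
            partitions[cond_a], partitions[cond_b],
            expr, design, config,
        )
    except Exception as exc:
        manifest = {str(p): _checksum(p) for p in written}
        raise RuntimeError(
            f"run aborted during {stage}: {exc}; partial manifest: "
            f"{sorted(manifest)}"
        ) from exc

    if out_path is not None:
        cpath = out_path / "module_comparison.tsv"
        write_comparison(comparison, cpath)
        written.append(cpath)
        hub_rows = []
        for c in (cond_a, cond_b):
            for module in partitions[c].module_labels:
                cent = module_centrality(networks[c], partitions[c].genes_in(module))
                for rank, g in enumerate(select_hubs(cent, config), start=1):
                    hub_rows.append(
                        {
                            "condition": c,
                            "module": module,
                            "rank": rank,
                            "gene_id": g,
                            "centrality": cent[g],
                        }
                    )
        hpath = out_path / "hub_genes.tsv"
        pd.DataFrame(hub_rows).to_csv(hpath, sep="\t", index=False)
        written.append(hpath)
        summary = {
            "conditions": [cond_a, cond_b],
            "config": dataclasses.asdict(config),
            "stages": {
                c: {
                    "beta": networks[c].soft_threshold.beta,
                    "fit_index": networks[c].soft_threshold.fit_index,
                    "alpha": networks[c].powerlaw.alpha,
                    "xmin": networks[c].powerlaw.xmin,
                    "ks": networks[c].powerlaw.ks_statistic,
                    "n_pruned": len(networks[c].removed_genes),
                    "n_modules": len(partitions[c].module_labels),
                }
                for c in (cond_a, cond_b)
            },
            "n_significant_pairs": len(comparison.significant_pairs()),
        }
        spath = out_path / "run_summary.json"
        spath.write_text(json.dumps(summary, indent=2))
        written.append(spath)

    manifest = {p.name: _checksum(p) for p in written}
    if out_path is not None:
        mpath = out_path / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunBundle(
        networks=networks,
        partitions=partitions,
        comparison=comparison,
        out_dir=out_path,
        manifest=manifest,
        config=config,
    )
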