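"""Core data containers and delimited-text I/O.

The universal input is a genes x samples matrix of already-normalized
expression intensities (log2-like or raw-positive); no transform is applied
here.  A design table maps each sample to a condition label and optional
binary traits.  Missing or non-finite values are rejected rather than
imputed: the downstream dependence measures have no missing-data form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix.

    Attributes
    ----------
    gene_ids : tuple of str
        Unique gene identifiers (rows).
    sample_ids : tuple of str
        Unique sample identifiers (columns).
    values : ndarray, shape (n_genes, n_samples)
        Finite expression values on the input scale.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = values.shape
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise ValueError("identifier lengths do not match matrix shape")
        if n_genes < 1:
            raise ValueError("expression matrix needs at least 1 gene")
        if n_samples < 3:
            raise ValueError("expression matrix needs at least 3 samples")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(values)):
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[gi]!r}, "
                f"sample {self.sample_ids[si]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, samples: Sequence[str]) -> np.ndarray:
        """Column indices of the given sample ids, in the given order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[s] for s in samples], dtype=int)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index(samples)
        return ExpressionMatrix(self.gene_ids, tuple(samples), self.values[:, idx])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        idx = np.array([lookup[g] for g in genes], dtype=int)
        return ExpressionMatrix(tuple(genes), self.sample_ids, self.values[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class ConditionDesign:
    """Sample -> condition mapping with optional binary trait columns."""

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    traits: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.conditions):
            raise ValueError("sample and condition lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in design")
        traits = self.traits
        if not traits.empty:
            if list(traits.index) != list(self.sample_ids):
                raise ValueError("trait rows must be indexed by the design samples")
            bad = ~traits.isin([0, 1]).all(axis=None)
            if bad:
                raise ValueError("trait values must be 0 or 1")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c, None)
        return tuple(seen)

    def samples_for(self, condition: str) -> tuple[str, ...]:
        out = tuple(
            s for s, c in zip(self.sample_ids, self.conditions) if c == condition
        )
        if not out:
            raise KeyError(f"condition {condition!r} not present in design")
        return out

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Every design sample must exist in the matrix; >=3 per condition."""
        expr.sample_index(self.sample_ids)
        for label in self.condition_labels:
            n = len(self.samples_for(label))
            if n < 3:
                raise ValueError(
                    f"condition {label!r} has only {n} samples (minimum 3)"
                )

    def trait_vector(self, name: str, samples: Sequence[str]) -> np.ndarray:
        if name not in self.traits.columns:
            raise KeyError(f"trait {name!r} not in design")
        return self.traits.loc[list(samples), name].to_numpy(dtype=float)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the network pipelines.

    ``soft_threshold_target_r2`` is the scale-free fit criterion used to pick
    the soft-thresholding power from ``beta_grid``; ``fallback_beta`` is used
    when no power in the grid reaches the target (the unsigned-network
    convention for studies of 40+ samples); ``min_module_size`` is the
    minimum gene count of a non-background module; ``n_hubs`` bounds the
    number of hub genes summarized per module; ``alpha_significance`` is the
    two-sided significance level for module comparisons and trait
    associations.
    """

    soft_threshold_target_r2: float = 0.9
    beta_grid: tuple[int, ...] = tuple(range(1, 21))
    fallback_beta: int = 6
    min_module_size: int = 30
    n_hubs: int = 10
    alpha_significance: float = 0.05
    correlation_mode: str = "dcor"
    cut_quantile: float = 0.99
    linkage_method: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.soft_threshold_target_r2 <= 1):
            raise ValueError("soft_threshold_target_r2 must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.n_hubs < 1:
            raise ValueError("n_hubs must be >= 1")
        if not (0 < self.alpha_significance < 1):
            raise ValueError("alpha_significance must be in (0, 1)")
        if self.correlation_mode not in ("pearson", "dcor"):
            raise ValueError("correlation_mode must be 'pearson' or 'dcor'")
        if not self.beta_grid:
            raise ValueError("beta_grid must be non-empty")

    def with_mode(self, mode: str) -> "AnalysisConfig":
        return replace(self, correlation_mode=mode)


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, **kwargs)


def read_expression(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionMatrix:
    """Read a delimited expression table into genes x samples orientation.

    Parameters
    ----------
    path : path to TSV/CSV with one header row and one identifier column.
    orientation : {'genes_in_rows', 'samples_in_rows'}
        Which entities occupy the file's rows.  Never guessed: silent
        transposition is the classic failure mode for these files.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, index_col=0)
    if orientation == "samples_in_rows":
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    if len(gene_ids) < 2:
        raise ValueError(f"expression table {path} has fewer than 2 genes")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any(axis=None):
        gi, si = np.argwhere(bad.to_numpy())[0]
        cell = df.iat[gi, si]
        kind = "missing value" if pd.isna(cell) or str(cell).strip() == "" else (
            f"non-numeric value {cell!r}"
        )
        raise ValueError(
            f"{kind} at gene {gene_ids[gi]!r}, sample {sample_ids[si]!r} in {path}"
        )
    # numpy's parser is correctly rounded; pandas' fast to_numeric path is not
    values = df.to_numpy(dtype=str).astype(float)
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # 17 significant digits guarantee an exact float64 round trip
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_design(path: str | Path) -> ConditionDesign:
    """Read a sample design table (sample_id, condition, optional 0/1 traits)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError("design table needs at least sample_id and condition columns")
    sample_col, condition_col = df.columns[:2]
    sample_ids = [str(s) for s in df[sample_col]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"repeated sample ids in design: {dupes}")
    conditions = tuple(str(c) for c in df[condition_col])
    trait_cols = list(df.columns[2:])
    traits = pd.DataFrame(index=sample_ids)
    for col in trait_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        valid = numeric.isin([0, 1])
        if not valid.all():
            offender = df[col][~valid].iloc[0]
            raise ValueError(
                f"trait column {col!r} has value {offender!r} outside {{0, 1}}"
            )
        traits[col] = numeric.to_numpy(dtype=int)
    return ConditionDesign(tuple(sample_ids), conditions, traits)


def write_design(design: ConditionDesign, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(
        {"sample_id": list(design.sample_ids), "condition": list(design.conditions)}
    )
    for col in design.traits.columns:
        df[col] = design.traits[col].to_numpy()
    df.to_csv(path, sep=sep, index=False)


def filter_zero_variance(
    expr: ExpressionMatrix, scope: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Drop genes that are constant within the given sample scope.

    Required before any correlation stage: a constant profile makes the
    distance-correlation denominator (and the Pearson denominator) zero.
    Idempotent; removals are logged with gene ids.
    """
    if scope is None:
        scope = expr.sample_ids
    if len(scope) == 0:
        raise ValueError("scope must be non-empty")
    idx = expr.sample_index(scope)
    sub = expr.values[:, idx]
    constant = np.ptp(sub, axis=1) == 0
    if constant.all():
        raise ValueError("all genes are constant within scope; nothing left")
    if constant.any():
        removed = [g for g, c in zip(expr.gene_ids, constant) if c]
        logger.info("filter_zero_variance removed %d genes: %s", len(removed), removed)
        keep = [g for g, c in zip(expr.gene_ids, constant) if not c]
        return expr.subset_genes(keep)
    return expr
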