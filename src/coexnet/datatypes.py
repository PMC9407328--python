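"""Core data containers: expression matrix, trait table, annotation table, config.

Expression values are FPKM-like (non-negative, unitless normalized abundances);
genes are rows, samples are columns, matching the on-disk layout. All containers
validate their invariants on construction and are treated as immutable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "TraitTable",
    "AnnotationTable",
    "PipelineConfig",
]


def _check_unique(ids, kind: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate {kind} ID: {dup!r}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative expression values.

    Parameters
    ----------
    data
        DataFrame with gene IDs as the index and sample IDs as columns.
        All values must be finite and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size:
            if not np.all(np.isfinite(values)):
                raise ValidationError("expression values must be finite")
            if values.min() < 0:
                raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Genes x samples array (float)."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_profiles(self) -> np.ndarray:
        """Samples x genes array, the orientation used for correlation work."""
        return self.values.T

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)])


@dataclass(frozen=True)
class TraitTable:
    """Per-sample quantitative trait (wax secretion, mg/individual)."""

    values: pd.Series  # index: sample_id

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("trait values must be finite")
        if arr.size and arr.min() < 0:
            raise ValidationError("trait values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def restrict(self, sample_ids) -> "TraitTable":
        return TraitTable(self.values.loc[list(sample_ids)])

    def aligned_to(self, expr: ExpressionMatrix) -> np.ndarray:
        """Trait vector in the expression matrix's sample order.

        Raises ValidationError listing any expression sample without a trait value.
        """
        missing = [s for s in expr.sample_ids if s not in self.values.index]
        if missing:
            raise ValidationError(
                "samples missing from trait table: " + ", ".join(missing)
            )
        return self.values.loc[expr.sample_ids].to_numpy(dtype=float)


@dataclass(frozen=True)
class AnnotationTable:
    """Optional Swiss-Prot annotation per gene; absence means unannotated."""

    data: pd.DataFrame  # index: gene_id; columns: swissprot_id, description

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        for col in ("swissprot_id", "description"):
            if col not in self.data.columns:
                raise ValidationError(f"annotation table missing column {col!r}")

    @classmethod
    def empty(cls) -> "AnnotationTable":
        return cls(
            pd.DataFrame(
                {"swissprot_id": pd.Series(dtype=str), "description": pd.Series(dtype=str)}
            )
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def is_annotated(self, gene_id: str) -> bool:
        return gene_id in self.data.index

    def description(self, gene_id: str) -> str | None:
        if gene_id not in self.data.index:
            return None
        return str(self.data.loc[gene_id, "description"])


def _default_powers() -> list[int]:
    return list(range(1, 21))


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, validated before any stage runs.

    MAD filtering
      mad_top_fraction : keep genes in the top fraction ranked by MAD (descending).
      mad_floor        : additionally require MAD above this floor.
      mad_scale        : multiplicative constant applied to the raw MAD
                         (1.4826 reproduces R's mad(); set 1.0 for the raw statistic).
    Sample outlier cut
      sample_cut_height : static-cut height on the sample dendrogram; None picks the
                          midpoint between the two highest merges automatically.
      min_cluster_size  : sample clusters smaller than this are dropped (default: the
                          replicate count, so an intact condition always survives).
    Network
      powers, fit_target, network_mode, n_bins, max_genes : soft-threshold scan and
      adjacency construction; max_genes guards the dense TOM against oversized input.
    Module detection
      min_module_size, deep_split (0..3), pam_stage, merge_cut_height.
    Trait relation / hub screen
      module_alpha, adjust_pvalues (optional Benjamini-Hochberg), export_threshold,
      top_k, hub_fraction, hub_sort_key.
    """

    mad_top_fraction: float = 0.75
    mad_floor: float = 0.01
    mad_scale: float = 1.4826
    sample_cut_height: float | None = None
    min_cluster_size: int = 3
    powers: list[int] = field(default_factory=_default_powers)
    fit_target: float = 0.9
    network_mode: str = "unsigned"
    n_bins: int = 10
    max_genes: int = 25000
    min_module_size: int = 20
    deep_split: int = 2
    pam_stage: bool = True
    merge_cut_height: float = 0.15
    module_alpha: float = 0.05
    adjust_pvalues: bool = False
    export_threshold: float = 0.02
    top_k: int = 100
    hub_fraction: float = 0.10
    hub_sort_key: str = "weighted_degree"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.mad_top_fraction <= 1:
            raise ParameterError("mad_top_fraction must be in (0, 1]")
        if self.mad_floor < 0:
            raise ParameterError("mad_floor must be >= 0")
        if self.mad_scale <= 0:
            raise ParameterError("mad_scale must be > 0")
        if self.sample_cut_height is not None and self.sample_cut_height <= 0:
            raise ParameterError("sample_cut_height must be > 0")
        if self.min_cluster_size < 1:
            raise ParameterError("min_cluster_size must be >= 1")
        if not self.powers or list(self.powers) != sorted(self.powers):
            raise ParameterError("powers must be a nonempty ascending list")
        if any(int(p) != p or p < 1 for p in self.powers):
            raise ParameterError("powers must be integers >= 1")
        if not -1 <= self.fit_target <= 1:
            raise ParameterError("fit_target must be in [-1, 1]")
        if self.network_mode not in ("unsigned", "signed"):
            raise ParameterError("network_mode must be 'unsigned' or 'signed'")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if self.max_genes < 2:
            raise ParameterError("max_genes must be >= 2")
        if self.min_module_size < 2:
            raise ParameterError("min_module_size must be >= 2")
        if self.deep_split not in (0, 1, 2, 3):
            raise ParameterError("deep_split must be in 0..3")
        if not 0 <= self.merge_cut_height < 1:
            raise ParameterError("merge_cut_height must be in [0, 1)")
        if not 0 < self.module_alpha <= 1:
            raise ParameterError("module_alpha must be in (0, 1]")
        if not 0 <= self.export_threshold < 1:
            raise ParameterError("export_threshold must be in [0, 1)")
        if self.top_k < 1:
            raise ParameterError("top_k must be >= 1")
        if not 0 < self.hub_fraction <= 1:
            raise ParameterError("hub_fraction must be in (0, 1]")
        if self.hub_sort_key not in ("weighted_degree", "eigenvector"):
            raise ParameterError("hub_sort_key must be 'weighted_degree' or 'eigenvector'")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
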