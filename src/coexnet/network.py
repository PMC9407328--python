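"""Weighted coexpression network construction.

Pearson correlation across samples -> soft-thresholded adjacency
(|cor|^beta unsigned, ((1+cor)/2)^beta signed) -> topological overlap matrix
(TOM). The soft-thresholding power is chosen as the lowest power whose
scale-free topology fit index reaches the target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import ParameterError, ValidationError

__all__ = [
    "AdjacencyMatrix",
    "TOMMatrix",
    "SoftThresholdScan",
    "correlation_matrix",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_similarity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric gene x gene adjacency in [0, 1] with unit diagonal."""

    matrix: np.ndarray
    gene_ids: list[str]
    mode: str  # "unsigned" | "signed"
    beta: int

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class TOMMatrix:
    """Topological overlap similarity in [0, 1] with unit diagonal."""

    matrix: np.ndarray
    gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def dissimilarity(self) -> np.ndarray:
        """1 - TOM, the clustering dissimilarity."""
        d = 1.0 - self.matrix
        np.fill_diagonal(d, 0.0)
        return d


@dataclass(frozen=True)
class SoftThresholdScan:
    """Per-power scale-free fit index and connectivity summaries."""

    table: pd.DataFrame  # columns: power, fit, mean_k, median_k, max_k


def correlation_matrix(expr: ExpressionMatrix, max_genes: int | None = None) -> np.ndarray:
    """Gene x gene Pearson correlation across samples.

    Inputs must be complete (no missing values) and free of constant genes;
    both are guaranteed downstream of the MAD filter with a positive floor.
    """
    if expr.n_samples < 3:
        raise ValidationError("correlation needs at least 3 samples")
    if max_genes is not None and expr.n_genes > max_genes:
        raise ParameterError(
            f"{expr.n_genes} genes exceed the dense-matrix guard ({max_genes}); "
            "raise max_genes explicitly to run anyway (slow)"
        )
    values = expr.values
    sds = values.std(axis=1)
    if np.any(sds == 0):
        gene = expr.gene_ids[int(np.argmax(sds == 0))]
        raise ValidationError(f"constant gene {gene!r} has undefined correlation")
    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def adjacency(
    cor: np.ndarray,
    beta: int,
    mode: str = "unsigned",
    gene_ids: list[str] | None = None,
) -> AdjacencyMatrix:
    """Soft-threshold the correlation matrix into a weighted adjacency."""
    if beta < 1:
        raise ParameterError("beta must be >= 1")
    if mode == "unsigned":
        a = np.abs(cor) ** beta
    elif mode == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ParameterError(f"unknown adjacency mode: {mode!r}")
    np.fill_diagonal(a, 1.0)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(a.shape[0])]
    return AdjacencyMatrix(matrix=a, gene_ids=list(gene_ids), mode=mode, beta=int(beta))


def connectivity(adj: AdjacencyMatrix) -> np.ndarray:
    """Weighted connectivity k_i = sum_{j != i} a_ij."""
    return adj.matrix.sum(axis=0) - np.diag(adj.matrix)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index and mean connectivity.

    Connectivities are binned into n_bins equal-width bins; log10 of the bin
    frequency is regressed on log10 of the bin mean connectivity over nonempty
    bins, and the R^2 is signed by the negated slope sign (a scale-free network
    has a decreasing log-log relation, hence a positive index).
    """
    k = connectivity(adj)
    mean_k = float(k.mean())
    if np.ptp(k) == 0:
        warnings.warn("all connectivities identical; scale-free fit undefined, using 0")
        return 0.0, mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk = np.full(n_bins, np.nan)
    freq = np.zeros(n_bins)
    for b in range(n_bins):
        members = k[which == b]
        if members.size:
            dk[b] = members.mean()
            freq[b] = members.size / k.size
    valid = (freq > 0) & np.isfinite(dk) & (dk > 0)
    if valid.sum() < 2:
        warnings.warn("fewer than 2 usable connectivity bins; scale-free fit set to 0")
        return 0.0, mean_k
    res = stats.linregress(np.log10(dk[valid]), np.log10(freq[valid]))
    r2 = float(res.rvalue**2)
    fit = -np.sign(res.slope) * r2 if res.slope != 0 else 0.0
    return float(fit), mean_k


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers=None,
    fit_target: float = 0.9,
    mode: str = "unsigned",
    n_bins: int = 10,
    max_genes: int | None = None,
) -> tuple[int, SoftThresholdScan]:
    """Scan candidate powers; choose the lowest one reaching the fit target.

    If no power reaches the target, the power maximizing the fit index is
    chosen and a warning is logged.
    """
    if powers is None:
        powers = list(range(1, 21))
    powers = [int(p) for p in powers]
    if not powers or powers != sorted(powers):
        raise ParameterError("powers must be a nonempty ascending list")
    cor = correlation_matrix(expr, max_genes=max_genes)
    rows = []
    for p in powers:
        adj = adjacency(cor, p, mode=mode, gene_ids=expr.gene_ids)
        fit, mean_k = scale_free_fit(adj, n_bins=n_bins)
        k = connectivity(adj)
        rows.append(
            {
                "power": p,
                "fit": fit,
                "mean_k": mean_k,
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    reached = table[table["fit"] >= fit_target]
    if len(reached):
        chosen = int(reached["power"].iloc[0])
    else:
        chosen = int(table.loc[table["fit"].idxmax(), "power"])
        logger.warning(
            "no power reached fit target %.2f; using power %d with best fit %.3f",
            fit_target,
            chosen,
            table["fit"].max(),
        )
    logger.info("soft threshold chosen: beta=%d", chosen)
    return chosen, SoftThresholdScan(table=table)


def tom_similarity(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu."""
    a = adj.matrix.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    l = a @ a  # (A^2)_ij = sum_u a_iu a_uj; u = i, j terms vanish (zero diagonal)
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0  # symmetrize against round-off
    return TOMMatrix(matrix=tom, gene_ids=adj.gene_ids)
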