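"""Module eigengenes and their relation to the quantitative trait.

The eigengene of a module is the first principal component of its
standardized expression over samples, scaled to unit variance and
sign-aligned with the module's mean standardized profile. Module-trait
association uses the Pearson correlation with the Student asymptotic
p-value t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, TraitTable
from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .modules import ModuleAssignment

__all__ = [
    "EigengeneSet",
    "ModuleTraitMatrix",
    "GeneTraitStats",
    "module_eigengene",
    "compute_eigengenes",
    "cor_pvalue_student",
    "module_trait_relation",
    "select_significant_modules",
    "gene_stats",
    "eigengene_network",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EigengeneSet:
    """Per-module representative sample profiles (unit variance, sign-aligned)."""

    data: pd.DataFrame  # index: sample_id; columns: module color

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def module_colors(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ModuleTraitMatrix:
    """Per-module correlation with the trait: r, p, and samples used."""

    table: pd.DataFrame  # index: module color; columns: r, p, n


@dataclass(frozen=True)
class GeneTraitStats:
    """Per-gene trait significance GS = |cor(gene, trait)| and module
    membership MM = cor(gene, own-module eigengene)."""

    table: pd.DataFrame  # index: gene_id; columns: module, GS, MM


def _standardize(values: np.ndarray, gene_ids) -> np.ndarray:
    """Standardize each gene (row) to mean 0, sample variance 1."""
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    if np.any(sds == 0):
        gene = list(gene_ids)[int(np.argmax(sds.ravel() == 0))]
        raise ValidationError(f"constant gene {gene!r} cannot be standardized")
    return (values - means) / sds


def module_eigengene(expr_module: ExpressionMatrix) -> np.ndarray:
    """First principal component of a module's standardized expression.

    Returns one value per sample, scaled to unit sample variance, with the
    sign chosen so the eigengene correlates non-negatively with the mean
    standardized module expression.
    """
    if expr_module.n_genes == 0:
        raise ValidationError("eigengene of an empty module is undefined")
    if expr_module.n_samples < 2:
        raise ValidationError("eigengene needs at least 2 samples")
    X = _standardize(expr_module.values, expr_module.gene_ids).T  # samples x genes
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    e = U[:, 0]
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate eigengene (zero variance)")
    e = e / sd
    reference = X.mean(axis=1)
    if np.dot(e - e.mean(), reference - reference.mean()) < 0:
        e = -e
    return e


def compute_eigengenes(expr: ExpressionMatrix, assign: "ModuleAssignment") -> EigengeneSet:
    """Eigengenes for every module (grey included when present)."""
    columns = {}
    labels = sorted(set(int(l) for l in assign.labels))
    for label in labels:
        genes = assign.genes_of_label(label)
        color = assign.label_to_color[label]
        columns[color] = module_eigengene(expr.subset_genes(genes))
    data = pd.DataFrame(columns, index=expr.sample_ids)
    return EigengeneSet(data=data)


def cor_pvalue_student(r: float, n: int) -> float:
    """Two-sided Student asymptotic p-value of a Pearson correlation.

    t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom; |r| = 1
    maps to p = 0.
    """
    if n < 3:
        raise ValidationError("p-value needs n >= 3")
    if abs(r) > 1 + 1e-12:
        raise ValidationError("|r| must be <= 1")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_relation(eigs: EigengeneSet, trait: TraitTable) -> ModuleTraitMatrix:
    """Correlate each module eigengene with the trait."""
    missing = [s for s in eigs.sample_ids if s not in trait.values.index]
    if missing:
        raise ValidationError("samples missing from trait table: " + ", ".join(missing))
    t = trait.values.loc[eigs.sample_ids].to_numpy(dtype=float)
    n = len(t)
    rows = {}
    for color in eigs.module_colors:
        e = eigs.data[color].to_numpy(dtype=float)
        if np.std(t) == 0:
            r = 0.0
        else:
            r = float(np.clip(np.corrcoef(e, t)[0, 1], -1.0, 1.0))
        rows[color] = {"r": r, "p": cor_pvalue_student(r, n), "n": n}
    table = pd.DataFrame.from_dict(rows, orient="index")[["r", "p", "n"]]
    return ModuleTraitMatrix(table=table)


def select_significant_modules(
    mt: ModuleTraitMatrix, alpha: float = 0.05, adjust: bool = False
) -> list[str]:
    """Modules with p < alpha, ascending p; grey is never selected.

    With adjust=True, Benjamini-Hochberg-adjusted p-values are compared to
    alpha instead of the raw ones (off by default).
    """
    table = mt.table.drop(index="grey", errors="ignore")
    p = table["p"].to_numpy(dtype=float)
    if adjust and len(p):
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            prev = min(prev, p[idx] * m / rank)
            adj[idx] = prev
        p = adj
    selected = table.index[p < alpha]
    return sorted(selected, key=lambda c: float(table.loc[c, "p"]))


def gene_stats(
    expr: ExpressionMatrix,
    trait: TraitTable,
    eigs: EigengeneSet,
    assign: "ModuleAssignment",
) -> GeneTraitStats:
    """GS and MM for every gene (MM against the gene's own module eigengene)."""
    t = trait.aligned_to(expr)
    values = expr.values
    colors = assign.color_per_gene()
    gs = np.empty(expr.n_genes)
    mm = np.empty(expr.n_genes)
    t_c = t - t.mean()
    t_norm = np.sqrt((t_c**2).sum())
    eig_arrays = {
        c: eigs.data[c].to_numpy(dtype=float) for c in eigs.module_colors
    }
    for i, (row, color) in enumerate(zip(values, colors)):
        r_c = row - row.mean()
        r_norm = np.sqrt((r_c**2).sum())
        if r_norm == 0 or t_norm == 0:
            gs[i] = 0.0
        else:
            gs[i] = abs(float(np.dot(r_c, t_c) / (r_norm * t_norm)))
        e = eig_arrays.get(color)
        if e is None or r_norm == 0:
            mm[i] = np.nan
        else:
            e_c = e - e.mean()
            mm[i] = float(np.dot(r_c, e_c) / (r_norm * np.sqrt((e_c**2).sum())))
    table = pd.DataFrame(
        {"module": colors, "GS": np.clip(gs, 0.0, 1.0), "MM": np.clip(mm, -1.0, 1.0)},
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    return GeneTraitStats(table=table)


def eigengene_network(eigs: EigengeneSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eigengene dissimilarity 1 - cor and adjacency (1 + cor) / 2."""
    if len(eigs.module_colors) < 2:
        raise ValidationError("eigengene network needs at least 2 modules")
    cor = np.clip(np.corrcoef(eigs.data.to_numpy(dtype=float).T), -1.0, 1.0)
    diss = 1.0 - cor
    np.fill_diagonal(diss, 0.0)
    adj = (1.0 + cor) / 2.0
    np.fill_diagonal(adj, 1.0)
    cols = eigs.module_colors
    return (
        pd.DataFrame(diss, index=cols, columns=cols),
        pd.DataFrame(adj, index=cols, columns=cols),
    )
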