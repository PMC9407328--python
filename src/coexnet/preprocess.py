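"""Expression cleaning and sample outlier removal.

The cleaning protocol: drop genes with zero expression in every sample, rank
the remainder by median absolute deviation (MAD) and keep the top fraction
whose MAD also exceeds a floor, then cluster samples by Euclidean distance
with average linkage (UPGMA) and drop samples that fall into small clusters
under a static cut of the dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datatypes import ExpressionMatrix, TraitTable
from .errors import CoexnetError, ValidationError

__all__ = [
    "FilterReport",
    "SampleDendrogram",
    "remove_zero_genes",
    "mad",
    "mad_filter",
    "euclidean_distance",
    "cluster_samples",
    "suggest_cut_height",
    "remove_outlier_samples",
]

logger = logging.getLogger(__name__)

#: Scale constant making the MAD a consistent estimator of the normal sd,
#: the default of R's mad().
R_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class FilterReport:
    """Gene counts before/after each filter; counts always reconcile."""

    n_input_genes: int
    n_zero_removed: int
    n_after_zero: int
    n_retained_mad: int
    mad_fraction: float
    mad_floor: float

    def __post_init__(self) -> None:
        if self.n_input_genes != self.n_zero_removed + self.n_after_zero:
            raise ValidationError("filter report counts do not reconcile")
        if self.n_retained_mad > self.n_after_zero:
            raise ValidationError("retained count exceeds post-zero count")


@dataclass(frozen=True)
class SampleDendrogram:
    """UPGMA tree over samples (scipy linkage matrix, Euclidean heights)."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def remove_zero_genes(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Drop genes whose expression is 0 in every sample."""
    values = expr.values
    nonzero = values.any(axis=1)
    count = int((~nonzero).sum())
    kept = ExpressionMatrix(expr.data.loc[nonzero])
    logger.info("zero-gene filter: %d of %d genes removed", count, expr.n_genes)
    return kept, count


def mad(values, scale: float = R_MAD_SCALE) -> float:
    """Median absolute deviation, median(|x - median(x)|) * scale.

    The default scale 1.4826 matches R's mad(); pass scale=1.0 for the raw
    statistic.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("mad of an empty vector is undefined")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("mad input contains non-finite values")
    return float(np.median(np.abs(arr - np.median(arr))) * scale)


def mad_filter(
    expr: ExpressionMatrix,
    top_fraction: float = 0.75,
    floor: float = 0.01,
    scale: float = R_MAD_SCALE,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes in the top fraction by MAD (descending) whose MAD exceeds floor.

    Ranking keeps the first ceil(top_fraction * n) genes after a stable
    descending sort, so ties are broken by input order and survivor order
    equals input order.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    values = expr.values
    if expr.n_genes == 0:
        report = FilterReport(0, 0, 0, 0, top_fraction, floor)
        return expr, report
    mads = np.median(np.abs(values - np.median(values, axis=1, keepdims=True)), axis=1)
    mads = mads * scale
    n = expr.n_genes
    n_top = int(np.ceil(top_fraction * n))
    # stable sort ascending on -mad = descending on mad, ties by input order
    order = np.argsort(-mads, kind="stable")
    in_top = np.zeros(n, dtype=bool)
    in_top[order[:n_top]] = True
    keep = in_top & (mads > floor)
    kept = ExpressionMatrix(expr.data.loc[keep])
    report = FilterReport(
        n_input_genes=n,
        n_zero_removed=0,
        n_after_zero=n,
        n_retained_mad=int(keep.sum()),
        mad_fraction=top_fraction,
        mad_floor=floor,
    )
    logger.info(
        "MAD filter: kept %d of %d genes (top %.0f%%, floor %g)",
        report.n_retained_mad,
        n,
        100 * top_fraction,
        floor,
    )
    return kept, report


def euclidean_distance(x, y) -> float:
    """Euclidean distance between two sample profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("profiles have different lengths")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def cluster_samples(expr: ExpressionMatrix) -> SampleDendrogram:
    """UPGMA (average-linkage) clustering of samples on Euclidean distance."""
    if expr.n_samples < 2:
        raise ValidationError("sample clustering needs at least 2 samples")
    profiles = expr.sample_profiles()
    Z = linkage(pdist(profiles, metric="euclidean"), method="average")
    return SampleDendrogram(linkage_matrix=Z, sample_ids=expr.sample_ids)


def suggest_cut_height(dend: SampleDendrogram) -> float:
    """Midpoint between the two highest merges: isolates a late-joining outlier
    while splitting a clean tree into large clusters that all survive."""
    h = np.sort(dend.heights)
    if len(h) == 1:
        return float(h[0] / 2)
    return float((h[-1] + h[-2]) / 2)


def remove_outlier_samples(
    dend: SampleDendrogram,
    expr: ExpressionMatrix,
    trait: TraitTable,
    cut_height: float,
    min_cluster_size: int = 3,
) -> tuple[ExpressionMatrix, TraitTable, list[str]]:
    """Static cut of the sample dendrogram; drop samples in small clusters.

    Clusters of size >= min_cluster_size survive; everything else is removed.
    The expression matrix and trait table are restricted consistently; values
    of retained entries are untouched.
    """
    if cut_height <= 0:
        raise ValidationError("cut_height must be > 0")
    labels = fcluster(dend.linkage_matrix, t=cut_height, criterion="distance")
    ids = np.asarray(dend.sample_ids)
    keep_ids: list[str] = []
    for lab in np.unique(labels):
        members = ids[labels == lab]
        if len(members) >= min_cluster_size:
            keep_ids.extend(members)
    if not keep_ids:
        raise CoexnetError("cut height removes every sample")
    kept_order = [s for s in expr.sample_ids if s in set(keep_ids)]
    removed = [s for s in expr.sample_ids if s not in set(keep_ids)]
    expr_out = expr.subset_samples(kept_order)
    trait_out = trait.restrict([s for s in kept_order if s in trait.values.index])
    if removed:
        logger.info("outlier cut at %g removed samples: %s", cut_height, removed)
    return expr_out, trait_out, removed
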