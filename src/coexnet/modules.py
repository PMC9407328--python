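"""Module detection: gene clustering on TOM dissimilarity, adaptive tree
cutting, eigengene-based module merging, and color naming.

The tree cut is a native implementation in the Dynamic Hybrid spirit: the
gene dendrogram is severed near its top, each remaining subtree is
decomposed at its real junctions (judged by topological-overlap contrast,
robust to the stragglers that chain onto genuine modules at high heights),
loose branches are rejected, and leftover genes are finally offered to the
nearest module by average dissimilarity (a PAM-like stage). This stage is
validated by planted-module recovery on synthetic data, not label-for-label
equality with any particular reference implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix
from .errors import ParameterError, ValidationError
from .network import TOMMatrix

__all__ = [
    "GeneDendrogram",
    "ModuleAssignment",
    "MODULE_COLOR_PALETTE",
    "cluster_genes",
    "dynamic_tree_cut",
    "merge_close_modules",
    "assign_colors",
]

logger = logging.getLogger(__name__)

#: Canonical module color sequence (grey is reserved for unassigned genes).
MODULE_COLOR_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
]

# Required topological-overlap contrast per deep_split level: a junction is a
# real module boundary (and a branch is tight enough to emit) when the mean
# within-branch similarity exceeds this multiple of the relevant outside
# similarity. Higher deep_split splits more readily and accepts looser
# modules; contrasts (rather than absolute heights) keep the criterion
# meaningful when TOM values compress toward 0 at high soft powers.
_MIN_CONTRAST = {0: 4.0, 1: 3.0, 2: 2.0, 3: 1.5}


@dataclass(frozen=True)
class GeneDendrogram:
    """Average-linkage tree of genes on dissTOM = 1 - TOM (heights in [0, 1])."""

    linkage_matrix: np.ndarray
    gene_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


@dataclass(frozen=True)
class ModuleAssignment:
    """Gene -> module label (0 = unassigned/grey) with color names.

    Labels are contiguous 1..M ordered by decreasing module size; colors follow
    the canonical palette, with ties in size broken by the input order of the
    modules' first member genes.
    """

    gene_ids: list[str]
    labels: np.ndarray
    label_to_color: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.labels):
            raise ValidationError("gene_ids and labels length mismatch")
        present = sorted(set(int(l) for l in self.labels) - {0})
        if present and present != list(range(1, len(present) + 1)):
            raise ValidationError("module labels must be contiguous 1..M")
        for lab in present + [0]:
            if lab not in self.label_to_color:
                raise ValidationError(f"no color for label {lab}")

    @property
    def n_modules(self) -> int:
        return len(set(int(l) for l in self.labels) - {0})

    def sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}

    @property
    def module_colors(self) -> list[str]:
        """Colors of real modules, in label order (size-descending)."""
        return [self.label_to_color[l] for l in range(1, self.n_modules + 1)]

    def color_per_gene(self) -> list[str]:
        return [self.label_to_color[int(l)] for l in self.labels]

    def genes_of_label(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if int(l) == label]

    def genes_of_color(self, color: str) -> list[str]:
        label = self.label_of_color(color)
        return self.genes_of_label(label)

    def label_of_color(self, color: str) -> int:
        for lab, col in self.label_to_color.items():
            if col == color:
                return lab
        raise KeyError(f"no module named {color!r}")


def cluster_genes(tom: TOMMatrix) -> GeneDendrogram:
    """Average-linkage hierarchical clustering of genes on 1 - TOM."""
    if tom.n_genes < 2:
        raise ValidationError("gene clustering needs at least 2 genes")
    diss = tom.dissimilarity()
    Z = linkage(squareform(diss, checks=False), method="average")
    Z[:, 2] = np.clip(Z[:, 2], 0.0, None)
    return GeneDendrogram(linkage_matrix=Z, gene_ids=tom.gene_ids)


class _Tree:
    """Array-backed view of a scipy linkage matrix for subtree queries."""

    def __init__(self, Z: np.ndarray, n_leaves: int):
        self.Z = Z
        self.n = n_leaves

    def is_leaf(self, node: int) -> bool:
        return node < self.n

    def height(self, node: int) -> float:
        return 0.0 if node < self.n else float(self.Z[node - self.n, 2])

    def children(self, node: int) -> tuple[int, int]:
        row = self.Z[node - self.n]
        return int(row[0]), int(row[1])

    def leaves(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                stack.extend(self.children(v))
        return out

    def internal_heights(self, node: int) -> list[float]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v >= self.n:
                out.append(self.height(v))
                stack.extend(self.children(v))
        return out

    def size(self, node: int) -> int:
        return 1 if node < self.n else int(self.Z[node - self.n, 3])


def dynamic_tree_cut(
    dend: GeneDendrogram,
    diss: np.ndarray,
    min_module_size: int = 20,
    deep_split: int = 2,
    pam_stage: bool = True,
    cut_height: float | None = None,
) -> np.ndarray:
    """Cut the gene dendrogram into raw module labels (0 = unassigned).

    The tree is decomposed at its junctions — merges whose two children each
    span at least ``min_module_size`` leaves. A small branch or singleton
    merging into a larger one is absorption, not a junction, which makes the
    decomposition robust to the stragglers that chain onto real modules at
    high heights. Starting at the root, each branch is walked down its spine
    to its first junction; the branch is emitted whole as a module when it is
    internally tight (mean within-branch topological overlap at least a
    ``deep_split``-dependent multiple of its mean overlap with the rest of
    the network) and the junction is not a real boundary (the overlaps
    within each sub-branch do not clearly exceed the overlap between them);
    otherwise the walk descends into the junction's two sub-branches, leaving
    spine stragglers unassigned. Higher ``deep_split`` accepts looser
    branches and splits more readily. Branches below ``min_module_size`` are
    discarded; if ``pam_stage``, each unlabelled gene then joins the module
    with the smallest average dissimilarity, provided it is closer to that
    module than to the remaining unlabelled genes and no farther from it
    than the module's most peripheral member.
    """
    if min_module_size < 2:
        raise ParameterError("min_module_size must be >= 2")
    if deep_split not in _MIN_CONTRAST:
        raise ParameterError("deep_split must be in 0..3")
    Z = dend.linkage_matrix
    n = len(dend.gene_ids)
    diss = np.asarray(diss, dtype=float)
    if diss.shape != (n, n):
        raise ValidationError("dissimilarity shape does not match the dendrogram")
    heights = Z[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    if cut_height is None:
        cut_height = h_min + 0.99 * (h_max - h_min)
    tree = _Tree(Z, n)

    sim = 1.0 - diss  # topological overlap
    contrast = _MIN_CONTRAST[deep_split]
    all_idx = np.arange(n)

    def mean_within_sim(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return 1.0
        sub = sim[np.ix_(idx, idx)]
        total = sub.sum() - np.trace(sub)
        return float(total / (len(idx) * (len(idx) - 1)))

    def is_tight(idx: np.ndarray) -> bool:
        rest = np.setdiff1d(all_idx, idx, assume_unique=True)
        if not len(rest):
            return True
        s_in = mean_within_sim(idx)
        s_out = float(sim[np.ix_(idx, rest)].mean())
        return s_in >= contrast * max(s_out, 1e-12)

    def first_junction(v: int) -> int | None:
        """Walk the spine of v (following the large child) to the first merge
        whose children both hold >= min_module_size leaves."""
        while not tree.is_leaf(v):
            a, b = tree.children(v)
            if tree.size(a) >= min_module_size and tree.size(b) >= min_module_size:
                return v
            v = a if tree.size(a) >= tree.size(b) else b
        return None

    def junction_is_real(junction: int) -> tuple[bool, int, int]:
        a, b = tree.children(junction)
        ia = np.asarray(tree.leaves(a))
        ib = np.asarray(tree.leaves(b))
        s_between = float(sim[np.ix_(ia, ib)].mean())
        s_within = min(mean_within_sim(ia), mean_within_sim(ib))
        return s_within >= contrast * max(s_between, 1e-12), a, b

    labels = np.zeros(n, dtype=int)
    next_label = 1

    def emit(idx: np.ndarray) -> None:
        """Label a branch, trimming members that barely overlap with it
        (stragglers absorbed on the way up the tree)."""
        nonlocal next_label
        sub = sim[np.ix_(idx, idx)]
        member_sim = (sub.sum(axis=1) - np.diag(sub)) / max(len(idx) - 1, 1)
        kept = idx[member_sim >= np.median(member_sim) / 3.0]
        if len(kept) >= min_module_size:
            labels[kept] = next_label
            next_label += 1

    # Sever the tree at the cut height and walk each remaining subtree.
    parent = np.full(2 * n - 1, -1, dtype=int)
    for i in range(n - 1):
        parent[int(Z[i, 0])] = parent[int(Z[i, 1])] = n + i
    stack = [
        v
        for v in range(2 * n - 1)
        if tree.height(v) <= cut_height
        and (parent[v] == -1 or tree.height(parent[v]) > cut_height)
    ]
    while stack:
        v = stack.pop()
        idx = np.asarray(tree.leaves(v))
        junction = first_junction(v)
        if junction is None:
            # cohesive terminal branch; spine stragglers were already skipped
            if len(idx) >= min_module_size and is_tight(idx):
                emit(idx)
            continue
        real, a, b = junction_is_real(junction)
        if not real and len(idx) >= min_module_size and is_tight(idx):
            emit(idx)
        else:
            # descend; stragglers on the spine above the junction stay unassigned
            stack.extend((a, b))

    if pam_stage and next_label > 1:
        labels = _pam_assign(labels, diss)
    n_mod = len(set(labels) - {0})
    logger.info(
        "tree cut: %d modules, %d of %d genes unassigned",
        n_mod,
        int((labels == 0).sum()),
        n,
    )
    return labels


def _pam_assign(labels: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Offer unassigned genes to the nearest module (see dynamic_tree_cut).

    A gene joins the module with the highest mean topological overlap if it
    overlaps that module more than it overlaps the remaining unassigned
    genes, and at least a third as strongly as the module's median member —
    the same membership rule the branch trim applies.
    """
    labels = labels.copy()
    module_ids = sorted(set(labels) - {0})
    unassigned = np.where(labels == 0)[0]
    if not len(unassigned) or not module_ids:
        return labels
    sim = 1.0 - diss
    members = {m: np.where(labels == m)[0] for m in module_ids}
    member_floor = {}
    for m, idx in members.items():
        sub = sim[np.ix_(idx, idx)]
        member_sim = (sub.sum(axis=1) - np.diag(sub)) / max(len(idx) - 1, 1)
        member_floor[m] = float(np.median(member_sim)) / 2.0
    new_labels = labels.copy()
    for g in unassigned:
        s_modules = {m: float(sim[g, idx].mean()) for m, idx in members.items()}
        best = max(s_modules, key=lambda m: (s_modules[m], -m))
        others = unassigned[unassigned != g]
        s_bg = float(sim[g, others].mean()) if len(others) else -np.inf
        if s_modules[best] > s_bg and s_modules[best] >= member_floor[best]:
            new_labels[g] = best
    return new_labels


def merge_close_modules(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    merge_cut_height: float = 0.15,
) -> ModuleAssignment:
    """Merge modules whose eigengenes are closer than merge_cut_height.

    Eigengene dissimilarity is 1 - cor(E_I, E_J); modules falling in the same
    average-linkage cluster below the cut are merged. The procedure iterates
    until stable, so it is idempotent. merge_cut_height = 0 disables merging.
    """
    from .traits import module_eigengene  # deferred: traits depends on this module

    labels = np.asarray(labels, dtype=int).copy()
    if merge_cut_height > 0:
        while True:
            module_ids = sorted(set(labels) - {0})
            if len(module_ids) < 2:
                break
            eig = np.column_stack(
                [
                    module_eigengene(
                        expr.subset_genes(
                            [g for g, l in zip(expr.gene_ids, labels) if l == m]
                        )
                    )
                    for m in module_ids
                ]
            )
            cor = np.clip(np.corrcoef(eig.T), -1.0, 1.0)
            d = 1.0 - cor
            np.fill_diagonal(d, 0.0)
            Z = linkage(squareform(d, checks=False), method="average")
            groups = fcluster(Z, t=merge_cut_height, criterion="distance")
            if len(set(groups)) == len(module_ids):
                break
            mapping = {}
            for grp in set(groups):
                group_modules = [m for m, g in zip(module_ids, groups) if g == grp]
                target = min(group_modules)
                for m in group_modules:
                    mapping[m] = target
            labels = np.array([mapping.get(int(l), 0) for l in labels])
            logger.info("merged eigengene clusters; %d modules remain", len(set(labels) - {0}))
    return assign_colors(expr.gene_ids, labels)


def assign_colors(gene_ids, raw_labels) -> ModuleAssignment:
    """Relabel modules 1..M by decreasing size and name them from the palette.

    Size ties are broken by the input order of each module's first member gene,
    making the naming deterministic. Beyond the palette, modules get numbered
    "extra-N" names. Label 0 is always grey.
    """
    raw_labels = np.asarray(raw_labels, dtype=int)
    gene_ids = list(gene_ids)
    module_ids = sorted(set(raw_labels.tolist()) - {0})
    first_member = {m: int(np.argmax(raw_labels == m)) for m in module_ids}
    sizes = {m: int((raw_labels == m).sum()) for m in module_ids}
    ordered = sorted(module_ids, key=lambda m: (-sizes[m], first_member[m]))
    relabel = {m: i + 1 for i, m in enumerate(ordered)}
    labels = np.array([relabel.get(int(l), 0) for l in raw_labels], dtype=int)
    label_to_color = {0: "grey"}
    for new_label in range(1, len(ordered) + 1):
        if new_label - 1 < len(MODULE_COLOR_PALETTE):
            label_to_color[new_label] = MODULE_COLOR_PALETTE[new_label - 1]
        else:
            label_to_color[new_label] = f"extra-{new_label - len(MODULE_COLOR_PALETTE)}"
    return ModuleAssignment(
        gene_ids=gene_ids, labels=labels, label_to_color=label_to_color
    )
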