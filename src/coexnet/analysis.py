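"""End-to-end coexpression analysis as a model/results pair.

``CoexpressionAnalysis`` holds the input data and configuration;
``fit()`` runs preprocessing, soft-threshold network construction, module
detection, module-trait correlation, and the hub screen, returning a
``CoexpressionResults`` with every intermediate product, a ``summary()``
table, and a ``save()`` that writes all stage outputs to a directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import hubs as chubs
from . import modules as cmodules
from . import network as cnetwork
from . import preprocess as cpre
from . import traits as ctraits
from .datatypes import AnnotationTable, ExpressionMatrix, PipelineConfig, TraitTable

__all__ = ["CoexpressionAnalysis", "CoexpressionResults"]

logger = logging.getLogger(__name__)


class CoexpressionAnalysis:
    """Weighted coexpression network analysis of a gene-by-sample table.

    Parameters
    ----------
    expression
        FPKM-like expression values, genes in rows.
    trait
        Per-sample quantitative trait (wax secretion, mg/individual).
    annotations
        Optional Swiss-Prot annotation; required for the hub screen
        (unannotated genes are excluded from module networks).
    config
        PipelineConfig; defaults follow the standard protocol (top-75% MAD
        filter with 0.01 floor, scale-free fit target 0.9, unsigned network,
        min module size 20, merge height 0.15, p < 0.05 modules, top-100
        degree subnetwork, top-10% hubs).

    Examples
    --------
    >>> from coexnet.simulate import generate_dataset
    >>> expr, trait, ann, truth = generate_dataset(seed=1)
    >>> result = CoexpressionAnalysis(expr, trait, ann).fit()
    >>> print(result.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        trait: TraitTable,
        annotations: AnnotationTable | None = None,
        config: PipelineConfig | None = None,
    ):
        self.expression = expression
        self.trait = trait
        self.annotations = annotations if annotations is not None else AnnotationTable.empty()
        self.config = config if config is not None else PipelineConfig()

    @classmethod
    def from_files(
        cls,
        expression_path,
        trait_path,
        annotation_path=None,
        config: PipelineConfig | None = None,
    ) -> "CoexpressionAnalysis":
        expr = cio.read_expression(expression_path)
        trait = cio.read_trait(trait_path)
        ann = cio.read_annotation(annotation_path) if annotation_path else None
        return cls(expr, trait, ann, config=config)

    def preprocess(self):
        """Run only the cleaning stages; returns (expr, trait, report, dend, removed)."""
        cfg = self.config
        expr0 = self.expression
        expr1, n_zero = cpre.remove_zero_genes(expr0)
        expr2, mad_report = cpre.mad_filter(
            expr1,
            top_fraction=cfg.mad_top_fraction,
            floor=cfg.mad_floor,
            scale=cfg.mad_scale,
        )
        report = cpre.FilterReport(
            n_input_genes=expr0.n_genes,
            n_zero_removed=n_zero,
            n_after_zero=expr1.n_genes,
            n_retained_mad=expr2.n_genes,
            mad_fraction=cfg.mad_top_fraction,
            mad_floor=cfg.mad_floor,
        )
        dend = cpre.cluster_samples(expr2)
        cut = cfg.sample_cut_height
        if cut is None:
            cut = cpre.suggest_cut_height(dend)
        expr3, trait3, removed = cpre.remove_outlier_samples(
            dend, expr2, self.trait, cut_height=cut, min_cluster_size=cfg.min_cluster_size
        )
        return expr3, trait3, report, dend, removed, cut

    def fit(self) -> "CoexpressionResults":
        cfg = self.config
        expr, trait, report, sample_tree, removed, cut = self.preprocess()

        power, scan = cnetwork.pick_soft_threshold(
            expr,
            powers=cfg.powers,
            fit_target=cfg.fit_target,
            mode=cfg.network_mode,
            n_bins=cfg.n_bins,
            max_genes=cfg.max_genes,
        )
        cor = cnetwork.correlation_matrix(expr, max_genes=cfg.max_genes)
        adj = cnetwork.adjacency(cor, power, mode=cfg.network_mode, gene_ids=expr.gene_ids)
        fit_at_power, _ = cnetwork.scale_free_fit(adj, n_bins=cfg.n_bins)
        tom = cnetwork.tom_similarity(adj)

        gene_tree = cmodules.cluster_genes(tom)
        raw_labels = cmodules.dynamic_tree_cut(
            gene_tree,
            tom.dissimilarity(),
            min_module_size=cfg.min_module_size,
            deep_split=cfg.deep_split,
            pam_stage=cfg.pam_stage,
        )
        assignment = cmodules.merge_close_modules(
            expr, raw_labels, merge_cut_height=cfg.merge_cut_height
        )

        eigengenes = ctraits.compute_eigengenes(expr, assignment)
        module_trait = ctraits.module_trait_relation(eigengenes, trait)
        significant = ctraits.select_significant_modules(
            module_trait, alpha=cfg.module_alpha, adjust=cfg.adjust_pvalues
        )
        stats = ctraits.gene_stats(expr, trait, eigengenes, assignment)

        hub_report = chubs.screen_hubs(
            tom,
            assignment,
            self.annotations,
            significant,
            threshold=cfg.export_threshold,
            top_k=cfg.top_k,
            hub_fraction=cfg.hub_fraction,
            sort_key=cfg.hub_sort_key,
        ) if significant else chubs.HubReport()

        return CoexpressionResults(
            config=cfg,
            annotations=self.annotations,
            filter_report=report,
            sample_tree=sample_tree,
            sample_cut_height=cut,
            removed_samples=removed,
            expression=expr,
            trait=trait,
            power=power,
            scan=scan,
            fit_at_power=fit_at_power,
            tom=tom,
            gene_tree=gene_tree,
            assignment=assignment,
            eigengenes=eigengenes,
            module_trait=module_trait,
            significant_modules=significant,
            gene_stats=stats,
            hub_report=hub_report,
        )


@dataclass
class CoexpressionResults:
    """Everything the fitted pipeline produced, stage by stage."""

    config: PipelineConfig
    annotations: AnnotationTable
    filter_report: cpre.FilterReport
    sample_tree: cpre.SampleDendrogram
    sample_cut_height: float
    removed_samples: list[str]
    expression: ExpressionMatrix
    trait: TraitTable
    power: int
    scan: cnetwork.SoftThresholdScan
    fit_at_power: float
    tom: cnetwork.TOMMatrix
    gene_tree: cmodules.GeneDendrogram
    assignment: cmodules.ModuleAssignment
    eigengenes: ctraits.EigengeneSet
    module_trait: ctraits.ModuleTraitMatrix
    significant_modules: list[str]
    gene_stats: ctraits.GeneTraitStats
    hub_report: chubs.HubReport = field(default_factory=chubs.HubReport)

    def summary(self) -> str:
        r = self.filter_report
        lines = [
            "Coexpression network analysis",
            "=" * 64,
            f"genes in / zero-removed / retained : {r.n_input_genes} / "
            f"{r.n_zero_removed} / {r.n_retained_mad}",
            f"samples retained                   : {self.expression.n_samples}"
            + (f"  (removed: {', '.join(self.removed_samples)})" if self.removed_samples else ""),
            f"soft-threshold power (fit index)   : {self.power}  ({self.fit_at_power:.3f})",
            f"modules detected                   : {self.assignment.n_modules} "
            f"(+{int((self.assignment.labels == 0).sum())} unassigned genes)",
            "",
            "module-trait correlations (wax secretion):",
        ]
        sizes = self.assignment.sizes()
        color_to_label = {v: k for k, v in self.assignment.label_to_color.items()}
        for color, row in self.module_trait.table.iterrows():
            size = sizes.get(color_to_label.get(color, -1), 0)
            star = " *" if color in self.significant_modules else ""
            lines.append(
                f"  {color:<14s} n_genes={size:<6d} r={row['r']:+.3f}  p={row['p']:.3g}{star}"
            )
        lines.append("")
        if self.hub_report.modules:
            lines.append(
                f"hub genes (top {100 * self.config.hub_fraction:.0f}% of top-"
                f"{self.config.top_k} degree subnetworks): {self.hub_report.total_hubs}"
            )
            for color, df in self.hub_report.modules.items():
                same = self.hub_report.comparisons[color]["same_set"]
                lines.append(
                    f"  {color}: {len(df)} hubs; DC/EC top sets "
                    + ("identical" if same else "differ")
                )
                for gene, hub in df.iterrows():
                    lines.append(
                        f"    #{int(hub['hub_rank']):<3d}{gene}  "
                        f"wDC={hub['weighted_degree']:.3f}  EC={hub['eigenvector']:.3f}  "
                        f"{hub['description']}"
                    )
        else:
            lines.append("no significant modules; hub screen not run")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write all stage outputs (TSV/JSON; Cytoscape files per module)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_expression(self.expression, outdir / "expression_clean.tsv")
        cio.write_trait(self.trait, outdir / "trait_clean.tsv")
        cio.write_json(
            {
                "filter_report": self.filter_report.__dict__,
                "sample_cut_height": self.sample_cut_height,
                "removed_samples": self.removed_samples,
                "power": self.power,
                "fit_at_power": self.fit_at_power,
                "n_modules": self.assignment.n_modules,
                "significant_modules": self.significant_modules,
                "total_hubs": self.hub_report.total_hubs,
                "config": self.config.to_dict(),
            },
            outdir / "run_summary.json",
        )
        self.scan.table.to_csv(outdir / "soft_threshold_scan.tsv", sep="\t", index=False)
        cio.write_module_assignment(self.assignment, outdir / "modules.tsv")
        self.eigengenes.data.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="sample_id")
        self.module_trait.table.to_csv(
            outdir / "module_trait.tsv", sep="\t", index_label="module"
        )
        self.gene_stats.table.to_csv(outdir / "gene_stats.tsv", sep="\t")
        hub_frames = self.hub_report.all_hubs()
        if len(hub_frames):
            hub_frames.to_csv(outdir / "hubs.tsv", sep="\t", index_label="gene_id")
        else:
            (outdir / "hubs.tsv").write_text("gene_id\tmodule\n", encoding="utf-8")
        for color in self.significant_modules:
            net = chubs.export_module_network(
                self.tom, self.assignment, color, threshold=self.config.export_threshold
            )
            net = chubs.filter_annotated(net, self.annotations)
            cio.write_cytoscape_network(
                net,
                outdir / f"CytoscapeInput-edges-{color}.txt",
                outdir / f"CytoscapeInput-nodes-{color}.txt",
                self.annotations,
            )
        with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")
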