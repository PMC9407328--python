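"""Synthetic expression/trait/annotation generator with planted ground truth.

The generator emulates the statistical structure the pipeline assumes: a
6-condition x 3-replicate design, latent condition-level factors driving
gene modules on the log scale, a trait that is a noisy linear combination of
a subset of module factors, planted all-zero and near-constant genes sized
to be exactly the genes the default preprocessing filters remove, one
globally shifted outlier sample, and partial Swiss-Prot-style annotation.
Hub ground truth is unambiguous by construction: each module has a
high-loading "head" block clearly separated from the loading range of the
remaining members, and head genes are always annotated (the screening
protocol discards unannotated nodes, so a recoverable hub must be
annotatable, as in any Swiss-Prot-based screen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AnnotationTable, ExpressionMatrix, TraitTable
from .errors import ParameterError

__all__ = ["SyntheticTruth", "generate_dataset", "truth_module_partition", "PRESET"]

#: Desk-scale preset mirroring the study design (6 conditions x 3 replicates)
#: at roughly 1/100 gene scale.
PRESET = dict(
    n_conditions=6,
    n_reps=3,
    n_genes=2000,
    module_sizes=(300, 200, 150, 120, 100),
    noise_sd=0.25,
    trait_modules=(1, 3),
    trait_module_cor=0.5,
    trait_noise_sd=0.5,
    zero_gene_frac=0.10,
    low_mad_frac=0.225,
    annotation_frac=0.7,
    outlier=True,
)

_HEAD_SIZE = 10  # planted hub head per module
_REPLICATE_JITTER_SD = 0.1
_OUTLIER_SHIFT = 2.5  # log-scale global shift of the planted outlier sample
#: Log-scale amplitude of the latent signal+noise. Kept moderate so that
#: FPKM fold-changes stay realistic (roughly 2-4x across conditions) and the
#: raw-scale Pearson correlations the pipeline computes remain faithful to
#: the planted log-scale structure (exp() distorts correlations of
#: high-variance log-normal profiles).
_LOG_SIGNAL_SCALE = 0.35
#: Residual-noise multiplier for hub-head genes: hubs are modelled as genes
#: tightly coupled to their module factor — high loading and low residual
#: noise — which is exactly the property that makes them the most connected
#: members, so planted hub identity is unambiguous in every centrality.
_HEAD_NOISE_FACTOR = 0.4

_DESCRIPTIONS = [
    "fatty acyl-CoA reductase",
    "very-long-chain fatty acid elongase",
    "glucose dehydrogenase (FAD, quinone)",
    "wax ester synthase",
    "acyl-CoA desaturase",
    "cuticular protein",
    "cytochrome P450 monooxygenase",
    "ABC transporter",
    "juvenile hormone esterase",
    "chitin synthase",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of a synthetic dataset.

    module_of_gene maps each gene to its module index (0 = background, which
    includes the planted all-zero and near-constant genes); loading holds
    each gene's factor loading in [0, 1]; factor is the module x sample
    matrix of latent profiles; planted_hub_ids lists, per module, the genes
    with the largest loadings (all annotated).
    """

    module_of_gene: pd.Series
    loading: pd.Series
    factor: pd.DataFrame
    trait_coefficients: dict[int, float]
    outlier_sample_ids: list[str]
    planted_hub_ids: dict[int, list[str]] = field(default_factory=dict)
    zero_gene_ids: list[str] = field(default_factory=list)
    low_mad_gene_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "module_of_gene": {g: int(m) for g, m in self.module_of_gene.items()},
            "loading": {g: float(v) for g, v in self.loading.items()},
            "factor": {
                str(m): [float(v) for v in row]
                for m, row in zip(self.factor.index, self.factor.to_numpy())
            },
            "sample_ids": list(self.factor.columns),
            "trait_coefficients": {str(k): float(v) for k, v in self.trait_coefficients.items()},
            "outlier_sample_ids": list(self.outlier_sample_ids),
            "planted_hub_ids": {str(k): list(v) for k, v in self.planted_hub_ids.items()},
            "zero_gene_ids": list(self.zero_gene_ids),
            "low_mad_gene_ids": list(self.low_mad_gene_ids),
            "seed": int(self.seed),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        factor = pd.DataFrame(
            {int(m): vals for m, vals in d["factor"].items()}
        ).T
        factor.columns = d["sample_ids"]
        return cls(
            module_of_gene=pd.Series(d["module_of_gene"]),
            loading=pd.Series(d["loading"]),
            factor=factor.sort_index(),
            trait_coefficients={int(k): v for k, v in d["trait_coefficients"].items()},
            outlier_sample_ids=d["outlier_sample_ids"],
            planted_hub_ids={int(k): v for k, v in d["planted_hub_ids"].items()},
            zero_gene_ids=d["zero_gene_ids"],
            low_mad_gene_ids=d["low_mad_gene_ids"],
            seed=d["seed"],
        )


def _orthogonal_profiles(raw: np.ndarray, n_conditions: int) -> np.ndarray:
    """Center, orthogonalize (up to the available dimension), and standardize
    condition-level profiles to unit variance."""
    centered = raw - raw.mean(axis=1, keepdims=True)
    if n_conditions < 2:
        return np.zeros_like(raw)
    max_orth = n_conditions - 1  # centering removes one dimension
    out = centered.copy()
    q, _ = np.linalg.qr(centered[: min(len(raw), max_orth)].T)
    n_orth = q.shape[1]
    out[:n_orth] = q.T[:n_orth]
    sds = out.std(axis=1, keepdims=True)
    sds[sds == 0] = 1.0
    return out / sds


def truth_module_partition(truth: SyntheticTruth) -> pd.Series:
    """Reference gene -> label partition (0 = background/unassigned) for
    Adjusted Rand Index scoring against a detected ModuleAssignment."""
    return truth.module_of_gene.astype(int)


def generate_dataset(
    n_conditions: int = 6,
    n_reps: int = 3,
    n_genes: int = 2000,
    module_sizes=(300, 200, 150, 120, 100),
    noise_sd: float = 0.25,
    trait_modules=(1, 3),
    trait_module_cor: float = 0.5,
    trait_noise_sd: float = 0.5,
    zero_gene_frac: float = 0.10,
    low_mad_frac: float = 0.225,
    annotation_frac: float = 0.7,
    outlier: bool = True,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TraitTable, AnnotationTable, SyntheticTruth]:
    """Generate a synthetic dataset with planted module/trait/hub structure.

    Model: per module m, a condition-level factor profile (one standard-normal
    value per condition, repeated over replicates with small jitter) gives the
    factor f_m,s per sample; gene g of module m has log-expression
    mu_g + lambda_g * f_m,s + eps with eps ~ N(0, noise_sd^2) and loadings
    lambda_g decreasing within the module; FPKM = exp(log-expression).
    Background genes are pure noise. The trait is
    sum_{m in trait_modules} c_m * f_m,s + eta, shifted to be positive.
    """
    module_sizes = [int(s) for s in module_sizes]
    n_modules = len(module_sizes)
    n_samples = n_conditions * n_reps
    if any(s < 1 for s in module_sizes):
        raise ParameterError("module sizes must be positive")
    if not all(0 <= f <= 1 for f in (zero_gene_frac, low_mad_frac, annotation_frac)):
        raise ParameterError("fractions must be in [0, 1]")
    if noise_sd < 0 or trait_noise_sd < 0:
        raise ParameterError("noise standard deviations must be >= 0")
    n_zero = int(round(zero_gene_frac * n_genes))
    n_low = int(round(low_mad_frac * n_genes))
    n_module_genes = sum(module_sizes)
    if n_module_genes + n_zero + n_low > n_genes:
        raise ParameterError(
            f"module sizes ({n_module_genes}) plus planted zero ({n_zero}) and "
            f"near-constant ({n_low}) genes exceed n_genes ({n_genes})"
        )
    bad_trait = [m for m in trait_modules if not 1 <= m <= n_modules]
    if bad_trait:
        raise ParameterError(f"trait modules out of range: {bad_trait}")
    if not -1 <= trait_module_cor <= 1:
        raise ParameterError("trait_module_cor must be in [-1, 1]")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    sample_ids = [
        f"C{c + 1}R{r + 1}" for c in range(n_conditions) for r in range(n_reps)
    ]

    # Latent condition-level factors, replicated with jitter. Profiles are
    # centered, mutually orthogonalized (as far as the condition count
    # allows) and standardized, so every module carries unit factor variance
    # and non-trait modules are not spuriously related to the trait. Trait
    # modules beyond the first are then deliberately given correlation
    # trait_module_cor with the first one — trait-associated modules in real
    # data are related to each other through the very trait they drive.
    raw_profiles = rng.normal(0.0, 1.0, size=(n_modules, n_conditions))
    cond_profiles = _orthogonal_profiles(raw_profiles, n_conditions)
    trait_list = sorted(int(m) for m in trait_modules)
    for m in trait_list[1:]:
        lead = cond_profiles[trait_list[0] - 1]
        cond_profiles[m - 1] = (
            trait_module_cor * lead
            + np.sqrt(max(1.0 - trait_module_cor**2, 0.0)) * cond_profiles[m - 1]
        )
    jitter = rng.normal(0.0, _REPLICATE_JITTER_SD, size=(n_modules, n_samples))
    factor = np.repeat(cond_profiles, n_reps, axis=1) + jitter

    # Scatter module members over random gene positions, like a real table.
    module_of_gene = np.zeros(n_genes, dtype=int)
    positions = rng.permutation(n_genes)
    cursor = 0
    members: dict[int, np.ndarray] = {}
    for m, size in enumerate(module_sizes, start=1):
        idx = np.sort(positions[cursor : cursor + size])
        members[m] = idx
        module_of_gene[idx] = m
        cursor += size
    background = np.sort(positions[cursor:])

    # Loadings: a clearly separated high-loading head block defines the hubs.
    loading = np.zeros(n_genes)
    for m, size in enumerate(module_sizes, start=1):
        head = min(_HEAD_SIZE, max(size // 2, 1))
        body = size - head
        lam = np.concatenate(
            [
                np.linspace(1.0, 0.92, head),
                # convex decay: few strong members, a long tail of weak ones,
                # giving the module a heavy-tailed connectivity profile
                0.42 + 0.43 * np.linspace(1.0, 0.0, body) ** 3 if body else [],
            ]
        )
        loading[members[m]] = lam

    head_of = {
        m: members[m][: min(_HEAD_SIZE, max(module_sizes[m - 1] // 2, 1))]
        for m in members
    }
    mu = rng.uniform(np.log(5.0), np.log(50.0), size=n_genes)
    eps = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    for m in head_of:
        eps[head_of[m]] *= _HEAD_NOISE_FACTOR
    signal = eps
    for m in members:
        signal[members[m]] += loading[members[m], None] * factor[m - 1][None, :]
    log_expr = mu[:, None] + _LOG_SIGNAL_SCALE * signal

    outlier_ids: list[str] = []
    if outlier:
        # first replicate of condition 5 (echoing a late-condition outlier)
        cond = min(4, n_conditions - 1)
        out_idx = cond * n_reps
        log_expr[:, out_idx] += _OUTLIER_SHIFT
        outlier_ids = [sample_ids[out_idx]]

    fpkm = np.exp(log_expr)

    # Planted filter targets come out of the background pool.
    zero_idx = background[:n_zero]
    low_idx = background[n_zero : n_zero + n_low]
    fpkm[zero_idx] = 0.0
    if n_low:
        base = rng.uniform(0.5, 5.0, size=n_low)
        fpkm[low_idx] = np.abs(
            base[:, None] + rng.normal(0.0, 1e-4, size=(n_low, n_samples))
        )

    # Trait: noisy linear combination of the designated module factors.
    coeffs = {int(m): 1.0 for m in trait_modules}
    raw = np.zeros(n_samples)
    for m, c in coeffs.items():
        raw += c * factor[m - 1]
    raw += rng.normal(0.0, trait_noise_sd, size=n_samples)
    trait_values = 2.0 * (raw - raw.min() + 0.25)  # positive, mg/individual scale

    # Annotation: hub heads always annotated; fill the rest at random.
    n_ann = int(round(annotation_frac * n_genes))
    head_idx = (
        np.concatenate([head_of[m] for m in head_of])
        if head_of
        else np.array([], dtype=int)
    )
    pool = np.setdiff1d(np.arange(n_genes), head_idx)
    n_fill = max(n_ann - len(head_idx), 0)
    fill = rng.choice(pool, size=min(n_fill, len(pool)), replace=False)
    annotated = np.sort(np.concatenate([head_idx, fill]))
    ann_df = pd.DataFrame(
        {
            "swissprot_id": [f"P{int(i) + 10000:05d}" for i in annotated],
            "description": [
                f"{_DESCRIPTIONS[int(i) % len(_DESCRIPTIONS)]} {int(i) + 1}"
                for i in annotated
            ],
        },
        index=pd.Index([gene_ids[int(i)] for i in annotated], name="gene_id"),
    )

    expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )
    trait = TraitTable(
        pd.Series(trait_values, index=pd.Index(sample_ids, name="sample_id"),
                  name="wax_secretion")
    )
    annotations = AnnotationTable(ann_df)
    truth = SyntheticTruth(
        module_of_gene=pd.Series(module_of_gene, index=gene_ids),
        loading=pd.Series(loading, index=gene_ids),
        factor=pd.DataFrame(factor, index=range(1, n_modules + 1), columns=sample_ids),
        trait_coefficients=coeffs,
        outlier_sample_ids=outlier_ids,
        planted_hub_ids={
            m: [gene_ids[int(i)] for i in head_of[m]] for m in head_of
        },
        zero_gene_ids=[gene_ids[int(i)] for i in zero_idx],
        low_mad_gene_ids=[gene_ids[int(i)] for i in low_idx],
        seed=int(seed),
    )
    return expr, trait, annotations, truth
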