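"""Seeded synthetic data with the structure the signature pipeline assumes.

The generator emulates the study design: eight genotypes (WT, atfs-1,
nuo-6, nuo-6;atfs-1, et15, et17, spg-7 RNAi, isp-1) with six biological
replicates of CPM expression each, and a three-replicate qPCR Ct table.
A block of planted ATFS-1-dependent target genes is activated
``activation_fold``-fold in every activating condition (nuo-6, et15, et17,
spg-7i, isp-1) and suppressed in the nuo-6;atfs-1 double (a ``suppression``
fraction of the activation is retained there; 0 means full dependence).
Decoy classes are activated in only one or two of the three consensus
inputs — or in nuo-6 AND the double (escaping the dependence call) — so
the three-way intersection must exclude them.  Baseline CPM is log-normal;
replicate noise is multiplicative log-normal with a chosen coefficient of
variation.

Two special genes mirror the real readouts: an ``hsp-6`` analogue planted
at a modest fold and absent from the spg-7i response (so, as in the real
data, it scores but is not in the consensus) and a flat ``act-3`` used as
the qPCR reference.  Ct values are back-computed from the expression ground
truth (Ct drops by one cycle per doubling of expression) plus Gaussian
jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .core_io import DEFAULT_GENOTYPES, ExpressionMatrix, GeneSet, QpcrTable

#: Decoy classes: which consensus inputs the class responds in, or
#: "nondependent" = up in nuo-6 and the double (fails the epistasis call).
DECOY_CLASSES = (
    "nuo6_only",
    "spg7_only",
    "et_only",
    "nuo6_spg7",
    "nuo6_et",
    "spg7_et",
    "nondependent",
)

_CLASS_GENOTYPES = {
    "nuo6_only": ("nuo-6",),
    "spg7_only": ("spg-7i",),
    "et_only": ("et15", "et17"),
    "nuo6_spg7": ("nuo-6", "spg-7i"),
    "nuo6_et": ("nuo-6", "et15", "et17"),
    "spg7_et": ("spg-7i", "et15", "et17"),
    "nondependent": ("nuo-6", "nuo-6;atfs-1"),
}

HSP6 = "hsp-6"
ACT3 = "act-3"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults mirror the design the pipeline targets: 61 planted signature
    genes, six expression replicates, three qPCR replicates, four-fold
    activation with full ATFS-1 dependence, 20% multiplicative noise, and
    a ChIP-bound fraction of 22/61.
    """

    n_genes: int = 500
    n_signature: int = 61
    n_decoys_per_class: int = 10
    n_reps_expr: int = 6
    n_reps_qpcr: int = 3
    activation_fold: float = 4.0
    suppression: float = 0.0
    cv: float = 0.2
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    chip_fraction: float = 22 / 61
    hsp6_fold: float = 2.5
    n_isp1_nonresponders: int = 4
    ct_jitter_sd: float = 0.2
    reference_ct: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_signature, self.n_reps_expr, self.n_reps_qpcr) < 1:
            raise ValueError("all counts must be positive")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        n_special = 2  # hsp-6 analogue + act-3 reference
        needed = self.n_signature + len(DECOY_CLASSES) * self.n_decoys_per_class + n_special
        if needed > self.n_genes:
            raise ValueError(
                f"gene-count partition infeasible: need {needed} genes, have {self.n_genes}"
            )
        if self.n_isp1_nonresponders > self.n_signature:
            raise ValueError("more isp-1 non-responders than signature genes")


@dataclass(frozen=True)
class GroundTruth:
    planted_signature: GeneSet
    planted_chip: GeneSet
    decoy_classes: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self):
        if not self.planted_chip.genes <= self.planted_signature.genes:
            raise ValueError("planted_chip must be a subset of planted_signature")


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: ExpressionMatrix
    truth: GroundTruth
    qpcr: QpcrTable
    chip: GeneSet
    config: SyntheticConfig


def _gene_universe(cfg: SyntheticConfig):
    """Deterministic (seed-independent) gene IDs, class memberships and the
    per-gene x per-genotype fold-multiplier table."""
    n_numbered = cfg.n_genes - 2
    numbered = [f"g{i:04d}" for i in range(n_numbered)]
    gene_ids = numbered + [HSP6, ACT3]

    cursor = 0
    signature = numbered[cursor : cursor + cfg.n_signature]
    cursor += cfg.n_signature
    decoys: dict[str, list[str]] = {}
    for cls in DECOY_CLASSES:
        decoys[cls] = numbered[cursor : cursor + cfg.n_decoys_per_class]
        cursor += cfg.n_decoys_per_class

    mult = pd.DataFrame(1.0, index=gene_ids, columns=list(DEFAULT_GENOTYPES))
    responders = signature[cfg.n_isp1_nonresponders:]
    mult.loc[signature, ["nuo-6", "et15", "et17", "spg-7i"]] = cfg.activation_fold
    mult.loc[responders, "isp-1"] = cfg.activation_fold
    mult.loc[signature, "nuo-6;atfs-1"] = 1.0 + cfg.suppression * (cfg.activation_fold - 1.0)
    for cls, genes in decoys.items():
        for genotype in _CLASS_GENOTYPES[cls]:
            mult.loc[genes, genotype] = cfg.activation_fold
    mult.loc[HSP6, ["nuo-6", "et15", "et17", "isp-1"]] = cfg.hsp6_fold
    mult.loc[HSP6, "nuo-6;atfs-1"] = 1.0 + cfg.suppression * (cfg.hsp6_fold - 1.0)

    n_chip = round(cfg.chip_fraction * cfg.n_signature)
    truth = GroundTruth(
        planted_signature=GeneSet("planted_signature", frozenset(signature),
                                  condition="planted", source="synthetic"),
        planted_chip=GeneSet("planted_chip", frozenset(signature[:n_chip]),
                             condition="chip", source="synthetic"),
        decoy_classes={
            cls: GeneSet(f"decoy_{cls}", frozenset(genes), condition=cls,
                         source="synthetic")
            for cls, genes in decoys.items()
        },
    )
    return gene_ids, mult, truth


def _baselines(cfg: SyntheticConfig, gene_ids: list[str]) -> pd.Series:
    rng = np.random.default_rng([cfg.seed, 0])
    base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, len(gene_ids))
    return pd.Series(base, index=gene_ids)


def _noise_sigma(cv: float) -> float:
    # log-normal sigma giving the requested CV, mean-preserving (mu = -sigma^2/2)
    return math.sqrt(math.log(1.0 + cv * cv))


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the expression matrix, ground truth, qPCR table and ChIP list.

    Fully reproducible from ``cfg.seed``; ground-truth memberships depend
    only on the counts, not the seed.
    """
    gene_ids, mult, truth = _gene_universe(cfg)
    base = _baselines(cfg, gene_ids)
    rng = np.random.default_rng([cfg.seed, 1])

    sample_ids, genotypes_col, reps_col = [], [], []
    for genotype in DEFAULT_GENOTYPES:
        for rep in range(1, cfg.n_reps_expr + 1):
            sample_ids.append(f"{genotype}_r{rep}")
            genotypes_col.append(genotype)
            reps_col.append(rep)
    meta = pd.DataFrame(
        {"genotype": genotypes_col, "replicate": reps_col}, index=pd.Index(sample_ids, name="sample_id")
    )

    means = mult.mul(base, axis=0)  # genes x genotypes expected CPM
    expected = means[genotypes_col].to_numpy()
    if cfg.cv > 0:
        sigma = _noise_sigma(cfg.cv)
        noise = np.exp(rng.normal(-sigma * sigma / 2.0, sigma, expected.shape))
    else:
        noise = 1.0
    values = pd.DataFrame(expected * noise, index=gene_ids, columns=sample_ids)

    matrix = ExpressionMatrix(values=values, sample_meta=meta)
    qpcr = generate_qpcr_only(
        cfg,
        GeneSet("qpcr_targets",
                frozenset(sorted(truth.planted_signature.genes)[: min(4, cfg.n_signature)]),
                condition="qpcr", source="synthetic"),
    )
    return SyntheticDataset(matrix=matrix, truth=truth, qpcr=qpcr,
                            chip=truth.planted_chip, config=cfg)


def generate_qpcr_only(
    cfg: SyntheticConfig,
    genes: GeneSet,
    strains: tuple[str, ...] = ("WT", "nuo-6"),
) -> QpcrTable:
    """Ct table for the requested target genes, consistent with the
    expression ground truth (Ct = base - log2(fold multiplier) + jitter)."""
    gene_ids, mult, _ = _gene_universe(cfg)
    unknown = sorted(set(genes.genes) - set(gene_ids))
    if unknown:
        raise ValueError(f"unknown genes requested for qPCR: {unknown}")
    base = _baselines(cfg, gene_ids)
    rng = np.random.default_rng([cfg.seed, 2])

    rows = []
    for strain in strains:
        for rep in range(1, cfg.n_reps_qpcr + 1):
            jit = rng.normal(0.0, cfg.ct_jitter_sd) if cfg.ct_jitter_sd > 0 else 0.0
            rows.append((strain, ACT3, ACT3, rep, cfg.reference_ct + jit))
            for gene in sorted(genes.genes):
                base_ct = 30.0 - math.log2(base.loc[gene] + 1.0)
                jit = rng.normal(0.0, cfg.ct_jitter_sd) if cfg.ct_jitter_sd > 0 else 0.0
                ct = base_ct - math.log2(mult.loc[gene, strain]) + jit
                rows.append((strain, gene, ACT3, rep, ct))
    df = pd.DataFrame(rows, columns=["strain", "target_gene", "reference_gene", "replicate", "ct"])
    return QpcrTable(df=df)


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a (YAML-loaded) dict, rejecting unknown keys."""
    known = {f.name for f in fields(SyntheticConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown synthetic-config keys: {sorted(unknown)}")
    return SyntheticConfig(**d)


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(cfg, seed=seed)
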