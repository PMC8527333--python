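"""ChIP-binding stratification, independent-dataset validation, and the
heatmap-ready fold-change export.

Signature genes bound by ATFS-1 in a ChIP experiment are flagged as direct
targets; the rest are presumed indirect (or bound under other conditions).
Validation asks how many signature genes are significantly up-regulated in
an independent dataset (e.g. the long-lived mitochondrial mutant isp-1).
Both steps only toggle boolean flags — scores and ranks are never touched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSet
from .scoring import PSEUDOCOUNT

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationReport:
    n_signature: int
    n_chip_bound: int
    n_validated: int

    def __post_init__(self):
        if not (0 <= self.n_chip_bound <= self.n_signature):
            raise ValueError("chip-bound count outside [0, n_signature]")
        if not (0 <= self.n_validated <= self.n_signature):
            raise ValueError("validated count outside [0, n_signature]")

    @property
    def n_not_validated(self) -> int:
        """The 'all but N' complement."""
        return self.n_signature - self.n_validated


def annotate_chip(table: pd.DataFrame, chip_bound: GeneSet) -> pd.DataFrame:
    """Flag signature genes present in the ChIP-bound list (direct targets)."""
    out = table.copy()
    out["chip_bound"] = out["gene_id"].isin(chip_bound.genes).to_numpy()
    logger.info("%d of %d signature genes ChIP-bound", int(out["chip_bound"].sum()), len(out))
    return out


def validate_in_dataset(
    table: pd.DataFrame, up_in_validation: GeneSet
) -> tuple[pd.DataFrame, ValidationReport]:
    """Flag signature genes up-regulated in an independent dataset."""
    out = table.copy()
    out["validated"] = out["gene_id"].isin(up_in_validation.genes).to_numpy()
    report = ValidationReport(
        n_signature=len(out),
        n_chip_bound=int(out["chip_bound"].sum()),
        n_validated=int(out["validated"].sum()),
    )
    logger.info(
        "%d of %d signature genes validated (all but %d)",
        report.n_validated, report.n_signature, report.n_not_validated,
    )
    return out, report


def export_heatmap_table(
    matrix: ExpressionMatrix,
    genes: GeneSet,
    contrast: tuple[str, str],
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 fold-change between two genotypes (B over A).

    Zero means are handled with the same pseudocount policy as scoring.
    Genes absent from the matrix get a NaN row plus a warning so a plot
    layer can still show the full signature.
    """
    geno_a, geno_b = contrast
    for genotype in contrast:
        if len(matrix.samples_for(genotype)) < 2:
            raise ValueError(f"genotype {genotype!r} needs >=2 replicates")
    mean_a = matrix.submatrix(geno_a).mean(axis=1)
    mean_b = matrix.submatrix(geno_b).mean(axis=1)
    needs_pc = (mean_a == 0) | (mean_b == 0)
    mean_a = mean_a.where(~needs_pc, mean_a + pseudocount)
    mean_b = mean_b.where(~needs_pc, mean_b + pseudocount)

    gene_list = sorted(genes.genes)
    log2fc = np.full(len(gene_list), np.nan)
    for i, gene in enumerate(gene_list):
        if gene not in matrix.values.index:
            warnings.warn(f"gene {gene!r} absent from matrix; emitting NaN", stacklevel=2)
            continue
        log2fc[i] = np.log2(mean_b.loc[gene] / mean_a.loc[gene])
    return pd.DataFrame({"gene_id": gene_list, "log2fc": log2fc})
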