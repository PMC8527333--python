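"""Wild-type normalization, the composite activation score, and ranking.

For each gene, expression is first put on a percent-of-wild-type scale:
every replicate CPM is divided by the gene's mean wild-type CPM and
multiplied by 100, so the wild-type mean is 100 by construction.  The
composite activation score is

    S = E[nuo-6] + E[et15] + E[et17] - 3 * E[nuo-6;atfs-1]

where E[s] is the normalized mean in genotype s.  With every genotype at
baseline (100) the score is exactly 0; activation that requires ATFS-1
(high in the single mutant and the constitutively active alleles, suppressed
in the double mutant) drives S up.  The variability-corrected score divides
S by the average per-genotype standard deviation of the normalized values
across the six strains WT, atfs-1, nuo-6, nuo-6;atfs-1, et15 and et17,
rewarding genes whose induction is large relative to their noise.

A ``formula="1x"`` variant (subtracting the double mutant once instead of
three times) is provided for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

#: Genotypes entering the composite score.
SCORE_GENOTYPES = ("nuo-6", "et15", "et17", "nuo-6;atfs-1")
#: Genotypes whose normalized-expression SDs are averaged for the
#: variability correction.
VC_GENOTYPES = ("WT", "atfs-1", "nuo-6", "nuo-6;atfs-1", "et15", "et17")

WT_LABEL = "WT"
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class StrainProfile:
    """Per-gene normalized means and SDs, one entry per genotype (percent of WT)."""

    gene_id: str
    mean_norm: Mapping[str, float]
    sd_norm: Mapping[str, float]
    n_reps: Mapping[str, int]


@dataclass
class StrainProfiles:
    """Vectorized collection of :class:`StrainProfile` rows.

    ``mean_norm`` and ``sd_norm`` are genes x genotypes DataFrames in
    percent-of-WT units; ``n_reps`` maps genotype to replicate count.
    """

    mean_norm: pd.DataFrame
    sd_norm: pd.DataFrame
    n_reps: dict[str, int]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean_norm.index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.mean_norm.index

    def __getitem__(self, gene_id: str) -> StrainProfile:
        if gene_id not in self.mean_norm.index:
            raise KeyError(f"no profile for gene {gene_id!r}")
        return StrainProfile(
            gene_id=gene_id,
            mean_norm=self.mean_norm.loc[gene_id].to_dict(),
            sd_norm=self.sd_norm.loc[gene_id].to_dict(),
            n_reps=dict(self.n_reps),
        )


def normalize_to_wildtype(
    m: ExpressionMatrix,
    wt_label: str = WT_LABEL,
    pseudocount: float = PSEUDOCOUNT,
) -> StrainProfiles:
    """Percent-of-WT normalization with per-replicate SDs.

    Each replicate CPM is scaled to 100 * CPM / mean(WT CPM) for its gene;
    per-genotype means and sample SDs (n-1 denominator) are taken over the
    scaled replicate values.  Genes whose WT mean is zero get ``pseudocount``
    added to every replicate value before scaling (logged).
    """
    wt_samples = m.samples_for(wt_label)
    if len(wt_samples) < 2:
        raise ValueError(f"need >=2 {wt_label!r} replicates, found {len(wt_samples)}")
    values = m.values.astype(float)
    wt_mean = values[wt_samples].mean(axis=1)
    zero_wt = wt_mean == 0
    if zero_wt.any():
        genes = list(values.index[zero_wt])
        logger.info("adding pseudocount %g to %d zero-WT genes: %s",
                    pseudocount, len(genes), genes[:10])
        values.loc[zero_wt] = values.loc[zero_wt] + pseudocount
        wt_mean = values[wt_samples].mean(axis=1)
    norm = values.div(wt_mean, axis=0) * 100.0

    meta = m.sample_meta.loc[m.sample_ids]
    present = [g for g in m.genotypes if (meta["genotype"] == g).any()]
    mean_norm = pd.DataFrame(index=values.index, columns=present, dtype=float)
    sd_norm = pd.DataFrame(index=values.index, columns=present, dtype=float)
    n_reps: dict[str, int] = {}
    for genotype in present:
        cols = m.samples_for(genotype)
        n_reps[genotype] = len(cols)
        mean_norm[genotype] = norm[cols].mean(axis=1)
        sd_norm[genotype] = norm[cols].std(axis=1, ddof=1) if len(cols) >= 2 else np.nan
    # the WT mean is 100 by construction; pin it against float round-off
    mean_norm[wt_label] = 100.0
    return StrainProfiles(mean_norm=mean_norm, sd_norm=sd_norm, n_reps=n_reps)


def _score_from_means(means: Mapping[str, float] | pd.DataFrame, formula: str):
    if formula not in {"3x", "1x"}:
        raise ValueError(f"unknown score formula {formula!r}")
    k = 3.0 if formula == "3x" else 1.0
    for genotype in SCORE_GENOTYPES:
        if genotype not in means:
            raise ValueError(f"profile lacks required genotype {genotype!r}")
    return (
        means["nuo-6"] + means["et15"] + means["et17"] - k * means["nuo-6;atfs-1"]
    )


def compute_score(p: StrainProfile, formula: str = "3x") -> float:
    """Composite activation score S for one gene."""
    return float(_score_from_means(p.mean_norm, formula))


def compute_vc_score(score: float, p: StrainProfile) -> float:
    """Variability-corrected score: S over the mean SD of the six strains.

    Returns NaN when the mean SD is zero or undefined (never infinity).
    """
    sds = []
    for genotype in VC_GENOTYPES:
        if genotype not in p.sd_norm:
            raise ValueError(f"profile lacks SD for genotype {genotype!r}")
        sds.append(p.sd_norm[genotype])
    mean_sd = float(np.mean(sds))
    if not np.isfinite(mean_sd) or mean_sd == 0:
        return float("nan")
    return float(score / mean_sd)


def compute_scores(profiles: StrainProfiles, formula: str = "3x") -> pd.Series:
    """Vectorized S over all genes in a profile collection."""
    return _score_from_means(profiles.mean_norm, formula).astype(float)


def compute_vc_scores(profiles: StrainProfiles, formula: str = "3x") -> pd.Series:
    """Vectorized variability-corrected scores (NaN where the mean SD is 0)."""
    missing = [g for g in VC_GENOTYPES if g not in profiles.sd_norm.columns]
    if missing:
        raise ValueError(f"profiles lack SDs for genotypes {missing}")
    scores = compute_scores(profiles, formula)
    mean_sd = profiles.sd_norm[list(VC_GENOTYPES)].mean(axis=1)
    vc = scores / mean_sd.where(mean_sd > 0)
    return vc.astype(float)


def _rank(values: pd.Series) -> pd.Series:
    """Rank 1..N, descending values, NaN last, gene ID as tie-break."""
    order = pd.DataFrame({"v": values, "g": values.index})
    order["nan"] = order["v"].isna()
    order = order.sort_values(["nan", "v", "g"], ascending=[True, False, True],
                              kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return ranks.reindex(values.index)


def rank_signature(
    genes: GeneSet,
    profiles: StrainProfiles,
    reference_gene: str,
    formula: str = "3x",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score and rank a gene set against a reference gene (e.g. hsp-6).

    Returns the signature table (gene_id, score, vc_score, rank_score,
    rank_vc, chip_bound, validated — flags initialized False) plus counts of
    genes scoring strictly above the reference on each metric.
    """
    if reference_gene not in profiles:
        raise ValueError(f"reference gene {reference_gene!r} has no profile")
    missing = [g for g in genes if g not in profiles]
    if missing:
        raise ValueError(f"no profiles for signature genes: {missing[:10]}")

    gene_list = sorted(genes.genes)
    scores = compute_scores(profiles, formula)
    vc_scores = compute_vc_scores(profiles, formula)
    sub_scores = scores.loc[gene_list]
    sub_vc = vc_scores.loc[gene_list]

    table = pd.DataFrame(
        {
            "gene_id": gene_list,
            "score": sub_scores.to_numpy(),
            "vc_score": sub_vc.to_numpy(),
            "rank_score": _rank(sub_scores).to_numpy(),
            "rank_vc": _rank(sub_vc).to_numpy(),
            "chip_bound": False,
            "validated": False,
        }
    )
    ref_score = float(scores.loc[reference_gene])
    ref_vc = float(vc_scores.loc[reference_gene])
    counts = {
        "above_reference_score": int((sub_scores > ref_score).sum()),
        "above_reference_vc": int((sub_vc > ref_vc).sum()) if np.isfinite(ref_vc) else 0,
        "reference_score": ref_score,
        "reference_vc_score": ref_vc,
    }
    return table, counts
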