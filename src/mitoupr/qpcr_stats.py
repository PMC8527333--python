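"""Relative qPCR quantification (2^-ddCt) and the supporting statistics:
Welch's t-test, one-way ANOVA with Dunnett many-to-one comparisons, and a
simple Welch+BH differential-expression caller for synthetic matrices.

The ddCt workflow follows the Livak presentation: per replicate,
dCt = Ct(target) - Ct(reference); ddCt subtracts the control strain's mean
dCt; fold change = 2^-ddCt.  Per-replicate folds are averaged
arithmetically and then rescaled by the control strain's mean fold so the
control bar is exactly 1.  No amplification-efficiency correction is
applied.

Dunnett adjusted p-values are obtained by Monte-Carlo sampling of the null
max-|t| distribution (pooled variance, many-to-one contrasts), which keeps
the procedure exact-in-the-limit for arbitrary group counts and sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, GeneSet, QpcrTable


@dataclass(frozen=True)
class FoldChangeResult:
    """Fold change of one target gene in one strain vs the control strain."""

    target_gene: str
    strain: str
    per_replicate_fold: tuple[float, ...]
    mean_fold: float
    sem: float
    p_value: float

    def __post_init__(self):
        if any(f <= 0 for f in self.per_replicate_fold):
            raise ValueError("fold changes must be positive")


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test from the closed-form statistic.

    Returns (t, p).  Both-groups-zero-variance edge cases: equal means give
    p = 1 by convention, unequal means p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom2 = va / a.size + vb / b.size
    if denom2 == 0:
        return (0.0, 1.0) if ma == mb else (math.inf, 0.0)
    t = (ma - mb) / math.sqrt(denom2)
    df = denom2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def delta_delta_ct(q: QpcrTable, control_strain: str) -> list[FoldChangeResult]:
    """Livak 2^-ddCt fold changes per (target gene, strain).

    dCt is computed per replicate against that replicate's reference-gene
    Ct; ddCt centers on the control strain's mean dCt; per-replicate folds
    are 2^-ddCt, rescaled by the control's mean fold so the control strain
    reports exactly 1.  The p-value is a two-sided Welch t-test on dCt
    values, strain vs control (1.0 for the control itself).
    """
    df = q.df
    ref_rows = df[df["target_gene"] == df["reference_gene"]]
    ref_ct = {
        (r["strain"], r["reference_gene"], r["replicate"]): r["ct"]
        for _, r in ref_rows.iterrows()
    }
    targets = df[df["target_gene"] != df["reference_gene"]].copy()
    dcts = []
    for _, row in targets.iterrows():
        key = (row["strain"], row["reference_gene"], row["replicate"])
        if key not in ref_ct:
            raise ValueError(f"missing reference Ct for row {row.to_dict()}")
        dcts.append(row["ct"] - ref_ct[key])
    targets["dct"] = dcts

    results: list[FoldChangeResult] = []
    for target, sub in targets.groupby("target_gene", sort=True):
        control = sub[sub["strain"] == control_strain]
        if control.empty:
            raise ValueError(f"control strain {control_strain!r} absent for {target!r}")
        control_mean_dct = control["dct"].mean()
        control_dct = control["dct"].to_numpy()
        # control's own mean arithmetic fold; rescaling keeps control at 1
        control_scale = float(np.mean(2.0 ** -(control_dct - control_mean_dct)))
        for strain, grp in sub.groupby("strain", sort=True):
            ddct = grp["dct"].to_numpy() - control_mean_dct
            folds = 2.0**-ddct / control_scale
            if len(folds) >= 2:
                sem = float(folds.std(ddof=1) / math.sqrt(len(folds)))
            else:
                warnings.warn(
                    f"<2 replicates for {target!r}/{strain!r}; SEM undefined",
                    stacklevel=2,
                )
                sem = float("nan")
            if strain == control_strain:
                p = 1.0
            else:
                _, p = welch_t_test(grp["dct"].to_numpy(), control_dct)
            results.append(
                FoldChangeResult(
                    target_gene=target,
                    strain=strain,
                    per_replicate_fold=tuple(float(f) for f in folds),
                    mean_fold=float(folds.mean()),
                    sem=sem,
                    p_value=float(p),
                )
            )
    return results


def fold_change_frame(results: list[FoldChangeResult]) -> pd.DataFrame:
    """Tabular view of ddCt results for writing to TSV."""
    return pd.DataFrame(
        {
            "target_gene": [r.target_gene for r in results],
            "strain": [r.strain for r in results],
            "mean_fold": [r.mean_fold for r in results],
            "sem": [r.sem for r in results],
            "p_value": [r.p_value for r in results],
            "n_replicates": [len(r.per_replicate_fold) for r in results],
        }
    )


@dataclass(frozen=True)
class DunnettResult:
    f_statistic: float
    f_pvalue: float
    comparisons: dict[str, dict] = field(default_factory=dict)


def anova_dunnett(
    groups: dict[str, np.ndarray],
    control_label: str,
    alpha: float = 0.05,
    n_mc: int = 20_000,
    seed: int | None = None,
) -> DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a control.

    Each non-control group is compared to the control with the pooled-variance
    t statistic; the family-wise adjusted p-value for |t_i| is the Monte-Carlo
    probability that the null max-|t| (over all comparisons, with the shared
    control and pooled variance estimate correlating them) exceeds |t_i|.

    Groups with fewer than two values are excluded with a warning.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    clean: dict[str, np.ndarray] = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {label!r} has <2 values; excluded", stacklevel=2)
            continue
        clean[label] = arr
    if control_label not in clean:
        raise ValueError(f"control group {control_label!r} has <2 values")
    others = [lab for lab in clean if lab != control_label]
    if not others:
        raise ValueError("need at least one non-control group")

    f_stat, f_p = stats.f_oneway(*clean.values())

    control = clean[control_label]
    n0 = control.size
    n_total = sum(a.size for a in clean.values())
    df_err = n_total - len(clean)
    s2 = sum((a.size - 1) * a.var(ddof=1) for a in clean.values()) / df_err
    n_i = np.array([clean[lab].size for lab in others])
    se = np.sqrt(s2 * (1.0 / n_i + 1.0 / n0))
    t_obs = np.array([clean[lab].mean() - control.mean() for lab in others]) / np.where(
        se == 0, np.nan, se
    )

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc) / math.sqrt(n0)
    zi = rng.standard_normal((n_mc, len(others))) / np.sqrt(n_i)
    s_null = np.sqrt(rng.chisquare(df_err, n_mc) / df_err)
    t_null = (zi - z0[:, None]) / (s_null[:, None] * np.sqrt(1.0 / n_i + 1.0 / n0))
    max_abs = np.abs(t_null).max(axis=1)

    comparisons = {}
    for j, lab in enumerate(others):
        if np.isnan(t_obs[j]):  # zero pooled variance: all values identical
            p_adj = 1.0 if clean[lab].mean() == control.mean() else 0.0
            t_j = 0.0 if p_adj == 1.0 else math.inf
        else:
            t_j = float(t_obs[j])
            p_adj = float(np.mean(max_abs >= abs(t_j)))
        comparisons[lab] = {
            "t": t_j,
            "p_adjusted": p_adj,
            "significant": bool(p_adj <= alpha),
        }
    return DunnettResult(
        f_statistic=float(f_stat), f_pvalue=float(f_p), comparisons=comparisons
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch p-values for genes x replicates blocks."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(denom2)
        df = denom2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = denom2 == 0
    p[zero & (ma == mb)] = 1.0
    p[zero & (ma != mb)] = 0.0
    return p


def simple_de_caller(
    m: ExpressionMatrix,
    contrast: tuple[str, str],
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> GeneSet:
    """Stand-in DE caller: Welch t on log2(CPM + pseudocount), BH at ``fdr``,
    returning genes significantly UP in the second genotype of ``contrast``.

    This is a deliberately simple caller for synthetic end-to-end runs; it
    makes no claim of equivalence to published DE pipelines.
    """
    geno_a, geno_b = contrast
    a = m.submatrix(geno_a).to_numpy(dtype=float)
    b = m.submatrix(geno_b).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each genotype needs >=2 replicates")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    p = _welch_rows(la, lb)
    p_adj = benjamini_hochberg(p)
    up = (p_adj <= fdr) & (lb.mean(axis=1) > la.mean(axis=1))
    genes = frozenset(np.asarray(m.gene_ids)[up])
    return GeneSet(
        name=f"{geno_b}_up", genes=genes, condition=f"up_in_{geno_b}_vs_{geno_a}",
        source="simple_de_caller",
    )
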