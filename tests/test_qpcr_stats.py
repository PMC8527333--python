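"""ddCt quantification and the statistical machinery: Welch t, BH, Dunnett
Monte-Carlo, and the stand-in DE caller, each against an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mitoupr.core_io import QpcrTable
from mitoupr.qpcr_stats import (
    anova_dunnett,
    benjamini_hochberg,
    delta_delta_ct,
    simple_de_caller,
    welch_t_test,
)
from mitoupr.synthetic_data import SyntheticConfig, generate


def qpcr_table(rows):
    return QpcrTable(df=pd.DataFrame(
        rows, columns=["strain", "target_gene", "reference_gene", "replicate", "ct"]))


def simple_table(target_cts_by_strain, ref_ct=15.0):
    rows = []
    for strain, cts in target_cts_by_strain.items():
        for rep, ct in enumerate(cts, start=1):
            rows.append((strain, "act-3", "act-3", rep, ref_ct))
            rows.append((strain, "tgt", "act-3", rep, ct))
    return qpcr_table(rows)


class TestDeltaDeltaCt:
    def test_zero_ddct_gives_fold_one(self):
        res = delta_delta_ct(simple_table({"WT": [25, 25, 25], "mut": [25, 25, 25]}), "WT")
        assert all(r.mean_fold == pytest.approx(1.0) for r in res)

    def test_one_cycle_down_doubles(self):
        res = delta_delta_ct(simple_table({"WT": [25, 25], "mut": [24, 24]}), "WT")
        mut = next(r for r in res if r.strain == "mut")
        assert mut.mean_fold == pytest.approx(2.0)

    def test_control_strain_reports_exactly_one_even_with_noise(self, rng):
        cts = {"WT": list(25 + rng.normal(0, 0.3, 3)), "mut": list(23 + rng.normal(0, 0.3, 3))}
        res = delta_delta_ct(simple_table(cts), "WT")
        wt = next(r for r in res if r.strain == "WT")
        assert wt.mean_fold == pytest.approx(1.0)
        assert wt.p_value == 1.0

    def test_random_table_matches_spreadsheet_style_oracle(self, rng):
        """Row-by-row recomputation with plain dict arithmetic."""
        strains = {"WT": list(rng.uniform(24, 26, 3)), "mut": list(rng.uniform(22, 24, 3))}
        refs = {("WT", r): rng.uniform(14, 16) for r in (1, 2, 3)}
        refs.update({("mut", r): rng.uniform(14, 16) for r in (1, 2, 3)})
        rows = []
        for strain, cts in strains.items():
            for rep, ct in enumerate(cts, start=1):
                rows.append((strain, "act-3", "act-3", rep, refs[(strain, rep)]))
                rows.append((strain, "tgt", "act-3", rep, ct))
        res = delta_delta_ct(qpcr_table(rows), "WT")
        # oracle
        dct = {(s, r): strains[s][r - 1] - refs[(s, r)]
               for s in strains for r in (1, 2, 3)}
        ctrl_mean = np.mean([dct[("WT", r)] for r in (1, 2, 3)])
        raw = {s: [2.0 ** -(dct[(s, r)] - ctrl_mean) for r in (1, 2, 3)] for s in strains}
        scale = np.mean(raw["WT"])
        for r in res:
            expected = np.mean(raw[r.strain]) / scale
            assert r.mean_fold == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=2))
    def test_plate_shift_invariance(self, shifts):
        """Adding a constant to every Ct of a replicate leaves folds unchanged."""
        base = simple_table({"WT": [25.0, 25.4], "mut": [23.1, 23.5]})
        shifted = base.df.copy()
        for rep, shift in enumerate(shifts, start=1):
            shifted.loc[shifted["replicate"] == rep, "ct"] += shift
        res0 = delta_delta_ct(base, "WT")
        res1 = delta_delta_ct(QpcrTable(df=shifted), "WT")
        for a, b in zip(res0, res1):
            assert a.mean_fold == pytest.approx(b.mean_fold, rel=1e-9)

    def test_missing_reference_is_hard_error(self):
        rows = [("WT", "act-3", "act-3", 1, 15.0), ("WT", "tgt", "act-3", 1, 25.0),
                ("mut", "tgt", "act-3", 1, 23.0)]
        with pytest.raises(ValueError, match="reference"):
            qpcr_table(rows)


class TestWelch:
    def test_identical_groups_p_one(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_near_zero_variance_separated_groups(self):
        _, p = welch_t_test([0.0, 0.0, 0.0], [10.0, 10.0, 10.0001])
        assert p < 1e-6

    def test_matches_scipy_reference_to_1e10(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 12))
            b = rng.normal(0.4, 2, rng.integers(2, 12))
            t, p = welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_adjusted_monotone_in_raw_rank(self, ps):
        adj = benjamini_hochberg(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert ((adj >= np.asarray(ps) - 1e-12) & (adj <= 1.0)).all()


class TestDunnett:
    def test_identical_groups_never_significant(self):
        vals = np.array([1.0, 1.0, 1.0, 1.0])
        res = anova_dunnett({"c": vals, "a": vals, "b": vals}, "c",
                            alpha=0.2, n_mc=2000, seed=0)
        assert not any(c["significant"] for c in res.comparisons.values())

    def test_two_group_degeneracy_matches_plain_t(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 6)
        res = anova_dunnett({"c": a, "x": b}, "c", n_mc=200_000, seed=42)
        p_t = stats.ttest_ind(b, a, equal_var=True).pvalue
        assert res.comparisons["x"]["p_adjusted"] == pytest.approx(p_t, abs=0.01)

    def test_matches_scipy_dunnett_oracle(self, rng):
        control = rng.normal(0, 1, 6)
        g1 = rng.normal(0.5, 1, 6)
        g2 = rng.normal(0, 1, 6)
        res = anova_dunnett({"c": control, "g1": g1, "g2": g2}, "c",
                            n_mc=200_000, seed=1)
        ref = stats.dunnett(g1, g2, control=control)
        assert res.comparisons["g1"]["p_adjusted"] == pytest.approx(ref.pvalue[0], abs=0.02)
        assert res.comparisons["g2"]["p_adjusted"] == pytest.approx(ref.pvalue[1], abs=0.02)

    def test_small_group_excluded_with_warning(self, rng):
        groups = {"c": rng.normal(0, 1, 5), "a": rng.normal(0, 1, 5),
                  "tiny": np.array([1.0])}
        with pytest.warns(UserWarning, match="tiny"):
            res = anova_dunnett(groups, "c", n_mc=1000, seed=0)
        assert set(res.comparisons) == {"a"}


class TestSimpleDeCaller:
    def test_noiseless_shift_returns_exactly_that_gene(self):
        cfg = SyntheticConfig(n_genes=100, n_signature=1, n_decoys_per_class=0,
                              cv=0.0, n_isp1_nonresponders=0,
                              activation_fold=16.0, chip_fraction=1.0, seed=5)
        ds = generate(cfg)
        up = simple_de_caller(ds.matrix, ("WT", "spg-7i"))
        assert up.genes == ds.truth.planted_signature.genes

    def test_null_false_positive_fraction_small(self, default_dataset):
        # WT vs atfs-1 is a pure-null contrast in the default design
        up = simple_de_caller(default_dataset.matrix, ("WT", "atfs-1"))
        assert len(up) / len(default_dataset.matrix.gene_ids) <= 0.05
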