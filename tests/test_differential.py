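"""Differential expression/methylation calling tests.

Frozen expected values for the statistical operations were computed
with the brute-force enumeration oracles in conftest before being
asserted here.
"""

import numpy as np
import pandas as pd
import pytest

from conftest import exact_mannwhitney_p, make_meth_dataset
from epistage.datatypes import ExpressionDataset, ValidationError
from epistage.differential import (
    collapse_probes_expression,
    collapse_probes_methylation,
    delta_beta,
    fdr_threshold,
    mann_whitney_p,
    mann_whitney_pvalues,
    permutation_pvalues,
    q_values,
    significant_expressed,
    significant_methylated,
)

GROUPS_2x2 = {"N1": "normal", "N2": "normal", "T1": "disease", "T2": "disease"}


def make_expr(probe_values: dict, probe_to_gene: dict, samples=None) -> ExpressionDataset:
    samples = samples or [f"S{i}" for i in range(len(next(iter(probe_values.values()))))]
    mat = pd.DataFrame(probe_values, index=samples).T
    return ExpressionDataset(stage="I", log2ratio=mat, probe_to_gene=probe_to_gene)


class TestExpression:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1.5, 1.3], 1.4),  # median of two
            ([2.0], 2.0),  # single probe unchanged
            ([1.0, 2.0, 9.0], 2.0),  # median of three
        ],
    )
    def test_probe_collapse_median(self, values, expected):
        probes = {f"P{i}": [v] for i, v in enumerate(values)}
        expr = make_expr(probes, {p: "G" for p in probes})
        assert collapse_probes_expression(expr).loc["G", "S0"] == expected

    def test_boundary_inclusive(self):
        expr = make_expr({"P1": [1.4, 1.4]}, {"P1": "G"})
        recs = significant_expressed(expr)
        assert len(recs) == 1 and recs[0].log2_summary == pytest.approx(1.4)

    def test_mixed_signs_not_significant(self):
        expr = make_expr({"P1": [0.5, -0.5]}, {"P1": "G"})
        assert significant_expressed(expr) == []

    def test_all_missing_gene_excluded(self):
        expr = make_expr({"P1": [np.nan, np.nan], "P2": [2.0, 2.0]}, {"P1": "G1", "P2": "G2"})
        assert [r.gene for r in significant_expressed(expr)] == ["G2"]

    def test_per_sample_modes(self):
        expr = make_expr({"P1": [3.0, 0.0]}, {"P1": "G"})
        # mean is 1.5 >= 1.4 -> significant under the default rule
        assert [r.gene for r in significant_expressed(expr)] == ["G"]
        assert [r.gene for r in significant_expressed(expr, mode="any")] == ["G"]
        assert significant_expressed(expr, mode="all") == []


class TestDeltaBeta:
    def test_arithmetic(self):
        ds = make_meth_dataset({"G": [0.2, 0.2, 0.6, 0.6]}, GROUPS_2x2)
        assert delta_beta(ds)["G"] == pytest.approx(0.4)

    def test_identical_groups_zero(self):
        ds = make_meth_dataset({"G": [0.5, 0.5, 0.5, 0.5]}, GROUPS_2x2)
        assert delta_beta(ds)["G"] == 0.0

    def test_negative_direction(self):
        ds = make_meth_dataset({"G": [0.7, 0.7, 0.3, 0.3]}, GROUPS_2x2)
        assert delta_beta(ds)["G"] == pytest.approx(-0.4)

    def test_min_per_group_exclusion(self):
        ds = make_meth_dataset({"G": [0.2, np.nan, 0.6, 0.6]}, GROUPS_2x2)
        assert "G" not in delta_beta(ds, min_per_group=2).index
        assert delta_beta(ds, min_per_group=1)["G"] == pytest.approx(0.4)


class TestMannWhitney:
    def test_exact_2v2_extreme(self):
        # all C(4,2)=6 labelings; the observed split is one of the two
        # most extreme -> p = 2/6
        p = mann_whitney_p(np.array([0.1, 0.2]), np.array([0.8, 0.9]))
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_samples_p_one(self):
        assert mann_whitney_p(np.array([0.5, 0.5]), np.array([0.5, 0.5])) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_p(np.array([]), np.array([0.5]))

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(0.5, size=4)
            assert mann_whitney_p(x, y) == pytest.approx(
                exact_mannwhitney_p(x, y), abs=1e-12
            )

    def test_approximation_close_to_exact_at_8v8(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(0.8, size=8)
            exact = exact_mannwhitney_p(x, y)
            res = mann_whitney_p(x, np.round(y, 1))  # rounding can add ties
            approx = mann_whitney_p(x, y)
            assert abs(approx - exact) <= 0.02
            assert 0.0 <= res <= 1.0


class TestPermutation:
    def test_converges_to_exact_for_2v2(self):
        ds = make_meth_dataset({"G": [0.1, 0.2, 0.8, 0.9]}, GROUPS_2x2)
        perm = permutation_pvalues(ds, n_perm=2000, seed=5)["G"]
        exact = exact_mannwhitney_p([0.1, 0.2], [0.8, 0.9])
        assert abs(perm - exact) <= 0.03

    def test_constant_gene_p_one(self):
        ds = make_meth_dataset({"G": [0.4] * 4}, GROUPS_2x2)
        assert permutation_pvalues(ds, n_perm=200, seed=0)["G"] == 1.0

    def test_same_seed_identical(self):
        vals = {"G1": [0.1, 0.3, 0.7, 0.9], "G2": [0.5, 0.6, 0.4, 0.2]}
        ds = make_meth_dataset(vals, GROUPS_2x2)
        a = permutation_pvalues(ds, n_perm=500, seed=42)
        b = permutation_pvalues(ds, n_perm=500, seed=42)
        pd.testing.assert_series_equal(a, b)

    def test_n_perm_validation(self):
        ds = make_meth_dataset({"G": [0.1, 0.2, 0.8, 0.9]}, GROUPS_2x2)
        with pytest.raises(ValidationError):
            permutation_pvalues(ds, n_perm=0)

    def test_missing_values_handled_per_row(self):
        vals = {"G1": [0.1, 0.3, 0.7, 0.9], "G2": [0.5, np.nan, 0.4, 0.2]}
        ds = make_meth_dataset(vals, GROUPS_2x2)
        out = permutation_pvalues(ds, n_perm=200, seed=1)
        assert set(out.index) == {"G1", "G2"}
        assert ((out > 0) & (out <= 1)).all()


class TestFdrThreshold:
    def test_all_null_sentinel(self):
        p = pd.Series(np.ones(20))
        assert fdr_threshold(p) == 0.0

    def test_bh_example(self):
        # 10 true signals at p=0.001 among 90 nulls at p=0.9:
        # BH q for the signal block is 0.001*100/10 = 0.01 <= FDR
        p = pd.Series([0.001] * 10 + [0.9] * 90)
        assert fdr_threshold(p, fdr=0.01) == pytest.approx(0.001)

    def test_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(3)
        p = pd.Series(rng.random(50))
        q = q_values(p)
        srt = q[p.sort_values().index].to_numpy()
        assert (np.diff(srt) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            fdr_threshold(pd.Series([0.5, 1.5]))

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(4)
        p = pd.Series(np.concatenate([rng.random(80), np.full(20, 1e-4)]))
        assert (q_values(p, method="storey") <= q_values(p, method="bh") + 1e-15).all()


class TestSignificantMethylated:
    GROUPS_8x8 = {f"N{i}": "normal" for i in range(8)} | {
        f"T{i}": "disease" for i in range(8)
    }

    def _dataset(self):
        rng = np.random.default_rng(0)
        vals = {}
        # 5 planted hyper, 3 planted hypo, 40 nulls
        for i in range(5):
            vals[f"HYP{i}"] = list(rng.uniform(0.05, 0.15, 8)) + list(
                rng.uniform(0.55, 0.65, 8)
            )
        for i in range(3):
            vals[f"LOW{i}"] = list(rng.uniform(0.75, 0.85, 8)) + list(
                rng.uniform(0.25, 0.35, 8)
            )
        for i in range(40):
            base = rng.uniform(0.3, 0.7)
            vals[f"NULL{i}"] = list(rng.uniform(base - 0.05, base + 0.05, 16))
        return make_meth_dataset(vals, self.GROUPS_8x8)

    def test_rule_application_and_disjointness(self):
        hyper, hypo = significant_methylated(self._dataset(), n_perm=100, seed=0)
        hyper_genes = {r.gene for r in hyper}
        hypo_genes = {r.gene for r in hypo}
        assert hyper_genes == {f"HYP{i}" for i in range(5)}
        assert hypo_genes == {f"LOW{i}" for i in range(3)}
        assert not hyper_genes & hypo_genes
        for r in hyper:
            assert r.delta_beta >= 0.25 and r.q_value <= 0.01

    def test_large_effect_weak_p_excluded(self):
        # delta-beta 0.4 but high variance / overlapping groups -> p ~ 1
        vals = {"G": [0.1, 0.9, 0.1, 0.9, 0.1, 0.9, 0.1, 0.9,
                      0.5, 0.9, 0.5, 0.1, 0.9, 0.5, 0.1, 0.5]}
        groups = self.GROUPS_8x8
        ds = make_meth_dataset(vals, groups)
        hyper, hypo = significant_methylated(ds, p_cutoff=0.0012, n_perm=50, seed=0)
        assert hyper == [] and hypo == []

    def test_invariant_to_sample_and_gene_order(self):
        ds = self._dataset()
        shuffled = ds.beta[list(reversed(ds.beta.columns))].iloc[::-1]
        ds2 = make_meth_dataset(
            {g: list(shuffled.loc[g]) for g in shuffled.index},
            {s: ds.group[s] for s in shuffled.columns},
        )
        a = significant_methylated(ds, n_perm=100, seed=0)
        b = significant_methylated(ds2, n_perm=100, seed=0)
        assert {r.gene for r in a[0]} == {r.gene for r in b[0]}
        assert {r.gene for r in a[1]} == {r.gene for r in b[1]}


class TestProbeCollapseMethylation:
    def test_largest_abs_delta_kept(self):
        vals = {
            "P1": [0.2, 0.2, 0.5, 0.5],  # |db| = 0.3
            "P2": [0.1, 0.1, 0.7, 0.7],  # |db| = 0.6  <- winner
            "P3": [0.4, 0.4, 0.4, 0.4],  # other gene
        }
        ds = make_meth_dataset(vals, GROUPS_2x2)
        ds.probe_to_gene = {"P1": "G1", "P2": "G1", "P3": "G2"}
        collapsed = collapse_probes_methylation(ds, min_per_group=2)
        assert list(collapsed.beta.index) == ["G1", "G2"]
        assert collapsed.beta.loc["G1"].tolist() == vals["P2"]
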