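"""PI assembly, differential t-tests, BH adjustment and marker calling."""

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from spatprox import (
    InvalidParameterError,
    assemble_pi,
    bh_adjust,
    deg_direction_summary,
    differential_pi,
    wilcoxon_markers,
)

SHEET = pd.DataFrame(
    {
        "sample_id": ["P1", "P2", "P3", "R1", "R2", "R3"],
        "group": ["primary"] * 3 + ["recurrent"] * 3,
    }
)


def _prox_frame(sample_id, rows):
    return pd.DataFrame(
        [
            {"sample_id": sample_id, "type_a": a, "type_b": b, "pi": pi}
            for a, b, pi in rows
        ]
    )


class TestAssemblePi:
    def test_complete_unit_no_imputation(self):
        results = [
            _prox_frame(sid, [("A", "B", 0.5)]) for sid in SHEET.sample_id
        ]
        table = assemble_pi(results, SHEET)
        assert table.loc["A--B", "n_imputed"] == 0
        assert (table.loc["A--B", SHEET.sample_id] == 0.5).all()

    def test_missing_unit_imputed_zero(self):
        results = [
            _prox_frame(sid, [("A", "B", 1.0)]) for sid in SHEET.sample_id[:-1]
        ] + [_prox_frame("R3", [("A", "C", 2.0)])]
        table = assemble_pi(results, SHEET)
        assert table.loc["A--B", "R3"] == 0.0
        assert table.loc["A--B", "n_imputed"] == 1
        assert table.loc["A--C", "n_imputed"] == 5

    def test_row_sums_match_concatenation(self):
        rng = np.random.default_rng(0)
        results = []
        for sid in SHEET.sample_id:
            rows = [
                (f"T{i}", f"T{j}", rng.normal())
                for i in range(3)
                for j in range(i, 3)
                if rng.random() < 0.8
            ]
            results.append(_prox_frame(sid, rows))
        table = assemble_pi(results, SHEET)
        concat = pd.concat(results)
        concat["unit"] = concat.type_a + "--" + concat.type_b
        expected = concat.groupby("unit")["pi"].sum()
        got = table[list(SHEET.sample_id)].sum(axis=1)
        assert np.allclose(got.loc[expected.index], expected)


class TestDifferentialPi:
    def test_known_t_statistic(self):
        results = []
        for sid, pi in zip(SHEET.sample_id, [0.1, 0.2, 0.3, 1.1, 1.2, 1.3]):
            results.append(_prox_frame(sid, [("A", "B", pi)]))
        diff = differential_pi(assemble_pi(results, SHEET), SHEET)
        row = diff.iloc[0]
        assert row.df == 4
        assert np.isclose(row.t, 12.247, atol=5e-4)
        # independent p via the regularised incomplete beta function
        p_expect = scipy.special.betainc(2.0, 0.5, 4 / (4 + row.t**2))
        assert np.isclose(row.p_value, p_expect, rtol=1e-10)
        assert np.isclose(row.p_value, 2.6e-4, rtol=0.05)
        assert row.significant and row.direction == 1

    def test_identical_groups_degenerate(self):
        results = [_prox_frame(sid, [("A", "B", 0.7)]) for sid in SHEET.sample_id]
        diff = differential_pi(assemble_pi(results, SHEET), SHEET)
        row = diff.iloc[0]
        assert row.direction == 0 and row.p_value == 1.0 and not row.degenerate

    def test_zero_variance_unequal_means_degenerate(self):
        pis = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
        results = [
            _prox_frame(sid, [("A", "B", pi)])
            for sid, pi in zip(SHEET.sample_id, pis)
        ]
        diff = differential_pi(assemble_pi(results, SHEET), SHEET)
        row = diff.iloc[0]
        assert row.p_value == 0.0 and row.degenerate

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        results = [
            _prox_frame(sid, [("A", "B", rng.normal()), ("A", "C", rng.normal())])
            for sid in SHEET.sample_id
        ]
        table = assemble_pi(results, SHEET)
        swapped = SHEET.assign(
            group=SHEET.group.map({"primary": "recurrent", "recurrent": "primary"})
        )
        d1 = differential_pi(table, SHEET)
        d2 = differential_pi(assemble_pi(results, swapped), swapped)
        assert np.allclose(d1.t, -d2.t)
        assert np.allclose(d1.p_value, d2.p_value)

    def test_welch_variant_matches_scipy(self):
        rng = np.random.default_rng(2)
        results = [
            _prox_frame(sid, [("A", "B", rng.normal())]) for sid in SHEET.sample_id
        ]
        table = assemble_pi(results, SHEET)
        d = differential_pi(table, SHEET, variant="welch").iloc[0]
        vals = table[list(SHEET.sample_id)].to_numpy().ravel()
        ref = scipy.stats.ttest_ind(vals[3:], vals[:3], equal_var=False)
        assert np.isclose(d.t, ref.statistic) and np.isclose(d.p_value, ref.pvalue)


class TestBhAdjust:
    def test_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_identities(self):
        assert bh_adjust([0.3]) == [0.3]
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.array(sorted(range(len(p)), key=lambda _: rnd.random()))
        direct = bh_adjust(p)
        via_perm = np.empty_like(direct)
        via_perm[perm] = bh_adjust(p[perm])
        assert np.allclose(direct, via_perm)


class TestWilcoxonMarkers:
    @staticmethod
    def _null_matrix(n_genes=200, n1=50, n2=50, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.negative_binomial(2, 0.5, size=(n_genes, n1 + n2)).astype(float)
        return np.log1p(X), np.array(["a"] * n1 + ["b"] * n2)

    def test_identical_gene_not_passed(self):
        X, groups = self._null_matrix(seed=1)
        X[0] = 1.0  # constant everywhere
        tab = wilcoxon_markers(X, groups, ("a", "b"), min_pct=0.0, min_lfc=-np.inf)
        row = tab.iloc[0]
        assert row.log2_fc == 0.0 and not row["pass"]

    def test_matches_scipy_mannwhitney(self):
        X, groups = self._null_matrix(n_genes=20, seed=2)
        tab = wilcoxon_markers(X, groups, ("a", "b"), min_pct=0.0, min_lfc=-np.inf)
        for i in range(20):
            ref = scipy.stats.mannwhitneyu(
                X[i, :50], X[i, 50:], alternative="two-sided", method="asymptotic"
            )
            assert np.isclose(tab.p_value[i], ref.pvalue, rtol=1e-9)

    def test_prefilter_excluded_from_bh(self):
        X, groups = self._null_matrix(seed=3)
        X[5, :50] += 5.0  # passes prefilter
        tab = wilcoxon_markers(X, groups, ("a", "b"))
        assert tab.tested[5]
        assert tab.p_value[~tab.tested].isna().all()
        tested_p = tab.p_value[tab.tested].to_numpy()
        assert np.allclose(
            tab.adj_p_value[tab.tested], bh_adjust(tested_p)
        )

    def test_undersized_group_rejected(self):
        X, groups = self._null_matrix(n1=2, n2=50)
        with pytest.raises(InvalidParameterError):
            wilcoxon_markers(X, groups, ("a", "b"))


class TestDegDirectionSummary:
    @staticmethod
    def _table(genes, lfcs, passes):
        return pd.DataFrame(
            {
                "gene": genes,
                "log2_fc": lfcs,
                "pass": passes,
            }
        )

    def test_disjoint_sets_all_k1(self):
        t1 = self._table(["g1", "g2"], [1.0, 1.0], [True, True])
        t2 = self._table(["g3"], [1.0], [True])
        s = deg_direction_summary([t1, t2])
        assert s["genes_by_k"] == {1: 3}
        assert s["opposite_direction"] == 0

    def test_opposite_direction_counted(self):
        t1 = self._table(["g1"], [1.0], [True])
        t2 = self._table(["g1"], [-0.5], [True])
        s = deg_direction_summary([t1, t2])
        assert s["genes_by_k"] == {2: 1}
        assert s["opposite_direction"] == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        tables = [
            self._table(
                genes,
                rng.normal(size=200),
                rng.random(200) < 0.3,
            )
            for _ in range(5)
        ]
        s = deg_direction_summary(tables)
        # brute force over genes
        by_k: dict[int, int] = {}
        opp = 0
        for gi, g in enumerate(genes):
            lfcs = [
                t.log2_fc[gi] for t in tables if t["pass"][gi]
            ]
            if not lfcs:
                continue
            by_k[len(lfcs)] = by_k.get(len(lfcs), 0) + 1
            if min(np.sign(lfcs)) != max(np.sign(lfcs)):
                opp += 1
        assert s["genes_by_k"] == by_k
        assert s["opposite_direction"] == opp
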