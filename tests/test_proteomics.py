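"""Normalization, differential abundance, candidate gating, triplot, Z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquekit.proteomics import (
    AbundanceTable,
    normalize_global_mean,
    pairwise_compare,
    select_candidates,
    triangle_vertices,
    triplot_coordinates,
    zscore_matrix,
)
from plaquekit.synthetic import ProteomicsDesign, generate_proteomics


def table_from(values, groups):
    df = pd.DataFrame(values)
    return AbundanceTable(df, groups)


def two_group_table(a_rows, b_rows, ids=None):
    """a_rows/b_rows: arrays (n_proteins, n_reps)."""
    a = np.asarray(a_rows, float)
    b = np.asarray(b_rows, float)
    cols = {f"A_{i+1}": a[:, i] for i in range(a.shape[1])}
    cols |= {f"B_{i+1}": b[:, i] for i in range(b.shape[1])}
    df = pd.DataFrame(cols, index=ids or [f"P{i}" for i in range(a.shape[0])])
    groups = {c: c[0] for c in df.columns}
    return AbundanceTable(df, groups)


class TestNormalization:
    def test_equal_mean_table_is_fixed_point(self):
        t = table_from({"s1": [1.0, 3.0], "s2": [2.0, 2.0]}, {"s1": "A", "s2": "B"})
        out = normalize_global_mean(t)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_scale_invariance_up_to_common_level(self):
        """Multiplying one sample by a constant pre-normalization leaves the
        normalized table unchanged up to the overall abundance level (all
        sample means are equalized either way)."""
        base = {"s1": [1.0, 3.0], "s2": [2.0, 6.0]}
        t1 = table_from(base, {"s1": "A", "s2": "B"})
        scaled = {"s1": [2.0, 6.0], "s2": [2.0, 6.0]}
        t2 = table_from(scaled, {"s1": "A", "s2": "B"})
        out1, out2 = normalize_global_mean(t1), normalize_global_mean(t2)
        v1 = out1.values / out1.values.to_numpy().mean()
        v2 = out2.values / out2.values.to_numpy().mean()
        pd.testing.assert_frame_equal(v1, v2)
        assert out1.values.mean(axis=0).nunique() == 1
        assert out2.values.mean(axis=0).nunique() == 1

    def test_hand_computed_scale_factors(self):
        t = table_from(
            {"s1": [10.0, 10.0], "s2": [20.0, 20.0], "s3": [30.0, 30.0]},
            {"s1": "A", "s2": "B", "s3": "C"},
        )
        out = normalize_global_mean(t)
        # grand mean 20 -> factors 2, 1, 2/3
        assert out.values["s1"].tolist() == [20.0, 20.0]
        assert out.values["s2"].tolist() == [20.0, 20.0]
        assert out.values["s3"].to_numpy() == pytest.approx([20.0, 20.0])

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(10, 1, (50, 6)),
                          columns=[f"s{i}" for i in range(6)])
        t = AbundanceTable(df, {f"s{i}": "A" if i < 3 else "B" for i in range(6)})
        once = normalize_global_mean(t)
        twice = normalize_global_mean(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_all_missing_sample_raises(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]})
        t = AbundanceTable(df, {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="all-missing"):
            normalize_global_mean(t)


class TestPairwiseCompare:
    def test_identical_groups_null_result(self):
        rows = np.tile([10.0, 12.0, 11.0], (3, 1))
        t = two_group_table(rows, rows)
        results = pairwise_compare(t, "A", "B")
        for r in results:
            assert r.log2_ratio == 0.0
            assert r.p_value == 1.0

    def test_noise_free_fc2_log2_ratio_exactly_one(self):
        a = np.full((2, 3), 20.0)
        b = np.full((2, 3), 10.0)
        r = pairwise_compare(two_group_table(a, b), "A", "B")[0]
        assert r.log2_ratio == pytest.approx(1.0)
        assert r.fold_change == pytest.approx(2.0)

    def test_worked_welch_example(self):
        a = np.array([[10.0, 12.0, 11.0, 13.0, 10.0]])
        b = np.array([[20.0, 22.0, 21.0, 23.0, 20.0]])
        r = pairwise_compare(two_group_table(a, b), "A", "B")[0]
        assert r.log2_ratio == pytest.approx(np.log2(11.2 / 21.2), abs=1e-9)
        assert r.log2_ratio == pytest.approx(-0.93, abs=0.02)
        assert r.p_value < 0.01

    def test_welch_p_matches_brute_force_formulas(self):
        """Explicit mean/variance Welch computation agrees to 1e-10."""
        from scipy.stats import t as tdist

        rng = np.random.default_rng(7)
        for _ in range(100):
            na, nb = rng.integers(3, 8), rng.integers(3, 8)
            a = rng.lognormal(10, 0.5, (4, na))
            b = rng.lognormal(10.2, 0.7, (4, nb))
            results = pairwise_compare(two_group_table(a, b), "A", "B")
            la, lb = np.log2(a), np.log2(b)
            va = la.var(axis=1, ddof=1) / na
            vb = lb.var(axis=1, ddof=1) / nb
            tstat = (la.mean(axis=1) - lb.mean(axis=1)) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            p = 2 * tdist.sf(np.abs(tstat), df)
            for r, expect in zip(results, p):
                assert r.p_value == pytest.approx(expect, abs=1e-10)

    def test_nonpositive_abundance_excluded(self):
        a = np.array([[10.0, 12.0, 11.0], [0.0, 5.0, 5.0]])
        b = np.array([[20.0, 22.0, 21.0], [5.0, 5.0, 5.0]])
        results = pairwise_compare(two_group_table(a, b), "A", "B")
        assert [r.protein_id for r in results] == ["P0"]

    def test_type_one_error_control_under_global_null(self):
        """Raw p ≤ 0.05 on 5 ± 2% of null proteins; joint FC∧p gate passes fewer."""
        design = ProteomicsDesign(
            n_proteins=2000, groups=[("A", 5), ("B", 5)], cv=0.2, seed=2024
        )
        table = generate_proteomics(design)
        results = pairwise_compare(normalize_global_mean(table), "A", "B")
        p_rate = np.mean([r.p_value <= 0.05 for r in results])
        assert p_rate == pytest.approx(0.05, abs=0.02)
        sel = select_candidates(results)
        joint = len(sel["increased"]) + len(sel["decreased"])
        assert joint <= p_rate * len(results)


class TestCandidateSelection:
    def _result(self, lr, p):
        from plaquekit.proteomics import ComparisonResult

        return ComparisonResult("P", lr, 2.0 ** abs(lr), p)

    def test_below_fc_gate_excluded(self):
        sel = select_candidates([self._result(np.log2(1.4), 0.001)])
        assert not sel["increased"] and not sel["decreased"]

    def test_above_p_gate_excluded(self):
        sel = select_candidates([self._result(np.log2(3.0), 0.2)])
        assert not sel["increased"] and not sel["decreased"]

    def test_decreased_side_gated_symmetrically(self):
        sel = select_candidates([self._result(-np.log2(2.0), 0.01)])
        assert len(sel["decreased"]) == 1

    def test_noise_free_selection_matches_generator_truth(self):
        rng = np.random.default_rng(5)
        lfc = np.zeros((300, 2))
        lfc[:150, 0] = rng.uniform(-2, 2, 150)  # mixture of effects
        design = ProteomicsDesign(
            n_proteins=300, groups=[("A", 3), ("B", 3)],
            log2_effects=lfc, cv=0.0, seed=1,
        )
        table = generate_proteomics(design)
        results = pairwise_compare(table, "A", "B")
        sel = select_candidates(results)
        flagged = {r.protein_id for r in sel["increased"] + sel["decreased"]}
        true_fc = {
            pid for pid, effect in zip(table.protein_ids, lfc[:, 0])
            if abs(effect) >= np.log2(1.5)
        }
        # noise-free: p=0 for any true difference, so gate reduces to FC
        assert flagged == true_fc

    def test_power_at_fc3(self):
        """FC=3 proteins at cv=0.1, n=5/group selected at ≥95% across seeds."""
        lfc = np.zeros((100, 2))
        lfc[:, 0] = np.log2(3.0)
        selected = total = 0
        for seed in range(50):
            design = ProteomicsDesign(
                n_proteins=100, groups=[("A", 5), ("B", 5)],
                log2_effects=lfc, cv=0.1, seed=seed,
            )
            results = pairwise_compare(generate_proteomics(design), "A", "B")
            sel = select_candidates(results)
            selected += len(sel["increased"])
            total += 100
        assert selected / total >= 0.95


class TestTriplot:
    def _table(self, means, reps=2):
        cols = {}
        groups = {}
        for g, m in zip("ABC", means):
            for i in range(reps):
                name = f"{g}{i+1}"
                cols[name] = [float(m)]
                groups[name] = g
        return AbundanceTable(pd.DataFrame(cols, index=["P"]), groups)

    def test_equal_means_map_to_centroid(self):
        pt = triplot_coordinates(self._table([1, 1, 1]), ("A", "B", "C"))[0]
        verts = triangle_vertices()
        centroid = verts.mean(axis=0)
        assert np.hypot(*(np.array(pt.xy) - centroid)) < 1e-9
        d = [np.hypot(*(np.array(pt.xy) - v)) for v in verts]
        assert max(d) - min(d) < 1e-9

    def test_elevated_group_weights_and_nearest_vertex(self):
        pt = triplot_coordinates(self._table([4, 1, 1]), ("A", "B", "C"))[0]
        assert pt.weights == pytest.approx((2 / 3, 1 / 6, 1 / 6))
        verts = triangle_vertices()
        d = [np.hypot(*(np.array(pt.xy) - v)) for v in verts]
        assert d[0] < d[1] and d[0] < d[2]

    def test_label_permutation_symmetry(self):
        t = self._table([5, 2, 1])
        base = triplot_coordinates(t, ("A", "B", "C"))[0]
        swapped = triplot_coordinates(t, ("B", "A", "C"))[0]
        # permuting labels permutes the weights accordingly
        assert swapped.weights == pytest.approx(
            (base.weights[1], base.weights[0], base.weights[2])
        )

    @settings(max_examples=30, deadline=None)
    @given(
        st.tuples(*(st.floats(0.01, 100) for _ in range(3))),
        st.floats(1.01, 10),
    )
    def test_weights_normalized_and_vertex_distance_monotone(self, means, boost):
        t1 = triplot_coordinates(self._table(list(means)), ("A", "B", "C"))[0]
        assert sum(t1.weights) == pytest.approx(1.0)
        assert all(w >= 0 for w in t1.weights)
        raised = (means[0] * boost, means[1], means[2])
        t2 = triplot_coordinates(self._table(list(raised)), ("A", "B", "C"))[0]
        v0 = triangle_vertices()[0]
        d1 = np.hypot(*(np.array(t1.xy) - v0))
        d2 = np.hypot(*(np.array(t2.xy) - v0))
        assert d2 < d1

    def test_all_zero_means_excluded(self):
        pts = triplot_coordinates(self._table([0, 0, 0]), ("A", "B", "C"))
        assert pts == []


class TestZscores:
    def test_hand_computed_row(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]})
        t = AbundanceTable(df, {"s1": "A", "s2": "B", "s3": "C"})
        z = zscore_matrix(t)
        # sample SD (n-1) convention: SD = 1
        assert z.iloc[0].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_all_zero(self):
        df = pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 3.0]})
        t = AbundanceTable(df, {"s1": "A", "s2": "B", "s3": "C"})
        z = zscore_matrix(t)
        assert (z.iloc[0] == 0).all()

    def test_rows_centered(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(8, 1, (20, 5)),
                          columns=[f"s{i}" for i in range(5)])
        t = AbundanceTable(df, {f"s{i}": "A" for i in range(5)})
        z = zscore_matrix(t)
        assert z.mean(axis=1).to_numpy() == pytest.approx(np.zeros(20), abs=1e-12)
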