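"""Jonckheere-Terpstra and spline trend tests, and opposite-trend genes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimorphnet.synthetic import CohortConfig, DTGSpec, generate_cohort
from dimorphnet.trend import (DTGSet, apoe_trend, jonckheere_test,
                              opposite_trend_genes, spline_trend_test,
                              trait_trends, trend_table)


def brute_force_jt(groups):
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    if b > a:
                        jt += 1.0
                    elif b == a:
                        jt += 0.5
    return jt


class TestJonckheere:
    def test_maximal_ordering_exact_p(self):
        res = jonckheere_test([(1, 2), (3, 4), (5, 6)],
                              alternative="increasing", mode="exact")
        assert res.jt == 12
        assert res.p == pytest.approx(1 / 90)
        assert res.direction == 1

    def test_all_ties_give_p_one(self):
        res = jonckheere_test([(2.0, 2.0)] * 3, mode="exact")
        assert res.jt == 6  # every cross pair counts one half
        assert res.p == 1.0
        assert res.direction == 0

    def test_reversing_order_swaps_alternatives(self, rng):
        groups = [rng.normal(size=3) for _ in range(3)]
        inc = jonckheere_test(groups, "increasing", "exact")
        dec = jonckheere_test(groups[::-1], "decreasing", "exact")
        assert inc.p == pytest.approx(dec.p)

    def test_statistic_matches_brute_force(self, rng):
        for _ in range(50):
            sizes = rng.integers(2, 5, size=rng.integers(2, 4))
            groups = [rng.integers(0, 4, s).astype(float) for s in sizes]
            res = jonckheere_test(groups, mode="normal")
            assert res.jt == pytest.approx(brute_force_jt(groups),
                                           abs=1e-12)

    @given(st.lists(st.lists(st.integers(min_value=0, max_value=5),
                             min_size=1, max_size=4),
                    min_size=2, max_size=4))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_statistic_is_a_pair_count_for_any_grouping(self, groups):
        res = jonckheere_test(groups, mode="normal")
        assert res.jt == pytest.approx(brute_force_jt(groups), abs=1e-12)
        sizes = [len(g) for g in groups]
        max_jt = sum(sizes[i] * sizes[j]
                     for i in range(len(sizes))
                     for j in range(i + 1, len(sizes)))
        assert 0 <= res.jt <= max_jt
        assert 0 <= res.p <= 1

    def test_normal_close_to_exact_at_small_n(self, rng):
        worst = 0.0
        for _ in range(50):
            groups = [rng.normal(size=3) for _ in range(3)]
            exact = jonckheere_test(groups, "increasing", "exact")
            approx = jonckheere_test(groups, "increasing", "normal")
            worst = max(worst, abs(exact.p - approx.p))
        assert worst < 0.02

    def test_preconditions(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            jonckheere_test([(1, 2, 3)])
        with pytest.raises(ValueError, match="infeasible"):
            jonckheere_test([tuple(range(6))] * 2, mode="exact")
        with pytest.raises(ValueError):
            jonckheere_test([(1,), (2,)], alternative="sideways")


class TestSplineTrend:
    def test_flat_null_is_calibrated(self, rng):
        ps = [spline_trend_test(rng.normal(size=60), np.repeat([0, 1, 2], 20))
              for _ in range(200)]
        assert 0.4 <= np.median(ps) <= 0.6

    def test_u_shape_caught_by_spline_not_jonckheere(self, rng):
        hits = 0
        for _ in range(50):
            levels = np.repeat([0, 1, 2], 20)
            base = (levels - 1.0) ** 2
            y = base + rng.normal(0, 0.2 * np.ptp(base), 60)
            p_spline = spline_trend_test(y, levels)
            p_jt = jonckheere_test([y[levels == k] for k in (0, 1, 2)],
                                   "two-sided", "normal").p
            hits += (p_spline < 0.01) and (p_jt > 0.1)
        assert hits >= 45

    def test_monotone_trend_caught_by_both(self, rng):
        levels = np.repeat([0, 1, 2], 20)
        y = levels + rng.normal(0, 0.1, 60)
        assert spline_trend_test(y, levels) < 0.01
        groups = [y[levels == k] for k in (0, 1, 2)]
        assert jonckheere_test(groups, "two-sided", "normal").p < 0.01

    def test_too_few_levels_for_df_raises(self):
        with pytest.raises(ValueError):
            spline_trend_test([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], df=3)


class TestTrendTables:
    def test_batch_table_agrees_with_scalar_test(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(5, 30)),
                              index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(30)])
        groups = [[f"s{i}" for i in range(10)],
                  [f"s{i}" for i in range(10, 20)],
                  [f"s{i}" for i in range(20, 30)]]
        table = trend_table(matrix, groups, "braak", "F")
        for _, row in table.iterrows():
            vals = [matrix.loc[row.gene_id, g].to_numpy() for g in groups]
            ref = jonckheere_test(vals, "two-sided", "normal")
            assert row.jt_stat == pytest.approx(ref.jt)
            assert row.p_linear == pytest.approx(ref.p)
            assert row.direction == ref.direction

    def test_single_sex_cohort_errors_for_missing_stratum(self):
        config = CohortConfig(n_genes=12, module_sizes=(4,),
                              n_samples_per_cell=3, seed=0)
        matrix, meta, _ = generate_cohort(config)
        only_f = meta[meta.sex == "F"]
        with pytest.raises(ValueError, match="sex"):
            apoe_trend(matrix, only_f, "M")

    def test_planted_apoe_gene_detected_with_opposite_directions(self):
        config = CohortConfig(
            n_genes=50, module_sizes=(10,), n_samples_per_cell=15,
            dtg_spec=(DTGSpec(axis="apoe", effect=1.5),), seed=8)
        matrix, meta, truth = generate_cohort(config)
        gene = truth.planted_dtg[0][0]
        groupings = {}
        f = trait_trends(matrix, meta, "F", groupings, include_apoe=True)
        m = trait_trends(matrix, meta, "M", groupings, include_apoe=True)
        dtg = opposite_trend_genes(f, m)
        assert gene in dtg.adta


class TestOppositeTrendGenes:
    def table(self, sex, rows):
        # rows: (gene, trait, direction, q)
        return pd.DataFrame(
            [(g, t, sex, 1.0, d, q / 2, q, q, q) for g, t, d, q in rows],
            columns=["gene_id", "trait", "sex", "jt_stat", "direction",
                     "p_linear", "p_spline", "q_linear", "q_spline"])

    def test_two_trait_opposite_gene_is_tdta(self):
        f = self.table("F", [("g", "braak", 1, 0.01), ("g", "cdr", 1, 0.01)])
        m = self.table("M", [("g", "braak", -1, 0.01),
                             ("g", "cdr", -1, 0.01)])
        dtg = opposite_trend_genes(f, m, min_traits=2)
        assert dtg.tdta == {"g"}

    def test_single_trait_gene_is_not_tdta(self):
        f = self.table("F", [("g", "braak", 1, 0.01), ("g", "cdr", 1, 0.5)])
        m = self.table("M", [("g", "braak", -1, 0.01),
                             ("g", "cdr", -1, 0.01)])
        assert opposite_trend_genes(f, m, min_traits=2).tdta == frozenset()

    def test_one_sided_evidence_is_excluded(self):
        f = self.table("F", [("g", "apoe", 1, 0.01)])
        m = self.table("M", [("g", "apoe", -1, 0.5)])
        assert opposite_trend_genes(f, m).adta == frozenset()

    def test_same_direction_is_excluded(self):
        f = self.table("F", [("g", "apoe", 1, 0.01)])
        m = self.table("M", [("g", "apoe", 1, 0.01)])
        assert opposite_trend_genes(f, m).adta == frozenset()

    def test_mismatched_universes_raise(self):
        f = self.table("F", [("g1", "apoe", 1, 0.01)])
        m = self.table("M", [("g2", "apoe", -1, 0.01)])
        with pytest.raises(ValueError, match="universe"):
            opposite_trend_genes(f, m)
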