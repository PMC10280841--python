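"""Eigengene summaries, trait correlation, enrichment and module ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from dimorphnet.modstats import (ModuleScore, assign_cell_types,
                                 combined_score, enrichment_fet,
                                 module_summary, module_trait_correlation,
                                 rank_modules)
from dimorphnet.synthetic import CohortConfig, generate_cohort


def hypergeom_tail_oracle(overlap, background, n_b, n_a):
    """Upper-tail P(X >= overlap) by explicit binomial-coefficient sums."""
    total = 0.0
    denom = math.comb(background, n_a)
    for k in range(overlap, min(n_a, n_b) + 1):
        total += math.comb(n_b, k) * math.comb(background - n_b, n_a - k) \
            / denom
    return min(total, 1.0)


class TestModuleSummary:
    def test_rank_one_matrix_recovers_the_common_vector(self, rng):
        v = rng.normal(size=12)
        matrix = pd.DataFrame([v, v, v], index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(12)])
        summary = module_summary(matrix, ["a", "b", "c"])
        assert abs(np.corrcoef(summary, v)[0, 1]) == pytest.approx(1.0)

    def test_sign_alignment_flips_with_members(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(4, 15)) + rng.normal(size=15),
                              index=list("abcd"))
        pos = module_summary(matrix, list("abcd"))
        neg = module_summary(-matrix, list("abcd"))
        assert np.allclose(pos, -neg, atol=1e-8)

    def test_summary_tracks_planted_latent_activity(self):
        config = CohortConfig(n_genes=30, module_sizes=(20,), noise_sd=0.5,
                              n_samples_per_cell=10, seed=6,
                              covariate_effects=(0.0, 0.0))
        matrix, meta, truth = generate_cohort(config)
        members = [g for g, m in truth.module_membership.items()
                   if m == "M0"]
        summary = module_summary(matrix, members)
        # the members' mean expression is a noisy copy of the activity
        proxy = matrix.loc[members].mean(axis=0)
        assert np.corrcoef(summary, proxy)[0, 1] >= 0.95

    def test_missing_members_raise(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(2, 5)), index=["a", "b"])
        with pytest.raises(KeyError, match="missing"):
            module_summary(matrix, ["a", "z"])


class TestTraitCorrelation:
    def test_perfect_rank_agreement(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        rho, p = module_trait_correlation(s, s.rank())
        assert rho == pytest.approx(1.0)

    def test_constant_trait_convention(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        t = pd.Series([2.0] * 5, index=list("abcde"))
        assert module_trait_correlation(s, t) == (0.0, 1.0)

    def test_null_rejection_rate_is_calibrated(self, rng):
        idx = [f"s{i}" for i in range(100)]
        hits = 0
        reps = 400
        for _ in range(reps):
            s = pd.Series(rng.normal(size=100), index=idx)
            t = pd.Series(rng.normal(size=100), index=idx)
            hits += module_trait_correlation(s, t)[1] < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_too_few_observations_raise(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            module_trait_correlation(s, s)


class TestEnrichmentFET:
    def universe(self, n):
        return [f"g{i:03d}" for i in range(n)]

    def test_fold_enrichment_worked_example(self):
        u = self.universe(1000)
        res = enrichment_fet(u[:5] + u[100:105], u[:100], 1000)
        assert res.overlap == 5
        assert res.fold_enrichment == pytest.approx(5.0)
        assert res.p == pytest.approx(
            hypergeom_tail_oracle(5, 1000, 100, 10), abs=1e-12)

    def test_matches_tail_oracle_on_random_configs(self, rng):
        u = self.universe(200)
        for _ in range(100):
            background = int(rng.integers(20, 201))
            pool = u[:background]
            a = list(rng.choice(pool, rng.integers(1, 15), replace=False))
            b = list(rng.choice(pool, rng.integers(0, 30), replace=False))
            res = enrichment_fet(a, b, background)
            oracle = hypergeom_tail_oracle(res.overlap, background,
                                           len(b), len(a))
            assert res.p == pytest.approx(oracle, abs=1e-12)

    def test_zero_overlap(self):
        u = self.universe(50)
        res = enrichment_fet(u[:5], u[10:15], 50)
        assert res.overlap == 0
        assert res.fold_enrichment == 0.0
        assert res.p == 1.0

    def test_preconditions(self):
        u = self.universe(10)
        with pytest.raises(ValueError, match="empty"):
            enrichment_fet([], u[:3], 10)
        with pytest.raises(ValueError, match="background"):
            enrichment_fet(u[:5], u[3:9], 8)


class TestRanking:
    def score(self, mid, ps):
        s = ModuleScore(module_id=mid)
        s.trait_p = {f"t{i}": p for i, p in enumerate(ps)}
        return s

    def test_combined_score_arithmetic(self):
        assert combined_score([0.1, 0.01]) == pytest.approx(3.0)
        assert combined_score([1.0, 1.0]) == 0.0
        assert np.isfinite(combined_score([0.0]))  # p-floor applies

    def test_missing_p_treated_as_one(self):
        assert combined_score([np.nan, 0.1]) == pytest.approx(1.0)

    def test_rank_order_and_tie_breaking(self):
        ranked = rank_modules([self.score("b", [1.0]),
                               self.score("a", [1.0]),
                               self.score("c", [0.001])])
        assert list(ranked.module_id) == ["c", "a", "b"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_permutation_invariance_and_monotonicity(self, rng):
        scores = [self.score(f"m{i}", rng.uniform(size=4)) for i in range(8)]
        ranked = rank_modules(scores)
        shuffled = rank_modules(scores[::-1])
        assert ranked.equals(shuffled)
        # lowering any p never lowers the module's rank
        target = scores[3]
        before = ranked.set_index("module_id").loc["m3", "rank"]
        target.trait_p["t0"] = target.trait_p["t0"] / 10
        after = rank_modules(scores).set_index("module_id").loc["m3", "rank"]
        assert after <= before


class TestCellTypes:
    def test_identity_overlap_is_assigned_with_maximal_fe(self):
        markers = {"neuron": [f"g{i}" for i in range(10)]}
        modules = {"m1": [f"g{i}" for i in range(10)]}
        table = assign_cell_types(modules, markers, background=100)
        row = table.iloc[0]
        assert row.cell_type == "neuron"
        assert row.FE == pytest.approx(100 / 10)

    def test_zero_overlap_is_unassigned(self):
        markers = {"neuron": ["g1", "g2"]}
        modules = {"m1": ["g8", "g9"]}
        table = assign_cell_types(modules, markers, background=100)
        assert table.iloc[0].cell_type == "unassigned"

    def test_seeded_module_recovers_its_cell_type(self, rng):
        neurons = [f"n{i:02d}" for i in range(30)]
        glia = [f"g{i:02d}" for i in range(30)]
        # module takes 80% of its members from the neuron markers
        module = neurons[:24] + [f"x{i}" for i in range(6)]
        table = assign_cell_types({"m": module},
                                  {"neuron": neurons, "microglia": glia},
                                  background=500)
        assert table.iloc[0].cell_type == "neuron"
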