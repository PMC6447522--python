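"""Unit and property tests for the Wilcoxon screen and multiplicity control."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from panscreen import (GenotypeMatrix, PhenotypeMatrix, ScreenConfig,
                       WilcoxonAssociationScreen, adjust, midrank, screen,
                       significant, wilcoxon_p_exact,
                       wilcoxon_rank_sum)
from panscreen.association import (SKIPPED, TESTED, AssociationTable,
                                   DegenerateGroupsError)
# alias so pytest does not collect the library function as a test
from panscreen import test_pair as pair_test

count_vectors = st.lists(st.integers(0, 6), min_size=2, max_size=7)


def brute_force_two_sided_p(pos, neg):
    """Independent enumeration oracle over midrank selections."""
    pooled = list(pos) + list(neg)
    ranks = sps.rankdata(pooled)
    n, k = len(pooled), len(pos)
    mu = k * (n + 1) / 2
    d_obs = abs(sum(ranks[:k]) - mu)
    hits = [abs(sum(ranks[list(c)]) - mu) >= d_obs - 1e-9
            for c in itertools.combinations(range(n), k)]
    return sum(hits) / len(hits)


class TestMidrank:
    @pytest.mark.parametrize("values,ranks,sizes", [
        ([1, 2, 2, 5], [1, 2.5, 2.5, 4], (1, 2, 1)),
        ([3, 1, 2], [3, 1, 2], (1, 1, 1)),
        ([7, 7, 7], [2, 2, 2], (3,)),
    ])
    def test_examples(self, values, ranks, sizes):
        rv = midrank(values)
        assert rv.midranks.tolist() == ranks
        assert rv.tie_group_sizes == sizes

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            midrank([])

    @given(count_vectors)
    @settings(deadline=None)
    def test_midranks_sum_to_triangular_number(self, values):
        rv = midrank(values)
        n = len(values)
        assert rv.midranks.sum() == pytest.approx(n * (n + 1) / 2)
        assert sum(rv.tie_group_sizes) == n


class TestWilcoxonRankSum:
    def test_complete_tie_forces_null(self):
        r = wilcoxon_rank_sum([5, 5], [5, 5])
        assert (r.statistic, r.mu, r.sigma, r.p) == (5.0, 5.0, 0.0, 1.0)

    def test_normal_approximation_with_continuity(self):
        r = wilcoxon_rank_sum([10, 12], [1, 2, 3], "normal", True)
        assert r.statistic == 9.0 and r.mu == 6.0
        assert r.sigma == pytest.approx(np.sqrt(3.0))
        # z = 2.5 / sqrt(3), p = 2 Phi(-|z|), frozen to full precision
        assert r.p == pytest.approx(0.14891467317876572, rel=1e-12)

    def test_exact_method_matches_enumeration(self):
        r = wilcoxon_rank_sum([10, 12], [1, 2, 3], "exact")
        assert r.p == 0.2

    def test_statistic_agrees_with_scipy_mannwhitneyu(self, rng):
        # W = U + n_pos (n_pos + 1) / 2 links the two conventions
        for _ in range(25):
            pos = rng.integers(0, 5, rng.integers(2, 10))
            neg = rng.integers(0, 5, rng.integers(2, 10))
            r = wilcoxon_rank_sum(pos, neg, "normal", True)
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided",
                                 method="asymptotic")
            assert r.statistic == pytest.approx(
                u.statistic + len(pos) * (len(pos) + 1) / 2)
            if r.sigma > 0:
                assert r.p == pytest.approx(u.pvalue, rel=1e-10)

    def test_empty_group_is_degenerate_error(self):
        with pytest.raises(DegenerateGroupsError):
            wilcoxon_rank_sum([], [1, 2])

    @given(count_vectors, count_vectors)
    @settings(deadline=None)
    def test_two_sided_p_invariant_under_label_swap(self, a, b):
        p_ab = wilcoxon_rank_sum(a, b, "normal", True).p
        p_ba = wilcoxon_rank_sum(b, a, "normal", True).p
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    @given(count_vectors, count_vectors, st.integers(1, 50))
    @settings(deadline=None)
    def test_rank_invariance_under_constant_shift(self, a, b, c):
        base = wilcoxon_rank_sum(a, b, "normal", True)
        shifted = wilcoxon_rank_sum([x + c for x in a], [x + c for x in b],
                                    "normal", True)
        assert base.statistic == shifted.statistic
        assert base.sigma == pytest.approx(shifted.sigma)
        assert base.p == pytest.approx(shifted.p)


class TestWilcoxonExact:
    @pytest.mark.parametrize("pos,neg,expected", [
        ([2], [1], 1.0),                 # n = 2 two-sided minimum
        ([10, 12], [1, 2, 3], 0.2),      # full enumeration, no ties
        ([3, 3, 3], [0, 0, 0], 0.1),     # 2 extreme of C(6,3)=20 selections
    ])
    def test_worked_examples(self, pos, neg, expected):
        assert wilcoxon_p_exact(pos, neg) == pytest.approx(expected)

    def test_tied_multiset_matches_oracle(self):
        assert wilcoxon_p_exact([0, 0], [0, 1]) == pytest.approx(
            brute_force_two_sided_p([0, 0], [0, 1]))

    def test_rejects_large_samples(self):
        with pytest.raises(ValueError, match="normal method"):
            wilcoxon_p_exact(list(range(8)), list(range(8)))

    @given(count_vectors, count_vectors)
    @settings(deadline=None, max_examples=40)
    def test_equals_independent_enumeration(self, pos, neg):
        assert wilcoxon_p_exact(pos, neg) == pytest.approx(
            brute_force_two_sided_p(pos, neg))


class TestTestPair:
    def test_one_class_phenotype_is_skipped(self):
        r = pair_test([1, 2, 3], [1, 1, 1])
        assert r.status == SKIPPED
        assert r.p_raw is None and r.statistic is None

    def test_constant_counts_give_p_one(self):
        r = pair_test([4, 4, 4, 4], [1, 1, 0, 0])
        assert r.status == TESTED and r.p_raw == 1.0

    def test_exact_enumeration_case(self):
        cfg = ScreenConfig(p_method="exact")
        r = pair_test([3, 3, 3, 0, 0, 0], [1, 1, 1, 0, 0, 0], cfg)
        assert r.p_raw == pytest.approx(0.1)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            pair_test([1, 2], [1])


class TestScreen:
    def test_single_pair(self):
        g = GenotypeMatrix.from_arrays(["A", "B"], ["f"], [[1], [2]])
        p = PhenotypeMatrix.from_arrays(["A", "B"], ["s"], [[1], [0]])
        table = screen(g, p)
        assert len(table.df) == 1
        assert table.df.iloc[0]["status"] == TESTED

    def test_record_count_is_product_of_dimensions(self, sim_small):
        g, p, _ = sim_small
        table = screen(g, p)
        assert len(table.df) == len(g.orthogroup_ids) * len(p.substrate_ids)

    def test_unaligned_species_is_error(self, small_genotype):
        p = PhenotypeMatrix.from_arrays(["C", "B", "A"], ["s"],
                                        [[1], [0], [1]])
        with pytest.raises(ValueError, match="aligned"):
            screen(small_genotype, p)

    def test_degenerate_substrates_skipped_and_counted_in_all_pairs_m(self):
        g = GenotypeMatrix.from_arrays(["A", "B", "C"], ["f1", "f2"],
                                       [[1, 0], [2, 3], [0, 1]])
        p = PhenotypeMatrix.from_arrays(["A", "B", "C"], ["s1", "s2"],
                                        [[1, 0], [0, 0], [1, 0]])
        table = screen(g, p)
        by = table.df.set_index(["orthogroup", "substrate"])
        assert (by.loc[("f1", "s2"), "status"] == SKIPPED)
        assert table.m_total == 4 and table.n_tested == 2
        tested_only = screen(g, p, ScreenConfig(m_mode="tested-only"))
        assert tested_only.m_total == 2

    def test_permutation_of_species_leaves_p_unchanged(self, rng):
        counts = rng.poisson(1.0, (10, 20))
        calls = rng.integers(0, 2, (10, 5))
        sp = [f"sp{i}" for i in range(10)]
        g = GenotypeMatrix.from_arrays(sp, [f"f{j}" for j in range(20)], counts)
        p = PhenotypeMatrix.from_arrays(sp, [f"s{j}" for j in range(5)], calls)
        perm = rng.permutation(10)
        g2 = GenotypeMatrix.from_arrays([sp[i] for i in perm],
                                        g.orthogroup_ids, counts[perm])
        p2 = PhenotypeMatrix.from_arrays([sp[i] for i in perm],
                                         p.substrate_ids, calls[perm])
        t1, t2 = screen(g, p), screen(g2, p2)
        np.testing.assert_allclose(t1.df["p_raw"], t2.df["p_raw"])

    def test_screen_is_deterministic(self, sim_small):
        g, p, _ = sim_small
        t1, t2 = screen(g, p), screen(g, p)
        assert t1.df.equals(t2.df)

    def test_vectorized_normal_path_matches_per_pair_route(self, rng):
        counts = rng.poisson(0.7, (20, 8))
        calls = rng.integers(0, 2, (20, 3))
        calls[:, 0] = [1] * 10 + [0] * 10
        sp = [f"sp{i}" for i in range(20)]
        g = GenotypeMatrix.from_arrays(sp, [f"f{j}" for j in range(8)], counts)
        p = PhenotypeMatrix.from_arrays(sp, [f"s{j}" for j in range(3)], calls)
        table = screen(g, p, ScreenConfig(p_method="normal"))
        for row in table.df.itertuples(index=False):
            f = g.orthogroup_ids.index(row.orthogroup)
            s = p.substrate_ids.index(row.substrate)
            expected = pair_test(counts[:, f], calls[:, s],
                                 ScreenConfig(p_method="normal"))
            if expected.status == TESTED:
                assert row.p_raw == pytest.approx(expected.p_raw, rel=1e-12)
                assert row.statistic == pytest.approx(expected.statistic)
            else:
                assert row.status == SKIPPED


class TestAdjust:
    def _table_from_p(self, p_values, m_total=None):
        import pandas as pd
        df = pd.DataFrame({
            "orthogroup": [f"og{i}" for i in range(len(p_values))],
            "substrate": "s1",
            "n_pos": 2, "n_neg": 2,
            "statistic": 5.0,
            "p_raw": p_values,
            "p_bonferroni": np.nan, "q_bh": np.nan,
            "status": TESTED,
        })
        return AssociationTable(df, m_total or len(p_values), ScreenConfig())

    def test_bonferroni_arithmetic(self):
        t = adjust(self._table_from_p([0.001], m_total=50), "bonferroni")
        assert t.df["p_bonferroni"].iloc[0] == pytest.approx(0.05)

    def test_bh_step_up_worked_example(self):
        t = adjust(self._table_from_p([0.01, 0.02, 0.03, 0.04]), "bh")
        np.testing.assert_allclose(t.df["q_bh"], [0.04] * 4)

    def test_bh_single_p_is_identity_at_m_1(self):
        t = adjust(self._table_from_p([0.03]), "bh")
        assert t.df["q_bh"].iloc[0] == pytest.approx(0.03)

    def test_bh_matches_statsmodels_when_m_equals_n(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(200)
        t = adjust(self._table_from_p(list(p)), "bh")
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(t.df["q_bh"], q_sm, rtol=1e-12)

    def test_bonferroni_monotone_in_m_total(self):
        t1 = adjust(self._table_from_p([0.01, 0.3], m_total=2), "bonferroni")
        t2 = adjust(self._table_from_p([0.01, 0.3], m_total=10), "bonferroni")
        assert (t2.df["p_bonferroni"] >= t1.df["p_bonferroni"]).all()

    def test_adjusted_never_below_raw(self, sim_small):
        g, p, _ = sim_small
        table = screen(g, p)
        tested = table.df[table.df["status"] == TESTED]
        assert (tested["p_bonferroni"] >= tested["p_raw"] - 1e-15).all()
        assert (tested["q_bh"] >= tested["p_raw"] - 1e-15).all()
        assert (tested["p_bonferroni"] <= 1).all()
        assert (tested["q_bh"] <= 1).all()


class TestSignificant:
    def test_empty_summary_when_nothing_passes(self, sim_small):
        g, p, _ = sim_small
        table = screen(g, p)
        s = significant(table, "bonferroni", 1e-300)
        assert s.n_significant_pairs == 0
        assert s.n_orthogroups == 0 and s.n_substrates == 0

    def test_distinct_counts(self):
        import pandas as pd
        df = pd.DataFrame({
            "orthogroup": ["og1", "og1"], "substrate": ["s1", "s2"],
            "n_pos": 2, "n_neg": 2, "statistic": 5.0,
            "p_raw": [0.001, 0.002], "p_bonferroni": [0.002, 0.004],
            "q_bh": np.nan, "status": TESTED})
        t = AssociationTable(df, 2, ScreenConfig(),
                             adjusted=frozenset({"bonferroni"}))
        s = significant(t, "bonferroni", 0.05)
        assert s.n_significant_pairs == 2
        assert s.n_orthogroups == 1 and s.n_substrates == 2

    def test_uncomputed_method_is_error(self):
        import pandas as pd
        df = pd.DataFrame(columns=["orthogroup", "substrate", "n_pos",
                                   "n_neg", "statistic", "p_raw",
                                   "p_bonferroni", "q_bh", "status"])
        t = AssociationTable(df, 0, ScreenConfig())
        with pytest.raises(ValueError, match="not been computed"):
            significant(t, "bh", 0.05)

    def test_recovers_planted_pairs_exactly(self):
        from panscreen import SimConfig, simulate
        g, p, truth = simulate(SimConfig(seed=11, balanced_planted=True))
        table = screen(g, p)
        s = significant(table, "bonferroni", 0.05)
        assert {(og, sub) for og, sub, _ in s.pairs} == set(truth.planted_pairs)


class TestEstimator:
    def test_sklearn_params_and_clone(self):
        from sklearn.base import clone
        est = WilcoxonAssociationScreen(alpha=0.01, p_method="normal")
        params = est.get_params()
        assert params["alpha"] == 0.01
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05

    def test_fit_exposes_table_and_m_total(self, sim_small):
        g, p, truth = sim_small
        est = WilcoxonAssociationScreen().fit(g, p)
        assert est.m_total_ == len(g.orthogroup_ids) * len(p.substrate_ids)
        assert est.table_.n_tested == est.n_tested_
        summary = est.significant()
        assert summary.method == "bonferroni"

    def test_unfitted_significant_raises(self):
        with pytest.raises(ValueError, match="not.*fitted"):
            WilcoxonAssociationScreen().significant()
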