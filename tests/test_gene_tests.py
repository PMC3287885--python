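"""Gene-level tests: weighted-sum rank test and CMC / Hotelling's T²."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from rvpath._utils import ValidationError
from rvpath.gene_tests import (
    VariantGroup,
    cmc_design,
    cmc_test,
    hotelling_t2,
    ws_statistic,
    ws_test,
)

from conftest import make_genotypes


def group_for(gm, indices=None, label="g"):
    if indices is None:
        indices = range(gm.n_variants)
    return VariantGroup(label=label, variant_indices=np.asarray(list(indices)))


# ---------------------------------------------------------------------------
# Weighted sum
# ---------------------------------------------------------------------------


class TestWsStatistic:
    def test_smoothed_unaffected_frequency_and_weight(self):
        # 100 unaffected with 0 minor alleles, 100 affected, all genotyped
        dosages = np.zeros((200, 1), dtype=int)
        dosages[100:, 0] = 1  # give the affecteds some minor alleles
        gm = make_genotypes(dosages)
        y = np.r_[np.zeros(100), np.ones(100)]
        comp = ws_statistic(gm, y, group_for(gm))
        q = 1 / 202
        assert comp.q[0] == pytest.approx(q)
        assert comp.w[0] == pytest.approx(math.sqrt(200 * q * (1 - q)))

    def test_all_dosages_zero_gives_midranks(self):
        gm = make_genotypes(np.zeros((10, 2), dtype=int))
        y = np.r_[np.ones(4), np.zeros(6)]
        comp = ws_statistic(gm, y, group_for(gm))
        n = 10
        assert comp.rank_sum == pytest.approx(4 * (n + 1) / 2)

    def test_two_individual_ordering(self):
        gm = make_genotypes([[2], [0]])
        comp = ws_statistic(gm, np.array([1, 0]), group_for(gm))
        assert comp.rank_sum == pytest.approx(2.0)

    def test_rank_sum_conserved_without_missingness(self):
        rng = np.random.default_rng(3)
        gm = make_genotypes(rng.integers(0, 3, size=(25, 6)))
        y = np.r_[np.ones(10), np.zeros(15)]
        comp = ws_statistic(gm, y, group_for(gm))
        ranks = stats.rankdata(comp.gamma)
        assert ranks.sum() == pytest.approx(25 * 26 / 2)
        assert np.all(comp.w > 0)

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(4)
        gm = make_genotypes(rng.integers(0, 3, size=(20, 5)))
        y = np.r_[np.ones(8), np.zeros(12)]
        a = ws_statistic(gm, y, group_for(gm, [0, 1, 2, 3, 4]))
        b = ws_statistic(gm, y, group_for(gm, [4, 2, 0, 3, 1]))
        assert a.rank_sum == pytest.approx(b.rank_sum)

    def test_all_affected_rejected(self):
        gm = make_genotypes([[0], [1]])
        with pytest.raises(ValidationError):
            ws_statistic(gm, np.array([1, 1]), group_for(gm))

    def test_missing_excluded_from_q_denominator(self):
        # one control genotyped 0, one control missing -> n_u = 1
        gm = make_genotypes([[0], [-1], [2], [1]])
        y = np.array([0, 0, 1, 1])
        comp = ws_statistic(gm, y, group_for(gm))
        assert comp.q[0] == pytest.approx((0 + 1) / (2 * 1 + 2))


class TestWsPermutation:
    def test_degenerate_data_gives_p_one(self):
        gm = make_genotypes(np.zeros((12, 3), dtype=int))
        y = np.r_[np.ones(5), np.zeros(7)]
        res = ws_test(gm, y, group_for(gm), n_permutations=50, seed=1)
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        gm = make_genotypes(rng.integers(0, 3, size=(30, 4)))
        y = np.r_[np.ones(12), np.zeros(18)]
        a = ws_test(gm, y, group_for(gm), n_permutations=200, seed=9)
        b = ws_test(gm, y, group_for(gm), n_permutations=200, seed=9)
        c = ws_test(gm, y, group_for(gm), n_permutations=200, seed=10)
        assert a.p_value == b.p_value
        assert a.statistic == c.statistic  # observed x does not depend on seed

    def test_exhaustive_equals_independent_enumeration_oracle(self):
        """Exact WS p on a 6-individual toy vs a from-scratch oracle."""
        dosages = np.array([[2, 0], [1, 1], [0, 0], [1, 0], [0, 2], [0, 0]])
        gm = make_genotypes(dosages)
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)

        def oracle_x(labels):
            aff = np.asarray(labels, dtype=bool)
            m_u = dosages[~aff].sum(axis=0)
            n_u = (~aff).sum()
            q = (m_u + 1) / (2 * n_u + 2)
            w = np.sqrt(len(labels) * q * (1 - q))
            gamma = (dosages / w).sum(axis=1)
            ranks = stats.rankdata(gamma)
            return ranks[aff].sum()

        x_obs = oracle_x(y)
        labelings = [
            [1 if i in idx else 0 for i in range(6)]
            for idx in combinations(range(6), 3)
        ]
        assert len(labelings) == 20
        exact_p = np.mean([oracle_x(l) >= x_obs - 1e-12 for l in labelings])

        res = ws_test(gm, y, group_for(gm), exhaustive=True)
        assert res.statistic == pytest.approx(x_obs)
        assert res.p_value == pytest.approx(exact_p)

    def test_null_pvalues_subuniform(self):
        """Permutation p under a true null never beats uniform by more
        than Monte Carlo noise."""
        rng = np.random.default_rng(11)
        n_sim, n, B = 1500, 30, 60
        pvals = np.empty(n_sim)
        for s in range(n_sim):
            gm = make_genotypes(rng.binomial(2, 0.1, size=(n, 3)))
            y = np.zeros(n)
            y[rng.choice(n, size=12, replace=False)] = 1
            pvals[s] = ws_test(
                gm, y, group_for(gm), n_permutations=B, seed=s
            ).p_value
        for alpha in (0.05, 0.1, 0.25):
            se = math.sqrt(alpha * (1 - alpha) / n_sim)
            assert (pvals <= alpha).mean() <= alpha + 3 * se


# ---------------------------------------------------------------------------
# CMC design
# ---------------------------------------------------------------------------


class TestCmcDesign:
    def test_any_rare_allele_sets_indicator(self):
        dosages = np.array(
            [[1, 0, 0], [0, 0, 2], [0, 0, 0], [0, 1, 0], [0, 0, 0], [0, 0, 0]]
        )
        gm = make_genotypes(dosages)  # all rare at these counts
        design = cmc_design(gm, group_for(gm), rare_threshold=0.5)
        assert design.n_columns == 1
        np.testing.assert_array_equal(design.columns[:, 0], [1, 1, 0, 1, 0, 0])

    def test_threshold_splits_common_from_rare(self):
        dosages = np.zeros((40, 3), dtype=int)
        dosages[:12, 0] = 1  # MAF 0.15: common
        dosages[0, 1] = 1    # MAF 1/80: rare
        dosages[1, 2] = 1    # MAF 1/80: rare
        gm = make_genotypes(dosages)
        design = cmc_design(gm, group_for(gm), rare_threshold=0.05)
        labels = design.column_labels
        assert sum(l.startswith("collapse:") for l in labels) == 1
        assert sum(l.startswith("dosage:") for l in labels) == 1

    def test_gene_grouping_gives_one_indicator_per_gene(self):
        dosages = np.array([[1, 0], [0, 1], [0, 0], [1, 1]])
        gm = make_genotypes(dosages, genes=["GENEA", "GENEB"])
        design = cmc_design(gm, group_for(gm), rare_threshold=0.5, grouping="gene")
        assert design.n_columns == 2
        design_set = cmc_design(
            gm, group_for(gm), rare_threshold=0.5, grouping="set"
        )
        assert design_set.n_columns == 1

    def test_all_constant_rejected(self):
        gm = make_genotypes(np.zeros((6, 2), dtype=int))
        with pytest.raises(ValidationError, match="non-constant"):
            cmc_design(gm, group_for(gm))

    def test_constant_column_dropped_with_warning(self, caplog):
        dosages = np.array([[1, 0], [0, 0], [1, 0], [0, 0]])
        gm = make_genotypes(dosages, genes=["GENEA", "GENEB"])
        with caplog.at_level("WARNING"):
            design = cmc_design(gm, group_for(gm), rare_threshold=0.5)
        assert design.n_columns == 1
        assert "constant" in caplog.text


# ---------------------------------------------------------------------------
# Hotelling's T²
# ---------------------------------------------------------------------------


class TestHotelling:
    def test_single_column_equals_pooled_t_squared(self):
        rng = np.random.default_rng(8)
        dosages = rng.binomial(2, 0.04, size=(60, 3))
        dosages[0] = [1, 0, 1]
        gm = make_genotypes(dosages)
        y = np.r_[np.ones(25), np.zeros(35)]
        design = cmc_design(gm, group_for(gm), rare_threshold=0.5)
        assert design.n_columns == 1
        res = hotelling_t2(design, y)
        x = design.columns[:, 0]
        t, p = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=True)
        assert res.statistic == pytest.approx(t**2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_brute_force_matrix_formula(self):
        """2-column design vs an independent dense implementation."""
        rng = np.random.default_rng(9)
        dosages = np.column_stack(
            [rng.binomial(2, 0.3, 40), rng.binomial(2, 0.04, 40), rng.binomial(2, 0.04, 40)]
        )
        dosages[0, 1] = 1
        gm = make_genotypes(dosages)
        y = np.r_[np.ones(18), np.zeros(22)]
        design = cmc_design(gm, group_for(gm), rare_threshold=0.05)
        assert design.n_columns == 2
        res = hotelling_t2(design, y)

        X = design.columns
        a, b = X[y == 1], X[y == 0]
        n1, n2, p = len(a), len(b), X.shape[1]
        d = a.mean(0) - b.mean(0)
        S = (
            (a - a.mean(0)).T @ (a - a.mean(0))
            + (b - b.mean(0)).T @ (b - b.mean(0))
        ) / (n1 + n2 - 2)
        t2 = n1 * n2 / (n1 + n2) * d @ np.linalg.inv(S) @ d
        F = t2 * (n1 + n2 - p - 1) / (p * (n1 + n2 - 2))
        p_val = stats.f.sf(F, p, n1 + n2 - p - 1)
        assert res.statistic == pytest.approx(t2, rel=1e-12)
        assert res.p_value == pytest.approx(p_val, rel=1e-12)

    def test_identical_group_means_give_zero_statistic(self):
        # symmetric construction: cases and controls see identical columns
        block = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        dosages = np.vstack([block, block])
        gm = make_genotypes(dosages)
        y = np.r_[np.ones(4), np.zeros(4)]
        design = cmc_design(gm, group_for(gm), rare_threshold=0.5, grouping="set")
        res = hotelling_t2(design, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_sample_size_precondition(self):
        gm = make_genotypes([[1], [0], [1], [0]])
        design = cmc_design(gm, group_for(gm), rare_threshold=0.5)
        with pytest.raises(ValidationError, match="≥2 cases"):
            hotelling_t2(design, np.array([1, 0, 0, 0]))


class TestCmcComposition:
    def test_single_rare_group_matches_hotelling_on_indicator(self):
        rng = np.random.default_rng(10)
        dosages = rng.binomial(2, 0.05, size=(50, 2))
        dosages[0, 0] = 1
        gm = make_genotypes(dosages)
        y = np.r_[np.ones(20), np.zeros(30)]
        res = cmc_test(gm, y, group_for(gm), rare_threshold=0.5)
        design = cmc_design(gm, group_for(gm), rare_threshold=0.5)
        direct = hotelling_t2(design, y)
        assert res.p_value == direct.p_value

    def test_grouping_irrelevant_for_single_gene(self):
        rng = np.random.default_rng(12)
        dosages = rng.binomial(2, 0.05, size=(50, 3))
        dosages[0, 0] = 1
        gm = make_genotypes(dosages)
        y = np.r_[np.ones(20), np.zeros(30)]
        a = cmc_test(gm, y, group_for(gm), rare_threshold=0.5, grouping="gene")
        b = cmc_test(gm, y, group_for(gm), rare_threshold=0.5, grouping="set")
        assert a.p_value == b.p_value

    def test_column_order_invariance(self):
        rng = np.random.default_rng(13)
        dosages = rng.binomial(2, [0.3, 0.25, 0.35], size=(60, 3))
        gm = make_genotypes(dosages)
        y = np.r_[np.ones(25), np.zeros(35)]
        a = cmc_test(gm, y, group_for(gm, [0, 1, 2]), rare_threshold=0.01)
        b = cmc_test(gm, y, group_for(gm, [2, 0, 1]), rare_threshold=0.01)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_null_calibration(self):
        """CMC type I error close to nominal on independent binary data."""
        rng = np.random.default_rng(14)
        n_sim, n = 2000, 80
        pvals = np.empty(n_sim)
        for s in range(n_sim):
            dosages = rng.binomial(2, [0.3, 0.1], size=(n, 2))
            if dosages.std(axis=0).min() == 0:
                pvals[s] = 1.0
                continue
            gm = make_genotypes(dosages)
            y = np.zeros(n)
            y[rng.choice(n, size=30, replace=False)] = 1
            pvals[s] = cmc_test(gm, y, group_for(gm), rare_threshold=0.01).p_value
        rate = (pvals <= 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 3 * se
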