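"""Unit and property tests for the three mapping tests and LD statistics."""

from __future__ import annotations

import subprocess

import numpy as np
import pytest
from scipy.stats import binomtest, linregress

from aimap.ai_status import AIStatusVector
from aimap.stats import (ContingencyTable2x3, binomial_haplotype_test,
                         classify_trio_position, contingency_genotype_test,
                         contingency_test_matrix, fisher_2x3_pvalue,
                         fisher_exact_2x3, ld_r2, linear_regression_test,
                         regression_test_matrix)

from conftest import all_2x3_tables, oracle_binomial_two_sided, oracle_fisher_2x3


class TestFisher2x3:
    def test_matches_rational_oracle_exhaustively(self):
        """Every 2x3 table with a small grand total agrees with the exact
        rational-arithmetic enumeration."""
        for a, b in all_2x3_tables(7):
            assert fisher_2x3_pvalue(a, b) == pytest.approx(
                oracle_fisher_2x3(a, b), rel=1e-9), (a, b)

    def test_matches_rational_oracle_random_tables(self, rng):
        for _ in range(250):
            counts = rng.multinomial(int(rng.integers(1, 31)),
                                     np.full(6, 1 / 6)).reshape(2, 3)
            a, b = counts[0], counts[1]
            assert fisher_2x3_pvalue(a, b) == pytest.approx(
                oracle_fisher_2x3(a, b), rel=1e-9)

    @pytest.mark.parametrize(
        "a,b",
        [((2, 4, 0), (6, 2, 3)), ((0, 10, 0), (5, 0, 5)),
         ((3, 2, 5), (5, 5, 0)), ((1, 1, 1), (8, 0, 2)),
         ((12, 3, 0), (2, 9, 4))],
    )
    def test_matches_r_fisher_test(self, a, b):
        """Cross-check against R's fisher.test on an r x c table."""
        script = (
            f"cat(fisher.test(matrix(c({a[0]},{b[0]},{a[1]},{b[1]},"
            f"{a[2]},{b[2]}), nrow=2))$p.value)"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        assert fisher_2x3_pvalue(a, b) == pytest.approx(float(out.stdout),
                                                        rel=1e-6)

    def test_single_admissible_table_gives_p_one(self):
        table = ContingencyTable2x3.from_arrays((3, 0, 0), (7, 0, 0))
        res = fisher_exact_2x3(table)
        assert res.p_value == 1.0
        assert "degenerate" in res.flags

    def test_empty_row_is_degenerate(self):
        res = fisher_exact_2x3(ContingencyTable2x3.from_arrays(
            (0, 0, 0), (3, 4, 5)))
        assert res.p_value == 1.0
        assert "degenerate" in res.flags


class TestContingencyGenotypeTest:
    def test_complete_ld_split_is_significant(self):
        """AI individuals only Aa/aa and non-AI only AA/Aa (the pattern a SNP
        in complete LD with the regulatory site produces) yields a small p
        that equals the enumeration oracle's."""
        genotypes = np.array([1] * 6 + [2] * 4 + [0] * 6 + [1] * 4)
        ai = np.array([True] * 10 + [False] * 10)
        res = contingency_genotype_test(genotypes, ai)
        expected = oracle_fisher_2x3((0, 6, 4), (6, 4, 0))
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.p_value < 0.01

    def test_identical_row_proportions_are_not_significant(self):
        genotypes = np.array([0, 0, 1, 1, 1, 1, 2, 2] * 2)
        ai = np.array([True] * 8 + [False] * 8)
        res = contingency_genotype_test(genotypes, ai)
        assert res.p_value >= 0.5

    def test_missing_genotypes_are_dropped(self):
        genotypes = np.array([0, 1, 2, -1, 1, 0, 2, 1, -1, 0, 1, 2])
        ai = np.array([True] * 6 + [False] * 6)
        res = contingency_genotype_test(genotypes, ai)
        assert res.n_used == 10

    def test_single_phenotype_class_is_degenerate(self):
        res = contingency_genotype_test(np.array([0, 1, 2]),
                                        np.array([True, True, True]))
        assert res.p_value == 1.0
        assert "degenerate" in res.flags


class TestBinomialHaplotypeTest:
    @pytest.mark.parametrize("n,k,expected", [
        (10, 10, 2 * 0.5**10),
        (4, 2, 1.0),
        (6, 5, 14 / 64),
    ])
    def test_closed_form_values(self, n, k, expected):
        h1 = np.array([1] * k + [0] * (n - k))
        h2 = 1 - h1
        d = np.ones(n, dtype=int)
        res = binomial_haplotype_test(h1, h2, d)
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.n_used == n

    def test_oracle_sweep_all_small_n(self):
        """The point-probability two-sided rule agrees with rational
        enumeration and with scipy's exact binomial test for all n <= 20."""
        from aimap.stats import _binom_half_row

        for n in range(1, 21):
            row = _binom_half_row(n)
            for k in range(n + 1):
                assert row[k] == pytest.approx(oracle_binomial_two_sided(n, k),
                                               rel=1e-9)
                assert row[k] == pytest.approx(
                    binomtest(k, n, 0.5).pvalue, rel=1e-9)

    def test_doubled_tail_equivalence_at_half(self):
        """At p = 1/2 the point-probability rule equals 2*min(tail, 1/2)."""
        from scipy.stats import binom

        from aimap.stats import _binom_half_row

        for n in range(1, 21):
            row = _binom_half_row(n)
            for k in range(n + 1):
                two_tail = 2 * min(binom.cdf(k, n, 0.5),
                                   binom.sf(k - 1, n, 0.5), 0.5)
                assert row[k] == pytest.approx(min(two_tail, 1.0), rel=1e-9)

    def test_homozygous_individuals_do_not_contribute(self):
        h1 = np.array([1, 1, 0, 1])
        h2 = np.array([1, 0, 0, 0])
        res = binomial_haplotype_test(h1, h2, np.array([1, 1, 1, -1]))
        assert res.n_used == 2

    def test_no_informative_individuals_degenerate(self):
        res = binomial_haplotype_test(np.array([1, 0]), np.array([1, 0]),
                                      np.array([1, -1]))
        assert res.p_value == 1.0
        assert "degenerate" in res.flags


class TestLinearRegressionTest:
    def _status(self, y):
        y = np.asarray(y)
        return AIStatusVector(ai=y != 0, direction=y.astype(np.int8))

    def test_perfect_fit_hits_floor(self):
        h1 = np.array([0, 0, 0, 0, 1, 1])
        h2 = np.array([1, 1, 0, 0, 0, 0])
        res = linear_regression_test(h1, h2, self._status([-1, -1, 0, 0, 1, 1]))
        assert res.statistic == pytest.approx(1.0)
        assert "perfect_fit" in res.flags
        assert res.p_value == pytest.approx(1e-300)

    def test_all_zero_response_gives_p_one(self):
        h1 = np.array([0, 1, 1, 0])
        h2 = np.array([1, 0, 0, 0])
        res = linear_regression_test(h1, h2, self._status([0, 0, 0, 0]))
        assert res.p_value == 1.0

    def test_matches_scipy_linregress(self):
        x = np.array([-1, 0, 1, -1, 0, 1])
        y = np.array([-1, 0, 0, 0, 0, 1])
        h1 = np.where(x == 1, 1, 0)
        h2 = np.where(x == -1, 1, 0)
        res = linear_regression_test(h1, h2, self._status(y))
        ref = linregress(x.astype(float), y.astype(float))
        assert res.statistic == pytest.approx(ref.slope, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matrix_matches_scipy_on_random_columns(self, rng):
        n = 30
        h1 = rng.integers(0, 2, (n, 25))
        h2 = rng.integers(0, 2, (n, 25))
        y = rng.choice([-1, 0, 1], n)
        slopes, pvals = regression_test_matrix(h1, h2, y)
        for j in range(25):
            x = (h1[:, j] - h2[:, j]).astype(float)
            if np.ptp(x) == 0:
                assert pvals[j] == 1.0
                continue
            ref = linregress(x, y.astype(float))
            assert slopes[j] == pytest.approx(ref.slope, rel=1e-10)
            assert pvals[j] == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_constant_predictor_is_degenerate(self):
        res = linear_regression_test(np.ones(5, int), np.ones(5, int),
                                     self._status([1, -1, 0, 0, 1]))
        assert res.p_value == 1.0
        assert "degenerate" in res.flags


class TestPhaseInvariance:
    """The package's central claim: the genotype test cannot see phase."""

    def _random_fixture(self, rng):
        n, s = 20, 15
        h1 = rng.integers(0, 2, (n, s), dtype=np.int8)
        h2 = rng.integers(0, 2, (n, s), dtype=np.int8)
        ai = rng.random(n) < 0.5
        if not ai.any():
            ai[0] = True
        if ai.all():
            ai[-1] = False
        d = np.where(ai, rng.choice([-1, 1], n), 0).astype(np.int8)
        return h1, h2, AIStatusVector(ai, d)

    def test_contingency_bit_identical_under_chromosome_swaps(self, rng):
        for _ in range(100):
            h1, h2, status = self._random_fixture(rng)
            p_before = contingency_test_matrix(h1 + h2, status.ai)
            swap = rng.random(h1.shape[0]) < 0.5
            s1 = np.where(swap[:, None], h2, h1)
            s2 = np.where(swap[:, None], h1, h2)
            p_after = contingency_test_matrix(s1 + s2, status.ai)
            assert np.array_equal(p_before, p_after)

    def test_haplotype_tests_are_affected_by_swaps(self, rng):
        from aimap.stats import binomial_test_matrix

        binom_changed = reg_changed = 0
        for _ in range(100):
            h1, h2, status = self._random_fixture(rng)
            ai, d = status.ai, status.direction
            y = np.where(ai, d, 0)
            pb0 = binomial_test_matrix(h1[ai], h2[ai], d[ai])
            _, pr0 = regression_test_matrix(h1, h2, y)
            swap = rng.random(h1.shape[0]) < 0.5
            s1 = np.where(swap[:, None], h2, h1)
            s2 = np.where(swap[:, None], h1, h2)
            pb1 = binomial_test_matrix(s1[ai], s2[ai], d[ai])
            _, pr1 = regression_test_matrix(s1, s2, y)
            binom_changed += not np.array_equal(pb0, pb1)
            reg_changed += not np.array_equal(pr0, pr1)
        assert binom_changed > 50
        assert reg_changed > 50

    def test_global_convention_flip_changes_no_p_value(self, rng):
        """Flipping the up/down convention (all directions) and/or the A/a
        allele labels leaves all three tests' p-values identical."""
        from aimap.stats import binomial_test_matrix

        for _ in range(25):
            h1, h2, status = self._random_fixture(rng)
            ai, d = status.ai, status.direction
            y = np.where(ai, d, 0)
            p_cont = contingency_test_matrix(h1 + h2, ai)
            p_bin = binomial_test_matrix(h1[ai], h2[ai], d[ai])
            _, p_reg = regression_test_matrix(h1, h2, y)
            # direction flip
            assert np.allclose(
                binomial_test_matrix(h1[ai], h2[ai], -d[ai]), p_bin)
            _, p_reg_f = regression_test_matrix(h1, h2, -y)
            assert np.allclose(p_reg_f, p_reg)
            # allele relabel (summation order changes, so allow float noise)
            assert np.allclose(
                contingency_test_matrix((1 - h1) + (1 - h2), ai), p_cont,
                rtol=1e-9)
            assert np.allclose(
                binomial_test_matrix(1 - h1[ai], 1 - h2[ai], d[ai]), p_bin)
            _, p_reg_a = regression_test_matrix(1 - h1, 1 - h2, y)
            assert np.allclose(p_reg_a, p_reg)


class TestLD:
    def test_identical_columns_give_r2_one(self):
        a = np.array([0, 0, 1, 1, 0, 1])
        res = ld_r2(a, a)
        assert res.r2 == pytest.approx(1.0)

    def test_product_haplotype_frequencies_give_r2_zero(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        res = ld_r2(a, b)
        assert res.r2 == pytest.approx(0.0)
        assert res.D == pytest.approx(0.0)

    def test_worked_example(self):
        """Haplotype counts 40/10/10/40 for the four two-site classes."""
        a = np.array([0] * 50 + [1] * 50)
        b = np.array([0] * 40 + [1] * 10 + [0] * 10 + [1] * 40)
        res = ld_r2(a, b)
        assert res.D == pytest.approx(0.15)
        assert res.r2 == pytest.approx(0.36)

    def test_monomorphic_site_is_undefined(self):
        res = ld_r2(np.zeros(6), np.array([0, 1, 0, 1, 0, 1]))
        assert "undefined" in res.flags


class TestTrioClassification:
    @pytest.mark.parametrize("haps,expected", [
        ([(0, 0), (0, 1), (1, 1)], "below"),
        ([(0, 0), (1, 0), (0, 1)], "parallel"),
        ([(0, 0), (1, 0), (1, 1)], "above"),
        ([(0, 0), (0, 1), (1, 0), (1, 1)], "all_four"),
        ([(0, 0), (1, 1)], "undefined"),
    ])
    def test_classes(self, haps, expected):
        a = np.array([h[0] for h in haps])
        r = np.array([h[1] for h in haps])
        assert classify_trio_position(a, r) == expected


class TestFisherSymmetries:
    """Structural invariances of the exact 2x3 test, swept with hypothesis."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    counts = st.tuples(*[st.integers(min_value=0, max_value=12)] * 6)

    @given(counts)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_row_swap_and_column_permutation_invariance(self, t):
        a, b = t[:3], t[3:]
        p = fisher_2x3_pvalue(a, b)
        assert 0.0 < p <= 1.0
        assert fisher_2x3_pvalue(b, a) == pytest.approx(p, rel=1e-9)
        perm = (2, 0, 1)
        assert fisher_2x3_pvalue(
            tuple(a[i] for i in perm), tuple(b[i] for i in perm)
        ) == pytest.approx(p, rel=1e-9)
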