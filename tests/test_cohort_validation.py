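import itertools
import math

import numpy as np
import pytest
from scipy import stats

from exomir.cohort_validation import (
    chi_square,
    cohort_expression,
    fisher_exact,
    mann_whitney,
    paired_direction_count,
    student_t,
    wilcoxon_signed_rank,
)
from exomir.datasets import load_stage_table
from exomir.discovery_screen import relative_expression
from exomir.errors import CensoredInputError, InsufficientDataError, ValidationError

from conftest import make_matrix


# --------------------------------------------------------------------------
# enumeration oracles (independent of the implementation's DP)


def brute_mann_whitney_p(x, y):
    allv = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(allv)
    obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(allv)), n1)]
    )
    return min(1.0, 2 * min((sums <= obs + 1e-9).mean(), (sums >= obs - 1e-9).mean()))


def brute_wilcoxon_p(diffs):
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    sums = np.array(
        [
            ranks[np.array(signs, bool)].sum()
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    return min(1.0, 2 * min((sums <= obs + 1e-9).mean(), (sums >= obs - 1e-9).mean()))


def hypergeom_fisher_p(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in support}
    obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-9)))


# --------------------------------------------------------------------------


class TestMannWhitney:
    def test_exact_small_example(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_p1(self):
        res = mann_whitney([1, 2, 3], [3, 1, 2], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n1, n2 = rng.integers(1, 8, 2)
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            got = mann_whitney(x, y, mode="exact").p_value
            assert got == pytest.approx(brute_mann_whitney_p(x, y), abs=1e-12)

    def test_normal_close_to_exact(self):
        """The tie-corrected normal approximation tracks the exact permutation
        p within 0.02 once groups reach ~15 observations (at smaller n the
        two-sided point-mass conventions alone differ by more than that)."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            x = rng.normal(size=rng.integers(15, 18))
            y = rng.normal(size=rng.integers(15, 18))
            pe = mann_whitney(x, y, mode="exact", exact_limit=60).p_value
            pn = mann_whitney(x, y, mode="normal").p_value
            assert abs(pe - pn) < 0.02

    def test_exact_limit_enforced(self):
        with pytest.raises(InsufficientDataError, match="exact"):
            mann_whitney(np.arange(20), np.arange(20), mode="exact", exact_limit=25)

    def test_degenerate_identical_values(self):
        with pytest.warns(UserWarning, match="identical"):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0


class TestWilcoxon:
    def test_exact_small_example(self):
        res = wilcoxon_signed_rank([(2, 1), (3, 1), (4, 1)], mode="exact")
        assert res.statistic == 0.0  # W- = 0
        assert res.p_value == pytest.approx(0.25)

    def test_antisymmetric_differences_give_p1(self):
        res = wilcoxon_signed_rank([(1, 0), (-1, 0)], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([(5, 5), (2, 1), (3, 1), (4, 1)], mode="exact")
        assert res.n1 == 3
        assert res.p_value == pytest.approx(0.25)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = rng.integers(1, 11)
            d = rng.integers(-4, 5, n).astype(float)
            if np.all(d == 0):
                continue
            pairs = np.column_stack([d, np.zeros_like(d)])
            got = wilcoxon_signed_rank(pairs, mode="exact").p_value
            assert got == pytest.approx(brute_wilcoxon_p(d), abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
        assert res.p_value == 1.0


class TestPairedDirection:
    def test_counts(self):
        pairs = [(0.5, 1.0), (0.8, 1.0), (1.2, 1.0)]
        assert paired_direction_count(pairs) == (2, 3)

    def test_unit_ratio_not_down(self):
        assert paired_direction_count([(1.0, 1.0)] * 4) == (0, 4)

    def test_matches_bruteforce_on_simulated_tissue(self):
        from exomir.synthetic_data import SimulationConfig, simulate_paired_tissue

        df = simulate_paired_tissue(SimulationConfig(seed=5))
        for assay, sub in df.groupby("assay_id"):
            pairs = sub[["tumour", "adjacent"]].to_numpy()
            n_down, n_tot = paired_direction_count(pairs)
            assert n_down == sum(t < a for t, a in pairs)
            assert n_tot == len(pairs)

    def test_agrees_with_signed_rank_direction(self):
        """When most pairs are down and the signed-rank test is significant,
        the median ratio is below 1."""
        from exomir.synthetic_data import SimulationConfig, simulate_paired_tissue

        df = simulate_paired_tissue(SimulationConfig(seed=5))
        sub = df[df["assay_id"] == "hsa-miR-379-5p"]
        pairs = sub[["tumour", "adjacent"]].to_numpy()
        n_down, n_tot = paired_direction_count(pairs)
        res = wilcoxon_signed_rank(np.log2(pairs))
        assert n_down / n_tot > 0.5 and res.p_value < 0.05
        assert np.median(pairs[:, 0] / pairs[:, 1]) < 1.0


class TestChiSquare:
    def test_stage_table_fixture(self):
        """Pearson chi-square (no continuity correction) on the shipped
        stage-by-metastasis table reproduces p = .0449 to 4 d.p."""
        counts, _, _ = load_stage_table()
        statistic, df, p = chi_square(counts)
        assert df == 2
        assert p == pytest.approx(0.0449, abs=5e-5)
        assert statistic == pytest.approx(6.21, abs=0.01)

    def test_proportional_table_is_null(self):
        statistic, df, p = chi_square([[10, 20], [20, 40]])
        assert statistic == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(1, 30, (rng.integers(2, 4), rng.integers(2, 4)))
            statistic, df, _ = chi_square(t)
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            assert statistic == pytest.approx(((t - exp) ** 2 / exp).sum())
            assert df == (t.shape[0] - 1) * (t.shape[1] - 1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            chi_square([[0, 0], [5, 3]])


class TestFisherExact:
    def test_small_example(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_zero_margin_gives_p1(self):
        assert fisher_exact([[0, 0], [2, 3]]) == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = np.array([[5, 2], [1, 7]])
        assert fisher_exact(t) == pytest.approx(fisher_exact(t.T))
        assert fisher_exact(t) == pytest.approx(fisher_exact(t[::-1]))

    def test_matches_hypergeometric_enumeration(self):
        """Exhaustive check against the hypergeometric-sum definition for all
        2x2 tables with cells up to 5."""
        for a, b, c, d in itertools.product(range(6), repeat=4):
            t = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact(t) == pytest.approx(hypergeom_fisher_p(t), abs=1e-9)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValidationError, match="2x2"):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestStudentT:
    def test_identical_groups(self):
        with pytest.warns(UserWarning):
            res = student_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_example(self):
        res = student_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-math.sqrt(1.5), rel=1e-6)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(math.sqrt(1.5), df=4), rel=1e-9
        )

    def test_pooled_equals_welch_for_equal_variances(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0.3, 1, 200)
        pooled = student_t(x, y, equal_var=True)
        welch = student_t(x, y, equal_var=False)
        assert pooled.p_value == pytest.approx(welch.p_value, abs=1e-3)


class TestCohortExpression:
    def test_unit_when_target_equals_reference(self):
        m = make_matrix([[25.0, 30.0], [25.0, 30.0]], ["a", "ref"], ["s1", "s2"])
        ev = cohort_expression(m, "a", "ref")
        assert ev.values.tolist() == [1.0, 1.0]
        assert ev.n_censored == 0

    def test_all_censored_gives_empty_with_count(self):
        m = make_matrix([[np.nan, np.nan], [25.0, 30.0]], ["a", "ref"], ["s1", "s2"])
        ev = cohort_expression(m, "a", "ref")
        assert ev.values.empty and ev.n_censored == 2

    def test_censored_reference_rejected(self):
        m = make_matrix([[25.0, 30.0], [np.nan, 30.0]], ["a", "ref"], ["s1", "s2"])
        with pytest.raises(CensoredInputError):
            cohort_expression(m, "a", "ref")

    def test_matches_relative_expression_elementwise(self, sim_validation):
        _, m, _, truth = sim_validation
        ref = truth.references[0]
        ev = cohort_expression(m, "hsa-miR-410-3p", ref)
        for s, v in ev.values.items():
            assert v == pytest.approx(
                relative_expression(m.value("hsa-miR-410-3p", s), m.value(ref, s))
            )
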