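import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from regdiff import (
    ExpressionMatrix,
    SampleAnnotation,
    build_null,
    call_degs,
    compute_group_stats,
    empirical_p,
    lmr_cutoff,
    run_diffexp,
    storey_qvalues,
    stouffer_combine,
)
from regdiff.errors import ConfigError, InputError


def _matrix(values, samples_a, samples_b):
    n_a, n_b = samples_a, samples_b
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    data = pd.DataFrame(np.atleast_2d(values), columns=cols,
                        index=[f"g{i}" for i in range(np.atleast_2d(values).shape[0])])
    ann = SampleAnnotation(pd.DataFrame(
        {"group": ["A"] * n_a + ["B"] * n_b}, index=pd.Index(cols, name="sample_id")))
    return ExpressionMatrix(data), ann


class TestGroupStats:
    def test_identical_groups_give_zero(self):
        expr, ann = _matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], 3, 3)
        row = compute_group_stats(expr, ann).iloc[0]
        assert row["t_stat"] == 0.0
        assert row["ranksum_z"] == 0.0
        assert row["lmr"] == 0.0

    def test_lmr_is_difference_of_medians(self):
        expr, ann = _matrix([[2.0, 4.0, 6.0, 1.0, 3.0, 5.0]], 3, 3)
        assert compute_group_stats(expr, ann).iloc[0]["lmr"] == pytest.approx(4 - 3)

    def test_welch_t_matches_scalar_formula(self):
        rng = np.random.default_rng(17)
        a = rng.normal(1.0, 1.0, size=20)
        b = rng.normal(0.0, 1.0, size=20)
        expr, ann = _matrix([np.concatenate([a, b])], 20, 20)
        t = compute_group_stats(expr, ann).iloc[0]["t_stat"]
        # independent scalar Welch formula
        expected = (a.mean() - b.mean()) / math.sqrt(
            a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert t == pytest.approx(expected)
        # and scipy's reference implementation
        assert t == pytest.approx(sps.ttest_ind(a, b, equal_var=False).statistic)

    def test_ranksum_z_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(19)
        a = rng.normal(0.6, 1.0, size=15)
        b = rng.normal(0.0, 1.0, size=25)
        expr, ann = _matrix([np.concatenate([a, b])], 15, 25)
        z = compute_group_stats(expr, ann).iloc[0]["ranksum_z"]
        # scipy ranksums reports the same standardized statistic
        assert z == pytest.approx(sps.ranksums(a, b).statistic)

    def test_zero_variance_flagged(self):
        expr, ann = _matrix([[5.0] * 6, [1, 2, 3, 4, 5, 6]], 3, 3)
        out = compute_group_stats(expr, ann)
        assert bool(out.iloc[0]["zero_variance"])
        assert out.iloc[0][["t_stat", "ranksum_z", "lmr"]].tolist() == [0.0, 0.0, 0.0]
        assert not bool(out.iloc[1]["zero_variance"])

    def test_label_swap_negates_statistics(self, small_cohort):
        expr, ann, *_ = small_cohort
        swapped = SampleAnnotation(
            ann.table.assign(group=ann.table["group"].map({"A": "B", "B": "A"})))
        s1 = compute_group_stats(expr, ann)
        s2 = compute_group_stats(expr, swapped)
        np.testing.assert_allclose(s1["t_stat"], -s2["t_stat"], atol=1e-10)
        np.testing.assert_allclose(s1["ranksum_z"], -s2["ranksum_z"], atol=1e-10)
        np.testing.assert_allclose(s1["lmr"], -s2["lmr"], atol=1e-10)


class TestBuildNull:
    def test_constant_matrix_gives_zero_null(self):
        expr, ann = _matrix([[3.0] * 8, [3.0] * 8], 4, 4)
        null = build_null(expr, ann, n_perm=10, seed=0)
        assert np.all(null.t == 0)
        assert np.all(null.ranksum == 0)
        assert np.all(null.lmr == 0)

    def test_pooled_null_t_centred_at_zero(self, null_cohort):
        expr, ann, *_ = null_cohort
        null = build_null(expr, ann, n_perm=50, seed=1)
        pool = null.t
        assert abs(pool.mean()) < 3 * pool.std() / np.sqrt(pool.size)

    def test_deterministic_given_seed(self, null_cohort):
        expr, ann, *_ = null_cohort
        n1 = build_null(expr, ann, n_perm=5, seed=9)
        n2 = build_null(expr, ann, n_perm=5, seed=9)
        np.testing.assert_array_equal(n1.t, n2.t)
        np.testing.assert_array_equal(n1.lmr, n2.lmr)

    def test_per_gene_mode_shape(self, null_cohort):
        expr, ann, *_ = null_cohort
        null = build_null(expr, ann, n_perm=7, seed=2, pooled=False)
        # each permutation contributes its statistic and the negation
        assert null.t.shape == (14, expr.shape[0])
        assert not null.pooled


class TestEmpiricalP:
    def test_observation_beyond_all_null(self):
        null = np.sort(np.linspace(-1, 1, 999))
        assert empirical_p(5.0, null) == pytest.approx(2 / 1000)

    def test_observation_at_symmetric_median(self):
        null = np.sort(np.concatenate([np.linspace(-1, 1, 999)]))
        assert empirical_p(0.0, null) == 1.0

    def test_hand_enumeration(self):
        null = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        # obs=1.5: 2 null >= obs side count (1)+1, 5 null <= side (4)+1 -> 2*2/6
        assert empirical_p(1.5, null) == pytest.approx(2 / 3)

    @given(st.floats(-10, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_in_unit_interval_and_never_zero(self, obs, seed):
        null = np.sort(np.random.default_rng(seed).normal(size=100))
        p = empirical_p(obs, null)
        assert 0 < p <= 1


class TestStouffer:
    def test_all_ones_give_null_result(self):
        z, p = stouffer_combine(np.array([[1.0, 1.0, 1.0]]), np.array([[1, 1, -1]]))
        assert z[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)

    def test_concordant_signs_closed_form(self):
        z, p = stouffer_combine(np.array([[0.05, 0.05, 0.05]]), np.array([[1, 1, 1]]))
        z_expected = math.sqrt(3) * sps.norm.isf(0.025)
        assert z[0] == pytest.approx(z_expected)
        assert p[0] == pytest.approx(2 * sps.norm.sf(z_expected))

    def test_discordant_sign_weakens_combination(self):
        z, p = stouffer_combine(np.array([[0.05, 0.05, 0.05]]), np.array([[1, 1, -1]]))
        assert abs(z[0]) == pytest.approx(sps.norm.isf(0.025) / math.sqrt(3))
        assert p[0] > 0.05

    def test_zero_p_rejected(self):
        with pytest.raises(InputError):
            stouffer_combine(np.array([[0.0, 0.5, 0.5]]), np.array([[1, 1, 1]]))

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_each_input(self, p1, p2):
        """Decreasing one input p (same signs) never decreases |z|."""
        lo, hi = sorted([p1, p2])
        signs = np.array([[1, 1, 1]])
        z_lo, _ = stouffer_combine(np.array([[lo, 0.5, 0.5]]), signs)
        z_hi, _ = stouffer_combine(np.array([[hi, 0.5, 0.5]]), signs)
        assert abs(z_lo[0]) >= abs(z_hi[0]) - 1e-12


class TestStorey:
    def test_single_p_of_one(self):
        assert storey_qvalues(np.array([1.0]))[0] == pytest.approx(1.0)

    def test_pi0_one_reduces_to_bh(self):
        p = np.array([0.01, 0.02, 0.9, 0.95])
        # pi0_hat = 2/(0.5*4) = 1 -> identical to BH
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(storey_qvalues(p), bh)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=200)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_storey_equals_pi0_times_bh(self):
        """q_storey = pi0_hat * q_BH elementwise (fixed-lambda variant)."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 150)])
        m = p.size
        pi0 = min(1.0, (p > 0.5).sum() / (0.5 * m))
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(storey_qvalues(p), np.minimum(pi0 * bh, 1.0))

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError):
            storey_qvalues(np.array([]))


class TestLmrCutoff:
    def test_constant_matrix_cutoff_zero(self):
        expr, ann = _matrix([[2.0] * 10, [2.0] * 10], 5, 5)
        assert lmr_cutoff(expr, ann, n_perm=20, seed=0) == 0.0

    def test_cutoff_non_negative(self, null_cohort):
        expr, ann, *_ = null_cohort
        assert lmr_cutoff(expr, ann, n_perm=10, seed=3) >= 0.0

    def test_normal_quantile_oracle(self):
        """95th pct of |N(0,1)| is the 97.5% normal quantile ~ 1.96."""
        draws = np.random.default_rng(12).normal(size=100_000)
        cutoff = np.percentile(np.abs(draws), 95.0)
        assert cutoff == pytest.approx(sps.norm.isf(0.025), abs=0.02)


class TestCallDegs:
    def test_all_q_one_gives_empty_sets(self):
        table = pd.DataFrame({"q_value": [1.0, 1.0], "lmr": [2.0, -2.0]},
                             index=["g1", "g2"])
        up_a, up_b = call_degs(table, fdr_cut=0.05, lmr_cut=0.1)
        assert up_a == frozenset() and up_b == frozenset()

    def test_direct_rule(self):
        table = pd.DataFrame(
            {"q_value": [0.01, 0.01, 0.2], "lmr": [0.5, -0.5, 0.9]},
            index=["g1", "g2", "g3"])
        up_a, up_b = call_degs(table, fdr_cut=0.05, lmr_cut=0.1)
        assert up_a == frozenset({"g1"})
        assert up_b == frozenset({"g2"})

    def test_negative_cut_rejected(self):
        table = pd.DataFrame({"q_value": [0.5], "lmr": [0.0]}, index=["g"])
        with pytest.raises(ConfigError):
            call_degs(table, lmr_cut=-1.0)


class TestRunDiffexp:
    def test_label_swap_keeps_combined_p(self, null_cohort):
        expr, ann, *_ = null_cohort
        swapped = SampleAnnotation(
            ann.table.assign(group=ann.table["group"].map({"A": "B", "B": "A"})))
        t1 = run_diffexp(expr, ann, n_perm=100, n_perm_cutoff=50, seed=5)
        t2 = run_diffexp(expr, swapped, n_perm=100, n_perm_cutoff=50, seed=5)
        np.testing.assert_allclose(t1["p_combined"], t2["p_combined"], atol=1e-12)
        np.testing.assert_allclose(t1["z_combined"], -t2["z_combined"], atol=1e-12)

    def test_gene_row_order_invariance(self, null_cohort):
        expr, ann, *_ = null_cohort
        shuffled = ExpressionMatrix(expr.data.sample(frac=1.0, random_state=1))
        t1 = run_diffexp(expr, ann, n_perm=100, n_perm_cutoff=50, seed=5)
        t2 = run_diffexp(shuffled, ann, n_perm=100, n_perm_cutoff=50, seed=5)
        common = t1.index
        np.testing.assert_allclose(
            t1.loc[common, "p_combined"], t2.loc[common, "p_combined"], atol=1e-12)

    def test_recovers_planted_genes(self, small_cohort):
        expr, ann, _, truth = small_cohort
        table = run_diffexp(expr, ann, n_perm=500, n_perm_cutoff=200, seed=13)
        called = frozenset(table.index[table["is_deg"]])
        truth_set = truth.de_gene_set
        jaccard = len(called & truth_set) / len(called | truth_set)
        assert jaccard >= 0.7

    def test_deg_direction_matches_lmr_sign(self, small_cohort):
        expr, ann, *_ = small_cohort
        table = run_diffexp(expr, ann, n_perm=300, n_perm_cutoff=100, seed=13)
        degs = table[table["is_deg"]]
        assert ((degs["direction"] == "up_in_A") == (degs["lmr"] > 0)).all()
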