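import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_matrix
from oracles import sam_d_oracle
from ucrna.differential import (
    SamConfig,
    block_t_test,
    choose_s0,
    class_comparison,
    comparative_ct_fold_change,
    fold_change,
    permutation_pvalues,
    sam_d_statistic,
    storey_qvalues,
)
from ucrna.simulate import gen_annotation


def _groups(m, n_a, n_b):
    s = m.sample_ids
    return s[:n_a], s[n_a : n_a + n_b]


class TestFoldChange:
    @pytest.mark.parametrize("shift,expected", [(1.0, 2.0), (-1.0, 0.5), (0.0, 1.0)])
    def test_log2_definition(self, shift, expected):
        vals = np.hstack([np.full((1, 3), 5.0), np.full((1, 3), 5.0 + shift)])
        m = make_matrix(vals)
        a, b = _groups(m, 3, 3)
        assert fold_change(m, a, b).iloc[0] == pytest.approx(expected)

    def test_group_without_data_is_nan(self):
        vals = np.array([[np.nan, np.nan, 5.0, 6.0]])
        m = make_matrix(vals)
        a, b = _groups(m, 2, 2)
        assert np.isnan(fold_change(m, a, b).iloc[0])


class TestSamD:
    def test_zero_variance_arithmetic(self):
        m = make_matrix(np.array([[2.0, 2.0, 2.0, 1.0, 1.0, 1.0]]))
        a, b = _groups(m, 3, 3)
        d, s = sam_d_statistic(m, a, b, s0=0.5)
        assert s.iloc[0] == 0.0
        assert d.iloc[0] == pytest.approx(-2.0)

    def test_identical_groups_d_zero(self):
        m = make_matrix(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]))
        a, b = _groups(m, 3, 3)
        d, _ = sam_d_statistic(m, a, b, s0=0.1)
        assert d.iloc[0] == pytest.approx(0.0)

    def test_matches_independent_formula(self, rng):
        vals = rng.normal(size=(10, 9))
        m = make_matrix(vals)
        a, b = _groups(m, 4, 5)
        d, s = sam_d_statistic(m, a, b, s0=0.2)
        for i in range(10):
            d_exp, s_exp = sam_d_oracle(vals[i, :4], vals[i, 4:], 0.2)
            assert d.iloc[i] == pytest.approx(d_exp, abs=1e-12)
            assert s.iloc[i] == pytest.approx(s_exp, abs=1e-12)

    def test_small_group_rejected(self):
        m = make_matrix(np.ones((12, 4)))
        with pytest.raises(ValueError, match="block_t_test"):
            sam_d_statistic(m, m.sample_ids[:1], m.sample_ids[1:], s0=0.1)


class TestChooseS0:
    def test_median_policy(self):
        s = np.arange(1.0, 12.0)
        assert choose_s0(s) == np.median(s)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="1e-06|zero"):
            assert choose_s0(np.zeros(20)) == 1e-6

    def test_constant_s_returns_it(self):
        assert choose_s0(np.full(15, 0.7)) == pytest.approx(0.7)


class TestPermutationP:
    def _matrix(self, rng, n_probes=30, n_a=6, n_b=6):
        m = make_matrix(rng.normal(size=(n_probes, n_a + n_b)))
        return m, *_groups(m, n_a, n_b)

    def test_add_one_lower_bound(self, rng):
        m, a, b = self._matrix(rng)
        # plant a huge effect: its |d| should beat every pooled null value
        m.values.iloc[0, : len(a)] += 50
        cfg = SamConfig(permutations=50, seed=0)
        p = permutation_pvalues(m, a, b, cfg, s0=0.1)
        n_pool = 50 * 30
        assert p.iloc[0] == pytest.approx(1.0 / (1 + n_pool))

    def test_constant_probe_p_one(self, rng):
        m, a, b = self._matrix(rng)
        m.values.iloc[0, :] = 5.0  # d = 0
        cfg = SamConfig(permutations=50, seed=0)
        p = permutation_pvalues(m, a, b, cfg, s0=0.1)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_null_p_uniform(self, rng):
        """Both groups from one distribution: pooled-null p are ~Uniform."""
        m = make_matrix(rng.normal(size=(962, 24)))
        a, b = _groups(m, 12, 12)
        cfg = SamConfig(permutations=200, seed=1)
        p = permutation_pvalues(m, a, b, cfg, s0=0.1)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_seeded_reproducibility(self, rng):
        m, a, b = self._matrix(rng)
        cfg = SamConfig(permutations=40, seed=7)
        p1 = permutation_pvalues(m, a, b, cfg, s0=0.1)
        p2 = permutation_pvalues(m, a, b, cfg, s0=0.1)
        assert (p1 == p2).all()

    def test_exhaustive_truncation_warns(self, rng):
        m = make_matrix(rng.normal(size=(5, 5)))
        a, b = _groups(m, 2, 3)  # only C(5,2)=10 distinct assignments
        cfg = SamConfig(permutations=500, seed=0)
        with pytest.warns(UserWarning, match="distinct"):
            permutation_pvalues(m, a, b, cfg, s0=0.1)


class TestStoreyQ:
    def test_all_ones(self):
        q = storey_qvalues(np.ones(10))
        assert np.allclose(q, 1.0)

    def test_step_up_hand_example(self):
        q = storey_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        assert np.allclose(q, 0.04)

    def test_order_preserving_and_input_order_invariant(self, rng):
        p = rng.uniform(0.001, 1.0, size=200)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(200)
        assert np.allclose(storey_qvalues(p[perm]), q[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0, 0.5]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=50))
    def test_q_in_unit_interval(self, p):
        q = storey_qvalues(np.array(p))
        assert ((q > 0) & (q <= 1.0)).all()


class TestClassComparison:
    def test_missing_field_lists_available(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(15, 8)))
        ann = pd.DataFrame({"sample_id": m.sample_ids})
        with pytest.raises(ValueError, match="available"):
            class_comparison(m, ann, "epe_yes_vs_no", SamConfig(permutations=5))

    def test_sorted_by_p_and_q_monotone(self, small_cohort_run):
        res = small_cohort_run["result"]
        assert (res["p_value"].diff().dropna() >= 0).all()
        assert (res["q_value"].diff().dropna() >= -1e-12).all()

    def test_fold_change_consistent_with_means(self, small_cohort_run):
        res = small_cohort_run["result"]
        assert np.allclose(
            res["fold_change"], 2.0 ** (res["mean_log2_B"] - res["mean_log2_A"])
        )

    def test_recovers_planted_effects(self, small_cohort_run):
        run = small_cohort_run
        assert run["sensitivity"] >= 0.8


class TestBlockT:
    def test_all_zero_differences(self):
        tbl = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        t, p = block_t_test(tbl)
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_differences_floor(self):
        tbl = pd.DataFrame([[2.0, 3.0, 4.0], [1.0, 2.0, 3.0]])
        t, p = block_t_test(tbl)
        assert np.isinf(t) and p < 1e-300

    def test_hand_computation(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.464, p = 0.0742 (2 df)
        tbl = pd.DataFrame([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        t, p = block_t_test(tbl)
        assert t == pytest.approx(3.464, abs=1e-3)
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_matches_scipy_paired(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        t, p = block_t_test(pd.DataFrame([x, y]))
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_too_few_blocks(self):
        with pytest.raises(ValueError, match="blocks"):
            block_t_test(pd.DataFrame([[1.0], [2.0]]))


class TestComparativeCt:
    def _records(self, treated_dct, control_dct):
        rows = []
        for k, d in enumerate(treated_dct):
            rows.append({"sample_id": f"t{k}", "condition": "treated",
                         "target_ct": 20.0 + d, "reference_ct": 20.0})
        for k, d in enumerate(control_dct):
            rows.append({"sample_id": f"c{k}", "condition": "control",
                         "target_ct": 20.0 + d, "reference_ct": 20.0})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "treated,control,expected",
        [([5.0], [5.0], 1.0), ([5.0], [6.0], 2.0), ([7.0], [5.0], 0.25)],
    )
    def test_closed_form(self, treated, control, expected):
        fold = comparative_ct_fold_change(self._records(treated, control))
        assert fold == pytest.approx(expected)

    def test_missing_condition(self):
        recs = self._records([5.0], [])
        recs = recs[recs["condition"] == "treated"]
        with pytest.raises(ValueError, match="control"):
            comparative_ct_fold_change(recs)
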