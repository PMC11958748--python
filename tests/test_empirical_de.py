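"""Empirical t-test: statistic, pooled null, p-values, cutoffs, DEG calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from permde import (
    ConfigurationError,
    DeConfig,
    NullDistribution,
    PermutationTTest,
    SimConfig,
    adjust_pvalues,
    build_null,
    call_degs,
    empirical_pvalue,
    fc_cutoff,
    filter_expressed,
    log_transform,
    quantile_normalize,
    simulate_fpkm,
    t_statistic,
)
from permde.empirical_de import _exhaustive_masks, _t_matrix


def preprocess(fpkm):
    return quantile_normalize(log_transform(filter_expressed(fpkm)))


class TestTStatistic:
    def test_hand_pooled_t(self):
        # pooled variance 1, mean difference 3 -> 3 / sqrt(2/3)
        assert t_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(3 / np.sqrt(2 / 3))

    def test_identical_groups_give_zero(self):
        assert t_statistic([2.0, 3.0, 4.0], [2.0, 3.0, 4.0]) == 0.0

    def test_variance_floor_keeps_constant_groups_finite(self):
        c = 2.0
        t = t_statistic([0, 0, 0], [c, c, c], variance_floor=1e-8)
        assert t == pytest.approx(c / np.sqrt(1e-8 * (2 / 3)))

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            t_statistic([1.0], [2.0, 3.0])

    def test_matrix_kernel_matches_scalar(self, rng):
        values = rng.normal(size=(20, 6))
        mask = np.array([False] * 3 + [True] * 3)
        ts = _t_matrix(values, mask[None], 1e-8)[:, 0]
        for i in range(20):
            assert ts[i] == pytest.approx(t_statistic(values[i, :3], values[i, 3:]))

    def test_welch_differs_under_unequal_groups(self):
        # pooled and Welch coincide for equal group sizes; use 4 vs 2
        x = np.array([0.0, 0.1, -0.1, 0.05])
        y = np.array([5.0, 9.0])
        mask = np.array([[False] * 4 + [True] * 2])
        pooled = _t_matrix(np.r_[x, y][None], mask, 1e-8, "pooled")[0, 0]
        welch = _t_matrix(np.r_[x, y][None], mask, 1e-8, "welch")[0, 0]
        assert pooled != pytest.approx(welch)


class TestBuildNull:
    def test_exhaustive_mode_enumerates_20_assignments(self):
        masks = _exhaustive_masks(6, 3)
        assert masks.shape == (20, 6)
        assert len({tuple(m) for m in masks}) == 20
        assert (masks.sum(axis=1) == 3).all()

    def test_null_size_and_sorting(self, rng):
        values = rng.normal(size=(50, 6))
        cfg = DeConfig(n_permutations=100, seed=3)
        null = build_null(values, np.array([False] * 3 + [True] * 3), cfg)
        assert null.size == 50 * 100
        assert (np.diff(null.pooled_abs_t) >= 0).all()
        assert (null.pooled_abs_t >= 0).all()

    def test_sampled_mode_deterministic_given_seed(self, rng):
        values = rng.normal(size=(30, 6))
        mask = np.array([False] * 3 + [True] * 3)
        cfg = DeConfig(n_permutations=50, seed=7)
        a = build_null(values, mask, cfg)
        b = build_null(values, mask, cfg)
        np.testing.assert_array_equal(a.pooled_abs_t, b.pooled_abs_t)

    def test_signed_permutation_t_symmetric_under_global_null(self):
        fpkm, _, truth = simulate_fpkm(SimConfig(n_genes=2000, frac_de=0.0, seed=23))
        values = preprocess(fpkm).to_numpy()
        mask = np.array([False] * 3 + [True] * 3)
        rng = np.random.default_rng(1)
        masks = rng.permuted(np.tile(mask, (100, 1)), axis=1)
        ts = _t_matrix(values, masks, 1e-8).ravel()
        assert abs(ts.mean()) < 3 * ts.std() / np.sqrt(ts.size)

    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ConfigurationError):
            DeConfig(n_permutations=0)


class TestEmpiricalPvalue:
    def null_of(self, values):
        arr = np.sort(np.abs(np.asarray(values, dtype=float)))
        return NullDistribution(arr, n_permutations=1, permutation_scheme="sampled", seed=0)

    def test_counting_oracle(self):
        null = self.null_of([0.1, 0.2, 0.3, 0.5, 0.7, 1.1, 1.5, 2.0, 3.0])
        # 3 of 9 null values >= 1.2 -> (1+3)/(1+9)
        assert empirical_pvalue(1.2, null) == pytest.approx(0.4)

    def test_zero_statistic_has_p_one(self):
        null = self.null_of(np.linspace(0.1, 2, 25))
        assert empirical_pvalue(0.0, null) == 1.0

    def test_exceeding_null_maximum_gives_smoothed_minimum(self):
        null = self.null_of(np.linspace(0.1, 2, 25))
        assert empirical_pvalue(99.0, null) == pytest.approx(1 / 26)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_non_increasing_in_abs_t(self, seed):
        rng = np.random.default_rng(seed)
        null = self.null_of(rng.normal(size=200))
        ts = np.sort(np.abs(rng.normal(size=50)))
        ps = empirical_pvalue(ts, null)
        assert (np.diff(ps) <= 0).all()


class TestAdjustPvalues:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_are_fixed_point(self):
        np.testing.assert_allclose(adjust_pvalues([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.3]), [0.3])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(1e-6, 1, size=100)
        assert (adjust_pvalues(p) >= p - 1e-12).all()

    def test_step_up_matches_direct_implementation(self, rng):
        p = rng.uniform(1e-6, 1, size=57)
        m = p.size
        order = np.argsort(p)
        staged = p[order] * m / np.arange(1, m + 1)
        expected = np.empty(m)
        expected[order] = np.minimum(np.minimum.accumulate(staged[::-1])[::-1], 1)
        np.testing.assert_allclose(adjust_pvalues(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


class TestFcCutoff:
    def test_fixed_mode_returns_published_cutoff(self):
        cfg = DeConfig(fc_cutoff_mode="fixed")
        assert fc_cutoff(np.linspace(-3, 3, 100), cfg) == 0.336

    def test_constant_distribution_is_its_own_percentile(self):
        cfg = DeConfig(fc_cutoff_mode="percentile")
        assert fc_cutoff(np.full(40, -0.7), cfg) == pytest.approx(0.7)

    def test_percentile_against_direct_indexing(self):
        fc = np.arange(1.0, 101.0)
        cfg = DeConfig(fc_cutoff_mode="percentile", fc_percentile=0.95)
        # linear interpolation between order statistics: h = 99*0.95 = 94.05
        assert fc_cutoff(fc, cfg) == pytest.approx(95.05)


class TestPermutationTTest:
    def fit_small(self, n_genes=300, frac_de=0.1, effect=2.0, seed=31, **kw):
        fpkm, groups, truth = simulate_fpkm(
            SimConfig(n_genes=n_genes, frac_de=frac_de, effect_size_log2=effect, seed=seed)
        )
        norm = preprocess(fpkm)
        est = PermutationTTest(n_permutations=kw.pop("n_permutations", 300),
                               random_state=1, **kw)
        est.fit(norm.T, groups.loc[norm.columns].to_numpy())
        return est, norm, groups, truth

    def test_detable_invariants(self):
        est, *_ = self.fit_small()
        res = est.results_
        assert ((res.p_emp > 0) & (res.p_emp <= 1)).all()
        assert ((res.p_adj > 0) & (res.p_adj <= 1)).all()
        assert (res.p_adj >= res.p_emp - 1e-12).all()
        expected = (res.p_adj < 0.05) & (res.log2fc.abs() > est.fc_cutoff_)
        assert (res.is_deg == expected).all()
        up = res.direction == "up"
        down = res.direction == "down"
        assert (res.loc[up, "log2fc"] > 0).all() and res.loc[up, "is_deg"].all()
        assert (res.loc[down, "log2fc"] < 0).all() and res.loc[down, "is_deg"].all()
        # sorted by p_adj, then |log2fc| descending
        assert (np.diff(res.p_adj) >= -1e-15).all()

    def test_duplicated_gene_gets_identical_statistics(self):
        est, norm, groups, _ = self.fit_small()
        dup = pd.concat([norm, norm.iloc[[0]].rename(index={norm.index[0]: "dup"})])
        table = call_degs(dup, groups, DeConfig(n_permutations=300, seed=1))
        a, b = table.loc[norm.index[0]], table.loc["dup"]
        for col in ("log2fc", "t_stat", "p_emp", "p_adj"):
            assert a[col] == b[col]

    def test_sample_order_invariance(self):
        est, norm, groups, _ = self.fit_small()
        shuffled = norm[["treated_2", "control_1", "treated_1",
                         "control_3", "treated_3", "control_2"]]
        table = call_degs(shuffled, groups, DeConfig(n_permutations=300, seed=1))
        pd.testing.assert_frame_equal(table, est.results_)

    def test_called_directions_match_planted_signs(self):
        est, _, _, truth = self.fit_small(n_genes=600, effect=2.0,
                                          fc_cutoff_mode="fixed", adjust_method="perm-fdr")
        res = est.results_
        called = res[res.is_deg]
        for gene, row in called.iterrows():
            planted = truth.loc[gene, "planted_effect_log2"]
            assert planted != 0
            assert np.sign(row.log2fc) == np.sign(planted)

    def test_requires_two_groups_of_two(self):
        est = PermutationTTest()
        with pytest.raises(ValueError):
            est.fit(np.zeros((4, 5)), ["a", "a", "a", "a"])
        with pytest.raises(ValueError):
            est.fit(np.zeros((3, 5)), ["a", "a", "b"])

    def test_get_params_round_trip(self):
        est = PermutationTTest(n_permutations=123, fc_cutoff_mode="fixed")
        clone = PermutationTTest(**est.get_params())
        assert clone.n_permutations == 123 and clone.fc_cutoff_mode == "fixed"

    def test_exhaustive_scheme_used_when_requested(self):
        est, *_ = self.fit_small(n_genes=120, permutation_scheme="exhaustive")
        assert est.null_distribution_.permutation_scheme == "exhaustive"
        assert est.null_distribution_.size == est.n_features_in_ * 20
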