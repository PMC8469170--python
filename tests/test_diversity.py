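"""Alpha diversity: closed-form values, rarefaction behavior, paired tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from skbio.diversity.alpha import chao1 as skbio_chao1
from skbio.diversity.alpha import shannon as skbio_shannon

from avigut.diversity import (chao1, paired_test, rarefied_alpha, rarefy,
                              shannon)
from avigut.io import CountMatrix, FormatError


class TestShannon:
    def test_uniform_composition(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(np.log(4), abs=1e-9)

    def test_single_taxon_is_zero(self):
        assert shannon([7]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        assert shannon([1, 1, 2]) == pytest.approx(1.039721, abs=1e-6)

    def test_base_two_option(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(FormatError):
            shannon([0, 0])

    def test_matches_skbio(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(0, 30, size=10)
            v[0] += 1
            assert shannon(v) == pytest.approx(skbio_shannon(v, base=np.e),
                                               abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=100), min_size=2,
                    max_size=12))
    def test_uniform_maximizes_on_same_support(self, counts):
        uniform = np.ones(len(counts))
        assert shannon(uniform) >= shannon(np.array(counts)) - 1e-12


class TestChao1:
    @pytest.mark.parametrize("vec,expected", [
        ((2, 3, 4), 3.0),          # no singletons: estimate = observed
        ((1, 1, 2, 5), 4.5),       # 4 + 2*1/(2*2)
        ((1, 1, 1), 6.0),          # 3 + 3*2/2, F2 = 0 still defined
    ])
    def test_bias_corrected_hand_values(self, vec, expected):
        assert chao1(np.array(vec)) == pytest.approx(expected, abs=1e-12)

    def test_classic_variant_and_f2_zero_error(self):
        # S_obs = 4, F1 = 2, F2 = 1 -> 4 + 2^2/(2*1) = 6
        assert chao1(np.array([1, 1, 2, 5]), bias_corrected=False) == \
            pytest.approx(6.0, abs=1e-12)
        with pytest.raises(FormatError):
            chao1(np.array([1, 1, 3]), bias_corrected=False)

    def test_non_integer_rejected(self):
        with pytest.raises(FormatError):
            chao1(np.array([0.5, 0.5]))

    def test_at_least_observed_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.integers(0, 10, size=15)
            v[0] += 1
            est = chao1(v)
            s_obs = (v > 0).sum()
            assert est >= s_obs - 1e-12
            if (v == 1).sum() == 0:
                assert est == pytest.approx(s_obs)

    def test_matches_skbio_bias_corrected(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.integers(0, 6, size=20)
            v[0] += 1
            assert chao1(v) == pytest.approx(skbio_chao1(v, bias_corrected=True),
                                             abs=1e-12)


class TestRarefy:
    def test_full_depth_returns_input(self):
        v = np.array([3, 0, 7])
        rng = np.random.default_rng(0)
        assert (rarefy(v, 10, rng) == v).all()

    def test_output_total_is_depth(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.integers(0, 50, size=8)
            v[0] += 5
            depth = int(rng.integers(1, v.sum() + 1))
            assert rarefy(v, depth, rng).sum() == depth

    def test_depth_above_total_names_sample(self):
        with pytest.raises(FormatError, match="S11J3"):
            rarefy(np.array([1, 2]), 10, np.random.default_rng(0),
                   sample_id="S11J3")

    def test_hypergeometric_means(self):
        v = np.array([50, 30, 15, 5])
        depth, n_draws = 40, 4000
        rng = np.random.default_rng(3)
        draws = np.array([rarefy(v, depth, rng) for _ in range(n_draws)])
        expected = depth * v / v.sum()
        n = v.sum()
        var = (depth * (v / n) * (1 - v / n) * (n - depth) / (n - 1))
        se = np.sqrt(var / n_draws)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9).all()


class TestRarefiedAlpha:
    def small_matrix(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 60, size=(12, 4))
        counts[0] += 30
        return CountMatrix(pd.DataFrame(
            counts, index=[f"t{i}" for i in range(12)],
            columns=["a", "b", "c", "d"]))

    def test_single_iteration_consistency(self):
        cm = self.small_matrix()
        res = rarefied_alpha(cm, depth=50, iterations=1, seed=9)
        from avigut.diversity import _sample_rng
        for s in cm.sample_ids:
            sub = rarefy(cm.df[s].to_numpy(), 50, _sample_rng(9, s),
                         sample_id=s)
            assert res.table.loc[s, "shannon_mean"] == pytest.approx(
                shannon(sub))

    def test_sample_exactly_at_depth_has_zero_variance(self):
        cm = self.small_matrix()
        depth = int(cm.sample_totals().min())
        res = rarefied_alpha(cm, depth=depth, iterations=10, seed=0)
        at_depth = cm.sample_totals().idxmin()
        assert res.table.loc[at_depth, "shannon_sd"] == pytest.approx(0.0)

    def test_shallow_samples_error_or_drop(self):
        cm = self.small_matrix()
        too_deep = int(cm.sample_totals().max())
        shallow = [s for s in cm.sample_ids
                   if cm.sample_totals()[s] < too_deep]
        with pytest.raises(FormatError, match=shallow[0]):
            rarefied_alpha(cm, depth=too_deep, iterations=2, seed=0)
        res = rarefied_alpha(cm, depth=too_deep, iterations=2, seed=0,
                             on_shallow="drop")
        assert set(res.table.index) == set(cm.sample_ids) - set(shallow)

    def test_result_independent_of_sample_order(self):
        cm = self.small_matrix()
        rev = CountMatrix(cm.df[cm.sample_ids[::-1]])
        a = rarefied_alpha(cm, depth=40, iterations=5, seed=4).table
        b = rarefied_alpha(rev, depth=40, iterations=5, seed=4).table
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_monte_carlo_sd_shrinks_with_iterations(self):
        cm = self.small_matrix()
        means = []
        for seed in range(8):
            res = rarefied_alpha(cm, depth=40, iterations=4, seed=seed)
            means.append(res.table["shannon_mean"].to_numpy())
        few = np.std(means, axis=0).mean()
        means = []
        for seed in range(8):
            res = rarefied_alpha(cm, depth=40, iterations=64, seed=seed)
            means.append(res.table["shannon_mean"].to_numpy())
        many = np.std(means, axis=0).mean()
        assert many < few  # 16x iterations -> ~4x smaller spread


class TestPairedTests:
    def test_identical_vectors_t_p_one(self):
        assert paired_test([1, 2, 3], [1, 2, 3], kind="t") == (0.0, 1.0)

    def test_constant_nonzero_differences_error(self):
        with pytest.raises(FormatError, match="sd = 0"):
            paired_test([1, 2, 3], [2, 3, 4], kind="t")

    def test_wilcoxon_all_zero_differences_error(self):
        with pytest.raises(FormatError, match="zero"):
            paired_test([1, 2], [1, 2], kind="wilcoxon")

    def test_t_matches_closed_form(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            a, b = rng.normal(size=n), rng.normal(size=n)
            stat, p = paired_test(a, b, kind="t")
            d = a - b
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p_ref = 2 * stats.t.sf(abs(t_ref), df=n - 1)
            assert stat == pytest.approx(t_ref, abs=1e-8)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_wilcoxon_matches_scipy(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=12), rng.normal(size=12)
        stat, p = paired_test(a, b, kind="wilcoxon")
        ref = stats.wilcoxon(a, b)
        assert (stat, p) == (ref.statistic, ref.pvalue)
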