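"""Community statistics against closed-form and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coreprof as cp
from coreprof.stats import StatsConfig, bh_adjust


class TestChao1:
    def test_no_singletons_equals_observed_richness(self):
        assert cp.chao1([3, 4, 5, 10]) == 4

    def test_formula_arithmetic(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert cp.chao1(counts) == pytest.approx(12.0)

    def test_incrementing_non_singleton_leaves_estimate(self):
        counts = [1, 1, 5, 7]
        bumped = [1, 1, 6, 7]
        assert cp.chao1(counts) == cp.chao1(bumped)

    def test_all_zero_sample_is_zero(self):
        assert cp.chao1([0, 0, 0]) == 0.0

    def test_matches_skbio(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        for _ in range(20):
            counts = rng.integers(0, 6, size=25)
            if counts.sum() == 0:
                continue
            assert cp.chao1(counts) == pytest.approx(
                float(skbio_alpha.chao1(counts, bias_corrected=True))
            )


class TestShannon:
    def test_uniform_is_log_n(self):
        for n in (2, 5, 17):
            assert cp.shannon([10] * n) == pytest.approx(np.log(n))

    def test_single_species_zero(self):
        assert cp.shannon([42]) == 0.0

    def test_direct_summation_oracle(self):
        counts = np.array([10, 10, 20])
        p = counts / counts.sum()
        assert cp.shannon(counts) == pytest.approx(float(-(p * np.log(p)).sum()))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cp.shannon([0, 0])

    def test_log2_base_option(self):
        assert cp.shannon([1, 1], base=2) == pytest.approx(1.0)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert cp.bray_curtis(m).loc["a", "b"] == 0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame([[5, 0], [0, 7]], index=["a", "b"])
        assert cp.bray_curtis(m).loc["a", "b"] == 1

    def test_matches_pairwise_oracle_and_symmetry(self, rng):
        x = rng.random((6, 10))
        dm = cp.bray_curtis(pd.DataFrame(x)).to_numpy()
        assert np.allclose(dm, dm.T, atol=1e-12)
        for i in range(6):
            for j in range(6):
                expected = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
                assert dm[i, j] == pytest.approx(expected)

    def test_all_zero_pair_warns_zero(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]])
        with pytest.warns(UserWarning, match="all-zero"):
            dm = cp.bray_curtis(m)
        assert dm.iloc[0, 1] == 0


class TestPermanova:
    def _clusters(self, rng, sep=4.0, n=8):
        a = rng.normal(0, 1, (n, 5))
        b = rng.normal(sep, 1, (n, 5))
        x = np.abs(np.vstack([a, b]))
        labels = ["g1"] * n + ["g2"] * n
        return cp.bray_curtis(pd.DataFrame(x)), labels

    def test_separated_clusters_minimal_p(self, rng):
        dm, labels = self._clusters(rng)
        cfg = StatsConfig(permutations=199, seed=1)
        f, p = cp.permanova(dm, labels, cfg)
        assert p == pytest.approx(1 / 200)
        assert f > 1

    def test_seeded_determinism(self, rng):
        dm, labels = self._clusters(rng, sep=0.5)
        cfg = StatsConfig(permutations=199, seed=5)
        assert cp.permanova(dm, labels, cfg) == cp.permanova(dm, labels, cfg)

    def test_pseudo_f_matches_skbio(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        dm, labels = self._clusters(rng, sep=1.0, n=6)
        f, _ = cp.permanova(dm, labels, StatsConfig(permutations=99, seed=0))
        sk = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(dm.to_numpy()), grouping=list(labels), permutations=9
        )
        assert f == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_singleton_group_rejected(self, rng):
        dm = cp.bray_curtis(pd.DataFrame(rng.random((4, 3))))
        with pytest.raises(ValueError, match=">= 2 samples"):
            cp.permanova(dm, ["a", "b", "b", "b"], StatsConfig(permutations=99))


class TestClr:
    def test_rows_sum_to_zero(self, rng):
        x = pd.DataFrame(rng.random((5, 8)))
        out = cp.clr_transform(x)
        assert np.allclose(out.sum(axis=1), 0, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=0.1, max_value=100),
        row=st.lists(st.floats(min_value=0.01, max_value=10), min_size=3, max_size=8),
    )
    def test_scale_invariance(self, scale, row):
        x = pd.DataFrame([row])
        a = cp.clr_transform(x)
        b = cp.clr_transform(x * scale)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_uniform_row_is_zero(self):
        out = cp.clr_transform(pd.DataFrame([[1.0, 1.0, 1.0, 1.0]]))
        assert np.allclose(out.to_numpy(), 0)

    def test_matches_skbio_on_positive_data(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x = rng.random((4, 6)) + 0.1
        ours = cp.clr_transform(pd.DataFrame(x)).to_numpy()
        theirs = skbio_comp.clr(x / x.sum(axis=1, keepdims=True))
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cp.clr_transform(pd.DataFrame([[-1.0, 2.0]]))


def step_up_bh(ps):
    """Independent BH step-up implementation for cross-checking."""
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    order = np.argsort(ps)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, ps[idx] * m / rank)
        q[idx] = prev
    return q


class TestGroupwiseMwu:
    def test_bh_hand_computation(self):
        ps = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(bh_adjust(ps), [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_independent_step_up(self, rng):
        ps = rng.random(40)
        assert np.allclose(bh_adjust(ps), step_up_bh(ps), atol=1e-12)

    def test_label_swap_flips_direction_keeps_p(self, rng):
        x = pd.DataFrame(rng.random((20, 4)))
        labels = pd.Series(["a"] * 10 + ["b"] * 10)
        res_ab = cp.groupwise_mwu(x, labels)
        res_ba = cp.groupwise_mwu(x, labels.map({"a": "b", "b": "a"}))
        for r1, r2 in zip(res_ab, res_ba):
            assert r1.p == pytest.approx(r2.p)
            if r1.direction != "none":
                assert r1.direction != r2.direction

    def test_constant_feature_p_one(self):
        x = pd.DataFrame({"c": [1.0] * 10, "v": np.arange(10.0)})
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        res = {r.feature: r for r in cp.groupwise_mwu(x, labels)}
        assert res["c"].p == 1.0

    def test_q_never_below_p(self, rng):
        x = pd.DataFrame(rng.random((16, 10)))
        labels = pd.Series(["a"] * 8 + ["b"] * 8)
        for r in cp.groupwise_mwu(x, labels):
            assert r.q >= r.p - 1e-12

    def test_null_calibration_rarely_rejects(self):
        # exchangeable groups: BH at q<0.05 yields zero rejections in >=48/50 seeds
        clean = 0
        for seed in range(50):
            tab, labels = cp.simulate_abundance_study(
                n_per_group=10, n_features=25, seed=seed
            )
            res = cp.groupwise_mwu(tab.relative, labels)
            clean += all(r.q >= 0.05 for r in res)
        assert clean >= 48


class TestLinearAssociation:
    def test_exact_linear_relation(self, rng):
        x = pd.Series(rng.random(12))
        y = pd.DataFrame({"f": 2 * x})
        out = cp.pairwise_linear_association(x, y)
        assert out.loc["f", "slope"] == pytest.approx(2.0)
        assert out.loc["f", "p"] < 1e-10

    def test_matches_closed_form_ols(self, rng):
        x = pd.Series(rng.random(15))
        y = pd.DataFrame(rng.random((15, 3)), columns=list("abc"))
        out = cp.pairwise_linear_association(x, y)
        xv = x.to_numpy()
        for col in "abc":
            yv = y[col].to_numpy()
            beta = np.cov(xv, yv, ddof=1)[0, 1] / np.var(xv, ddof=1)
            assert out.loc[col, "slope"] == pytest.approx(beta)

    def test_independent_null_rarely_significant(self):
        sig = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = pd.Series(r.random(20))
            y = pd.DataFrame(r.random((20, 5)))
            out = cp.pairwise_linear_association(x, y)
            sig += (out["q"] < 0.05).any()
        assert sig <= 10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            cp.pairwise_linear_association(pd.Series([1, 2]), pd.DataFrame({"a": [1, 2]}))


class TestTwoProportion:
    @pytest.mark.parametrize(
        "a,n1,expected",
        [(43, 91, 47.3), (11, 85, 12.9), (49, 91, 53.8)],
    )
    def test_cohort_percentages(self, a, n1, expected):
        res = cp.two_proportion_summary(a, n1, 1, 10)
        assert res.pct1 == expected

    def test_constipation_contrast_significant(self):
        res = cp.two_proportion_summary(43, 91, 11, 85)
        assert res.p < 0.001
        assert res.test == "chi2"

    def test_zero_margin_uses_fisher(self):
        res = cp.two_proportion_summary(0, 10, 0, 12)
        assert res.test == "fisher"
        assert res.p == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            cp.two_proportion_summary(11, 10, 1, 5)
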