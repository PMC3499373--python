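import numpy as np
import pytest
from scipy import stats

from starqt import rvtests
from starqt.rvtests import (
    burden_score,
    code_cmc,
    code_wss,
    kbac_qt_statistic,
    single_variant_score,
    skat_statistic,
    vt_statistic,
)

from conftest import make_matrix


class TestCodings:
    def test_cmc_carrier_indicator(self):
        G = make_matrix([[0, 2, 0], [0, 0, 0], [1, 1, 0]])
        x = code_cmc(G, 0.5).x
        assert list(x) == [1.0, 0.0, 1.0]

    def test_cmc_threshold_excludes_common_site(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:4, 0] = 1     # MAF 0.02: excluded at 1%
        counts[:1, 1] = 1     # MAF 0.005: retained
        G = make_matrix(counts)
        x = code_cmc(G, 0.01).x
        assert x.sum() == 1.0

    def test_cmc_no_qualifying_sites_errors(self):
        counts = np.zeros((10, 1), dtype=int)
        counts[:5, 0] = 2  # MAF 0.5
        G = make_matrix(counts)
        with pytest.raises(ValueError, match="MAF"):
            code_cmc(G, 0.01)

    def test_wss_weight_formula(self):
        # n=4, minor count 1: q=(1+1)/10=0.2, w = 1/sqrt(4*0.2*0.8) = 1.25
        counts = np.array([[1], [0], [0], [0]])
        G = make_matrix(counts)
        coding = code_wss(G, 0.5)
        assert coding.weights[0] == pytest.approx(1.25)
        assert coding.x[0] == pytest.approx(1.25)

    def test_wss_monomorphic_contributes_zero(self):
        counts = np.column_stack([np.zeros(8, dtype=int), [1, 0, 0, 0, 0, 0, 0, 0]])
        G = make_matrix(counts)
        coding = code_wss(G, 0.5)
        assert np.isfinite(coding.weights).all()
        # individual 0 carries the only allele; everyone else scores 0
        assert coding.x[1:].sum() == 0.0

    def test_wss_linear_in_counts_at_fixed_weights(self, rng):
        counts = rng.binomial(1, 0.1, (30, 4))
        w = rvtests.wss_weights(make_matrix(counts))
        assert np.allclose((2 * counts) @ w, 2 * (counts @ w))


class TestBurdenScore:
    def test_hand_example(self):
        # e=(1,-1,0), x=(1,0,1): U = sum e_i (x_i - 2/3) = 1/3 + 2/3 + 0 = 1
        assert burden_score(np.array([1.0, -1.0, 0.0]), np.array([1.0, 0.0, 1.0])) == pytest.approx(1.0)

    def test_zero_residuals(self):
        assert burden_score(np.zeros(5), np.arange(5.0)) == 0.0

    def test_relabeling_invariance(self, rng):
        e = rng.standard_normal(20)
        x = rng.binomial(2, 0.2, 20).astype(float)
        perm = rng.permutation(20)
        assert burden_score(e, x) == pytest.approx(burden_score(e[perm], x[perm]))

    def test_shift_invariance(self, rng):
        e = rng.standard_normal(20)
        x = rng.binomial(1, 0.3, 20).astype(float)
        assert burden_score(e + 7.0, x) == pytest.approx(burden_score(e, x))

    def test_constant_coding_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert burden_score(np.array([1.0, 2.0]), np.array([1.0, 1.0])) == 0.0


def brute_force_vt(e, G, maf_cap):
    """Independent threshold enumeration for the VT oracle."""
    maf = G.counts.mean(axis=0) / 2.0
    best, best_t = -np.inf, None
    for t in sorted(set(maf[(maf > 0) & (maf <= maf_cap)])):
        x = G.counts[:, (maf > 0) & (maf <= t)].sum(axis=1).astype(float)
        xc = x - x.mean()
        var = np.sum((e - e.mean()) ** 2) * np.sum(xc**2) / (len(e) - 1)
        z = 0.0 if var == 0 else abs(e @ xc) / np.sqrt(var)
        if z > best:
            best, best_t = z, t
    return best, best_t


class TestVT:
    def test_matches_brute_force(self, toy_region):
        G, e = toy_region
        t_max, thr = vt_statistic(e, G, 0.5)
        bf, bf_t = brute_force_vt(e, G, 0.5)
        assert t_max == pytest.approx(bf, abs=1e-12)
        assert thr == bf_t

    def test_single_threshold_equals_burden_z(self, rng):
        counts = rng.binomial(1, 0.05, (30, 2))
        counts[:, 1] = counts[:, 0]  # identical MAFs -> one distinct threshold
        G = make_matrix(counts)
        e = rng.standard_normal(30)
        t_max, _ = vt_statistic(e, G, 0.5)
        x = counts.sum(axis=1).astype(float)
        xc = x - x.mean()
        var = np.sum((e - e.mean()) ** 2) * np.sum(xc**2) / 29
        assert t_max == pytest.approx(abs(e @ xc) / np.sqrt(var))

    def test_max_property(self, toy_region):
        G, e = toy_region
        t_max, _ = vt_statistic(e, G, 0.5)
        maf = G.sample_maf()
        for t in np.unique(maf[maf > 0]):
            x = G.counts[:, (maf > 0) & (maf <= t)].sum(axis=1).astype(float)
            xc = x - x.mean()
            var = np.sum((e - e.mean()) ** 2) * np.sum(xc**2) / (len(e) - 1)
            z = 0.0 if var == 0 else abs(e @ xc) / np.sqrt(var)
            assert t_max >= z - 1e-12

    def test_cap_below_smallest_maf_errors(self, toy_region):
        G, e = toy_region
        with pytest.raises(ValueError, match="VT"):
            vt_statistic(e, G, maf_cap=1e-6)


class TestSKAT:
    def test_single_site_kernel(self):
        G = make_matrix([[1], [0]], mafs=[0.005])
        e = np.array([1.0, -1.0])
        # unit weight via direct double-sum check instead of the MB weight
        w = rvtests.skat_weights(G)[0]
        assert skat_statistic(e, G, maf_threshold=0.5) == pytest.approx(w * 1.0)

    def test_fast_form_equals_double_sum(self, rng):
        counts = rng.binomial(2, 0.04, (10, 4))
        counts[0, 0] = max(counts[0, 0], 1)  # ensure polymorphic
        G = make_matrix(counts)
        e = rng.standard_normal(10)
        maf = G.sample_maf()
        mask = (maf > 0) & (maf <= 0.5)
        w = rvtests.skat_weights(G)[mask]
        C = counts[:, mask].astype(float)
        K = C @ np.diag(w) @ C.T
        double_sum = e @ K @ e
        assert skat_statistic(e, G, maf_threshold=0.5) == pytest.approx(double_sum, abs=1e-12)

    def test_orthogonal_residuals_give_zero(self):
        counts = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        G = make_matrix(counts)
        e = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal to both columns
        assert skat_statistic(e, G, maf_threshold=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_beta_weight_option(self, toy_region):
        G, e = toy_region
        q_mb = skat_statistic(e, G, "madsen-browning", 0.5)
        q_beta = skat_statistic(e, G, "beta", 0.5)
        assert q_mb > 0 and q_beta > 0 and q_mb != q_beta


def brute_force_kbac(e, G, maf_threshold):
    """Dictionary-based genotype grouping, independent of the implementation."""
    maf = G.counts.mean(axis=0) / 2.0
    sub = G.counts[:, (maf > 0) & (maf <= maf_threshold)]
    groups = {}
    for i, row in enumerate(map(tuple, sub)):
        groups.setdefault(row, []).append(i)
    sigma = np.std(e, ddof=1)
    total = 0.0
    for geno, members in groups.items():
        if all(v == 0 for v in geno):
            continue
        ebar = float(np.mean([e[i] for i in members]))
        n_k = len(members)
        total += stats.norm.cdf(ebar * np.sqrt(n_k) / sigma) * n_k * ebar
    return total


class TestKBAC:
    def test_matches_brute_force(self, rng):
        counts = rng.binomial(2, 0.15, (12, 3))
        G = make_matrix(counts)
        e = rng.standard_normal(12)
        assert kbac_qt_statistic(e, G, 0.5) == pytest.approx(brute_force_kbac(e, G, 0.5), abs=1e-12)

    def test_symmetric_null_gives_zero(self):
        counts = np.array([[1], [1], [0], [0]])
        G = make_matrix(counts)
        e = np.array([1.0, -1.0, 2.0, -2.0])  # every group mean is exactly 0
        assert kbac_qt_statistic(e, G, 0.5) == 0.0

    def test_saturation_limit(self):
        # one carrier group with a huge positive mean: w -> 1, T -> n_k * ebar
        counts = np.array([[1], [1], [0], [0], [0]])
        e = np.array([10.0, 10.0, -0.1, 0.05, 0.05])
        G = make_matrix(counts)
        t = kbac_qt_statistic(e, G, 0.5)
        assert t == pytest.approx(2 * 10.0, rel=0.01)

    def test_single_genotype_group_warns(self):
        G = make_matrix(np.zeros((5, 2), dtype=int), mafs=[0.01, 0.01])
        with pytest.warns(UserWarning, match="one multi-site genotype"):
            assert kbac_qt_statistic(np.arange(5.0), G, 0.5) == 0.0


class TestSingleVariant:
    def test_equals_one_site_burden(self, rng):
        g = rng.binomial(2, 0.1, 25).astype(float)
        g[0] = 1
        e = rng.standard_normal(25)
        assert single_variant_score(e, g) == pytest.approx(burden_score(e, g))

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            single_variant_score(np.arange(4.0), np.zeros(4))

    def test_sign_flips_with_allele_coding(self, rng):
        g = rng.binomial(2, 0.2, 30).astype(float)
        g[0] = 1
        e = rng.standard_normal(30)
        assert single_variant_score(e, 2 - g) == pytest.approx(-single_variant_score(e, g))
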