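import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmakit import network as net
from tmakit.errors import DegenerateDataError

from conftest import make_table


def enumeration_p(x, y):
    """Independent oracle: two-sided Spearman p by brute-force permutation."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_perfect_concordance(self):
        e = net.spearman_edge([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert e.statistic == 1.0 and e.sign == 1
        assert abs(e.p_raw - 2 / 120) < 1e-15
        assert e.p_regime == "exact_enumeration"

    def test_perfect_discordance(self):
        e = net.spearman_edge([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert e.statistic == -1.0 and e.sign == -1

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            e = net.spearman_edge(x, y)
            assert e.p_regime == "exact_enumeration"
            assert abs(e.p_raw - enumeration_p(x, y)) < 1e-12

    def test_as89_regime_close_to_exact_null(self):
        # the exact S distribution (full n! enumeration via DP) bounds the
        # Edgeworth approximation error in the AS89 regime
        for n in (10, 11, 12):
            counts, total = net.exact_s_distribution(n)
            denom = n * (n * n - 1)
            for s in range(0, len(counts), 5):
                if counts[s] == 0:
                    continue
                rho = 1 - 6 * s / denom
                exact = net._spearman_exact_p(rho, n)
                as89 = net._spearman_as89_p(rho, n)
                assert abs(exact - as89) < 5e-3

    def test_dp_distribution_equals_brute_force(self):
        from collections import Counter

        n = 6
        counts, total = net.exact_s_distribution(n)
        brute = Counter(sum((p[i] - i) ** 2 for i in range(n))
                        for p in itertools.permutations(range(n)))
        assert total == 720
        assert all(counts[s] == brute.get(s, 0) for s in range(len(counts)))

    def test_ties_force_t_regime(self):
        e = net.spearman_edge([1, 1, 2, 3, 4, 5], [2, 3, 1, 5, 4, 6])
        assert e.p_regime == "t_approx"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        e1 = net.spearman_edge(x, y)
        e2 = net.spearman_edge(np.exp(x), y ** 3)
        assert e1.statistic == e2.statistic and e1.p_raw == e2.p_raw

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 15))
        a = net.spearman_edge(x, y)
        b = net.spearman_edge(y, x)
        assert a.statistic == b.statistic and a.p_raw == b.p_raw

    def test_missing_handled_pairwise(self):
        x = np.array([1, 2, 3, 4, 5, np.nan])
        y = np.array([1, 2, 3, 4, np.nan, 6])
        e = net.spearman_edge(x, y)
        assert e.n_used == 4

    def test_zero_variance_refused(self):
        with pytest.raises(DegenerateDataError):
            net.spearman_edge([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestPearson:
    def test_affine_dependence(self):
        x = np.arange(10.0)
        e = net.pearson_edge(x, 2 * x + 1)
        assert abs(e.statistic - 1.0) < 1e-12 and e.sign == 1

    def test_zero_correlation_p_one(self):
        # orthogonal vectors: r = 0 exactly, t = 0, p = 1
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.arange(10.0) - 4.5
        y = y - y.mean()
        y = y - (y @ x) / (x @ x) * x
        e = net.pearson_edge(x, y)
        assert abs(e.statistic) < 1e-12 and abs(e.p_raw - 1.0) < 1e-12

    def test_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(10)
        x, y = rng.normal(size=(2, 30))
        e = net.pearson_edge(x, y)
        ref_r, ref_p = pearsonr(x, y)
        assert abs(e.statistic - ref_r) < 1e-12
        assert abs(e.p_raw - ref_p) < 1e-9


class TestMI:
    def test_self_information_is_log_b(self):
        x = np.random.default_rng(11).normal(size=100)
        e = net.mi_edge(x, x, n_perm=50, seed=0)
        B = 10  # clamp(floor(sqrt(100)), 2, 10)
        assert abs(e.statistic - np.log(B)) < 1e-10
        assert e.sign == 0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 50))
        e1 = net.mi_edge(x, y, n_perm=200, seed=5)
        e2 = net.mi_edge(x, y, n_perm=200, seed=5)
        assert e1.p_raw == e2.p_raw and e1.statistic == e2.statistic

    def test_dependence_detected(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=150)
        y = x ** 2 + 0.1 * rng.normal(size=150)  # non-monotone dependence
        e = net.mi_edge(x, y, n_perm=200, seed=1)
        assert e.p_raw < 0.05

    def test_categorical_native_levels(self):
        rng = np.random.default_rng(14)
        x = rng.integers(0, 3, 60).astype(float)
        y = rng.normal(size=60)
        e = net.mi_edge(x, y, n_perm=50, seed=2, x_categorical=True)
        assert e.statistic >= 0

    def test_too_small_refused(self):
        with pytest.raises(DegenerateDataError):
            net.mi_edge([1, 2, 3, 4], [1, 2, 3, 4], n_perm=10, seed=0)


class TestAdjust:
    def test_by_hand_example(self):
        adj = net.adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="BY")
        np.testing.assert_allclose(adj, [0.04 * 25 / 12] * 4, atol=1e-12)

    def test_bonferroni(self):
        np.testing.assert_allclose(
            net.adjust_pvalues([0.01, 0.4, 0.9], method="bonferroni"),
            [0.03, 1.0, 1.0])

    def test_single_p_identity(self):
        for method in ("BY", "BH", "bonferroni"):
            np.testing.assert_allclose(
                net.adjust_pvalues([0.2], method=method), [0.2])

    def test_ordering_by_ge_bh_ge_raw(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            p = rng.random(rng.integers(2, 40))
            by = net.adjust_pvalues(p, "BY")
            bh = net.adjust_pvalues(p, "BH")
            assert np.all(by >= bh - 1e-15) and np.all(bh >= p - 1e-15)

    def test_matches_statsmodels_by(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(16)
        p = rng.random(30) ** 2
        ref = multipletests(p, method="fdr_by")[1]
        np.testing.assert_allclose(net.adjust_pvalues(p, "BY"), ref,
                                   atol=1e-12)

    def test_empty_list(self):
        assert net.adjust_pvalues([], "BY").size == 0

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0),
                    min_size=1, max_size=25))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_adjustment_ordering_property(self, p):
        """BY >= BH >= raw elementwise, all capped at 1, for any p-list."""
        p = np.asarray(p)
        by = net.adjust_pvalues(p, "BY")
        bh = net.adjust_pvalues(p, "BH")
        assert np.all(by >= bh - 1e-12)
        assert np.all(bh >= p - 1e-12)
        assert np.all(by <= 1.0) and np.all(bh <= 1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_spearman_symmetry_property(self, seed):
        """Swapping the two vectors never changes the statistic or p."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        x, y = rng.normal(size=(2, n))
        a = net.spearman_edge(x, y)
        b = net.spearman_edge(y, x)
        assert a.statistic == b.statistic
        assert a.p_raw == b.p_raw and a.p_regime == b.p_regime


class TestBuildNetwork:
    def planted_table(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        return make_table(np.column_stack([x, x + 1e-9 * rng.normal(size=n), z]),
                          columns=["x", "y", "z"])

    def test_planted_pair_found(self):
        netw = net.build_network(self.planted_table(), method="spearman")
        comps = {frozenset(c) for c in netw.components}
        assert frozenset({"x", "y"}) in comps
        assert frozenset({"z"}) in comps

    def test_alpha_one_keeps_all_pairs(self):
        netw = net.build_network(self.planted_table(), alpha=1.0)
        assert len(netw.edges) == 3

    def test_two_block_structure(self):
        rng = np.random.default_rng(20)
        M = 6
        corr = np.eye(M)
        for i, j in itertools.combinations(range(3), 2):
            corr[i, j] = corr[j, i] = 0.8
            corr[i + 3, j + 3] = corr[j + 3, i + 3] = 0.8
        vals = rng.multivariate_normal(np.zeros(M), corr, size=120)
        netw = net.build_network(make_table(vals), method="spearman")
        assert len(netw.components) == 2
        assert sum(len(c) for c in netw.components) == 6

    def test_edge_count_monotone_in_alpha(self):
        t = self.planted_table(seed=2)
        sizes = [len(net.build_network(t, alpha=a).edges)
                 for a in (0.001, 0.05, 0.5, 1.0)]
        assert sizes == sorted(sizes)

    def test_degenerate_pairs_excluded_from_m(self):
        rng = np.random.default_rng(3)
        vals = np.column_stack([rng.normal(size=50), rng.normal(size=50),
                                np.full(50, 7.0)])
        netw = net.build_network(make_table(vals, columns=["a", "b", "c"]))
        assert len(netw.degenerate) == 2
        assert len(netw.all_edges) == 1
        # m = 1, so the adjusted p equals the raw p
        assert netw.all_edges[0].p_adj == pytest.approx(
            netw.all_edges[0].p_raw)
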