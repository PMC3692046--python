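import numpy as np
import pytest

from tmakit import distribution as dist
from tmakit import io, survival
from tmakit.errors import DegenerateDataError


def random_censored(rng, n):
    t = rng.exponential(20.0, size=n).round(1)  # rounding forces ties
    e = (rng.random(n) < 0.7).astype(int)
    return t, e


class TestKM:
    def test_product_limit_arithmetic(self):
        c = survival.km_curve([5, 8, 12], [1, 0, 1])
        np.testing.assert_allclose(c.times, [5, 12])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])
        # censored at 8 reduced the risk set for the event at 12
        np.testing.assert_array_equal(c.at_risk, [3, 1])

    def test_all_events(self):
        c = survival.km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored(self):
        c = survival.km_curve([1, 2, 3], [0, 0, 0])
        assert c.times.size == 0
        np.testing.assert_allclose(c.survival_at([0.5, 5.0]), [1.0, 1.0])

    def test_negative_time_rejected(self):
        with pytest.raises(Exception):
            survival.km_curve([-1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_lifelines(self, seed):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(seed)
        t, e = random_censored(rng, 40)
        mine = survival.km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(mine.times).to_numpy()
        np.testing.assert_allclose(mine.survival, ref, atol=1e-10)


class TestLogRank:
    def test_identical_groups_null(self):
        t = [3, 5, 7, 9]
        e = [1, 1, 0, 1]
        r = survival.logrank_test(["A"] * 4 + ["B"] * 4, t + t, e + e)
        assert r.chi_square < 1e-10 and abs(r.p_raw - 1.0) < 1e-9

    def test_hand_computed_example(self):
        # A events at 1,2; B events at 3,4: chi2 = 49/17 ~ 2.882
        r = survival.logrank_test(["A", "A", "B", "B"], [1, 2, 3, 4],
                                  [1, 1, 1, 1])
        assert abs(r.chi_square - 49 / 17) < 1e-10
        assert r.df == 1

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        t, e = random_censored(rng, 30)
        g = rng.integers(0, 2, 30)
        r1 = survival.logrank_test(g, t, e)
        r2 = survival.logrank_test(1 - g, t, e)
        assert abs(r1.chi_square - r2.chi_square) < 1e-10

    def test_matches_normal_form_square(self):
        # 2-group chi-square equals the squared standard-normal form
        rng = np.random.default_rng(3)
        t, e = random_censored(rng, 50)
        g = rng.integers(0, 2, 50)
        r = survival.logrank_test(g, t, e)
        # independent accumulation of O-E and V for group 0
        o = ex = v = 0.0
        for et in np.unique(t[e == 1]):
            risk = t >= et
            n = risk.sum()
            d = np.sum((t == et) & (e == 1))
            n0 = np.sum(risk & (g == 0))
            o += np.sum((t == et) & (e == 1) & (g == 0))
            ex += d * n0 / n
            if n > 1:
                v += d * (n - d) / (n - 1) * (n0 / n) * (1 - n0 / n)
        assert abs(r.chi_square - (o - ex) ** 2 / v) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines_multigroup(self, seed):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(100 + seed)
        t, e = random_censored(rng, 60)
        g = rng.integers(0, 3, 60)
        r = survival.logrank_test(g, t, e)
        ref = multivariate_logrank_test(t, g, e)
        assert abs(r.chi_square - ref.test_statistic) < 1e-8
        assert abs(r.p_raw - ref.p_value) < 1e-10

    def test_degenerate_inputs_refused(self):
        with pytest.raises(DegenerateDataError):
            survival.logrank_test(["A"] * 4, [1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(DegenerateDataError, match="no events"):
            survival.logrank_test(["A", "A", "B", "B"], [1, 2, 3, 4],
                                  [0, 0, 0, 0])


class TestStratify:
    def test_tertiles_exact_thirds(self):
        labels = survival.stratify(np.arange(1.0, 10.0), "tertile")
        assert labels.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_categorical_levels(self):
        labels = survival.stratify(np.array([0.0, 0.0, 1.0, 2.0]), "categorical")
        assert labels.tolist() == [0, 0, 1, 2]

    def test_unimodal_mixture_refused_with_hint(self):
        x = np.random.default_rng(0).normal(size=50)
        model = dist.fit_gmm(x, K=1, seed=0)
        with pytest.raises(DegenerateDataError, match="tertile"):
            survival.stratify(x, "mixture", model=model)

    def test_mixture_mode_uses_map_labels(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        model = dist.fit_gmm(x, K=2, seed=0)
        labels = survival.stratify(x, "mixture", model=model)
        assert set(labels.tolist()) == {0, 1}
        assert labels[:50].mean() < 0.1 and labels[50:].mean() > 0.9

    def test_missing_unassigned(self):
        v = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        labels = survival.stratify(v, "tertile")
        assert labels[1] == dist.UNASSIGNED


class TestBH:
    def test_step_up_hand_example(self):
        adj = survival.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_test_identity(self):
        np.testing.assert_allclose(survival.bh_adjust([0.031]), [0.031])

    def test_order_invariant(self):
        rng = np.random.default_rng(4)
        p = rng.random(25)
        perm = rng.permutation(25)
        adj = survival.bh_adjust(p)
        adj_perm = survival.bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm, atol=1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(40) ** 2
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(survival.bh_adjust(p), ref, atol=1e-12)


class TestScreen:
    @pytest.fixture
    def linked(self, default_cohort):
        return io.attach_survival(io.collapse_replicates(default_cohort.markers),
                                  default_cohort.survival)

    def test_mixture_screen_finds_planted_marker(self, linked):
        screen = survival.survival_screen(linked, mode="mixture", seed=1,
                                          K_max=3, n_restarts=4)
        assert screen.results[0].marker == "M1"
        assert screen.results[0].p_fdr <= screen.results[-1].p_fdr
        skipped = {s["marker"] for s in screen.skipped}
        assert "M2" in skipped  # unimodal markers fall out of the BH universe

    def test_tertile_screen_tests_all_markers(self, linked):
        screen = survival.survival_screen(linked, mode="tertile")
        assert len(screen.results) == 9 and screen.skipped == []
        for r in screen.results:
            assert r.p_fdr >= r.p_raw - 1e-15

    def test_null_type_one_error(self):
        # group labels independent of survival: ~5% of markers significant
        rng = np.random.default_rng(77)
        rejections = 0
        total = 0
        for _ in range(40):
            t = rng.exponential(20, 60)
            e = (rng.random(60) < 0.7).astype(int)
            g = rng.integers(0, 2, 60)
            r = survival.logrank_test(g, t, e)
            rejections += r.p_raw < 0.05
            total += 1
        assert rejections / total < 0.15
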