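import itertools

import numpy as np
import pytest
from scipy import stats

from crossnorm import (
    PValueList,
    QValueList,
    ValidationError,
    brown_forsythe,
    combine_qlists,
    detection_areas,
    mean_mean_r2,
    qvalues,
    rank_methods,
    roc_like_curve,
    welch_pvalues,
)
from crossnorm.core import ExpressionMatrix
from crossnorm.evaluation import estimate_pi0
from conftest import make_dataset


def qlist(values, pi0=1.0):
    values = np.asarray(values, dtype=float)
    return QValueList([f"g{i}" for i in range(values.size)], values, pi0=pi0)


class TestMeanMeanR2:
    def test_identical_means_give_one(self, rng):
        v = rng.normal(5, 1, size=(50, 3))
        d = make_dataset(v, v.copy())
        assert mean_mean_r2(d, "A").r2 == pytest.approx(1.0)

    def test_affine_transform_gives_one(self, rng):
        v = rng.normal(5, 1, size=(50, 3))
        d = make_dataset(v, 2.0 * v + 3.0)
        assert mean_mean_r2(d, "A").r2 == pytest.approx(1.0)
        # the concordance correlation coefficient penalizes the same offset
        ccc = mean_mean_r2(d, "A", with_ccc=True).ccc
        assert ccc < 0.9

    def test_independent_platforms_near_zero(self):
        rng = np.random.default_rng(8)
        d = make_dataset(rng.normal(0, 1, size=(1000, 3)),
                         rng.normal(0, 1, size=(1000, 3)))
        assert mean_mean_r2(d, "A").r2 < 0.01

    def test_symmetric_in_platforms(self, small_linear):
        d, _ = small_linear
        swapped = make_dataset(d.platform2.values, d.platform1.values,
                               ["A"] * 4 + ["B"] * 4, ["A"] * 4 + ["B"] * 4)
        assert mean_mean_r2(d, "A").r2 == pytest.approx(
            mean_mean_r2(swapped, "A").r2
        )

    def test_group_on_one_platform_only(self):
        d = make_dataset([[1.0, 2.0]], [[3.0, 4.0]],
                         ["A", "A"], ["B", "B"])
        with pytest.raises(ValidationError, match="concordance undefined"):
            mean_mean_r2(d, "A")


class TestWelch:
    def test_identical_groups_p_one(self):
        m = ExpressionMatrix(
            ["g0"], ["a1", "a2", "b1", "b2"],
            np.array([[1.0, 2.0, 1.0, 2.0]]),
        )
        p = welch_pvalues(m, ["a1", "a2"], ["b1", "b2"])
        assert p.p[0] == pytest.approx(1.0)

    def test_power_on_strong_shift(self):
        rng = np.random.default_rng(15)
        G = 100
        a = rng.normal(0, 1, size=(G, 10))
        b = rng.normal(3, 1, size=(G, 10))
        ids = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        m = ExpressionMatrix([f"g{i}" for i in range(G)], ids, np.hstack([a, b]))
        p = welch_pvalues(m, ids[:10], ids[10:])
        assert (p.p < 0.01).sum() >= 95

    def test_null_uniformity(self):
        rng = np.random.default_rng(16)
        G = 10000
        x = rng.normal(0, 1, size=(G, 12))
        ids = [f"s{i}" for i in range(12)]
        m = ExpressionMatrix([f"g{i}" for i in range(G)], ids, x)
        p = welch_pvalues(m, ids[:6], ids[6:])
        ks = stats.kstest(p.p, "uniform").statistic
        assert ks < 0.02

    def test_zero_variance_conventions(self):
        m = ExpressionMatrix(
            ["equal", "unequal"],
            ["a1", "a2", "b1", "b2"],
            np.array([[2.0, 2.0, 2.0, 2.0], [1.0, 1.0, 5.0, 5.0]]),
        )
        p = welch_pvalues(m, ["a1", "a2"], ["b1", "b2"])
        assert p.p[0] == 1.0
        assert p.p[1] == 0.0

    def test_small_group_rejected(self):
        m = ExpressionMatrix(["g0"], ["a1", "b1", "b2"],
                             np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValidationError, match="at least 2"):
            welch_pvalues(m, ["a1"], ["b1", "b2"])


def brute_force_qvalues(p, pi0):
    """q_i = min over j with p_j >= p_i of pi0 * G * p_(j) / rank(j)."""
    p = np.asarray(p, dtype=float)
    G = p.size
    order = np.argsort(p)
    ps = p[order]
    q = np.empty(G)
    for i in range(G):
        q[i] = min(pi0 * G * ps[j] / (j + 1) for j in range(i, G))
    out = np.empty(G)
    out[order] = np.minimum(q, 1.0)
    return out


class TestQValues:
    def test_all_ones(self):
        p = PValueList(["g0", "g1"], np.array([1.0, 1.0]))
        q = qvalues(p)
        assert q.pi0 == 1.0
        np.testing.assert_array_equal(q.q, [1.0, 1.0])

    def test_step_down_hand_example(self):
        p = PValueList(["g0", "g1", "g2"], np.array([0.001, 0.01, 0.5]))
        q = qvalues(p, pi0=1.0)
        np.testing.assert_allclose(q.q, [0.003, 0.015, 0.5])

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            p_raw = rng.uniform(0, 1, size=20)
            p = PValueList([f"g{i}" for i in range(20)], p_raw)
            q = qvalues(p, pi0=0.8)
            np.testing.assert_allclose(q.q, brute_force_qvalues(p_raw, 0.8),
                                       atol=1e-12)

    def test_null_pi0_near_one(self):
        rng = np.random.default_rng(77)
        p_raw = rng.uniform(0, 1, size=10000)
        assert 0.9 <= estimate_pi0(p_raw) <= 1.0

    def test_monotone_in_p_order(self, rng):
        p_raw = rng.uniform(0, 1, size=200)
        q = qvalues(PValueList([f"g{i}" for i in range(200)], p_raw))
        order = np.argsort(p_raw)
        assert np.all(np.diff(q.q[order]) >= -1e-15)


class TestRocCurve:
    def test_all_zero_q(self):
        c = roc_like_curve(qlist([0.0, 0.0]))
        assert np.all(c.height == 1.0)

    def test_two_gene_steps(self):
        c = roc_like_curve(qlist([0.25, 0.75]))
        grid = c.grid
        np.testing.assert_allclose(c.height[grid < 0.25], 0.0)
        np.testing.assert_allclose(
            c.height[(grid >= 0.25) & (grid < 0.75)], 0.5
        )
        np.testing.assert_allclose(c.height[grid >= 0.75], 1.0)

    def test_non_decreasing(self, rng):
        c = roc_like_curve(qlist(rng.uniform(0, 1, size=100)))
        assert np.all(np.diff(c.height) >= 0)
        assert c.grid[1] - c.grid[0] == pytest.approx(0.001)


class TestCombine:
    def test_identical_lists(self):
        q = qlist([0.1, 0.9])
        for mode in ("union", "intersection"):
            np.testing.assert_array_equal(combine_qlists(q, q, mode).q, q.q)

    def test_min_max_semantics(self):
        q1, q2 = qlist([0.1, 0.9]), qlist([0.5, 0.2])
        np.testing.assert_array_equal(combine_qlists(q1, q2, "union").q,
                                      [0.1, 0.2])
        np.testing.assert_array_equal(combine_qlists(q1, q2, "intersection").q,
                                      [0.5, 0.9])

    def test_bounds(self, rng):
        q1 = qlist(rng.uniform(0, 1, size=50))
        q2 = qlist(rng.uniform(0, 1, size=50))
        u = combine_qlists(q1, q2, "union").q
        i = combine_qlists(q1, q2, "intersection").q
        assert np.all(u <= q1.q) and np.all(u <= q2.q)
        assert np.all(i >= q1.q) and np.all(i >= q2.q)

    def test_mismatched_genes(self):
        q1 = qlist([0.1])
        q2 = QValueList(["other"], np.array([0.2]), 1.0)
        with pytest.raises(ValidationError, match="gene list"):
            combine_qlists(q1, q2, "union")


class TestDetectionAreas:
    def test_identical_lists_zero_areas(self, rng):
        q = qlist(rng.uniform(0, 1, size=30))
        areas = detection_areas(q, q, q)
        assert areas.o == 0.0 and areas.u == 0.0

    def test_empty_detection(self, rng):
        qn1 = qlist(rng.uniform(0, 1, size=30))
        qn2 = qlist(rng.uniform(0, 1, size=30))
        q_cross = qlist(np.ones(30))
        areas = detection_areas(q_cross, qn1, qn2)
        assert areas.o == 0.0
        q_i = np.maximum(qn1.q, qn2.q)
        grid = np.linspace(0, 1, 1001)
        h_i = np.searchsorted(np.sort(q_i), grid, side="right") / 30
        # the q=1 genes still count as "detected" at threshold 1 for both
        # curves, so u is the native-intersection area above the cross curve
        h_cross = (grid >= 1.0).astype(float)
        expected_u = np.trapezoid(h_i - np.minimum(h_i, h_cross), grid)
        assert areas.u == pytest.approx(expected_u)

    def test_nonnegative_always(self, rng):
        for _ in range(20):
            qs = [qlist(rng.uniform(0, 1, size=25)) for _ in range(3)]
            areas = detection_areas(*qs)
            assert areas.o >= 0 and areas.u >= 0

    def test_coarse_grid_matches_fine_grid(self, rng):
        for _ in range(10):
            qs = [qlist(rng.uniform(0, 1, size=40)) for _ in range(3)]
            coarse = detection_areas(*qs, step=0.001)
            fine = detection_areas(*qs, step=1e-5)
            assert coarse.o == pytest.approx(fine.o, abs=2e-3)
            assert coarse.u == pytest.approx(fine.u, abs=2e-3)

    def test_two_gene_hand_case(self):
        # cross detects g0 early; natives detect g0 at 0.3/0.4 and g1 never
        q_cross = qlist([0.1, 1.0])
        qn1 = qlist([0.3, 1.0])
        qn2 = qlist([0.4, 1.0])
        # union q = (0.3, 1.0); cross-and-union heights rise at 0.3
        # o = area between step at 0.1 and step at 0.3 for half the genes
        areas = detection_areas(q_cross, qn1, qn2)
        assert areas.o == pytest.approx(0.5 * (0.3 - 0.1), abs=2e-3)
        # intersection q = (0.4, 1.0); cross max intersection rises at 0.4
        # => u = 0 (cross found g0 before the natives agreed)
        assert areas.u == pytest.approx(0.0, abs=1e-12)


class TestBrownForsythe:
    def test_identical_groups_zero_statistic(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        stat, _ = brown_forsythe([g, g.copy()])
        assert stat == pytest.approx(0.0)

    def test_calibration_under_null(self):
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(100):
            groups = [rng.normal(0, 1, size=50) for _ in range(2)]
            _, p = brown_forsythe(groups)
            rejections += p < 0.05
        assert rejections <= 10

    def test_power_on_variance_ratio(self):
        rng = np.random.default_rng(22)
        _, p = brown_forsythe([rng.normal(0, 1, size=50),
                               rng.normal(0, 4, size=50)])
        assert p < 0.01

    def test_degenerate_group(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            brown_forsythe([np.array([1.0]), np.array([1.0, 2.0])])


def exact_mannwhitney_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    total = 0
    extreme = 0
    mu = n * len(y) / 2
    for comb in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


class TestRankMethods:
    def test_non_overlapping_distributions(self):
        r = rank_methods({"lo": np.arange(10.0), "hi": np.arange(10.0) + 100})
        assert r.ordered == ["lo", "hi"]
        assert r.marks == ["<"]

    def test_identical_distributions(self):
        vals = np.arange(10.0)
        r = rank_methods({"a": vals, "b": vals.copy()})
        assert r.marks == [","]

    def test_against_exact_enumeration(self):
        rng = np.random.default_rng(30)
        x = rng.normal(0, 1, size=8)
        y = rng.normal(0.8, 1, size=8)
        z = rng.normal(5.0, 1, size=8)
        r = rank_methods({"x": x, "y": y, "z": z}, alpha_base=0.05)
        alpha = 0.05 / 9
        named = dict(x=x, y=y, z=z)
        for (a, b), mark in zip(zip(r.ordered, r.ordered[1:]), r.marks):
            p_exact = exact_mannwhitney_p(named[a], named[b])
            assert (p_exact < alpha) == (mark == "<")

    def test_render(self):
        r = rank_methods({"lo": np.arange(10.0), "hi": np.arange(10.0) + 100})
        assert r.render() == "lo < hi"
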