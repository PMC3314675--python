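import numpy as np
import pytest
from scipy.optimize import minimize

from crossnorm import (
    SyntheticConfig,
    ValidationError,
    dwd_normalize,
    scramble_shift,
    shift_correlation,
    simulate_linear,
    solve_dwd,
    transfer_shift,
)
from crossnorm.dwd import DWDShift, auto_penalty, dwd_objective
from conftest import make_dataset


def slsqp_reference(points, labels, C):
    """Independent solve of the raw DWD program (w, beta, xi variables)."""
    n, p = points.shape

    def obj(z):
        w, beta, xi = z[:p], z[p], z[p + 1:]
        r = labels * (points @ w + beta) + xi
        return np.sum(1.0 / r) + C * np.sum(xi)

    cons = [
        {"type": "ineq", "fun": lambda z: 1.0 - z[:p] @ z[:p]},
        {"type": "ineq",
         "fun": lambda z: labels * (points @ z[:p] + z[p]) + z[p + 1:] - 1e-9},
        {"type": "ineq", "fun": lambda z: z[p + 1:]},
    ]
    w0 = points[labels > 0].mean(axis=0) - points[labels < 0].mean(axis=0)
    w0 = w0 / np.linalg.norm(w0) * 0.5
    z0 = np.concatenate([w0, [0.0], np.full(n, 1.0)])
    res = minimize(obj, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-12})
    assert res.success
    return res


class TestSolveDWD:
    def test_symmetric_axis_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.zeros((20, 10))
        pts[:10, 0] = 1.0
        pts[10:, 0] = -1.0
        labels = np.array([1.0] * 10 + [-1.0] * 10)
        model = solve_dwd(pts, labels, C=1.0)
        cos = abs(model.w[0]) / np.linalg.norm(model.w)
        assert cos > 0.99
        assert abs(model.beta) < 1e-6

    def test_duplicating_samples_leaves_w(self, rng):
        pts = rng.normal(0, 1, size=(12, 5))
        pts[:6] += 2.0
        labels = np.array([1.0] * 6 + [-1.0] * 6)
        m1 = solve_dwd(pts, labels, C=2.0)
        m2 = solve_dwd(np.vstack([pts, pts]), np.concatenate([labels, labels]),
                       C=2.0)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-5)

    def test_objective_matches_independent_solver(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([
            rng.normal([2.0, 0.0], 0.5, size=(8, 2)),
            rng.normal([-2.0, 0.0], 0.5, size=(8, 2)),
        ])
        labels = np.array([1.0] * 8 + [-1.0] * 8)
        C = auto_penalty(pts, labels)
        model = solve_dwd(pts, labels, C=C)
        margins = model.margins(pts, labels)
        assert np.all(margins > 0)
        ref = slsqp_reference(pts, labels, C)
        assert model.objective == pytest.approx(ref.fun, abs=1e-4)

    def test_returned_solution_beats_random_feasible_points(self, rng):
        pts = rng.normal(0, 1, size=(14, 4))
        pts[:7] += 1.5
        labels = np.array([1.0] * 7 + [-1.0] * 7)
        model = solve_dwd(pts, labels, C=5.0)
        for _ in range(100):
            w = rng.normal(0, 1, size=4)
            w /= max(np.linalg.norm(w), 1.0) * (1 + rng.uniform(0, 1))
            beta = rng.normal(0, 2)
            assert model.objective <= dwd_objective(pts, labels, 5.0, w, beta) + 1e-6

    def test_single_class_rejected(self, rng):
        pts = rng.normal(0, 1, size=(6, 3))
        with pytest.raises(ValidationError, match="both classes"):
            solve_dwd(pts, np.ones(6), C=1.0)


class TestDWDNormalize:
    def test_projected_platform_means_zero(self, small_linear):
        # after adjustment, both platforms' mean deviations from the pooled
        # gene means project to zero on the DWD direction
        d, _ = small_linear
        adjusted, shift = dwd_normalize(d)
        eta1 = shift.eta[sorted(shift.eta)[0]]
        w_unit = eta1 / np.linalg.norm(eta1)
        pooled = adjusted.merged().values.mean(axis=1)
        for m in (adjusted.platform1, adjusted.platform2):
            assert abs(w_unit @ (m.values.mean(axis=1) - pooled)) < 1e-6

    def test_within_platform_differences_untouched(self, small_linear):
        d, _ = small_linear
        adjusted, _ = dwd_normalize(d)
        before = d.platform1.values[:, 0] - d.platform1.values[:, 1]
        after = adjusted.platform1.values[:, 0] - adjusted.platform1.values[:, 1]
        # identical up to float rounding of the per-sample subtraction
        np.testing.assert_allclose(after, before, rtol=0, atol=1e-12)

    def test_identical_platforms_small_shift(self, rng):
        base = rng.normal(5, 1, size=(150, 16))
        d = make_dataset(base[:, :8], base[:, 8:])
        _, shift = dwd_normalize(d)
        for v in shift.eta.values():
            assert np.linalg.norm(v) < np.linalg.norm(base.std(axis=1))

    def test_rerun_contracts_shift(self, small_linear):
        # one pass removes the platform separation along the DWD direction;
        # a rerun finds only the residual orthogonal component, which is an
        # order of magnitude smaller (exact annihilation is impossible on
        # noisy data since the direction is not the mean-difference axis)
        d, _ = small_linear
        adjusted, shift1 = dwd_normalize(d)
        _, shift2 = dwd_normalize(adjusted)
        for lab in shift1.eta:
            assert (np.linalg.norm(shift2.eta[lab])
                    <= 0.1 * np.linalg.norm(shift1.eta[lab]))

    def test_location_shift_recovered(self):
        # pure per-gene location platform effect: eta2 - eta1 should track it
        cfg = SyntheticConfig(
            n_genes=500, n_per_group=15, seed=3, de_fraction=0.0,
            platform_shift_mean=0.0, platform_shift_sd=1.0,
            interaction_fraction=0.0, noise_sd=0.1,
        )
        d, truth = simulate_linear(cfg)
        _, shift = dwd_normalize(d)
        labs = sorted(shift.eta)
        est = shift.eta[labs[1]] - shift.eta[labs[0]]
        true_shift = truth.P[:, 1] - truth.P[:, 0]
        r = np.corrcoef(est, true_shift)[0, 1]
        assert abs(r) > 0.9


class TestShiftOps:
    def make_shift(self, rng, n=100):
        eta = {"pa": rng.normal(0, 1, size=n), "pb": rng.normal(0, 1, size=n)}
        return DWDShift([f"g{i}" for i in range(n)], eta)

    def test_self_transfer_equals_normalize(self, small_linear):
        d, _ = small_linear
        adjusted, shift = dwd_normalize(d)
        via_transfer = transfer_shift(shift, d)
        np.testing.assert_allclose(
            via_transfer.merged().values, adjusted.merged().values, atol=1e-12
        )

    def test_zero_shift_identity(self, small_linear):
        d, _ = small_linear
        lab1, lab2 = d.platform_labels
        zero = DWDShift(list(d.gene_ids),
                        {lab1: np.zeros(d.n_genes), lab2: np.zeros(d.n_genes)})
        out = transfer_shift(zero, d)
        np.testing.assert_array_equal(out.merged().values, d.merged().values)

    def test_matched_effect_transfer(self):
        # two studies with identical platform effects: a shift trained on one
        # removes most of the other's platform gap
        cfg1 = SyntheticConfig(n_genes=400, n_per_group=15, seed=5,
                               de_fraction=0.0, platform_shift_sd=1.0,
                               interaction_fraction=0.0, noise_sd=0.1)
        d1, truth = simulate_linear(cfg1)
        # study 2: same effects (truth), fresh replicate noise
        rng2 = np.random.default_rng(99)
        n = cfg1.n_per_group * cfg1.m
        v = []
        for pj in range(2):
            mean = np.repeat(truth.T[:, :, None], cfg1.n_per_group, axis=2)
            mean = mean + truth.P[:, pj, None, None] + truth.C[:, :, pj, None]
            cols = mean.reshape(cfg1.n_genes, n)
            v.append(cols + rng2.normal(0, cfg1.noise_sd, size=cols.shape))
        treat = [t for t in cfg1.treatments for _ in range(cfg1.n_per_group)]
        d2 = make_dataset(v[0], v[1], treat, treat)
        _, shift = dwd_normalize(d1)
        shift = DWDShift(  # rekey onto the second study's platform/gene labels
            [f"g{i}" for i in range(cfg1.n_genes)],
            {"p1": shift.eta["platform1"], "p2": shift.eta["platform2"]},
        )
        out = transfer_shift(shift, d2)
        gap_before = np.abs(d2.platform1.values.mean(axis=1)
                            - d2.platform2.values.mean(axis=1)).mean()
        gap_after = np.abs(out.platform1.values.mean(axis=1)
                           - out.platform2.values.mean(axis=1)).mean()
        assert gap_after <= 0.10 * gap_before

    def test_scramble_preserves_norm(self, rng):
        shift = self.make_shift(rng)
        scr = scramble_shift(shift, seed=9)
        for lab in shift.eta:
            assert np.linalg.norm(scr.eta[lab]) == pytest.approx(
                np.linalg.norm(shift.eta[lab])
            )

    def test_scramble_constant_is_identity(self):
        shift = DWDShift(["g0", "g1", "g2"],
                         {"pa": np.full(3, 2.5), "pb": np.full(3, -1.0)})
        scr = scramble_shift(shift, seed=0)
        np.testing.assert_array_equal(scr.eta["pa"], shift.eta["pa"])

    def test_scramble_deterministic(self, rng):
        shift = self.make_shift(rng)
        a = scramble_shift(shift, seed=4)
        b = scramble_shift(shift, seed=4)
        for lab in shift.eta:
            np.testing.assert_array_equal(a.eta[lab], b.eta[lab])

    def test_shift_correlation_extremes(self, rng):
        shift = self.make_shift(rng)
        assert shift_correlation(shift, shift) == pytest.approx(1.0)
        neg = DWDShift(list(shift.gene_ids),
                       {k: -v for k, v in shift.eta.items()})
        assert shift_correlation(shift, neg) == pytest.approx(-1.0)

    def test_independent_shifts_uncorrelated(self):
        rng = np.random.default_rng(2)
        a = self.make_shift(rng, n=1000)
        b = self.make_shift(rng, n=1000)
        assert abs(shift_correlation(a, b)) < 0.1

    def test_round_trip_tsv(self, tmp_path, rng):
        shift = self.make_shift(rng)
        shift.provenance["trained_on"] = "unit-test"
        path = tmp_path / "shift.tsv"
        shift.to_tsv(path)
        back = DWDShift.from_tsv(path)
        assert back.gene_ids == shift.gene_ids
        assert back.provenance["trained_on"] == "unit-test"
        for lab in shift.eta:
            np.testing.assert_allclose(back.eta[lab], shift.eta[lab], atol=1e-12)
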