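"""Predictive-potential criteria vs independent brute-force references."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracle as oracle
from cwqsar.stats import (
    TrainingContext,
    UndefinedStatisticError,
    ccc,
    full_report,
    golbraikh_tropsha,
    iic,
    loo_q2,
    pearson_r,
    q2_family,
    rm2_metrics,
    through_origin,
)


class TestPearson:
    def test_identity_and_negation(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [0, 1, 2])


class TestCcc:
    def test_identity(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_value_with_shift(self):
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0)

    def test_shift_penalty_keeps_ccc_below_r(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + 0.5  # pure shift: r = 1, CCC < 1
        assert abs(ccc(x, y)) < abs(pearson_r(x, y))


class TestThroughOrigin:
    def test_identity(self):
        k, kp, r0, r0p = through_origin([1, 2, 3], [1, 2, 3])
        assert (k, kp) == (1.0, 1.0)
        assert r0 == pytest.approx(1.0)
        assert r0p == pytest.approx(1.0)

    def test_exact_proportionality_slopes(self):
        y = np.array([1.0, 2.0, 3.0])
        k, kp, r0, r0p = through_origin(y, 2 * y)
        assert k == pytest.approx(0.5)
        assert kp == pytest.approx(2.0)
        assert r0 == pytest.approx(1.0)
        assert r0p == pytest.approx(1.0)

    def test_hand_oracle(self):
        y, yt = [1.0, 2.0, 3.0], [1.1, 1.9, 3.2]
        got = through_origin(y, yt)
        want = oracle.through_origin(y, yt)
        assert got == pytest.approx(want, abs=1e-12)


class TestQ2Family:
    def test_perfect_predictions(self):
        ctx = TrainingContext.from_endpoints([0.0, 1.0, 2.0])
        vals = q2_family([0, 1, 2], [0, 1, 2], ctx)
        assert vals == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_f1_equals_f2_when_means_coincide(self):
        y = [0.0, 1.0, 2.0]
        ctx = TrainingContext(mean=float(np.mean(y)), n=3, variance=1.0)
        q2, f1, f2, f3 = q2_family(y, [0.2, 1.1, 1.7], ctx)
        assert f1 == pytest.approx(f2)

    def test_hand_oracle(self):
        obs, pred = [0.0, 1.0, 2.0], [0.0, 1.0, 4.0]
        ctx = TrainingContext.from_endpoints([0.0, 1.0, 2.0])
        got = q2_family(obs, pred, ctx)
        want = oracle.q2_family(obs, pred, ctx.mean, ctx.variance)
        assert got == pytest.approx(want, abs=1e-12)

    def test_absent_without_context(self):
        q2, f1, f2, f3 = q2_family([0, 1, 2], [0, 1, 4])
        assert f1 is None and f3 is None
        assert q2 == f2


class TestRm2:
    def test_perfect(self):
        avg, delta = rm2_metrics([1, 2, 3], [1, 2, 3])
        assert avg == pytest.approx(1.0)
        assert delta == pytest.approx(0.0)

    def test_sqrt_variant_hand_value(self):
        # r2=0.81, r0_sq=0.77 -> rm2 = 0.81*(1-0.2) = 0.648 in one direction
        r2, r0 = 0.81, 0.77
        assert r2 * (1 - np.sqrt(abs(r2 - r0))) == pytest.approx(0.648)

    def test_variants_agree_at_zero_gap(self):
        # at r^2 == r0^2 both variants reduce to r^2
        y = np.array([1.0, 2.0, 3.0, 4.0])
        avg_s, _ = rm2_metrics(y, y, sqrt_form=True)
        avg_l, _ = rm2_metrics(y, y, sqrt_form=False)
        assert avg_s == pytest.approx(avg_l) == pytest.approx(1.0)

    def test_hand_oracle_both_variants(self):
        y, yt = [0.5, 1.7, 2.1, 3.9], [0.7, 1.5, 2.6, 3.5]
        for form in (True, False):
            got = rm2_metrics(y, yt, sqrt_form=form)
            want = oracle.rm2(y, yt, sqrt_form=form)
            assert got == pytest.approx(want, abs=1e-12)


class TestIic:
    def test_symmetric_residuals_give_r(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        calc = obs + np.array([0.1, -0.1, 0.1, -0.1])
        r = pearson_r(obs, calc)
        assert iic(obs, calc, r) == pytest.approx(r)

    def test_one_sided_residuals_give_zero(self):
        obs = [0.0, 1.0, 2.0]
        calc = [-0.5, 0.5, 1.5]  # all residuals positive
        assert iic(obs, calc, 0.99) == 0.0

    def test_hand_value(self):
        obs = [0.0, 1.0, 2.0, 3.0]
        calc = [0.1, 0.9, 2.2, 2.9]
        # MAE- = 0.15 (residuals -0.1, -0.2), MAE+ = 0.1 -> ratio 2/3
        assert iic(obs, calc, 1.0) == pytest.approx(2.0 / 3.0)


class TestBruteForceAgreement:
    def test_all_statistics_match_oracle_on_random_instances(self):
        """1e-12 agreement with naive-loop implementations, 100 instances."""
        rng = np.random.default_rng(20240101)
        ctxs = 0
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(loc=rng.uniform(-2, 2), scale=rng.uniform(0.5, 3), size=n)
            y = x + rng.normal(scale=rng.uniform(0.05, 1.0), size=n)
            xl, yl = x.tolist(), y.tolist()
            assert pearson_r(x, y) == pytest.approx(oracle.pearson(xl, yl), abs=1e-12)
            assert ccc(x, y) == pytest.approx(oracle.ccc(xl, yl), abs=1e-12)
            assert through_origin(x, y) == pytest.approx(
                oracle.through_origin(xl, yl), abs=1e-12
            )
            tr = rng.normal(size=max(n, 5))
            ctx = TrainingContext.from_endpoints(tr)
            assert q2_family(x, y, ctx) == pytest.approx(
                oracle.q2_family(xl, yl, ctx.mean, ctx.variance), abs=1e-12
            )
            # the printed rm^2 formula (no square root) is well-conditioned
            assert rm2_metrics(x, y, sqrt_form=False) == pytest.approx(
                oracle.rm2(xl, yl, sqrt_form=False), abs=1e-12
            )
            # the sqrt variant amplifies roundoff near r^2 == r0^2
            assert rm2_metrics(x, y, sqrt_form=True) == pytest.approx(
                oracle.rm2(xl, yl, sqrt_form=True), abs=1e-9
            )
            r = pearson_r(x, y)
            assert iic(x, y, r) == pytest.approx(oracle.iic(xl, yl, r), abs=1e-12)
            ctxs += 1
        assert ctxs == 100

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_ccc_bounded_by_r(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert abs(ccc(x, y)) <= abs(pearson_r(x, y)) + 1e-12


class TestLooQ2:
    def test_matches_explicit_leave_one_out(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        y = 2.0 + 0.5 * x + rng.normal(scale=0.2, size=15)
        press = 0.0
        for i in range(15):
            mask = np.arange(15) != i
            c1, c0 = np.polyfit(x[mask], y[mask], 1)
            press += (y[i] - (c0 + c1 * x[i])) ** 2
        expected = 1.0 - press / ((y - y.mean()) ** 2).sum()
        assert loo_q2(x, y) == pytest.approx(expected, abs=1e-10)


class TestFullReport:
    def test_identity_predictions_ideal_everywhere(self):
        y = [0.0, 1.0, 2.0, 3.0, 4.5]
        ctx = TrainingContext.from_endpoints(y)
        report = full_report(y, y, ctx=ctx)
        assert report.r == pytest.approx(1.0)
        assert report.ccc == pytest.approx(1.0)
        assert report.q2 == pytest.approx(1.0)
        assert report.q2_f1 == pytest.approx(1.0)
        assert report.q2_f3 == pytest.approx(1.0)
        assert report.rm2_avg == pytest.approx(1.0)
        assert report.k == pytest.approx(1.0)
        assert all(report.gt_flags.values())

    def test_absent_training_context(self):
        report = full_report([0, 1, 2, 3], [0.1, 1.2, 1.9, 3.3])
        assert report.q2_f1 is None
        assert report.q2_f3 is None
        assert report.q2 is not None

    def test_undefined_statistics_reported_absent(self):
        report = full_report([1, 1, 1], [0, 1, 2])
        assert report.r is None
        assert report.rm2_avg is None
        assert report.n == 3

    def test_golbraikh_tropsha_flags_fail_on_shifted_scale(self):
        y = np.linspace(0, 1, 20)
        flags = golbraikh_tropsha(y, 5.0 + 0.1 * y)
        assert not flags["k_ok"] or not flags["k_prime_ok"]
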