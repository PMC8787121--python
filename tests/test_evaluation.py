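import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmiqa import ImagePlane, ValidationError
from mmiqa.evaluation import (
    EvalReport,
    LogisticParams,
    baseline_scores,
    evaluate_metric,
    fit_logistic,
    krocc,
    logistic_map,
    plcc_rmse_mae,
    srocc,
)

from _oracles import brute_kendall_tau_b, brute_spearman


class TestLogisticMap:
    def test_midpoint_kills_sigmoid_term(self):
        p = LogisticParams((3.0, 0.7, 1.2, 0.4, -0.5))
        assert logistic_map(1.2, p) == pytest.approx(1.2 * 0.4 - 0.5)

    def test_degenerate_constant_curve(self):
        p = LogisticParams((0.0, 1.0, 0.0, 0.0, 2.5))
        q = np.linspace(-5, 5, 11)
        assert np.allclose(logistic_map(q, p), 2.5)

    def test_hand_evaluation(self):
        p = LogisticParams((2.0, 1.0, 0.0, 0.5, 1.0))
        assert logistic_map(0.0, p) == pytest.approx(1.0)

    def test_zero_tau2_rejected(self):
        with pytest.raises(ValidationError):
            logistic_map(1.0, LogisticParams((1, 0.0, 0, 0, 0)))

    def test_extreme_arguments_stay_finite(self):
        p = LogisticParams((1.0, 1e-6, 0.0, 0.0, 0.0))
        assert np.isfinite(logistic_map(1e6, p))


class TestFitLogistic:
    def test_curve_recovery(self):
        rng = np.random.default_rng(0)
        truth = LogisticParams((2.0, 0.15, 0.5, 0.3, 2.0))
        q = np.sort(rng.uniform(0, 1, 50))
        s = logistic_map(q, truth)
        fitted = fit_logistic(q, s)
        assert np.abs(logistic_map(q, fitted) - s).max() < 1e-6

    def test_constant_subjective(self):
        q = np.linspace(0, 1, 20)
        s = np.full(20, 3.3)
        fitted = fit_logistic(q, s)
        assert np.abs(logistic_map(q, fitted) - 3.3).max() < 1e-6

    def test_refit_is_idempotent_in_rmse(self):
        rng = np.random.default_rng(1)
        q = np.sort(rng.uniform(0, 2, 40))
        s = 1.0 + 2.0 / (1 + np.exp(-(q - 1.0) / 0.2)) + rng.normal(0, 0.05, 40)
        p1 = fit_logistic(q, s)
        mapped = logistic_map(q, p1)
        p2 = fit_logistic(q, mapped)
        r1 = np.sqrt(np.mean((logistic_map(q, p2) - mapped) ** 2))
        assert r1 < 1e-8

    def test_never_worse_than_best_start(self):
        # adversarially jagged data: the optimizer may stall, but the
        # returned curve can only improve on the analytic starts
        rng = np.random.default_rng(2)
        q = rng.uniform(0, 1, 30)
        s = rng.uniform(1, 5, 30)
        fitted = fit_logistic(q, s)
        rmse_fit = np.sqrt(np.mean((logistic_map(q, fitted) - s) ** 2))

        spread = s.max() - s.min()
        sign = np.sign(np.corrcoef(q, s)[0, 1]) or 1.0
        t2 = max(np.std(q) / 4.0, 1e-6) * sign
        start = LogisticParams((spread, t2, float(np.median(q)), 0.0, s.mean()))
        rmse_start = np.sqrt(np.mean((logistic_map(q, start) - s) ** 2))
        assert rmse_fit <= rmse_start + 1e-12

    def test_degenerate_objective_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            fit_logistic([1, 2, 3], [1, 2, 3])


class TestRankCorrelations:
    def test_srocc_perfect_monotone(self):
        a = [1, 2, 3, 4, 5]
        assert srocc(a, np.exp(a)) == pytest.approx(1.0)
        assert srocc(a, -np.asarray(a)) == pytest.approx(-1.0)

    def test_srocc_hand_value(self):
        assert srocc([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_krocc_perfect_monotone(self):
        assert krocc([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_krocc_hand_value(self):
        assert krocc([1, 2, 3], [1, 3, 2]) == pytest.approx(1.0 / 3.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValidationError, match="zero rank variance"):
            srocc([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError, match="zero rank variance"):
            krocc([1, 2, 3], [2, 2, 2])

    @pytest.mark.parametrize("seed", range(10))
    def test_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        # heavy ties via rounding, exercising the tie corrections
        a = np.round(rng.uniform(0, 5, n), 1)
        b = np.round(rng.uniform(0, 5, n), 1)
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            pytest.skip("degenerate draw")
        assert srocc(a, b) == pytest.approx(brute_spearman(a, b), abs=1e-12)
        assert krocc(a, b) == pytest.approx(brute_kendall_tau_b(a, b), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=-1000, max_value=1000), min_size=4,
                    max_size=20, unique=True).map(lambda xs: [x / 10 for x in xs]),
           st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_under_monotone_transform(self, a, kind):
        rng = np.random.default_rng(abs(hash(tuple(a))) % 2**32)
        b = rng.permutation(a)
        if np.unique(b).size < 2:
            return
        f = {"exp": lambda x: np.exp(np.asarray(x) / 50.0),
             "cube": lambda x: np.asarray(x) ** 3,
             "affine": lambda x: 2.0 * np.asarray(x) + 7.0}[kind]
        assert srocc(a, b) == pytest.approx(srocc(f(a), b), abs=1e-9)
        assert krocc(a, b) == pytest.approx(krocc(f(a), b), abs=1e-9)


class TestPlccRmseMae:
    def test_perfect_agreement(self):
        p, r, m = plcc_rmse_mae([1, 2, 3], [1, 2, 3])
        assert (p, r, m) == (pytest.approx(1.0), 0.0, 0.0)

    def test_hand_arithmetic(self):
        p, r, m = plcc_rmse_mae([0.0, 2.0], [0.0, 0.0])
        assert r == pytest.approx(np.sqrt(2.0))
        assert m == pytest.approx(1.0)

    def test_affine_transform_gives_unit_correlation(self):
        s = np.array([1.0, 2.5, 4.0, 2.0])
        p, _, _ = plcc_rmse_mae(-3.0 * s + 1.0, s)
        assert p == pytest.approx(-1.0)

    def test_zero_variance_yields_nan_plcc(self):
        p, r, m = plcc_rmse_mae([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(p)
        assert np.isfinite(r) and np.isfinite(m)


class TestEvaluateMetric:
    def test_smooth_monotone_decreasing(self):
        q = np.linspace(0.1, 1.0, 30)
        dmos = 4.0 / (1 + np.exp((q - 0.5) / 0.1))  # smooth, decreasing
        report = evaluate_metric(q, dmos)
        assert report.srocc == pytest.approx(-1.0)
        assert abs(report.plcc) >= 0.999
        assert report.n == 30

    def test_self_comparison(self):
        v = np.array([0.1, 0.4, 0.2, 0.9, 0.6])
        report = evaluate_metric(v, v)
        assert report.srocc == pytest.approx(1.0)
        assert report.krocc == pytest.approx(1.0)
        assert report.plcc == pytest.approx(1.0)
        assert report.rmse == pytest.approx(0.0, abs=1e-9)
        assert report.mae == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        q = rng.uniform(0, 1, 25)
        d = 4 - 3 * q + rng.normal(0, 0.2, 25)
        a = evaluate_metric(q, d)
        perm = rng.permutation(25)
        b = evaluate_metric(q[perm], d[perm])
        for key in ("srocc", "krocc", "plcc", "rmse", "mae"):
            assert getattr(a, key) == pytest.approx(getattr(b, key), abs=1e-9)

    def test_report_dict_keys(self):
        q = np.linspace(0, 1, 10)
        report = evaluate_metric(q, 4 - 3 * q)
        d = report.to_dict()
        assert set(d) == {"srocc", "krocc", "plcc", "rmse", "mae", "tau", "n"}
        assert len(d["tau"]) == 5


class TestBaselineScores:
    def _plane(self, value):
        return ImagePlane(np.full((8, 8), float(value)))

    def test_identical(self):
        mse, psnr = baseline_scores(self._plane(100), self._plane(100))
        assert mse == 0.0
        assert psnr == np.inf

    def test_full_swing(self):
        mse, psnr = baseline_scores(self._plane(0), self._plane(255))
        assert mse == pytest.approx(65025.0)
        assert psnr == pytest.approx(0.0)

    def test_symmetry(self, rng):
        a = ImagePlane(rng.uniform(0, 255, (8, 8)))
        b = ImagePlane(rng.uniform(0, 255, (8, 8)))
        assert baseline_scores(a, b)[0] == pytest.approx(baseline_scores(b, a)[0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            baseline_scores(self._plane(0), ImagePlane(np.zeros((8, 9))))
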