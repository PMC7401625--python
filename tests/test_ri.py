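"""Reference-interval estimators: nonparametric, parametric, robust,
bootstrap CIs, method selection, and the orchestrated pipeline."""

import numpy as np
import pytest
from scipy import stats

from vetri import (
    ReferenceIntervalEstimator,
    bootstrap_limit_ci,
    describe,
    estimate_reference_interval,
    nonparametric_ri,
    parametric_ri,
    robust_ri,
    select_method,
)
from vetri.distributions import BoxCoxTransform, assess_gaussianity
from vetri.ri import METHOD_NONPARAMETRIC, METHOD_ROBUST


class TestDescribe:
    def test_basic(self):
        d = describe([1, 2, 3])
        assert (d.mean, d.sd, d.median, d.minimum, d.maximum, d.n) == (2, 1, 2, 1, 3, 3)

    def test_single_value(self):
        d = describe([7.0])
        assert (d.mean, d.sd, d.median) == (7.0, 0.0, 7.0)

    def test_generator_moments_recovered(self, cohort_specs):
        # at n = 1e5 the synthetic generator reproduces its target mean
        from vetri.synthetic import CohortSpec, generate_cohort

        from vetri.synthetic import truncated_moments

        entry = cohort_specs["A"].entries["RBC"]
        spec = CohortSpec(breed="A", n=100_000, entries={"RBC": entry})
        table = generate_cohort(spec, seed=42)
        d = describe(table.values_for("RBC").to_numpy())
        # the asymmetric min/max window shifts the realised mean slightly;
        # the quadrature oracle quantifies that bias, which enters the budget
        bias = abs(truncated_moments(entry)[0] - entry.mean)
        assert abs(d.mean - 6.86) <= 0.01 * 6.86 + bias


class TestNonparametric:
    def test_rank_interpolation_1_to_1000(self):
        lrl, url = nonparametric_ri(np.arange(1, 1001))
        assert lrl == pytest.approx(25.025)
        assert url == pytest.approx(975.975)

    def test_n_119_exact_order_statistics(self, rng):
        x = np.sort(rng.normal(0, 1, 119))
        lrl, url = nonparametric_ri(x)
        assert lrl == x[2] and url == x[116]  # ranks 3 and 117 exactly

    def test_n_39_limits_are_extremes(self, rng):
        x = rng.normal(0, 1, 39)
        lrl, url = nonparametric_ri(x)
        assert lrl == x.min() and url == x.max()

    def test_n_below_floor_errors(self, rng):
        with pytest.raises(ValueError):
            nonparametric_ri(rng.normal(0, 1, 38))

    def test_brute_force_oracle_all_n(self, rng):
        # independent path: sort + explicit index arithmetic
        for n in range(39, 201):
            x = rng.normal(50, 7, n)
            s = np.sort(x)

            def oracle(r):
                r = min(max(r, 1.0), float(n))
                k = int(np.floor(r))
                g = r - k
                return s[k - 1] if k >= n else s[k - 1] + g * (s[k] - s[k - 1])

            lrl, url = nonparametric_ri(x)
            assert lrl == pytest.approx(oracle(0.025 * (n + 1)), rel=1e-12)
            assert url == pytest.approx(oracle(0.975 * (n + 1)), rel=1e-12)

    def test_limits_within_sample_range(self, rng):
        x = rng.exponential(3.0, 77)
        lrl, url = nonparametric_ri(x)
        assert x.min() <= lrl <= url <= x.max()

    def test_affine_equivariance(self, rng):
        x = rng.normal(0, 1, 150)
        lrl, url = nonparametric_ri(x)
        lrl2, url2 = nonparametric_ri(2.5 * x + 7)
        assert lrl2 == pytest.approx(2.5 * lrl + 7)
        assert url2 == pytest.approx(2.5 * url + 7)


class TestParametric:
    def test_standard_normal_closed_form(self):
        # symmetric sample normalised to mean 0, sd exactly 1
        x = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        x = (x - x.mean()) / x.std(ddof=1)
        lrl, url = parametric_ri(x)
        assert lrl == pytest.approx(-1.959964, abs=1e-4)
        assert url == pytest.approx(1.959964, abs=1e-4)

    def test_log_transform_analytic_inverse(self):
        # log-scale limits (0, 2) invert to (1, e^2)
        t = BoxCoxTransform(lmbda=0.0, shift=0.0)
        assert t.inverse(0.0) == pytest.approx(1.0)
        assert t.inverse(2.0) == pytest.approx(np.e**2)

    def test_normal_10_2_recovers_closed_form(self, rng):
        x = rng.normal(10, 2, 10_000)
        lrl, url = parametric_ri(x)
        assert lrl == pytest.approx(6.08, rel=0.02)
        assert url == pytest.approx(13.92, rel=0.02)

    def test_affine_equivariance(self, rng):
        x = rng.normal(5, 1, 300)
        lrl, url = parametric_ri(x)
        lrl2, url2 = parametric_ri(3 * x + 2)
        assert lrl2 == pytest.approx(3 * lrl + 2)
        assert url2 == pytest.approx(3 * url + 2)


class TestRobust:
    def test_agrees_with_parametric_on_clean_gaussian(self, rng):
        x = rng.normal(100, 15, 500)
        p = parametric_ri(x)
        r = robust_ri(x)
        width = p[1] - p[0]
        assert abs(r[0] - p[0]) / width < 0.05
        assert abs(r[1] - p[1]) / width < 0.05

    def test_resists_contamination(self, rng):
        x = rng.normal(0, 1, 200)
        contaminated = np.concatenate([x, [10.0, 10.5]])
        p_clean = parametric_ri(x)[1]
        p_cont = parametric_ri(contaminated)[1]
        r_clean = robust_ri(x)[1]
        r_cont = robust_ri(contaminated)[1]
        assert (r_cont - r_clean) < 0.5 * (p_cont - p_clean)

    def test_constant_vector_degenerates(self):
        assert robust_ri([4.2] * 30) == (4.2, 4.2)


class TestBootstrap:
    def test_point_estimate_containment(self, rng):
        x = rng.normal(10, 2, 150)
        point = nonparametric_ri(x)
        (llo, lhi), (ulo, uhi) = bootstrap_limit_ci(
            x, nonparametric_ri, reps=400, seed=7
        )
        tol = 0.2 * (point[1] - point[0])
        assert llo - tol <= point[0] <= lhi + tol
        assert ulo - tol <= point[1] <= uhi + tol
        assert llo <= lhi and ulo <= uhi

    def test_same_seed_identical(self, rng):
        x = rng.normal(0, 1, 60)
        a = bootstrap_limit_ci(x, parametric_ri, reps=300, seed=11)
        b = bootstrap_limit_ci(x, parametric_ri, reps=300, seed=11)
        assert a == b

    def test_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n in (100, 400):
            x = rng.normal(0, 1, n)
            (llo, lhi), (ulo, uhi) = bootstrap_limit_ci(
                x, parametric_ri, reps=300, seed=3
            )
            widths.append((lhi - llo) + (uhi - ulo))
        assert widths[1] < widths[0]

    def test_too_few_reps(self, rng):
        with pytest.raises(ValueError):
            bootstrap_limit_ci(rng.normal(0, 1, 50), parametric_ri, reps=100)


class TestSelectMethod:
    def test_large_cohort_nonparametric(self, rng):
        v = assess_gaussianity(rng.normal(0, 1, 156))
        assert select_method(156, v).method == METHOD_NONPARAMETRIC

    def test_moderate_non_gaussian_robust_on_boxcox(self, rng):
        v = assess_gaussianity(rng.lognormal(0, 1, 500))
        choice = select_method(52, v)
        assert choice.method == METHOD_ROBUST
        assert choice.use_transform

    def test_moderate_gaussian_robust_raw(self, rng):
        v = assess_gaussianity(rng.normal(0, 1, 500))
        choice = select_method(52, v)
        assert choice.method == METHOD_ROBUST
        assert not choice.use_transform

    def test_small_sample_warns(self, rng):
        v = assess_gaussianity(rng.normal(0, 1, 25))
        assert select_method(25, v).small_sample_warning

    def test_below_floor_errors(self, rng):
        v = assess_gaussianity(rng.normal(0, 1, 30))
        with pytest.raises(ValueError):
            select_method(19, v)


class TestPipeline:
    def test_gaussian_cohort_recovers_true_percentile(self):
        # true 2.5th percentile of N(10, 2) is 6.08
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, 150)
        est = estimate_reference_interval(x, seed=1, bootstrap_reps=200)
        assert est.method == METHOD_NONPARAMETRIC
        assert est.lrl == pytest.approx(6.08, abs=0.5)
        assert est.lrl_ci[0] <= est.lrl <= est.lrl_ci[1]

    def test_injected_outlier_removed_limits_stable(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, 150)
        est_clean = estimate_reference_interval(x, seed=1, bootstrap_reps=200)
        est_dirty = estimate_reference_interval(
            np.concatenate([x, [40.0]]), seed=1, bootstrap_reps=200
        )
        assert est_dirty.removed_outliers == 1
        assert est_dirty.url == pytest.approx(est_clean.url, rel=0.02)

    def test_small_input_errors(self, rng):
        with pytest.raises(ValueError):
            estimate_reference_interval(rng.normal(0, 1, 10))

    def test_coverage_recovery(self):
        # nonparametric RI at n = 5000 covers 0.95 +/- 0.01 of fresh draws
        rng = np.random.default_rng(99)
        x = rng.normal(0, 1, 5000)
        lrl, url = nonparametric_ri(x)
        fresh = rng.normal(0, 1, 200_000)
        frac = np.mean((fresh >= lrl) & (fresh <= url))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_sklearn_estimator_contract(self, rng):
        est = ReferenceIntervalEstimator(bootstrap_reps=0, random_state=0)
        params = est.get_params()
        assert params["coverage"] == 0.95
        est.set_params(coverage=0.90)
        x = rng.normal(10, 2, 150)
        est.fit(x)
        assert est.lrl_ <= est.url_
        pred = est.predict([est.lrl_ - 1, 10.0, est.url_ + 1])
        assert list(pred) == [-1, 1, -1]

    def test_estimate_records_provenance(self, rng):
        x = rng.lognormal(1, 0.6, 80)
        est = estimate_reference_interval(x, seed=2, bootstrap_reps=200)
        assert est.method == METHOD_ROBUST
        assert est.verdict is not None
        rec = est.to_record()
        assert rec["n"] == est.n_used and rec["method"] == est.method
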