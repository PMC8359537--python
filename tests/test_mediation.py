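"""Path estimation, bootstrap intervals and mediation orchestration."""

import numpy as np
import pytest
import statsmodels.api as sm

from cmetspipe import (
    CollinearDesignError,
    ConfigurationError,
    SingleMediatorModel,
    bootstrap_indirect,
    fit_parallel_paths,
    fit_paths,
    proportion_mediated,
    run_mediation,
    standardize_for_paths,
    standardize_paths,
)
from cmetspipe.mediation import PathEstimates


def simulate_chain(n, a, b, c_prime, rng, with_cov=True):
    x = rng.integers(0, 2, n).astype(float)
    cov = rng.normal(0, 1, (n, 2)) if with_cov else None
    m = a * x + (0.3 * cov[:, 0] if with_cov else 0) + rng.normal(0, 1, n)
    y = b * m + c_prime * x + (0.2 * cov[:, 1] if with_cov else 0) + rng.normal(0, 1, n)
    return x, m, y, cov


class TestFitPaths:
    def test_matches_statsmodels_ols(self, rng):
        # independent oracle: the same three regressions via statsmodels
        x, m, y, cov = simulate_chain(300, 0.5, 0.4, 0.2, rng)
        paths = fit_paths(x, m, y, cov)
        Xa = sm.add_constant(np.column_stack([x, cov]))
        Xb = sm.add_constant(np.column_stack([x, m, cov]))
        assert paths.a == pytest.approx(sm.OLS(m, Xa).fit().params[1], abs=1e-10)
        fit_b = sm.OLS(y, Xb).fit().params
        assert paths.c_prime == pytest.approx(fit_b[1], abs=1e-10)
        assert paths.b == pytest.approx(fit_b[2], abs=1e-10)
        assert paths.c == pytest.approx(sm.OLS(y, Xa).fit().params[1], abs=1e-10)

    def test_effect_decomposition_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(30, 120))
            x, m, y, cov = simulate_chain(
                n, rng.normal(), rng.normal(), rng.normal(), rng
            )
            paths = fit_paths(x, m, y, cov)
            assert paths.c == pytest.approx(paths.c_prime + paths.indirect, abs=1e-10)

    def test_fully_mediated_chain(self, rng):
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        m = x + rng.normal(0, 1e-3, n)
        y = m + rng.normal(0, 1e-3, n)
        paths = fit_paths(x, m, y)
        assert paths.a == pytest.approx(1.0, abs=0.01)
        assert paths.b == pytest.approx(1.0, abs=0.01)
        assert paths.c == pytest.approx(1.0, abs=0.01)
        assert paths.c_prime == pytest.approx(0.0, abs=0.01)

    def test_null_mediator_gives_null_indirect(self, rng):
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        m = rng.normal(0, 1, n)  # independent of x
        y = 0.5 * x + rng.normal(0, 1, n)
        paths = fit_paths(x, m, y)
        se_a = 1.0 / (x.std(ddof=1) * np.sqrt(n))
        assert abs(paths.a) < 3 * se_a
        assert abs(paths.indirect) < 0.05

    def test_collinear_design_named(self, rng):
        x = rng.integers(0, 2, 100).astype(float)
        cov = np.column_stack([x, rng.normal(0, 1, 100)])  # duplicates exposure
        with pytest.raises(CollinearDesignError):
            fit_paths(x, rng.normal(0, 1, 100), rng.normal(0, 1, 100), cov,
                      covariate_names=["x_copy", "noise"])

    def test_too_small_sample_rejected(self, rng):
        with pytest.raises(Exception, match="too small"):
            fit_paths([0, 1, 0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestStandardization:
    def test_idempotent_on_standardized_input(self, rng):
        m = rng.normal(0, 1, 200)
        m = (m - m.mean()) / m.std(ddof=1)
        y = rng.normal(0, 1, 200)
        y = (y - y.mean()) / y.std(ddof=1)
        x = rng.integers(0, 2, 200).astype(float)
        _, m2, y2, _ = standardize_for_paths(x, m, y)
        np.testing.assert_allclose(m2, m, atol=1e-12)
        np.testing.assert_allclose(y2, y, atol=1e-12)

    def test_outcome_unit_change_leaves_standardized_b(self, rng):
        x, m, y, cov = simulate_chain(300, 0.5, 0.4, 0.2, rng)
        p1 = fit_paths(*standardize_for_paths(x, m, y, cov)[:3], cov)
        p2 = fit_paths(*standardize_for_paths(x, m, 2.0 * y, cov)[:3], cov)
        assert p1.b == pytest.approx(p2.b, abs=1e-10)

    def test_standardized_equals_rescaled_raw(self, rng):
        x, m, y, cov = simulate_chain(400, 0.5, 0.4, 0.2, rng)
        raw = fit_paths(x, m, y, cov)
        std = standardize_paths(raw, m.std(ddof=1), y.std(ddof=1))
        direct = fit_paths(*standardize_for_paths(x, m, y, cov)[:3], cov)
        assert std.a == pytest.approx(direct.a, abs=1e-10)
        assert std.b == pytest.approx(direct.b, abs=1e-10)
        assert std.indirect == pytest.approx(raw.indirect / y.std(ddof=1), abs=1e-12)


class TestBootstrap:
    def test_seed_reproducibility(self, rng):
        x, m, y, cov = simulate_chain(200, 0.5, 0.4, 0.2, rng)
        ci1 = bootstrap_indirect(x, m, y, cov, n_boot=500, seed=7)
        ci2 = bootstrap_indirect(x, m, y, cov, n_boot=500, seed=7)
        assert (ci1.lower, ci1.upper) == (ci2.lower, ci2.upper)

    def test_degenerate_distribution_collapses_to_point(self):
        # deterministic chain: every resample gives the same indirect effect
        n = 40
        x = np.tile([0.0, 1.0], n // 2)
        jit = np.tile(np.linspace(-0.01, 0.01, n // 2), 2)
        m = x + jit
        y = m.copy()
        ci = bootstrap_indirect(x, m, y, n_boot=300, seed=1)
        # for a noiseless chain all bootstrap estimates agree up to jitter
        assert ci.upper - ci.lower < 0.05

    def test_bc_reduces_to_percentile_when_symmetric(self, rng):
        x, m, y, cov = simulate_chain(2000, 0.5, 0.4, 0.2, rng)
        pc = bootstrap_indirect(x, m, y, cov, n_boot=2000, method="percentile", seed=5)
        bc = bootstrap_indirect(x, m, y, cov, n_boot=2000, method="bias_corrected", seed=5)
        assert abs(bc.z0) < 0.1  # near-symmetric bootstrap distribution
        hw_pc = (pc.upper - pc.lower) / 2
        hw_bc = (bc.upper - bc.lower) / 2
        assert abs(hw_pc - hw_bc) < 0.02

    def test_significance_flag_matches_interval(self, rng):
        x, m, y, cov = simulate_chain(500, 0.8, 0.8, 0.0, rng)
        ci = bootstrap_indirect(x, m, y, cov, n_boot=500, seed=2)
        assert ci.significant == (ci.lower > 0 or ci.upper < 0)
        assert ci.lower <= ci.upper

    def test_small_n_boot_rejected(self, rng):
        x, m, y, cov = simulate_chain(100, 0.5, 0.4, 0.2, rng)
        with pytest.raises(ConfigurationError):
            bootstrap_indirect(x, m, y, cov, n_boot=100)


class TestProportionMediated:
    def test_full_mediation_is_one(self):
        paths = PathEstimates(a=0.5, b=0.8, c=0.4, c_prime=0.0)
        assert proportion_mediated(paths).value == pytest.approx(1.0)

    def test_zero_indirect_is_zero(self):
        paths = PathEstimates(a=0.0, b=0.8, c=0.4, c_prime=0.4)
        assert proportion_mediated(paths).value == 0.0

    def test_tiny_total_effect_undefined(self):
        paths = PathEstimates(a=0.5, b=0.8, c=1e-12, c_prime=-0.4)
        assert proportion_mediated(paths).value is None
        assert "undefined" in proportion_mediated(paths).status

    def test_opposite_signs_flagged_inconsistent(self):
        paths = PathEstimates(a=0.5, b=-0.8, c=0.2, c_prime=0.6)
        out = proportion_mediated(paths)
        assert out.value < 0 and "inconsistent" in out.status


class TestRunMediation:
    def test_point_estimates_are_seed_free(self, paper_cohort):
        r1 = run_mediation(paper_cohort, "vfl", n_boot=300, seed=1)
        r2 = run_mediation(paper_cohort, "vfl", n_boot=300, seed=99)
        assert r1.paths.a == r2.paths.a
        assert r1.paths_std.indirect == r2.paths_std.indirect
        assert (r1.ci.lower, r1.ci.upper) != (r2.ci.lower, r2.ci.upper)

    def test_adding_second_mediator_keeps_first_interval(self, paper_cohort):
        solo = run_mediation(paper_cohort, ["vfl"], n_boot=300, seed=11)[0]
        pair = run_mediation(paper_cohort, ["vfl", "tbf"], n_boot=300, seed=11)[0]
        assert (solo.ci.lower, solo.ci.upper) == (pair.ci.lower, pair.ci.upper)

    def test_mediator_as_covariate_rejected(self, paper_cohort):
        with pytest.raises(ConfigurationError, match="covariate"):
            run_mediation(paper_cohort, "vfl", covariates=["age", "vfl"], n_boot=300)

    def test_missing_column_rejected(self, paper_cohort):
        with pytest.raises(ConfigurationError, match="nonexistent"):
            run_mediation(paper_cohort, "nonexistent", n_boot=300)

    def test_estimator_interface(self, paper_cohort):
        model = SingleMediatorModel(mediator="vfl", n_boot=300, seed=3)
        assert model.get_params()["mediator"] == "vfl"
        model.fit(paper_cohort)
        assert model.n_used_ == paper_cohort.n
        assert model.paths_.c == pytest.approx(
            model.paths_.c_prime + model.paths_.indirect, abs=1e-10
        )
        assert model.result_.to_dict()["mediator"] == "vfl"
        assert "indirect" in model.result_.summary()

    def test_outcome_can_be_plain_column(self, paper_cohort):
        r = run_mediation(paper_cohort, "vfl", outcome="wc", n_boot=300, seed=4)
        assert r.outcome == "wc" and np.isfinite(r.paths.indirect)


class TestParallelMediation:
    def test_joint_decomposition(self, rng):
        n = 800
        x = rng.integers(0, 2, n).astype(float)
        m1 = 0.6 * x + rng.normal(0, 1, n)
        m2 = 0.4 * x + rng.normal(0, 1, n)
        y = 0.5 * m1 + 0.3 * m2 + 0.2 * x + rng.normal(0, 1, n)
        results = fit_parallel_paths(x, np.column_stack([m1, m2]), y)
        total_indirect = sum(r.indirect for r in results)
        assert results[0].c == pytest.approx(results[0].c_prime + total_indirect, abs=1e-10)
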