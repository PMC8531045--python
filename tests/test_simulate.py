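"""Synthetic cohort generator: calibration, reproducibility, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from deliriscore.errors import ConfigurationError, NumericError
from deliriscore.screening import fit_univariate_logistic
from deliriscore.simulate import (
    BinaryCovariate,
    CohortSpec,
    ContinuousCovariate,
    DerivedFlag,
    calibrate_intercept,
    expected_prevalence,
    generate_cohort,
    resolve_spec,
    testing_default as make_testing_spec,
    training_default,
)


def _simple_spec(betas, prevalences, target, n=100):
    covs = [BinaryCovariate(f"x{i}", p) for i, p in enumerate(prevalences)]
    effects = {f"x{i}": b for i, b in enumerate(betas)}
    return CohortSpec(n=n, covariates=covs, effects=effects, target_prevalence=target)


class TestCalibrateIntercept:
    def test_null_effects_target_half_gives_zero(self):
        spec = _simple_spec([0.0, 0.0], [0.3, 0.6], 0.5)
        assert calibrate_intercept(spec) == pytest.approx(0.0, abs=1e-10)

    def test_null_effects_closed_form_logit(self):
        # with all beta = 0 the intercept is exactly logit(target)
        spec = _simple_spec([0.0], [0.4], 0.161)
        assert calibrate_intercept(spec) == pytest.approx(logit(0.161), abs=1e-10)

    @given(
        st.lists(st.floats(-2.5, 2.5), min_size=1, max_size=5),
        st.floats(0.02, 0.98),
        st.integers(0, 10_000),
    )
    @settings(max_examples=40)
    def test_exact_enumeration_hits_target(self, betas, target, salt):
        rng = np.random.default_rng(salt)
        prevs = rng.uniform(0.05, 0.95, len(betas))
        spec = _simple_spec(betas, prevs, target)
        alpha = calibrate_intercept(spec)
        assert expected_prevalence(spec, alpha) == pytest.approx(target, abs=1e-4)

    def test_default_training_spec_hits_stated_prevalence(self):
        spec = training_default(n=200_000)
        alpha = calibrate_intercept(spec)
        cohort = generate_cohort(spec, seed=1)
        assert expected_prevalence(spec, alpha) == pytest.approx(0.161, abs=1e-6)
        assert cohort.outcome().mean() == pytest.approx(0.161, abs=0.005)

    def test_monte_carlo_path_with_continuous_effect(self):
        spec = CohortSpec(
            n=100,
            covariates=[ContinuousCovariate("age", 80, 8)],
            effects={"age": 0.05},
            target_prevalence=0.3,
        )
        alpha = calibrate_intercept(spec)
        assert expected_prevalence(spec, alpha) == pytest.approx(0.3, abs=2e-3)

    def test_fixed_intercept_spec_refuses_calibration(self):
        spec = CohortSpec(n=10, covariates=[BinaryCovariate("x", 0.5)],
                          effects={"x": 1.0}, intercept=0.0)
        with pytest.raises(ConfigurationError):
            calibrate_intercept(spec)


class TestSpecValidation:
    def test_needs_exactly_one_of_intercept_target(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n=10, covariates=[BinaryCovariate("x", 0.5)], effects={},
                       intercept=0.0, target_prevalence=0.5)
        with pytest.raises(ConfigurationError):
            CohortSpec(n=10, covariates=[BinaryCovariate("x", 0.5)], effects={})

    def test_effects_must_name_covariates(self):
        with pytest.raises(ConfigurationError, match="ghost"):
            CohortSpec(n=10, covariates=[BinaryCovariate("x", 0.5)],
                       effects={"ghost": 1.0}, target_prevalence=0.5)

    def test_prevalence_bounds(self):
        with pytest.raises(ConfigurationError):
            BinaryCovariate("x", 1.0)

    def test_non_psd_correlation_rejected(self):
        corr = [[1.0, 0.99], [0.99, 0.5]]
        with pytest.raises(ConfigurationError, match="positive definite"):
            CohortSpec(n=10,
                       covariates=[BinaryCovariate("a", 0.5), BinaryCovariate("b", 0.5)],
                       effects={"a": 1.0}, target_prevalence=0.5, correlation=corr)

    def test_yaml_round_trip(self, tmp_path):
        spec = training_default(n=500)
        path = spec.to_yaml(tmp_path / "spec.yaml")
        back = CohortSpec.from_yaml(path)
        assert back.to_dict() == spec.to_dict()
        assert resolve_spec(str(path), n=123).n == 123


class TestGenerateCohort:
    def test_same_seed_is_bitwise_identical(self):
        spec = training_default(n=500)
        a = generate_cohort(spec, seed=11)
        b = generate_cohort(spec, seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_cohort(spec, seed=12)
        assert not a.data.equals(c.data)

    def test_covariate_prevalence_concentrates(self):
        spec = _simple_spec([0.0], [0.30], 0.2, n=100_000)
        cohort = generate_cohort(spec, seed=2)
        assert cohort.values("x0").mean() == pytest.approx(0.30, abs=0.01)

    def test_derived_flag_is_or_of_sources(self):
        spec = training_default(n=20_000)
        cohort = generate_cohort(spec, seed=3)
        sources = next(d.sources for d in spec.derived if d.name == "psychotropics")
        manual = (cohort.data[list(sources)].to_numpy() == 1).any(axis=1).astype(float)
        np.testing.assert_array_equal(cohort.values("psychotropics"), manual)

    def test_correlated_binaries_via_copula(self):
        corr = [[1.0, 0.6], [0.6, 1.0]]
        spec = CohortSpec(n=50_000,
                          covariates=[BinaryCovariate("a", 0.4), BinaryCovariate("b", 0.4)],
                          effects={"a": 1.0}, target_prevalence=0.3, correlation=corr)
        cohort = generate_cohort(spec, seed=4)
        r = np.corrcoef(cohort.values("a"), cohort.values("b"))[0, 1]
        assert r > 0.3  # tetrachoric 0.6 implies clearly positive phi
        assert cohort.values("a").mean() == pytest.approx(0.4, abs=0.01)

    def test_seed_required(self):
        spec = _simple_spec([0.0], [0.5], 0.5)
        with pytest.raises(ConfigurationError, match="seed"):
            generate_cohort(spec)


class TestModelProperties:
    def test_prevalence_monotone_in_effect(self):
        base = [0.5, -0.5, 1.0]
        prevs = [0.3, 0.4, 0.2]
        alpha = -1.0
        for i in range(3):
            spec_lo = CohortSpec(n=10, covariates=[BinaryCovariate(f"x{j}", p) for j, p in enumerate(prevs)],
                                 effects={f"x{j}": b for j, b in enumerate(base)}, intercept=alpha)
            bumped = list(base)
            bumped[i] += 0.7
            spec_hi = CohortSpec(n=10, covariates=spec_lo.covariates,
                                 effects={f"x{j}": b for j, b in enumerate(bumped)}, intercept=alpha)
            assert expected_prevalence(spec_hi, alpha) >= expected_prevalence(spec_lo, alpha)

    def test_null_model_univariate_ors_near_one(self):
        spec = _simple_spec([0.0, 0.0, 0.0], [0.3, 0.5, 0.2], 0.25, n=50_000)
        cohort = generate_cohort(spec, seed=6)
        for name in cohort.candidate_names():
            r = fit_univariate_logistic(cohort, name)
            assert 0.9 < r.odds_ratio < 1.1

    def test_multivariable_refit_recovers_planted_effects(self):
        # each planted beta within 3 SE of its MLE in >= 95% of seeds
        spec = training_default(n=20_000)
        truth = np.array(list(spec.effects.values()))
        names = list(spec.effects)
        hits = np.zeros(len(names))
        n_seeds = 20
        for seed in range(n_seeds):
            cohort = generate_cohort(spec, seed=1000 + seed)
            X = np.column_stack([cohort.values(v) for v in names])
            fit = sm.Logit(cohort.outcome().astype(float), sm.add_constant(X)).fit(disp=0)
            hits += np.abs(fit.params[1:] - truth) <= 3 * fit.bse[1:]
        assert (hits >= 0.95 * n_seeds).all()

    def test_testing_default_targets_higher_prevalence(self):
        tr, te = training_default(), make_testing_spec()
        assert tr.target_prevalence == 0.161
        assert te.target_prevalence == 0.346
        assert tr.n == 257 and te.n == 107
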