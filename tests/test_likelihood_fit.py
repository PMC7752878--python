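import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime

import survodds as so
from survodds.estimators import ProbabilityRegression, log_likelihood
from survodds.model import (
    LikelihoodObjective,
    LogHazardLink,
    LogitProbabilityLink,
    ModelDesign,
    ModelSpec,
    RankDeficiencyError,
    build_likelihood_parts,
)

CONST = ModelSpec(time_form="constant", age_form="none")


def test_empty_dataset_loglik_is_zero():
    X = pd.DataFrame({"age_years": []})
    y = so.survival_outcome([], [])
    assert log_likelihood(X, y, CONST, params=[0.4]) == 0.0


def test_exponential_closed_form(exp_data):
    """Constant-hazard model: l = D log(lambda) - lambda T with
    lambda = softplus(gamma0)."""
    X, y, D, T = exp_data
    gamma0 = -0.3
    lam = np.logaddexp(0, gamma0)
    expected = D * np.log(lam) - lam * T
    assert log_likelihood(X, y, CONST, params=[gamma0]) == pytest.approx(
        expected, rel=1e-12
    )


def test_fit_recovers_exponential_mle(exp_data):
    X, y, D, T = exp_data
    fit = so.fit_mle(X, y, CONST)
    assert np.logaddexp(0, fit.coef_[0]) == pytest.approx(D / T, rel=1e-6)
    assert fit.loglik_ == pytest.approx(D * np.log(D / T) - D, rel=1e-9)
    assert fit.converged_
    assert fit.n_events_ == D


def test_aic_definition(exp_data):
    X, y, *_ = exp_data
    fit = so.fit_mle(X, y, ModelSpec(time_form="linear", age_form="none"))
    assert fit.aic_ == pytest.approx(2 * len(fit.coef_) - 2 * fit.loglik_)


def test_left_truncation_reduces_integrated_hazard():
    """A record entering at 0.25 y contributes less -H than the same record
    entering at 0 (hazard strictly positive on [0, 0.25])."""
    X = pd.DataFrame({"age_years": [65.0]})
    params = {"(Intercept)": 0.2, "time": -0.1}
    spec = ModelSpec(time_form="linear", age_form="none")
    ll_from_0 = log_likelihood(X, so.survival_outcome([1.0], [1]), spec, params)
    ll_delayed = log_likelihood(
        X, so.survival_outcome([1.0], [1], entry=[0.25]), spec, params
    )
    assert ll_delayed > ll_from_0


@pytest.mark.parametrize("link", [LogitProbabilityLink, LogHazardLink])
def test_analytic_gradient_matches_numeric(link):
    rng = np.random.default_rng(5)
    n = 40
    time = rng.exponential(1.0, n) + 0.05
    event = rng.random(n) < 0.6
    X = pd.DataFrame(
        {
            "age_years": rng.uniform(50, 85, n),
            "sex": rng.choice(["male", "female"], n),
        }
    )
    spec = ModelSpec(
        time_form="rcs",
        time_knots=(0.05, 0.6, 3.0),
        age_form="linear",
        covariates=("sex",),
    ).resolve()
    design = ModelDesign(spec)
    parts = build_likelihood_parts(design, X, np.zeros(n), time, event)
    obj = LikelihoodObjective(parts, link)
    theta = rng.normal(scale=0.3, size=design.n_params)
    numeric = approx_fprime(theta, obj.loglik, 1e-7)
    np.testing.assert_allclose(obj.grad(theta), numeric, rtol=5e-5, atol=5e-5)


def test_refit_from_perturbed_init_reaches_same_optimum(small_cohort):
    prep = so.prepare_endpoint(small_cohort, "y5_all_cause")
    spec = ModelSpec(time_form="linear", age_form="linear", covariates=("sex",))
    fit = so.fit_mle(prep.X(), prep.y(), spec)
    rng = np.random.default_rng(0)
    refit = so.fit_mle(
        prep.X(), prep.y(), spec, init=fit.coef_ + rng.normal(scale=0.5, size=len(fit.coef_))
    )
    assert refit.loglik_ == pytest.approx(fit.loglik_, abs=1e-6)


def test_optimum_beats_random_perturbations(small_cohort):
    prep = so.prepare_endpoint(small_cohort, "y5_all_cause")
    spec = ModelSpec(time_form="linear", age_form="linear")
    fit = so.fit_mle(prep.X(), prep.y(), spec)
    rng = np.random.default_rng(1)
    for _ in range(50):
        theta = fit.coef_ + rng.normal(scale=0.1, size=len(fit.coef_))
        assert fit._objective.loglik(theta) <= fit.loglik_ + 1e-9


def test_time_unit_invariance_of_hazard_ratios(small_cohort):
    """Rescaling time from years to days shifts the baseline (per-unit-time
    hazard) but leaves covariate hazard ratios identical to within 1e-4.
    The odds-of-probability estimand, by contrast, is intrinsically tied to
    the time unit (g is a per-unit-interval probability), which is why the
    package fixes years as the analysis unit."""
    prep = so.prepare_endpoint(small_cohort, "y5_all_cause")
    X, y = prep.X(), prep.y()
    spec = ModelSpec(time_form="linear", age_form="linear", covariates=("stage",))
    fit_years = so.fit_ph_model(X, y, spec)
    y_days = so.survival_outcome(y["time"] * 365.25, y["event"], y["entry"] * 365.25)
    fit_days = so.fit_ph_model(X, y_days, spec)
    for term in ("age", "stage[III-IV]"):
        a = fit_years.hazard_ratios([term])["estimate"].iloc[0]
        b = fit_days.hazard_ratios([term])["estimate"].iloc[0]
        assert b == pytest.approx(a, abs=1e-4)
    # the baseline intercept absorbs the unit change (shift by log 365.25)
    assert fit_days.coef_[0] == pytest.approx(
        fit_years.coef_[0] - np.log(365.25), abs=1e-3
    )


def test_rank_deficiency_names_offending_column():
    n = 60
    rng = np.random.default_rng(2)
    X = pd.DataFrame(
        {"age_years": rng.uniform(50, 80, n), "stage": ["0-II"] * n}
    )
    y = so.survival_outcome(rng.exponential(1, n) + 0.01, np.ones(n))
    with pytest.raises(RankDeficiencyError) as err:
        so.fit_mle(X, y, ModelSpec(age_form="linear", covariates=("stage",)))
    assert "stage[III-IV]" in str(err.value)


def test_no_events_raises():
    X = pd.DataFrame({"age_years": [60.0, 70.0]})
    y = so.survival_outcome([1.0, 2.0], [0, 0])
    with pytest.raises(ValueError, match="no events"):
        so.fit_mle(X, y, CONST)


def test_unknown_covariate_level_rejected():
    X = pd.DataFrame({"age_years": [60.0, 70.0], "sex": ["male", "unknown"]})
    y = so.survival_outcome([1.0, 2.0], [1, 1])
    with pytest.raises(ValueError, match="unknown level"):
        so.fit_mle(X, y, ModelSpec(age_form="linear", covariates=("sex",)))


def test_convergence_flag_reflects_gradient_norm(exp_data):
    X, y, *_ = exp_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        crippled = ProbabilityRegression(
            time_form="constant", age_form="none", max_iter=1, n_restarts=0,
            init=[5.0],
        ).fit(X, y)
    assert not crippled.converged_
    ok = ProbabilityRegression(time_form="constant", age_form="none").fit(X, y)
    assert ok.converged_ and ok.grad_norm_ < ok.grad_tol
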