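import numpy as np
import pandas as pd
import pytest
from scipy import stats

import survodds as so
from survodds.endpoints import FIVE_YEARS_DAYS
from survodds.simulate import SimulationConfigError, _band_probs, _cci_conditional


def test_same_seed_reproduces_cohort_byte_identically(tmp_path):
    cfg = so.default_config(n=300, seed=5)
    a, b = so.assemble_cohort(cfg), so.assemble_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False)
    b.to_csv(pb, index=False)
    assert pa.read_bytes() == pb.read_bytes()
    # a different seed changes the draw
    cfg2 = so.default_config(n=300, seed=6)
    assert not so.assemble_cohort(cfg2).equals(a)


def test_covariate_marginals_match_targets():
    """At n = 1e5 every simulated covariate frequency is within 3 binomial
    standard errors of its configured target."""
    cfg = so.default_config(n=100_000, seed=31)
    cov = so.simulate_covariates(cfg, np.random.default_rng(31))
    n = len(cov)
    for name, probs in cfg.covariate_marginals.items():
        freq = cov[name].value_counts(normalize=True)
        for level, p in probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq.get(level, 0.0) - p) < 3 * se, (name, level)


def test_age_distribution_median_range_and_bands():
    cfg = so.default_config(n=100_000, seed=32)
    age = so.simulate_covariates(cfg, np.random.default_rng(32))["age_years"]
    assert age.min() >= 18.0 and age.max() <= 89.0
    assert age.median() == pytest.approx(65.6, abs=0.5)
    bands = pd.cut(age, [0, 60, 70, 75, 200], right=False).value_counts(
        normalize=True, sort=False
    )
    for observed, target in zip(bands, (0.291, 0.377, 0.196, 0.136)):
        assert observed == pytest.approx(target, abs=0.02)


def test_comorbidity_confounding_preserves_marginal():
    """Older age bands get more comorbidity mass, yet the marginal cci
    distribution still matches its target (IPF correction)."""
    cfg = so.default_config()
    bands = _band_probs(cfg.age_dist)
    target = np.array(
        [cfg.covariate_marginals["cci"][k] for k in ("0", "1", "2+")]
    )
    cond = _cci_conditional(bands, target, cfg.cci_age_tilt)
    np.testing.assert_allclose(cond.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(bands @ cond, target, atol=1e-9)
    assert cond[-1, 2] > cond[0, 2]  # oldest band has most comorbidity
    assert cond[0, 0] > cond[-1, 0]


def test_event_times_match_exponential_distribution():
    """Constant hazard 0.5/year: simulated death times pass a KS comparison
    against Exponential(rate 0.5) at n = 1e4."""
    spec = so.ModelSpec(time_form="constant", age_form="none")
    coefs = {"(Intercept)": float(np.log(np.expm1(0.5)))}  # softplus^-1(0.5)
    X = pd.DataFrame({"age_years": np.full(10_000, 65.0)})
    t = so.simulate_event_time(spec, coefs, X, np.random.default_rng(8), horizon=80.0)
    t = t[np.isfinite(t)]
    assert len(t) > 9_990
    res = stats.kstest(t, "expon", args=(0, 2.0))
    assert res.pvalue > 0.01


def test_zero_exponential_draw_gives_time_zero():
    spec = so.ModelSpec(time_form="constant", age_form="none")
    X = pd.DataFrame({"age_years": [65.0, 65.0]})
    t = so.invert_cumulative_hazard(
        spec, {"(Intercept)": 0.0}, X, [0.0, 0.5], horizon=10.0
    )
    assert t[0] == 0.0
    assert t[1] > 0.0


def test_inversion_solves_cumulative_hazard_to_tolerance():
    spec = so.ModelSpec(time_form="linear", age_form="linear")
    coefs = {"(Intercept)": -0.5, "time": -0.2, "age": 0.05}
    X = pd.DataFrame({"age_years": [60.0, 75.0, 85.0]})
    E = np.array([0.3, 1.0, 2.0])
    t = so.invert_cumulative_hazard(spec, coefs, X, E, horizon=40.0)
    from survodds.model import ModelDesign, cumulative_hazard_value

    design = ModelDesign(spec)
    theta = design.coefficients_from_dict(coefs)
    H = cumulative_hazard_value(design, theta, X, 0.0, t)
    np.testing.assert_allclose(H, E, atol=1e-6)


def test_stronger_age_effect_shortens_old_age_survival():
    """Raising the age coefficient strictly lowers the median simulated
    death time for an 80-year-old profile."""
    X = pd.DataFrame({"age_years": np.full(10_000, 80.0)})
    spec = so.ModelSpec(time_form="linear", age_form="linear")
    medians = []
    for beta in (0.01, 0.05, 0.10):
        coefs = {"(Intercept)": -1.2, "time": -0.2, "age": beta}
        t = so.simulate_event_time(spec, coefs, X, np.random.default_rng(77), horizon=60.0)
        medians.append(np.median(t[np.isfinite(t)]))
    assert medians[0] > medians[1] > medians[2]


def test_five_year_followup_guarantee():
    coh = so.assemble_cohort(so.default_config(n=800, seed=12))
    censored = coh[coh["dead"] == 0]
    assert (censored["followup_days"] >= FIVE_YEARS_DAYS).all()
    assert (coh.loc[coh["cancer_death"] == 1, "dead"] == 1).all()
    valid, errors, warns = so.validate_cohort(coh)
    assert not errors


def test_admin_censoring_under_five_years_rejected():
    with pytest.raises(SimulationConfigError):
        so.SimulationConfig(admin_censor_years=3.0)


def test_invalid_marginals_rejected():
    with pytest.raises(SimulationConfigError):
        so.SimulationConfig(covariate_marginals={"sex": {"male": 0.8, "female": 0.3}})


def test_crude_mortality_gradient_across_age_groups():
    """With a positive per-year age effect, the crude 90-day death rate in
    the >=75 group exceeds the <70 group."""
    cfg = so.default_config(n=20_000, seed=21)
    coh = so.assemble_cohort(cfg)
    d90 = (coh["dead"] == 1) & (coh["followup_days"] <= 90)
    old = coh["age_years"] >= 75
    young = coh["age_years"] < 70
    assert d90[old].mean() > d90[young].mean()


def test_no_cancer_deaths_propagates_no_events_error():
    cfg = so.default_config(n=400, seed=13)
    cfg.cancer_death_prob = 0.0
    coh = so.assemble_cohort(cfg)
    prep = so.prepare_endpoint(coh, "y5_disease_specific")
    assert prep.n_events == 0
    with pytest.raises(ValueError, match="no events"):
        so.fit_mle(prep.X(), prep.y(), so.ModelSpec(time_form="linear"))


def test_config_yaml_round_trip(tmp_path):
    cfg = so.default_config(n=123, seed=9)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = so.SimulationConfig.from_yaml(path)
    assert back.n == 123 and back.seed == 9
    assert back.truth_spec == cfg.truth_spec
    assert back.truth_coefs == cfg.truth_coefs
    pd.testing.assert_frame_equal(so.assemble_cohort(back), so.assemble_cohort(cfg))
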