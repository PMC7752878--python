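"""Synthetic esophagectomy-cohort generator.

Emulates the statistical structure the analysis assumes: cohort covariate
composition matching published nationwide-cohort marginals, an age
distribution with the observed median and range, age-dependent comorbidity
(the minimal confounding structure making crude and adjusted odds ratios
differ), death times drawn from the instantaneous-probability model family
by inverse-transform sampling, a stage-dependent cancer-cause mixture among
deaths, and administrative censoring that guarantees at least five years of
potential follow-up for every subject.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .endpoints import COHORT_COLUMNS, DAYS_PER_YEAR
from .model import (
    COVARIATE_LEVELS,
    LogitProbabilityLink,
    ModelDesign,
    ModelSpec,
    build_quadrature,
    _time_cutpoints,
)

_AGE_BAND_EDGES = (60.0, 70.0, 75.0)
_BAND_SCORES = np.array([-1.5, -0.5, 0.5, 1.5])
_CCI_SCORES = np.array([-1.0, 0.0, 1.0])


class SimulationConfigError(ValueError):
    pass


def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "time_form": spec.time_form,
        "time_knots": list(spec.time_knots) if spec.time_knots else None,
        "n_time_knots": spec.n_time_knots,
        "age_form": spec.age_form,
        "age_knots": list(spec.age_knots) if spec.age_knots else None,
        "n_age_knots": spec.n_age_knots,
        "covariates": list(spec.covariates),
        "interactions": [list(p) for p in spec.interactions],
    }


def _spec_from_dict(d: dict) -> ModelSpec:
    d = dict(d)
    return ModelSpec(
        time_form=d.get("time_form", "linear"),
        time_knots=tuple(d["time_knots"]) if d.get("time_knots") else None,
        n_time_knots=d.get("n_time_knots", 3),
        age_form=d.get("age_form", "linear"),
        age_knots=tuple(d["age_knots"]) if d.get("age_knots") else None,
        n_age_knots=d.get("n_age_knots", 3),
        covariates=tuple(d.get("covariates", ())),
        interactions=tuple(tuple(p) for p in d.get("interactions", ())),
    )


@dataclass
class SimulationConfig:
    """Truth parameters, covariate marginals and censoring scheme.

    ``truth_spec``/``truth_coefs`` define the data-generating model on the
    logit-of-instantaneous-probability scale; ``covariate_marginals`` are
    category probabilities per covariate; ``age_dist`` holds the truncated
    skew-normal parameters; ``cci_age_tilt`` controls how strongly the
    comorbidity distribution shifts with age band (0 = independence);
    ``cancer_death_prob`` maps tumour stage to the probability that a death
    is cancer-caused.
    """

    n: int = 1737
    seed: int = 20870
    covariate_marginals: dict = field(default_factory=dict)
    age_dist: dict = field(default_factory=dict)
    truth_spec: ModelSpec = field(default_factory=ModelSpec)
    truth_coefs: dict = field(default_factory=dict)
    cci_age_tilt: float = 0.35
    cancer_death_prob: dict | float = 0.9
    admin_censor_years: float = 6.0

    def __post_init__(self):
        if self.n < 1:
            raise SimulationConfigError("n must be >= 1")
        if self.admin_censor_years < 5.0:
            raise SimulationConfigError(
                "admin_censor_years must be >= 5 (every subject must have "
                "five years of potential follow-up)"
            )
        for cov, probs in self.covariate_marginals.items():
            if cov not in COVARIATE_LEVELS:
                raise SimulationConfigError(f"unknown covariate {cov!r}")
            levels = COVARIATE_LEVELS[cov]
            if set(probs) != set(levels):
                raise SimulationConfigError(
                    f"marginals for {cov!r} must cover levels {levels}"
                )
            p = np.array([probs[lev] for lev in levels], dtype=float)
            if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-6:
                raise SimulationConfigError(
                    f"marginals for {cov!r} must be in [0,1] and sum to 1"
                )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth_spec"] = _spec_to_dict(self.truth_spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "truth_spec" in d and not isinstance(d["truth_spec"], ModelSpec):
            d["truth_spec"] = _spec_from_dict(d["truth_spec"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(n: int | None = None, seed: int | None = None) -> SimulationConfig:
    """The bundled cohort configuration (n = 1737 by default)."""
    resource = importlib.resources.files("survodds") / "configs" / "default_cohort.yaml"
    with importlib.resources.as_file(resource) as path:
        config = SimulationConfig.from_yaml(path)
    if n is not None:
        config.n = int(n)
    if seed is not None:
        config.seed = int(seed)
    return config


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


def _truncated_skewnorm(age_dist: dict, size: int, rng: np.random.Generator):
    a, loc, scale = age_dist["a"], age_dist["loc"], age_dist["scale"]
    lo, hi = age_dist["min"], age_dist["max"]
    dist = stats.skewnorm(a, loc=loc, scale=scale)
    u_lo, u_hi = dist.cdf(lo), dist.cdf(hi)
    u = rng.uniform(u_lo, u_hi, size=size)
    return np.clip(dist.ppf(u), lo, hi)


def _band_probs(age_dist: dict) -> np.ndarray:
    a, loc, scale = age_dist["a"], age_dist["loc"], age_dist["scale"]
    lo, hi = age_dist["min"], age_dist["max"]
    dist = stats.skewnorm(a, loc=loc, scale=scale)
    edges = np.array([lo, *_AGE_BAND_EDGES, hi])
    cdf = dist.cdf(edges)
    p = np.diff(cdf) / (cdf[-1] - cdf[0])
    return p / p.sum()


def _cci_conditional(band_probs: np.ndarray, cci_probs: np.ndarray, tilt: float):
    """Conditional comorbidity distribution per age band.

    Exponential tilting (older bands put more mass on higher comorbidity)
    followed by iterative proportional fitting so the implied *marginal*
    comorbidity distribution matches the target exactly under the band
    probabilities.
    """
    w = np.outer(band_probs, cci_probs) * np.exp(
        tilt * np.outer(_BAND_SCORES, _CCI_SCORES)
    )
    for _ in range(500):
        w *= (band_probs / w.sum(axis=1))[:, None]
        w *= (cci_probs / w.sum(axis=0))[None, :]
    return w / w.sum(axis=1, keepdims=True)


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw covariate rows: age from the truncated skew-normal, comorbidity
    conditional on age band (the built-in confounding), everything else
    independent from its marginal distribution."""
    n = config.n
    age = _truncated_skewnorm(config.age_dist, n, rng)
    out = {"age_years": np.round(age, 1)}
    band_idx = np.searchsorted(_AGE_BAND_EDGES, out["age_years"], side="right")
    for cov, levels in COVARIATE_LEVELS.items():
        probs = config.covariate_marginals.get(cov)
        if probs is None:
            raise SimulationConfigError(f"no marginals configured for {cov!r}")
        p = np.array([probs[lev] for lev in levels], dtype=float)
        p = p / p.sum()
        if cov == "cci" and config.cci_age_tilt != 0.0:
            cond = _cci_conditional(_band_probs(config.age_dist), p, config.cci_age_tilt)
            u = rng.random(n)
            cum = np.cumsum(cond, axis=1)
            codes = (u[:, None] > cum[band_idx]).sum(axis=1)
        else:
            codes = rng.choice(len(levels), size=n, p=p)
        out[cov] = np.asarray(levels, dtype=object)[codes]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Event times
# ---------------------------------------------------------------------------


def _cumhaz_to(design, theta, subject, t, n_quad=20):
    qt, qs, qw = build_quadrature(
        np.zeros_like(t), t, _time_cutpoints(design.spec), n_quad
    )
    out = np.zeros(t.size)
    if qt.size:
        h = LogitProbabilityLink.hazard(design.rows(qt, subject[qs]) @ theta)
        np.add.at(out, qs, qw * h)
    return out


def invert_cumulative_hazard(
    spec: ModelSpec,
    coefs,
    covariates: pd.DataFrame,
    exponential_draws,
    horizon: float,
    tol: float = 1e-8,
) -> np.ndarray:
    """Solve H(0, t) = E per subject by bracketing + bisection.

    Subjects whose cumulative hazard stays below their exponential draw
    within ``horizon`` get ``t = inf`` (censored downstream).
    """
    design = ModelDesign(spec)
    theta = (
        design.coefficients_from_dict(coefs)
        if isinstance(coefs, dict)
        else np.asarray(coefs, dtype=float)
    )
    subject = design.subject_block(covariates)
    E = np.asarray(exponential_draws, dtype=float)
    if np.any(E < 0):
        raise ValueError("exponential draws must be nonnegative")
    n = subject.shape[0]
    t = np.full(n, np.inf)
    H_max = _cumhaz_to(design, theta, subject, np.full(n, float(horizon)))
    active = E <= H_max
    t[E == 0.0] = 0.0
    solve = active & (E > 0.0)
    lo = np.zeros(solve.sum())
    hi = np.full(solve.sum(), float(horizon))
    sub_active = subject[solve]
    e_active = E[solve]
    for _ in range(64):
        if np.all(hi - lo <= tol):
            break
        mid = 0.5 * (lo + hi)
        H_mid = _cumhaz_to(design, theta, sub_active, mid)
        above = H_mid >= e_active
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    t[solve] = 0.5 * (lo + hi)
    return t


def simulate_event_time(
    spec: ModelSpec,
    coefs,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
    horizon: float = 50.0,
) -> np.ndarray:
    """Death times (years) from the instantaneous-probability model by
    inverse-transform sampling: t solves H(0, t) = E, E ~ Exponential(1)."""
    E = rng.exponential(size=len(covariates))
    return invert_cumulative_hazard(spec, coefs, covariates, E, horizon)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def assemble_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a full cohort table in the analysis schema.

    One master seed spawns named substreams (covariates, event times,
    causes) so adding a draw in one stage does not perturb the others.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_event, rng_cause = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    cov = simulate_covariates(config, rng_cov)
    horizon = float(config.admin_censor_years) + 1.0
    t_death = simulate_event_time(
        config.truth_spec, config.truth_coefs, cov, rng_event, horizon=horizon
    )
    censor = float(config.admin_censor_years)
    dead = (t_death <= censor).astype(int)
    followup_years = np.minimum(t_death, censor)
    followup_days = np.rint(DAYS_PER_YEAR * followup_years).astype(int)

    if isinstance(config.cancer_death_prob, dict):
        p_cancer = np.array(
            [config.cancer_death_prob[s] for s in cov["stage"]], dtype=float
        )
    else:
        p_cancer = np.full(len(cov), float(config.cancer_death_prob))
    cancer_draw = (rng_cause.random(len(cov)) < p_cancer).astype(int)
    cancer_death = cancer_draw * dead

    df = pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(len(cov))],
            "age_years": cov["age_years"],
            **{c: cov[c] for c in COVARIATE_LEVELS},
            "followup_days": followup_days,
            "dead": dead,
            "cancer_death": cancer_death,
        }
    )
    return df[list(COHORT_COLUMNS)]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
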