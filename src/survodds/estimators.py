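"""Scikit-learn-style estimators for instantaneous-probability and
proportional-hazards survival regression.

``ProbabilityRegression`` models ``logit(g) = eta`` where ``g(t)`` is the
instantaneous probability of dying at time ``t`` (so ``exp(coef)`` is an odds
ratio of ``g``, constant over follow-up time).  ``HazardRegression`` models
``log h(t) = eta`` (so ``exp(coef)`` is a hazard ratio).  Both share one
censored/left-truncated likelihood engine with a spline or linear baseline in
time, maximised by a trust-region Newton method with analytic gradient and
Hessian.

The outcome ``y`` is a structured array with fields ``entry``, ``time`` and
``event`` (years, years, 0/1), built with :func:`survival_outcome`.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .model import (
    LikelihoodObjective,
    LogHazardLink,
    LogitProbabilityLink,
    ModelDesign,
    ModelSpec,
    build_likelihood_parts,
    check_full_rank,
    cumulative_hazard_value,
)

OUTCOME_DTYPE = np.dtype([("entry", float), ("time", float), ("event", bool)])


class ConvergenceWarning(UserWarning):
    pass


def survival_outcome(time, event, entry=None) -> np.ndarray:
    """Pack (entry, time, event) into the structured outcome array.

    Times are in years; ``entry`` defaults to 0 (no delayed entry).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    entry = np.zeros_like(time) if entry is None else np.asarray(entry, dtype=float)
    out = np.empty(time.shape[0], dtype=OUTCOME_DTYPE)
    out["entry"], out["time"], out["event"] = entry, time, event.astype(bool)
    return out


def _as_outcome(y) -> np.ndarray:
    if isinstance(y, pd.DataFrame):
        entry = y["entry"] if "entry" in y.columns else None
        return survival_outcome(y["time"], y["event"], entry)
    y = np.asarray(y)
    if y.dtype.names and set(y.dtype.names) >= {"entry", "time", "event"}:
        return y
    raise ValueError(
        "y must be a structured array with fields (entry, time, event) "
        "or a DataFrame with those columns; see survival_outcome()"
    )


class _BaseEventRegression(BaseEstimator):
    _link = None  # set by subclasses

    def __init__(
        self,
        time_form="linear",
        time_knots=None,
        n_time_knots=3,
        age_form="linear",
        age_knots=None,
        n_age_knots=3,
        covariates=(),
        interactions=(),
        max_iter=200,
        grad_tol=1e-5,
        init=None,
        n_restarts=5,
        random_state=0,
        n_quad=20,
    ):
        self.time_form = time_form
        self.time_knots = time_knots
        self.n_time_knots = n_time_knots
        self.age_form = age_form
        self.age_knots = age_knots
        self.n_age_knots = n_age_knots
        self.covariates = covariates
        self.interactions = interactions
        self.max_iter = max_iter
        self.grad_tol = grad_tol
        self.init = init
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.n_quad = n_quad

    # -- fitting ----------------------------------------------------------
    def _make_spec(self) -> ModelSpec:
        return ModelSpec(
            time_form=self.time_form,
            time_knots=self.time_knots,
            n_time_knots=self.n_time_knots,
            age_form=self.age_form,
            age_knots=self.age_knots,
            n_age_knots=self.n_age_knots,
            covariates=tuple(self.covariates),
            interactions=tuple(tuple(p) for p in self.interactions),
        )

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = _as_outcome(y)
        if len(X) != y.shape[0]:
            raise ValueError("X and y have different lengths")
        entry, time, event = y["entry"], y["time"], y["event"].astype(bool)
        if y.shape[0] == 0:
            raise ValueError("empty dataset")
        if event.sum() < 1:
            raise ValueError("no events in the data; the model is not estimable")
        spec = self._make_spec().resolve(
            event_times=time[event],
            ages=X["age_years"] if "age_years" in X.columns else None,
        )
        design = ModelDesign(spec)
        parts = build_likelihood_parts(
            design, X, entry, time, event, n_quad=self.n_quad
        )
        check_full_rank(parts.quad_design, design.names)
        objective = LikelihoodObjective(parts, self._link)

        theta0 = self._initial_theta(design, parts)
        theta, converged, grad_norm = self._optimize(objective, theta0)

        neg_hess = objective.neg_hess(theta)
        try:
            covariance = np.linalg.inv(neg_hess)
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by rank check
            covariance = np.linalg.pinv(neg_hess)
            converged = False
        self.spec_ = spec
        self.design_ = design
        self.coef_ = theta
        self.coef_names_ = list(design.names)
        self.covariance_ = covariance
        self.loglik_ = objective.loglik(theta)
        self.aic_ = 2.0 * theta.size - 2.0 * self.loglik_
        self.converged_ = bool(converged)
        self.grad_norm_ = float(grad_norm)
        self.n_subjects_ = parts.n_subjects
        self.n_events_ = parts.n_events
        self.total_time_ = parts.total_time
        self.time_knots_ = spec.time_knots
        self.age_knots_ = spec.age_knots
        self.time_range_ = (0.0, float(np.max(time)))
        self.data_signature_ = hashlib.sha256(
            np.ascontiguousarray(entry).tobytes()
            + np.ascontiguousarray(time).tobytes()
            + np.ascontiguousarray(event).tobytes()
        ).hexdigest()
        self._objective = objective
        if not converged:
            warnings.warn(
                f"optimizer did not reach gradient tolerance "
                f"(|grad| = {grad_norm:.3g} > {self.grad_tol:g})",
                ConvergenceWarning,
            )
        return self

    def _initial_theta(self, design: ModelDesign, parts) -> np.ndarray:
        theta0 = np.zeros(design.n_params)
        if self.init is not None:
            init = np.asarray(self.init, dtype=float)
            if init.shape != theta0.shape:
                raise ValueError(
                    f"init has length {init.size}, expected {theta0.size}"
                )
            return init
        rate = max(parts.n_events / max(parts.total_time, 1e-12), 1e-10)
        if self._link is LogitProbabilityLink:
            # softplus(theta0) = D/T  <=>  theta0 = log(exp(D/T) - 1)
            theta0[0] = np.log(np.expm1(rate)) if rate < 30 else rate
        else:
            theta0[0] = np.log(rate)
        return theta0

    def _optimize(self, objective: LikelihoodObjective, theta0):
        def run(start):
            res = optimize.minimize(
                objective.neg,
                start,
                jac=objective.neg_grad,
                hess=objective.neg_hess,
                method="trust-exact",
                options={"gtol": self.grad_tol * 0.1, "maxiter": self.max_iter},
            )
            gn = float(np.linalg.norm(objective.grad(res.x)))
            return res.x, gn

        theta, grad_norm = run(theta0)
        if grad_norm < self.grad_tol:
            return theta, True, grad_norm
        # multi-start fallback from perturbed initial values
        rng = np.random.default_rng(self.random_state)
        best_theta, best_gn = theta, grad_norm
        best_ll = objective.loglik(theta)
        for _ in range(self.n_restarts):
            cand, gn = run(theta0 + rng.normal(scale=0.1, size=theta0.size))
            ll = objective.loglik(cand)
            if gn < self.grad_tol and ll >= best_ll - 1e-9:
                return cand, True, gn
            if ll > best_ll:
                best_theta, best_gn, best_ll = cand, gn, ll
        return best_theta, best_gn < self.grad_tol, best_gn

    # -- shared post-fit API ----------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted yet; call fit() first")

    def _coef_index(self, term: str) -> int:
        self._check_fitted()
        if term not in self.coef_names_:
            raise KeyError(
                f"unknown term {term!r}; available terms: {self.coef_names_}"
            )
        return self.coef_names_.index(term)

    def predict_linear_predictor(self, X: pd.DataFrame, times) -> np.ndarray:
        self._check_fitted()
        X = pd.DataFrame(X).reset_index(drop=True)
        subject = self.design_.subject_block(X)
        times = np.broadcast_to(
            np.asarray(times, dtype=float), (subject.shape[0],)
        )
        return self.design_.rows(times, subject) @ self.coef_

    def predict_hazard(self, X, times) -> np.ndarray:
        """Instantaneous hazard h(t | x), per year."""
        return self._link.hazard(self.predict_linear_predictor(X, times))

    def predict_probability(self, X, times) -> np.ndarray:
        """Instantaneous probability of dying g(t | x) = 1 - exp(-h)."""
        return self._link.probability(self.predict_linear_predictor(X, times))

    def predict_cumulative_hazard(self, X, t_end, t_start=0.0) -> np.ndarray:
        self._check_fitted()
        X = pd.DataFrame(X).reset_index(drop=True)
        return cumulative_hazard_value(
            self.design_,
            self.coef_,
            X,
            t_start,
            t_end,
            link=self._link,
            n_quad=self.n_quad,
        )

    def predict_survival(self, X, times) -> np.ndarray:
        """S(t | x) = exp(-H(0, t))."""
        return np.exp(-self.predict_cumulative_hazard(X, times))

    def score(self, X, y) -> float:
        """Mean log-likelihood per subject on (X, y)."""
        self._check_fitted()
        X = pd.DataFrame(X).reset_index(drop=True)
        y = _as_outcome(y)
        parts = build_likelihood_parts(
            self.design_, X, y["entry"], y["time"], y["event"], n_quad=self.n_quad
        )
        return LikelihoodObjective(parts, self._link).loglik(self.coef_) / max(
            parts.n_subjects, 1
        )

    def effect_estimates(self, terms=None, delta=1.0, level=0.95) -> pd.DataFrame:
        """Exponentiated coefficients with Wald confidence intervals.

        ``delta`` scales the contrast (e.g. OR per ``delta`` years of age).
        """
        self._check_fitted()
        z = stats.norm.ppf(0.5 + level / 2.0)
        if terms is None:
            terms = [n for n in self.coef_names_ if n != "(Intercept)"]
        rows = []
        for term in terms:
            i = self._coef_index(term)
            beta = self.coef_[i] * delta
            se = np.sqrt(self.covariance_[i, i]) * abs(delta)
            rows.append(
                {
                    "term": term,
                    "estimate": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - z * se)),
                    "ci_high": float(np.exp(beta + z * se)),
                    "scale": self._link.scale,
                }
            )
        return pd.DataFrame(rows)

    def _profile_frame(self, profile: dict | pd.DataFrame | None) -> pd.DataFrame:
        from .model import AGE_CENTER, COVARIATE_LEVELS

        if isinstance(profile, pd.DataFrame):
            return profile.reset_index(drop=True)
        row = {"age_years": AGE_CENTER}
        for cov in self.spec_.covariates:
            row[cov] = COVARIATE_LEVELS[cov][0]
        if profile:
            row.update(profile)
        return pd.DataFrame([row])

    def probability_curve(
        self, profile=None, t_grid=None, level=0.95, t_start=0.0
    ) -> pd.DataFrame:
        """Curve of (t, g, h, S) for one covariate profile, with pointwise
        delta-method confidence bounds for g.

        ``profile`` is a dict of covariate values (unlisted covariates take
        their reference level; age defaults to 65).  ``S`` is survival from
        ``t_start`` (use the delayed-entry time for landmark endpoints).
        Times outside the fitted range trigger a warning, not an error.
        """
        self._check_fitted()
        if t_grid is None:
            t_grid = np.linspace(0.0, self.time_range_[1], 101)
        t_grid = np.asarray(t_grid, dtype=float).ravel()
        if t_grid.size and t_grid.max() > self.time_range_[1] * (1 + 1e-9):
            warnings.warn(
                f"t_grid extends beyond the fitted time range "
                f"(max {self.time_range_[1]:.3g} y); extrapolating",
                UserWarning,
            )
        frame = self._profile_frame(profile)
        subject = self.design_.subject_block(frame)
        rows = self.design_.rows(t_grid, np.repeat(subject, t_grid.size, axis=0))
        eta = rows @ self.coef_
        se_eta = np.sqrt(np.einsum("ij,jk,ik->i", rows, self.covariance_, rows))
        z = stats.norm.ppf(0.5 + level / 2.0)
        g = self._link.probability(eta)
        h = self._link.hazard(eta)
        H = cumulative_hazard_value(
            self.design_,
            self.coef_,
            pd.concat([frame] * t_grid.size, ignore_index=True),
            np.minimum(float(t_start), t_grid),
            t_grid,
            link=self._link,
            n_quad=self.n_quad,
        )
        return pd.DataFrame(
            {
                "t": t_grid,
                "g": g,
                "g_low": self._link.probability(eta - z * se_eta),
                "g_high": self._link.probability(eta + z * se_eta),
                "h": h,
                "S": np.exp(-H),
            }
        )


class ProbabilityRegression(_BaseEventRegression):
    """Regression for the instantaneous probability of dying.

    Models ``logit g(t|x) = gamma0 + B(t).gamma + x.beta``; ``exp(beta)`` is
    the odds ratio of the instantaneous death probability, constant over
    time.  The hazard is ``h = softplus(eta)`` and the likelihood handles
    right censoring and delayed entry.
    """

    _link = LogitProbabilityLink

    def odds_ratios(self, terms=None, delta=1.0, level=0.95) -> pd.DataFrame:
        return self.effect_estimates(terms=terms, delta=delta, level=level)


class HazardRegression(_BaseEventRegression):
    """Parametric proportional-hazards regression with the same baseline
    machinery: ``log h(t|x) = gamma0 + B(t).gamma + x.beta``; ``exp(beta)``
    is a hazard ratio."""

    _link = LogHazardLink

    def hazard_ratios(self, terms=None, delta=1.0, level=0.95) -> pd.DataFrame:
        return self.effect_estimates(terms=terms, delta=delta, level=level)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def fit_mle(
    X,
    y,
    spec: ModelSpec | None = None,
    link: str = "odds-of-probability",
    **options,
):
    """Fit a model by maximum likelihood and return the fitted estimator."""
    spec = spec if spec is not None else ModelSpec()
    cls = ProbabilityRegression if link == "odds-of-probability" else HazardRegression
    est = cls(
        time_form=spec.time_form,
        time_knots=spec.time_knots,
        n_time_knots=spec.n_time_knots,
        age_form=spec.age_form,
        age_knots=spec.age_knots,
        n_age_knots=spec.n_age_knots,
        covariates=spec.covariates,
        interactions=spec.interactions,
        **options,
    )
    return est.fit(X, y)


def log_likelihood(
    X,
    y,
    spec: ModelSpec | None = None,
    params=None,
    link: str = "odds-of-probability",
    n_quad: int = 20,
) -> float:
    """Censored/left-truncated log-likelihood at the given coefficients.

    ``params`` is a coefficient vector in design order or a ``{name: value}``
    dict (unlisted coefficients are zero).  An empty dataset has
    log-likelihood 0.
    """
    spec = spec if spec is not None else ModelSpec()
    X = pd.DataFrame(X).reset_index(drop=True)
    y = _as_outcome(y)
    event_times = y["time"][y["event"].astype(bool)]
    spec = spec.resolve(
        event_times=event_times if event_times.size else None,
        ages=X["age_years"] if "age_years" in X.columns else None,
    )
    design = ModelDesign(spec)
    theta = (
        design.coefficients_from_dict(params)
        if isinstance(params, dict)
        else np.asarray(params, dtype=float)
    )
    if theta.size != design.n_params:
        raise ValueError(
            f"params has length {theta.size}, expected {design.n_params}"
        )
    if len(X) == 0:
        return 0.0
    parts = build_likelihood_parts(design, X, y["entry"], y["time"], y["event"], n_quad)
    lnk = LogitProbabilityLink if link == "odds-of-probability" else LogHazardLink
    return LikelihoodObjective(parts, lnk).loglik(theta)


def odds_ratio(fit, term: str, delta: float = 1.0) -> dict:
    """One term's exponentiated effect with its 95% Wald interval."""
    row = fit.effect_estimates(terms=[term], delta=delta).iloc[0]
    return row.to_dict()


def probability_curve(fit, profile=None, t_grid=None) -> pd.DataFrame:
    return fit.probability_curve(profile=profile, t_grid=t_grid)
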