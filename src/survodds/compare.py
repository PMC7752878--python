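"""Bridge between odds ratios of the instantaneous death probability and
hazard ratios.

Under proportional hazards, ``h1(t) = HR * h0(t)`` and ``g = 1 - exp(-h)``
imply the power identity ``1 - g1 = (1 - g0) ** HR``: the hazard ratio equals
the power relating the complements of the two instantaneous probabilities.
For small probabilities and effects near one, the OR of ``g`` and the HR are
numerically close; they diverge when ``g`` is large.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import HazardRegression, ModelSpec, ProbabilityRegression


def fit_ph_model(X, y, spec: ModelSpec | None = None, **options) -> HazardRegression:
    """Fit the proportional-hazards variant (log-hazard link, shared
    likelihood machinery); ``exp(coef)`` are hazard ratios."""
    spec = spec if spec is not None else ModelSpec()
    est = HazardRegression(
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


def power_from_hr(g0, hr):
    """Probability for the contrast profile implied by the power identity:
    ``g1 = 1 - (1 - g0) ** hr``."""
    g0 = np.asarray(g0, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(g0 < 0.0) or np.any(g0 >= 1.0):
        raise ValueError("g0 must satisfy 0 <= g0 < 1")
    if np.any(hr <= 0.0):
        raise ValueError("hr must be positive")
    out = -np.expm1(hr * np.log1p(-g0))
    return float(out) if out.ndim == 0 else out


def _shifted_profile(fit, profile: dict | None, term: str, delta: float) -> dict:
    from .model import COVARIATE_LEVELS

    base = dict(profile or {})
    if term == "age":
        base["age_years"] = base.get("age_years", 65.0) + delta
        return base
    # covariate dummy term like "sex[female]"
    if "[" in term:
        cov, level = term[:-1].split("[", 1)
        if cov in COVARIATE_LEVELS and level in COVARIATE_LEVELS[cov]:
            base[cov] = level
            return base
    raise KeyError(
        f"cannot build a contrast profile for term {term!r}; "
        "use 'age' or a covariate dummy like 'sex[female]'"
    )


def compare_or_power(
    prob_fit: ProbabilityRegression,
    ph_fit: HazardRegression,
    term: str,
    t_grid,
    profile: dict | None = None,
    delta: float = 1.0,
    similar_tol: float = 0.05,
) -> pd.DataFrame:
    """Tabulate OR vs HR for one term over a time grid.

    Per time point: the instantaneous probability at the reference and
    contrast profiles (probability model), the OR of g (time-constant), the
    HR, the contrast probability implied by the power identity applied to
    the reference probability, and a flag marking relative OR–HR agreement
    within ``similar_tol``.
    """
    if not hasattr(prob_fit, "coef_") or not hasattr(ph_fit, "coef_"):
        raise ValueError("both models must be fitted")
    if prob_fit.data_signature_ != ph_fit.data_signature_:
        raise ValueError("fits are on different datasets; comparison undefined")
    coef_term = "age" if term == "age" else term
    or_value = float(np.exp(delta * prob_fit.coef_[prob_fit._coef_index(coef_term)]))
    hr_value = float(np.exp(delta * ph_fit.coef_[ph_fit._coef_index(coef_term)]))
    t_grid = np.asarray(t_grid, dtype=float).ravel()
    ref = prob_fit._profile_frame(profile)
    contrast = prob_fit._profile_frame(_shifted_profile(prob_fit, profile, term, delta))
    g_ref = prob_fit.predict_probability(
        pd.concat([ref] * t_grid.size, ignore_index=True), t_grid
    )
    g_contrast = prob_fit.predict_probability(
        pd.concat([contrast] * t_grid.size, ignore_index=True), t_grid
    )
    implied = power_from_hr(g_ref, hr_value)
    similar = abs(or_value - hr_value) / hr_value < similar_tol
    return pd.DataFrame(
        {
            "t": t_grid,
            "g_ref": g_ref,
            "g_contrast": g_contrast,
            "or": or_value,
            "hr": hr_value,
            "implied_power_probability": implied,
            "similar_flag": similar,
        }
    )
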