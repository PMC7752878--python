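"""Model selection (AIC) and likelihood-ratio tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .estimators import _BaseEventRegression


def aic_select(X, y, candidates, return_table: bool = True):
    """Fit every candidate estimator and pick the one with minimal AIC.

    Parameters
    ----------
    candidates : sequence of unfitted estimators
        Each is cloned before fitting.
    Returns
    -------
    (best_fitted_estimator, table) where ``table`` records label, n_params,
    loglik, AIC and convergence for every candidate.  Candidates that fail
    to fit or converge are recorded and excluded from selection (with a
    warning).  Ties are broken in favour of fewer parameters, then first
    listed.
    """
    candidates = list(candidates)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    rows = []
    fits = []
    for i, cand in enumerate(candidates):
        if not isinstance(cand, _BaseEventRegression):
            raise TypeError(f"candidate {i} is not an event-regression estimator")
        est = clone(cand)
        label = est._make_spec().label()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X, y)
            ok = bool(est.converged_)
            rows.append(
                {
                    "candidate": i,
                    "label": label,
                    "n_params": len(est.coef_),
                    "loglik": est.loglik_,
                    "aic": est.aic_,
                    "converged": ok,
                    "error": "" if ok else "did not converge",
                }
            )
            fits.append(est if ok else None)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            rows.append(
                {
                    "candidate": i,
                    "label": label,
                    "n_params": np.nan,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
            fits.append(None)
    table = pd.DataFrame(rows)
    usable = table[table["converged"]]
    if usable.empty:
        raise RuntimeError(
            "no candidate model could be fitted:\n" + table.to_string(index=False)
        )
    if len(usable) < len(table):
        warnings.warn(
            f"{len(table) - len(usable)} candidate(s) failed and were excluded "
            "from AIC selection",
            UserWarning,
        )
    # minimal AIC; ties (within 1e-9) go to fewer parameters, then first listed
    order = usable.sort_values(
        by=["aic", "n_params", "candidate"], kind="stable"
    )
    best_aic = order["aic"].iloc[0]
    tied = order[order["aic"] <= best_aic + 1e-9]
    best_idx = int(tied.iloc[0]["candidate"])
    best = fits[best_idx]
    return (best, table) if return_table else best


def lr_test(fit_null, fit_alt) -> dict:
    """Likelihood-ratio test of a nested null model against an alternative.

    Both fits must be on the same data (checked by fingerprint) and the null
    model's terms must be a subset of the alternative's.  Returns
    ``{"statistic", "df", "p"}`` with the p-value from the chi-square upper
    tail.
    """
    for fit in (fit_null, fit_alt):
        if not hasattr(fit, "loglik_"):
            raise ValueError("both models must be fitted")
    if type(fit_null._link) is not type(fit_alt._link) and fit_null._link is not fit_alt._link:
        raise ValueError("models use different links; not comparable")
    if fit_null.data_signature_ != fit_alt.data_signature_:
        raise ValueError("models were fitted on different data")
    null_terms = set(fit_null.coef_names_)
    alt_terms = set(fit_alt.coef_names_)
    if not null_terms <= alt_terms:
        raise ValueError(
            "models are not nested; terms only in the null model: "
            f"{sorted(null_terms - alt_terms)}"
        )
    df = len(alt_terms) - len(null_terms)
    statistic = 2.0 * (fit_alt.loglik_ - fit_null.loglik_)
    if statistic < -1e-6:
        warnings.warn(
            f"negative LR statistic ({statistic:.3g}); optimizer tolerance "
            "or non-nested structure",
            UserWarning,
        )
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return {"statistic": float(statistic), "df": int(df), "p": p}
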