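"""Desk-scale orchestration of the full mortality study.

``run_study`` takes a cohort (CSV path, DataFrame, or a simulation config),
runs the three endpoint analyses — crude and adjusted models with linear and
categorical age, AIC selection of the baseline time form, stratified
analyses — and writes a deterministic report bundle: descriptive table, OR
tables, stratified tables, AIC log, probability/survival curve tables and a
run manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .endpoints import (
    DAYS_PER_YEAR,
    ENDPOINTS,
    descriptive_summary,
    prepare_endpoint,
    read_cohort_csv,
    validate_cohort,
)
from .estimators import ProbabilityRegression
from .model import AGE_CATEGORIES, ModelConfigurationError
from .selection import aic_select

#: default adjustment sets per endpoint (the disease-specific endpoint swaps
#: the comorbidity index for neoadjuvant therapy)
DEFAULT_ADJUSTMENT: dict[str, tuple[str, ...]] = {
    "d90_all_cause": ("sex", "education", "cci", "histology", "stage", "margin"),
    "y5_all_cause": ("sex", "education", "cci", "histology", "stage", "margin"),
    "y5_disease_specific": (
        "sex",
        "education",
        "neoadjuvant",
        "histology",
        "stage",
        "margin",
    ),
}

#: candidate baseline time forms per endpoint, primary form first
DEFAULT_TIME_CANDIDATES: dict[str, tuple[str, ...]] = {
    "d90_all_cause": ("linear", "rcs3"),
    "y5_all_cause": ("rcs3", "linear", "rcs4"),
    "y5_disease_specific": ("rcs4", "linear", "rcs3"),
}

OR_TABLE_COLUMNS = (
    "term",
    "deaths_n",
    "deaths_pct",
    "or_unadjusted",
    "ci_low_unadjusted",
    "ci_high_unadjusted",
    "or_adjusted",
    "ci_low_adjusted",
    "ci_high_adjusted",
)
OR_TABLE_ROWS = ("age_linear", "age[<70]", "age[70-74]", "age[>=75]")


@dataclass
class AnalysisPlan:
    """What to run: endpoints, age forms, adjustment sets, strata and the
    candidate baseline time forms offered to AIC selection."""

    endpoints: tuple[str, ...] = (
        "d90_all_cause",
        "y5_all_cause",
        "y5_disease_specific",
    )
    adjustment: dict = field(default_factory=lambda: dict(DEFAULT_ADJUSTMENT))
    time_candidates: dict = field(
        default_factory=lambda: dict(DEFAULT_TIME_CANDIDATES)
    )
    strata: tuple[str, ...] = ("sex", "histology", "stage", "margin")
    stratified_endpoints: tuple[str, ...] = ("d90_all_cause", "y5_all_cause")
    drop_stratifier: bool = True  # drop the stratifying variable within strata
    curve_ages: tuple[float, ...] = (60.0, 70.0, 80.0)

    def __post_init__(self):
        for ep in (*self.endpoints, *self.stratified_endpoints):
            if ep not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {ep!r}")
        from .model import COVARIATE_LEVELS

        for s in self.strata:
            if s not in COVARIATE_LEVELS:
                raise ValueError(f"unknown stratum variable {s!r}")


def _time_form_kwargs(code: str) -> dict:
    if code == "linear":
        return {"time_form": "linear"}
    if code.startswith("rcs"):
        return {"time_form": "rcs", "n_time_knots": int(code[3:])}
    raise ValueError(f"unknown time form code {code!r}")


def _estimator(time_code, age_form, covariates):
    return ProbabilityRegression(
        age_form=age_form, covariates=tuple(covariates), **_time_form_kwargs(time_code)
    )


def _or_rows(fit, age_form):
    """(term, or, lo, hi) rows for the age terms of one fitted model."""
    if age_form == "linear":
        e = fit.odds_ratios(["age"]).iloc[0]
        return {"age_linear": (e["estimate"], e["ci_low"], e["ci_high"])}
    out = {"age[<70]": (1.0, np.nan, np.nan)}
    for lab in AGE_CATEGORIES[1:]:
        e = fit.odds_ratios([f"age[{lab}]"]).iloc[0]
        out[f"age[{lab}]"] = (e["estimate"], e["ci_low"], e["ci_high"])
    return out


def _death_rows(frame):
    rows = {"age_linear": (int(frame["event"].sum()), len(frame))}
    for lab in AGE_CATEGORIES:
        sub = frame[frame["age_cat"] == lab]
        rows[f"age[{lab}]"] = (int(sub["event"].sum()), len(sub))
    return rows


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False)


def run_study(
    cohort,
    plan: AnalysisPlan | None = None,
    output_dir=None,
    seed: int | None = None,
    config_digest: str | None = None,
) -> dict:
    """Run the complete analysis and write the report bundle.

    ``cohort`` is a DataFrame or a CSV path.  Returns a report dict with the
    in-memory tables and per-endpoint status; files are written under
    ``output_dir`` when given.  Strata or endpoints without events are
    reported as non-estimable and the run continues.
    """
    plan = plan or AnalysisPlan()
    if isinstance(cohort, (str, Path)):
        records, _, _ = read_cohort_csv(cohort)
    else:
        records, _, _ = validate_cohort(pd.DataFrame(cohort))
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    report: dict = {"endpoints": {}, "n_subjects": len(records)}

    summary = descriptive_summary(records)
    report["descriptive"] = summary
    if outdir is not None:
        _write_csv(summary, outdir / "descriptive_summary.csv")
        (outdir / "descriptive_summary.json").write_text(
            json.dumps(summary.to_dict(orient="records"), indent=1, sort_keys=True)
        )
        outputs += ["descriptive_summary.csv", "descriptive_summary.json"]

    aic_rows = []
    for ep_name in plan.endpoints:
        ep_report: dict = {}
        report["endpoints"][ep_name] = ep_report
        prep = prepare_endpoint(records, ep_name)
        ep_report["n_subjects"] = prep.n_subjects
        ep_report["n_events"] = prep.n_events
        ep_report["n_excluded"] = len(prep.excluded)
        if prep.n_events == 0:
            ep_report["status"] = "no events; endpoint not estimable"
            continue
        X, y = prep.X(), prep.y()
        adjust = tuple(plan.adjustment[ep_name])

        # AIC selection of the baseline time form (adjusted linear-age model)
        candidates = [
            _estimator(code, "linear", adjust)
            for code in plan.time_candidates[ep_name]
        ]
        try:
            best, aic_table = aic_select(X, y, candidates)
        except RuntimeError as exc:
            ep_report["status"] = f"fit failure: {exc}"
            continue
        selected_code = plan.time_candidates[ep_name][
            int(aic_table.loc[aic_table["label"] == best._make_spec().label(),
                              "candidate"].iloc[0])
        ]
        aic_table.insert(0, "endpoint", ep_name)
        aic_table["selected"] = aic_table["label"] == best._make_spec().label()
        aic_rows.append(aic_table)
        ep_report["time_form"] = selected_code

        # crude/adjusted x linear/categorical age
        fits = {}
        failed = None
        for age_form in ("linear", "categorical"):
            for label, covs in (("unadjusted", ()), ("adjusted", adjust)):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fits[(age_form, label)] = _estimator(
                            selected_code, age_form, covs
                        ).fit(X, y)
                except (ValueError, ModelConfigurationError, RuntimeError) as exc:
                    failed = f"{age_form}/{label}: {exc}"
        if failed is not None:
            ep_report["status"] = f"fit failure: {failed}"
            continue
        deaths = _death_rows(prep.frame)
        table_rows = []
        ors = {
            label: {
                **_or_rows(fits[("linear", label)], "linear"),
                **_or_rows(fits[("categorical", label)], "categorical"),
            }
            for label in ("unadjusted", "adjusted")
        }
        from .endpoints import round_half_up_pct

        for term in OR_TABLE_ROWS:
            d_n, d_den = deaths[term]
            u = ors["unadjusted"].get(term, (np.nan,) * 3)
            a = ors["adjusted"].get(term, (np.nan,) * 3)
            table_rows.append(
                {
                    "term": term,
                    "deaths_n": d_n,
                    "deaths_pct": round_half_up_pct(d_n, d_den) if d_den else np.nan,
                    "or_unadjusted": u[0],
                    "ci_low_unadjusted": u[1],
                    "ci_high_unadjusted": u[2],
                    "or_adjusted": a[0],
                    "ci_low_adjusted": a[1],
                    "ci_high_adjusted": a[2],
                }
            )
        or_table = pd.DataFrame(table_rows, columns=list(OR_TABLE_COLUMNS))
        ep_report["or_table"] = or_table
        ep_report["status"] = "ok"
        if outdir is not None:
            name = f"or_table_{ep_name}.csv"
            _write_csv(or_table, outdir / name)
            outputs.append(name)

        # probability / survival curves for the adjusted linear-age model
        fit_adj = fits[("linear", "adjusted")]
        entry_years = ENDPOINTS[ep_name].entry_days / DAYS_PER_YEAR
        horizon_years = ENDPOINTS[ep_name].horizon_days / DAYS_PER_YEAR
        curve_parts = []
        for age in plan.curve_ages:
            t_grid = np.linspace(entry_years, horizon_years, 101)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                c = fit_adj.probability_curve(
                    {"age_years": age}, t_grid, t_start=entry_years
                )
            c.insert(0, "age_profile", age)
            curve_parts.append(c)
        curves = pd.concat(curve_parts, ignore_index=True)
        ep_report["curves"] = curves
        if outdir is not None:
            name = f"curves_{ep_name}.csv"
            _write_csv(curves, outdir / name)
            outputs.append(name)

    aic_log = (
        pd.concat(aic_rows, ignore_index=True)
        if aic_rows
        else pd.DataFrame(
            columns=["endpoint", "candidate", "label", "n_params", "loglik",
                     "aic", "converged", "error", "selected"]
        )
    )
    report["aic_log"] = aic_log
    if outdir is not None:
        _write_csv(aic_log, outdir / "aic_log.csv")
        outputs.append("aic_log.csv")

    # stratified analyses (descriptive; categorical age, adjusted)
    for ep_name in plan.stratified_endpoints:
        ep_status = report["endpoints"].get(ep_name, {}).get("status")
        if ep_status != "ok":
            continue
        prep = prepare_endpoint(records, ep_name)
        selected_code = report["endpoints"][ep_name]["time_form"]
        strat_rows = []
        from .model import COVARIATE_LEVELS
        from .endpoints import round_half_up_pct

        for strat in plan.strata:
            adjust = tuple(plan.adjustment[ep_name])
            if plan.drop_stratifier:
                adjust = tuple(c for c in adjust if c != strat)
            for level in COVARIATE_LEVELS[strat]:
                sub = prep.frame[prep.frame[strat] == level].reset_index(drop=True)
                deaths = _death_rows(sub) if len(sub) else {}
                base = {"stratifier": strat, "stratum": level}
                n_events = int(sub["event"].sum()) if len(sub) else 0
                if n_events == 0:
                    for term in OR_TABLE_ROWS[1:]:
                        strat_rows.append(
                            {**base, "term": term, "deaths_n": 0, "deaths_pct": np.nan,
                             "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "estimable": False}
                        )
                    continue
                Xs = sub[["age_years", *COVARIATE_LEVELS]].reset_index(drop=True)
                ys = prep.y()[prep.frame[strat].to_numpy() == level]
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = _estimator(selected_code, "categorical", adjust).fit(
                            Xs, ys
                        )
                    rows = _or_rows(fit, "categorical")
                    ok = True
                except (ValueError, RuntimeError, np.linalg.LinAlgError):
                    rows = {t: (np.nan, np.nan, np.nan) for t in OR_TABLE_ROWS[1:]}
                    ok = False
                for term in OR_TABLE_ROWS[1:]:
                    d_n, d_den = deaths.get(term, (0, 0))
                    est, lo, hi = rows.get(term, (np.nan,) * 3)
                    strat_rows.append(
                        {**base, "term": term, "deaths_n": d_n,
                         "deaths_pct": round_half_up_pct(d_n, d_den) if d_den else np.nan,
                         "or": est, "ci_low": lo, "ci_high": hi, "estimable": ok}
                    )
        strat_table = pd.DataFrame(strat_rows)
        report["endpoints"][ep_name]["stratified"] = strat_table
        if outdir is not None:
            name = f"stratified_{ep_name}.csv"
            _write_csv(strat_table, outdir / name)
            outputs.append(name)

    # manifest: seed, config hash, versions — no timestamps (determinism)
    cohort_digest = hashlib.sha256(
        records.to_csv(index=False).encode()
    ).hexdigest()
    manifest = {
        "package": "survodds",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_digest,
        "cohort_sha256": cohort_digest,
        "n_subjects": len(records),
        "outputs": sorted(set(outputs)) + ["manifest.json"],
    }
    report["manifest"] = manifest
    if outdir is not None:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    return report
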