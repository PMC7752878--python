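"""Cohort schema, endpoint risk-set construction, and descriptive summaries.

The cohort table has one row per patient undergoing esophagectomy:
``id, age_years, sex, education, cci, neoadjuvant, histology, stage, margin,
followup_days, dead, cancer_death``.  Three mortality endpoints are studied:

* ``d90_all_cause`` — all-cause death within 90 days of surgery (day 90
  inclusive);
* ``y5_all_cause`` — all-cause death within 5 years (1826 days);
* ``y5_disease_specific`` — death with esophageal cancer as primary or
  contributing cause, among patients surviving the first 90 days (delayed
  entry at day 90; non-cancer deaths censored at death).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .estimators import survival_outcome
from .model import AGE_BREAKS, AGE_CATEGORIES, COVARIATE_LEVELS

DAYS_PER_YEAR = 365.25
LANDMARK_DAYS = 90
FIVE_YEARS_DAYS = 1826  # 5 * 365.25, rounded
#: deaths recorded on day 0 are moved to half a day (registry day resolution;
#: the hazard must be integrable from t = 0)
ZERO_TIME_DAYS = 0.5

COHORT_COLUMNS = (
    "id",
    "age_years",
    "sex",
    "education",
    "cci",
    "neoadjuvant",
    "histology",
    "stage",
    "margin",
    "followup_days",
    "dead",
    "cancer_death",
)

STUDY_AGE_RANGE = (18.0, 89.0)

AGE_BANDS = ("<60", "60-69", "70-74", "75+")


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Endpoint:
    name: str
    horizon_days: int
    entry_days: int
    event_rule: str  # "all" or "cancer"

    def __post_init__(self):
        if self.entry_days >= self.horizon_days:
            raise ValueError("entry must precede the horizon")
        if self.event_rule not in ("all", "cancer"):
            raise ValueError(f"unknown event rule {self.event_rule!r}")


ENDPOINTS: dict[str, Endpoint] = {
    "d90_all_cause": Endpoint("d90_all_cause", LANDMARK_DAYS, 0, "all"),
    "y5_all_cause": Endpoint("y5_all_cause", FIVE_YEARS_DAYS, 0, "all"),
    "y5_disease_specific": Endpoint(
        "y5_disease_specific", FIVE_YEARS_DAYS, LANDMARK_DAYS, "cancer"
    ),
}


def age_category(age_years):
    """Age in the three analysis categories: [0,70) -> "<70",
    [70,75) -> "70-74", [75,inf) -> ">=75"."""
    age = np.asarray(age_years, dtype=float)
    if np.any(~np.isfinite(age)) or np.any(age < 0):
        raise ValueError("age must be finite and nonnegative")
    cat = np.where(
        age < AGE_BREAKS[0],
        AGE_CATEGORIES[0],
        np.where(age < AGE_BREAKS[1], AGE_CATEGORIES[1], AGE_CATEGORIES[2]),
    )
    return cat.item() if np.isscalar(age_years) else cat


def _age_band(age):
    age = np.asarray(age, dtype=float)
    return np.select(
        [age < 60, age < 70, age < 75], AGE_BANDS[:3], default=AGE_BANDS[3]
    )


def round_half_up_pct(numerator, denominator, decimals: int = 1) -> float:
    """Percentage 100*numerator/denominator, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator))
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_cohort(df: pd.DataFrame, strict: bool = True):
    """Schema and invariant checks on a cohort table.

    Returns ``(valid_rows, errors, warnings_)`` where ``errors`` and
    ``warnings_`` are lists of ``(row_index, message)``.  With
    ``strict=True`` any structural error raises :class:`CohortValidationError`.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort table is missing columns: {missing}")
    errors: list[tuple[int, str]] = []
    warns: list[tuple[int, str]] = []
    df = df.copy()
    age = pd.to_numeric(df["age_years"], errors="coerce")
    fup = pd.to_numeric(df["followup_days"], errors="coerce")
    dead = pd.to_numeric(df["dead"], errors="coerce")
    cancer = pd.to_numeric(df["cancer_death"], errors="coerce")
    for i in df.index[age.isna() | (age < 0)]:
        errors.append((int(i), "age_years must be a nonnegative number"))
    for i in df.index[fup.isna() | (fup < 0)]:
        errors.append((int(i), "followup_days must be a nonnegative number"))
    for i in df.index[~dead.isin((0, 1))]:
        errors.append((int(i), "dead must be 0 or 1"))
    for i in df.index[~cancer.isin((0, 1))]:
        errors.append((int(i), "cancer_death must be 0 or 1"))
    ok_flags = dead.isin((0, 1)) & cancer.isin((0, 1))
    for i in df.index[ok_flags & (cancer == 1) & (dead == 0)]:
        errors.append((int(i), "cancer_death=1 requires dead=1"))
    for cov, levels in COVARIATE_LEVELS.items():
        bad = ~df[cov].astype(str).isin(levels)
        for i in df.index[bad]:
            errors.append(
                (int(i), f"{cov}={df.loc[i, cov]!r} is not one of {levels}")
            )
    in_range = (age >= STUDY_AGE_RANGE[0]) & (age <= STUDY_AGE_RANGE[1])
    for i in df.index[age.notna() & (age >= 0) & ~in_range]:
        warns.append(
            (
                int(i),
                f"age_years={age[i]:g} outside the study range "
                f"{STUDY_AGE_RANGE[0]:g}-{STUDY_AGE_RANGE[1]:g}",
            )
        )
    if errors and strict:
        head = "; ".join(f"row {i}: {m}" for i, m in errors[:5])
        raise CohortValidationError(
            f"{len(errors)} invalid row(s), e.g. {head}"
        )
    bad_rows = {i for i, _ in errors}
    valid = df.loc[[i for i in df.index if i not in bad_rows]].copy()
    valid["age_years"] = pd.to_numeric(valid["age_years"])
    valid["followup_days"] = pd.to_numeric(valid["followup_days"])
    valid["dead"] = pd.to_numeric(valid["dead"]).astype(int)
    valid["cancer_death"] = pd.to_numeric(valid["cancer_death"]).astype(int)
    return valid, errors, warns


def read_cohort_csv(path, strict: bool = True):
    """Read and validate a cohort CSV; returns (records, errors, warnings)."""
    df = pd.read_csv(path, dtype={"id": str})
    return validate_cohort(df, strict=strict)


# ---------------------------------------------------------------------------
# Endpoint preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparedDataset:
    """Analysis-ready dataset for one endpoint.

    ``frame`` has per-subject entry/exit times in years, the event indicator
    and the covariates; ``excluded`` logs every input row left out and why,
    so counts reconcile: ``len(frame) + len(excluded) == n input rows``.
    """

    endpoint: Endpoint
    frame: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def X(self) -> pd.DataFrame:
        cols = ["age_years", *COVARIATE_LEVELS]
        return self.frame[cols].reset_index(drop=True)

    def y(self) -> np.ndarray:
        return survival_outcome(
            self.frame["time"], self.frame["event"], self.frame["entry"]
        )


def prepare_endpoint(records: pd.DataFrame, endpoint: Endpoint | str) -> PreparedDataset:
    """Build the risk set for one endpoint from validated cohort records.

    Rules (days): ``d90_all_cause`` — exit = min(followup, 90), event = death
    on or before day 90.  ``y5_all_cause`` — exit = min(followup, 1826),
    event = death within the window.  ``y5_disease_specific`` — subjects with
    followup <= 90 days are excluded, entry = day 90, exit = min(followup,
    1826), event = cancer-cause death in (90, 1826]; non-cancer deaths are
    censoring.  Deaths recorded on day 0 are moved to day 0.5.
    """
    if isinstance(endpoint, str):
        if endpoint not in ENDPOINTS:
            raise KeyError(
                f"unknown endpoint {endpoint!r}; known: {sorted(ENDPOINTS)}"
            )
        endpoint = ENDPOINTS[endpoint]
    if len(records) == 0:
        raise ValueError("empty cohort")
    df = records.copy().reset_index(drop=True)
    fup = df["followup_days"].astype(float)
    dead = df["dead"].astype(int).to_numpy()
    cancer = df["cancer_death"].astype(int).to_numpy()
    fup = np.where((fup == 0) & (dead == 1), ZERO_TIME_DAYS, fup)

    reasons = np.full(len(df), "", dtype=object)
    if endpoint.entry_days > 0:
        reasons[fup <= endpoint.entry_days] = (
            f"died or left follow-up within the first {endpoint.entry_days} days"
        )
    reasons[(fup == 0) & (dead == 0)] = "zero follow-up without event"
    keep = reasons == ""

    exit_days = np.minimum(fup, endpoint.horizon_days)
    in_window = fup <= endpoint.horizon_days
    if endpoint.event_rule == "all":
        event = (dead == 1) & in_window
    else:
        event = (dead == 1) & (cancer == 1) & in_window

    frame = pd.DataFrame(
        {
            "id": df["id"],
            "entry": endpoint.entry_days / DAYS_PER_YEAR,
            "time": exit_days / DAYS_PER_YEAR,
            "event": event.astype(int),
            "age_years": df["age_years"].astype(float),
            "age_cat": age_category(df["age_years"].to_numpy(dtype=float)),
        }
    )
    for cov in COVARIATE_LEVELS:
        frame[cov] = df[cov].astype(str)
    excluded = pd.DataFrame(
        {"id": df.loc[~keep, "id"], "reason": reasons[~keep]}
    ).reset_index(drop=True)
    return PreparedDataset(
        endpoint=endpoint,
        frame=frame.loc[keep].reset_index(drop=True),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Descriptive summary (cohort-characteristics table)
# ---------------------------------------------------------------------------


def endpoint_death_counts(records: pd.DataFrame) -> dict:
    """Death counts and denominators for the three endpoints.

    The disease-specific denominator is the number of 90-day survivors
    (total minus 90-day deaths); its numerator counts cancer-cause deaths in
    days (90, 1826].
    """
    fup = records["followup_days"].astype(float).to_numpy()
    dead = records["dead"].astype(int).to_numpy()
    cancer = records["cancer_death"].astype(int).to_numpy()
    n = len(records)
    d90 = int(((dead == 1) & (fup <= LANDMARK_DAYS)).sum())
    y5 = int(((dead == 1) & (fup <= FIVE_YEARS_DAYS)).sum())
    survivors_90d = n - d90
    y5ds = int(
        (
            (dead == 1)
            & (cancer == 1)
            & (fup > LANDMARK_DAYS)
            & (fup <= FIVE_YEARS_DAYS)
        ).sum()
    )
    return {
        "n": n,
        "d90_all_cause": {"deaths": d90, "denominator": n},
        "y5_all_cause": {"deaths": y5, "denominator": n},
        "y5_disease_specific": {"deaths": y5ds, "denominator": survivors_90d},
    }


def descriptive_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by category plus endpoint mortality rates.

    Returns a long table with columns (section, category, count, pct);
    percentages are rounded half-up to one decimal.  Endpoint rates use the
    endpoint-appropriate denominator (90-day survivors for disease-specific
    mortality).
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    n = len(records)
    rows = [("total", "all", n, 100.0)]
    band = _age_band(records["age_years"].to_numpy(dtype=float))
    for lab in AGE_BANDS:
        c = int((band == lab).sum())
        rows.append(("age_band", lab, c, round_half_up_pct(c, n)))
    for cov, levels in COVARIATE_LEVELS.items():
        values = records[cov].astype(str)
        for lev in levels:
            c = int((values == lev).sum())
            rows.append((cov, lev, c, round_half_up_pct(c, n)))
    deaths = endpoint_death_counts(records)
    for name in ("d90_all_cause", "y5_all_cause", "y5_disease_specific"):
        d = deaths[name]
        rows.append(
            (
                "deaths",
                name,
                d["deaths"],
                round_half_up_pct(d["deaths"], d["denominator"]),
            )
        )
    return pd.DataFrame(rows, columns=["section", "category", "count", "pct"])
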