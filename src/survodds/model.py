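"""Model specification, design matrices, links, and the censored/truncated
likelihood for instantaneous-probability and proportional-hazards regression.

The linear predictor is

    eta(t, x) = gamma0 + B_time(t) . gamma + D(x) . beta + interactions,

where ``B_time`` is a linear or restricted-cubic-spline basis of time since
surgery and ``D(x)`` holds the age term(s) and dummy-coded covariates.  Two
links are supported:

* odds-of-probability: ``g = expit(eta)`` is the instantaneous probability of
  dying, so the hazard is ``h = -log(1 - g) = softplus(eta)`` and ``exp(beta)``
  is a time-constant odds ratio of ``g``;
* log-hazard: ``h = exp(eta)``, the proportional-hazards parametrisation,
  where ``exp(beta)`` is a hazard ratio.

The log-likelihood with right censoring and left truncation (delayed entry) is

    l = sum_i [ d_i * log h(t_i) - integral_{entry_i}^{t_i} h(u) du ],

with the cumulative hazard evaluated by Gauss–Legendre quadrature on
subintervals split at the spline knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit

from .splines import SplineSpec, rcs_basis, knots_from_quantiles

# ---------------------------------------------------------------------------
# Covariate coding shared across the package
# ---------------------------------------------------------------------------

#: Fixed category codings; the first level is the reference level.
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "education": ("<=9", "10-12", ">12"),
    "cci": ("0", "1", "2+"),
    "neoadjuvant": ("no", "yes"),
    "histology": ("adenocarcinoma", "squamous"),
    "stage": ("0-II", "III-IV"),
    "margin": ("R0", "R1-R2"),
}

AGE_CENTER = 65.0  # years; the intercept refers to a 65-year-old reference
AGE_BREAKS = (70.0, 75.0)
AGE_CATEGORIES = ("<70", "70-74", ">=75")

_VALID_TIME_FORMS = ("constant", "linear", "rcs")
_VALID_AGE_FORMS = ("none", "linear", "rcs", "categorical")


class ModelConfigurationError(ValueError):
    pass


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is not full rank; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


@dataclass(frozen=True)
class ModelSpec:
    """Formula of one model: time baseline, age form, adjustment covariates
    and interactions.

    ``time_knots`` / ``age_knots`` may be left ``None`` for spline forms, in
    which case they are resolved from the data at fit time (boundary knots at
    the observed min/max event times, interior knots at event-time quantiles).
    """

    time_form: str = "linear"
    time_knots: tuple[float, ...] | None = None
    n_time_knots: int = 3
    age_form: str = "linear"
    age_knots: tuple[float, ...] | None = None
    n_age_knots: int = 3
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(
            self, "interactions", tuple(tuple(p) for p in self.interactions)
        )
        if self.time_knots is not None:
            object.__setattr__(self, "time_knots", tuple(map(float, self.time_knots)))
        if self.age_knots is not None:
            object.__setattr__(self, "age_knots", tuple(map(float, self.age_knots)))
        if self.time_form not in _VALID_TIME_FORMS:
            raise ModelConfigurationError(f"unknown time_form {self.time_form!r}")
        if self.age_form not in _VALID_AGE_FORMS:
            raise ModelConfigurationError(f"unknown age_form {self.age_form!r}")
        for c in self.covariates:
            if c not in COVARIATE_LEVELS:
                raise ModelConfigurationError(
                    f"unknown covariate {c!r}; known: {sorted(COVARIATE_LEVELS)}"
                )
        terms = {
            *(("time",) if self.time_form != "constant" else ()),
            *(("age",) if self.age_form != "none" else ()),
            *self.covariates,
        }
        for pair in self.interactions:
            if len(pair) != 2:
                raise ModelConfigurationError(f"interaction {pair!r} is not a pair")
            for term in pair:
                if term not in terms:
                    raise ModelConfigurationError(
                        f"interaction term {term!r} not present in the model "
                        f"(available: {sorted(terms)})"
                    )
            if pair[0] == pair[1]:
                raise ModelConfigurationError(f"degenerate interaction {pair!r}")

    # -- resolution of data-driven knots ---------------------------------
    def resolve(self, event_times=None, ages=None) -> "ModelSpec":
        """Return a copy with spline knots resolved from data if needed."""
        time_knots = self.time_knots
        if self.time_form == "rcs" and time_knots is None:
            if event_times is None:
                raise ModelConfigurationError("event times needed to place time knots")
            time_knots = knots_from_quantiles(event_times, self.n_time_knots).knots
        age_knots = self.age_knots
        if self.age_form == "rcs" and age_knots is None:
            if ages is None:
                raise ModelConfigurationError("ages needed to place age knots")
            age_knots = knots_from_quantiles(ages, self.n_age_knots).knots
        return ModelSpec(
            time_form=self.time_form,
            time_knots=time_knots,
            n_time_knots=self.n_time_knots,
            age_form=self.age_form,
            age_knots=age_knots,
            n_age_knots=self.n_age_knots,
            covariates=self.covariates,
            interactions=self.interactions,
        )

    @property
    def is_resolved(self) -> bool:
        return not (
            (self.time_form == "rcs" and self.time_knots is None)
            or (self.age_form == "rcs" and self.age_knots is None)
        )

    def label(self) -> str:
        """Short human-readable formula label for logs and AIC tables."""
        if self.time_form == "constant":
            t = "1"
        elif self.time_form == "linear":
            t = "t"
        else:
            t = f"rcs(t,{self.n_time_knots_effective})"
        if self.age_form == "none":
            a = ""
        elif self.age_form == "linear":
            a = "+age"
        elif self.age_form == "categorical":
            a = "+agecat"
        else:
            a = f"+rcs(age,{len(self.age_knots) if self.age_knots else self.n_age_knots})"
        cov = "".join(f"+{c}" for c in self.covariates)
        inter = "".join(f"+{x}:{y}" for x, y in self.interactions)
        return t + a + cov + inter

    @property
    def n_time_knots_effective(self) -> int:
        if self.time_knots is not None:
            return len(self.time_knots)
        return self.n_time_knots


# ---------------------------------------------------------------------------
# Links
# ---------------------------------------------------------------------------


class LogitProbabilityLink:
    """g = expit(eta); h = softplus(eta); exp(beta) = OR of g."""

    scale = "odds-of-probability"

    @staticmethod
    def hazard(eta):
        return np.logaddexp(0.0, eta)

    @staticmethod
    def log_hazard(eta):
        eta = np.asarray(eta, dtype=float)
        p = np.logaddexp(0.0, eta)
        # softplus underflows to exp(eta) for very negative eta
        with np.errstate(divide="ignore"):
            out = np.where(eta < -33.0, eta, np.log(np.where(p > 0, p, 1.0)))
        return out

    @staticmethod
    def event_terms(eta):
        """(log h, d log h / d eta, d^2 log h / d eta^2), numerically stable."""
        eta = np.asarray(eta, dtype=float)
        s = expit(eta)
        p = np.logaddexp(0.0, eta)
        small = eta < -33.0
        p_safe = np.where(small, 1.0, p)
        log_h = np.where(small, eta, np.log(p_safe))
        r = np.where(small, 1.0, s / p_safe)
        d2 = np.where(small, 0.0, s * (1.0 - s) / p_safe - r * r)
        return log_h, r, d2

    @staticmethod
    def quad_terms(eta):
        """(h, h', h'') as functions of eta."""
        eta = np.asarray(eta, dtype=float)
        s = expit(eta)
        h = np.logaddexp(0.0, eta)
        return h, s, s * (1.0 - s)

    @staticmethod
    def probability(eta):
        return expit(eta)


class LogHazardLink:
    """h = exp(eta): the proportional-hazards parametrisation."""

    scale = "hazard"

    @staticmethod
    def hazard(eta):
        return np.exp(np.minimum(np.asarray(eta, dtype=float), 500.0))

    log_hazard = staticmethod(lambda eta: np.asarray(eta, dtype=float))

    @staticmethod
    def event_terms(eta):
        eta = np.asarray(eta, dtype=float)
        return eta, np.ones_like(eta), np.zeros_like(eta)

    @staticmethod
    def quad_terms(eta):
        h = np.exp(np.minimum(np.asarray(eta, dtype=float), 500.0))
        return h, h, h

    @staticmethod
    def probability(eta):
        # instantaneous probability implied by the hazard: g = 1 - exp(-h)
        return -np.expm1(-np.exp(np.minimum(np.asarray(eta, dtype=float), 500.0)))


# ---------------------------------------------------------------------------
# Elementary transforms (module-level operations)
# ---------------------------------------------------------------------------


def inst_probability(eta):
    """Instantaneous probability of dying, ``g = expit(eta)``, in (0, 1)."""
    return expit(np.asarray(eta, dtype=float))


def hazard_from_probability(g):
    """Invert ``g = 1 - exp(-h)``: ``h = -log(1 - g)`` (per-year rate)."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0.0) or np.any(g >= 1.0):
        raise ValueError("probability must satisfy 0 <= g < 1")
    return -np.log1p(-g)


def probability_from_hazard(h):
    """``g = 1 - exp(-h)`` for a nonnegative hazard ``h``."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0.0):
        raise ValueError("hazard must be nonnegative")
    return -np.expm1(-h)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


class ModelDesign:
    """Maps a resolved :class:`ModelSpec` to design-matrix columns.

    The full parameter layout is ``[(Intercept), time block, age block,
    covariate dummies, interaction columns]``.
    """

    def __init__(self, spec: ModelSpec):
        if not spec.is_resolved:
            raise ModelConfigurationError("spec has unresolved spline knots")
        self.spec = spec
        self.time_names = self._make_time_names()
        self.subject_names, self._term_cols = self._make_subject_names()
        self.interaction_names = self._make_interaction_names()
        self.names = (
            ["(Intercept)"]
            + self.time_names
            + self.subject_names
            + self.interaction_names
        )
        self.n_params = len(self.names)

    # -- column naming ----------------------------------------------------
    def _make_time_names(self):
        if self.spec.time_form == "constant":
            return []
        if self.spec.time_form == "linear":
            return ["time"]
        k = len(self.spec.time_knots)
        return ["time"] + [f"time_s{j}" for j in range(1, k - 1)]

    def _make_subject_names(self):
        names: list[str] = []
        term_cols: dict[str, list[str]] = {}
        spec = self.spec
        if spec.age_form == "linear":
            term_cols["age"] = ["age"]
        elif spec.age_form == "rcs":
            k = len(spec.age_knots)
            term_cols["age"] = ["age"] + [f"age_s{j}" for j in range(1, k - 1)]
        elif spec.age_form == "categorical":
            term_cols["age"] = [f"age[{lab}]" for lab in AGE_CATEGORIES[1:]]
        for cov in spec.covariates:
            levels = COVARIATE_LEVELS[cov]
            term_cols[cov] = [f"{cov}[{lev}]" for lev in levels[1:]]
        for cols in term_cols.values():
            names.extend(cols)
        return names, term_cols

    def _make_interaction_names(self):
        names = []
        for a, b in self.spec.interactions:
            for ca in self._term_colnames(a):
                for cb in self._term_colnames(b):
                    names.append(f"{ca}:{cb}")
        return names

    def _term_colnames(self, term):
        if term == "time":
            return self.time_names
        return self._term_cols[term]

    # -- numeric blocks ---------------------------------------------------
    def time_block(self, t) -> np.ndarray:
        """Time-basis columns at times ``t`` (years); shape (m, n_time)."""
        t = np.asarray(t, dtype=float).ravel()
        if self.spec.time_form == "constant":
            return np.empty((t.size, 0))
        if self.spec.time_form == "linear":
            return t[:, None]
        return rcs_basis(t, SplineSpec(self.spec.time_knots))

    def subject_block(self, data: pd.DataFrame) -> np.ndarray:
        """Age + covariate columns per subject; shape (n, len(subject_names))."""
        spec = self.spec
        cols = []
        if spec.age_form != "none":
            if "age_years" not in data.columns:
                raise ValueError("data must contain an 'age_years' column")
            age = np.asarray(data["age_years"], dtype=float)
            if not np.all(np.isfinite(age)) or np.any(age < 0):
                raise ValueError("age_years must be finite and nonnegative")
            if spec.age_form == "linear":
                cols.append((age - AGE_CENTER)[:, None])
            elif spec.age_form == "rcs":
                basis = rcs_basis(age, SplineSpec(spec.age_knots)).copy()
                basis[:, 0] -= AGE_CENTER
                cols.append(basis)
            else:  # categorical
                cols.append(
                    np.column_stack(
                        [
                            ((age >= AGE_BREAKS[0]) & (age < AGE_BREAKS[1])).astype(float),
                            (age >= AGE_BREAKS[1]).astype(float),
                        ]
                    )
                )
        for cov in spec.covariates:
            levels = COVARIATE_LEVELS[cov]
            if cov not in data.columns:
                raise ValueError(f"data must contain a {cov!r} column")
            values = data[cov].astype(str)
            bad = set(values.unique()) - set(levels)
            if bad:
                raise ValueError(
                    f"unknown level(s) {sorted(bad)} for covariate {cov!r}; "
                    f"expected one of {levels}"
                )
            cat = pd.Categorical(values, categories=levels)
            dummies = np.eye(len(levels))[cat.codes][:, 1:]
            cols.append(dummies)
        if not cols:
            return np.empty((len(data), 0))
        return np.column_stack(cols)

    def _subject_term_slices(self):
        slices = {}
        start = 0
        for term, colnames in self._term_cols.items():
            slices[term] = slice(start, start + len(colnames))
            start += len(colnames)
        return slices

    def rows(self, t, subject_rows: np.ndarray) -> np.ndarray:
        """Full design rows for aligned times ``t`` and subject rows."""
        t = np.asarray(t, dtype=float).ravel()
        subject_rows = np.atleast_2d(subject_rows)
        if subject_rows.shape[0] == 1 and t.size > 1:
            subject_rows = np.broadcast_to(
                subject_rows, (t.size, subject_rows.shape[1])
            )
        if subject_rows.shape[0] != t.size:
            raise ValueError("t and subject_rows must be aligned")
        tb = self.time_block(t)
        blocks = [np.ones((t.size, 1)), tb, subject_rows]
        slices = self._subject_term_slices()

        def term_matrix(term):
            if term == "time":
                return tb
            return subject_rows[:, slices[term]]

        for a, b in self.spec.interactions:
            ma, mb = term_matrix(a), term_matrix(b)
            for i in range(ma.shape[1]):
                for j in range(mb.shape[1]):
                    blocks.append((ma[:, i] * mb[:, j])[:, None])
        return np.column_stack(blocks)

    def coefficients_from_dict(self, values: dict[str, float]) -> np.ndarray:
        """Build a coefficient vector from ``{name: value}``; names not listed
        default to zero; unknown names raise."""
        theta = np.zeros(self.n_params)
        index = {name: i for i, name in enumerate(self.names)}
        for name, value in values.items():
            if name not in index:
                raise KeyError(
                    f"unknown coefficient {name!r}; available: {self.names}"
                )
            theta[index[name]] = float(value)
        return theta


# ---------------------------------------------------------------------------
# Quadrature and likelihood
# ---------------------------------------------------------------------------


def _time_cutpoints(spec: ModelSpec):
    if spec.time_form == "rcs":
        return tuple(spec.time_knots)
    return ()


def build_quadrature(entry, exit_, cutpoints, n_quad: int = 20):
    """Gauss–Legendre nodes/weights over per-subject intervals split at the
    spline knots.

    Returns ``(times, subject_index, weights)`` flattened over all subjects
    and subintervals.
    """
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    if np.any(exit_ < entry):
        raise ValueError("interval end before start")
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_quad)
    cuts = sorted(set(float(c) for c in cutpoints))
    lows = [-np.inf, *cuts]
    highs = [*cuts, np.inf]
    t_parts, s_parts, w_parts = [], [], []
    idx = np.arange(entry.size)
    for lo, hi in zip(lows, highs):
        a = np.maximum(entry, lo)
        b = np.minimum(exit_, hi)
        mask = b > a
        if not mask.any():
            continue
        a, b = a[mask], b[mask]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        t_parts.append((mid[:, None] + half[:, None] * gl_x[None, :]).ravel())
        w_parts.append((half[:, None] * gl_w[None, :]).ravel())
        s_parts.append(np.repeat(idx[mask], n_quad))
    if not t_parts:
        p = np.empty(0)
        return p, p.astype(int), p
    return np.concatenate(t_parts), np.concatenate(s_parts), np.concatenate(w_parts)


@dataclass
class LikelihoodParts:
    """Precomputed design pieces: the likelihood is then pure linear algebra."""

    event_design: np.ndarray  # (n_events, p) design at event times
    quad_design: np.ndarray  # (M, p) design at quadrature nodes
    quad_weights: np.ndarray  # (M,)
    names: list[str] = field(default_factory=list)
    n_subjects: int = 0
    n_events: int = 0
    total_time: float = 0.0  # at-risk person-years


def build_likelihood_parts(
    design: ModelDesign,
    data: pd.DataFrame,
    entry,
    exit_,
    event,
    n_quad: int = 20,
) -> LikelihoodParts:
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    event = np.asarray(event)
    if np.any(exit_ <= 0.0):
        raise ValueError("exit times must be positive")
    if np.any(exit_ <= entry):
        raise ValueError("every record needs entry < exit time")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    event = event.astype(bool)
    subject = design.subject_block(data)
    qt, qs, qw = build_quadrature(entry, exit_, _time_cutpoints(design.spec), n_quad)
    quad_design = design.rows(qt, subject[qs])
    event_design = design.rows(exit_[event], subject[event])
    return LikelihoodParts(
        event_design=event_design,
        quad_design=quad_design,
        quad_weights=qw,
        names=list(design.names),
        n_subjects=int(entry.size),
        n_events=int(event.sum()),
        total_time=float(np.sum(exit_ - entry)),
    )


class LikelihoodObjective:
    """Log-likelihood with analytic gradient and Hessian.

    ``l(theta) = sum log h(eta_event) - sum w * h(eta_quad)`` — concave for
    both links (log-softplus and the identity are concave; softplus and exp
    are convex), so Newton-type optimisation is globally convergent.
    """

    def __init__(self, parts: LikelihoodParts, link):
        self.parts = parts
        self.link = link
        self._cache_key = None
        self._cache = None

    def _compute(self, theta):
        key = theta.tobytes()
        if key == self._cache_key:
            return self._cache
        p = self.parts
        eta_e = p.event_design @ theta
        eta_q = p.quad_design @ theta
        log_h, d1, d2 = self.link.event_terms(eta_e)
        h, dh, d2h = self.link.quad_terms(eta_q)
        w = p.quad_weights
        value = float(log_h.sum() - w @ h)
        grad = p.event_design.T @ d1 - p.quad_design.T @ (w * dh)
        hess = (p.event_design * d2[:, None]).T @ p.event_design - (
            p.quad_design * (w * d2h)[:, None]
        ).T @ p.quad_design
        self._cache_key = key
        self._cache = (value, grad, hess)
        return self._cache

    def loglik(self, theta):
        return self._compute(np.asarray(theta, dtype=float))[0]

    def grad(self, theta):
        return self._compute(np.asarray(theta, dtype=float))[1]

    def hess(self, theta):
        return self._compute(np.asarray(theta, dtype=float))[2]

    # negated versions for scipy.optimize.minimize
    def neg(self, theta):
        return -self.loglik(theta)

    def neg_grad(self, theta):
        return -self.grad(theta)

    def neg_hess(self, theta):
        return -self.hess(theta)


def check_full_rank(matrix: np.ndarray, names, tol: float = 1e-8) -> None:
    """QR-based rank check; raises :class:`RankDeficiencyError` naming the
    offending columns."""
    if matrix.shape[1] == 0:
        return
    if matrix.shape[0] < matrix.shape[1]:
        raise RankDeficiencyError(names)
    _, r, piv = scipy.linalg.qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag[0] == 0.0:
        raise RankDeficiencyError(names)
    bad = diag < tol * diag[0]
    if bad.any():
        raise RankDeficiencyError([names[j] for j in piv[bad]])


def cumulative_hazard_value(
    design: ModelDesign,
    theta: np.ndarray,
    data: pd.DataFrame,
    t_start,
    t_end,
    link=LogitProbabilityLink,
    n_quad: int = 20,
) -> np.ndarray:
    """H = integral of h over [t_start, t_end] per subject row of ``data``.

    ``t_start``/``t_end`` broadcast against the rows of ``data``.
    """
    subject = design.subject_block(data)
    n = subject.shape[0]
    t_start = np.broadcast_to(np.asarray(t_start, dtype=float), (n,)).copy()
    t_end = np.broadcast_to(np.asarray(t_end, dtype=float), (n,)).copy()
    if np.any(t_end < t_start):
        raise ValueError("t_end must be >= t_start")
    if np.any(t_start < 0.0):
        raise ValueError("t_start must be nonnegative")
    qt, qs, qw = build_quadrature(t_start, t_end, _time_cutpoints(design.spec), n_quad)
    if qt.size == 0:
        return np.zeros(n)
    eta = design.rows(qt, subject[qs]) @ theta
    h = link.hazard(eta)
    out = np.zeros(n)
    np.add.at(out, qs, qw * h)
    return out
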