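"""Restricted cubic splines (natural cubic splines) on the time or age axis.

A restricted cubic spline with ``k`` knots is piecewise cubic between
adjacent knots, has continuous value, first and second derivative at every
knot, and is constrained to be *linear* beyond the two boundary knots.  The
basis has ``k - 1`` columns: the identity (linear) term plus ``k - 2``
truncated-power terms, following the Harrell/Royston–Parmar convention with
the nonlinear terms scaled by the squared boundary-knot span so that all
columns live on comparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SplineConfigurationError(ValueError):
    """Raised for an invalid knot configuration."""


@dataclass(frozen=True)
class SplineSpec:
    """Ordered knot locations (boundary + interior), in axis units (years)."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 3:
            raise SplineConfigurationError(
                f"a restricted cubic spline needs at least 3 knots, got {len(knots)}"
            )
        if not all(np.isfinite(knots)):
            raise SplineConfigurationError(f"knots must be finite, got {knots}")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise SplineConfigurationError(
                f"knots must be strictly increasing, got {knots}"
            )

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def n_basis(self) -> int:
        """Basis dimension, including the linear column: k - 1."""
        return len(self.knots) - 1


def _pos_cube(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0.0, u, 0.0) ** 3


def rcs_basis(x, spline: SplineSpec) -> np.ndarray:
    """Evaluate the restricted-cubic-spline basis at ``x``.

    Parameters
    ----------
    x : array-like
        Points on the axis (years).  Any shape; flattened to 1-D.
    spline : SplineSpec
        Knot configuration.

    Returns
    -------
    ndarray of shape ``(len(x), spline.n_knots - 1)``
        Column 0 is ``x`` itself; columns ``1..k-2`` are the restricted
        truncated-power terms, each linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("spline basis input must be finite")
    t = np.asarray(spline.knots)
    k = len(t)
    t_first, t_pen, t_last = t[0], t[-2], t[-1]
    scale = (t_last - t_first) ** 2
    cols = [x]
    for j in range(k - 2):
        tj = t[j]
        term = (
            _pos_cube(x - tj)
            - _pos_cube(x - t_pen) * (t_last - tj) / (t_last - t_pen)
            + _pos_cube(x - t_last) * (t_pen - tj) / (t_last - t_pen)
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def knots_from_quantiles(values, n_knots: int) -> SplineSpec:
    """Place knots from observed values: boundary knots at the min/max,
    interior knots at evenly spaced quantiles (the median for 3 knots,
    the 33rd/67th centiles for 4)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < n_knots:
        raise SplineConfigurationError(
            f"need at least {n_knots} observed values to place {n_knots} knots"
        )
    if n_knots < 3:
        raise SplineConfigurationError("n_knots must be at least 3")
    n_interior = n_knots - 2
    probs = [(i + 1) / (n_interior + 1) for i in range(n_interior)]
    interior = np.quantile(values, probs)
    knots = [float(values.min()), *map(float, interior), float(values.max())]
    if any(b <= a for a, b in zip(knots, knots[1:])):
        raise SplineConfigurationError(
            f"quantile knot placement produced ties: {knots}; "
            "too few distinct observed values"
        )
    return SplineSpec(tuple(knots))
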