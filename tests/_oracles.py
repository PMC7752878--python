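"""Independent oracles used by the test-suite: brute-force integration,
symbolic spline evaluation, closed forms.  These deliberately avoid the
package's own quadrature/basis code paths."""

import numpy as np
import sympy


def riemann_cumulative_hazard(hazard_fn, a, b, n_steps=1_000_000, chunk=200_000):
    """Midpoint Riemann sum of a vectorized hazard function over [a, b]."""
    if b <= a:
        return 0.0
    width = (b - a) / n_steps
    total = 0.0
    for start in range(0, n_steps, chunk):
        stop = min(start + chunk, n_steps)
        mids = a + (np.arange(start, stop) + 0.5) * width
        total += float(np.sum(hazard_fn(mids)))
    return total * width


def symbolic_rcs_columns(knots, xs):
    """Evaluate the restricted-cubic truncated-power basis symbolically,
    term by term: for knots t_1 < ... < t_k the j-th nonlinear column is

        [(x - t_j)+^3 - (x - t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
         + (x - t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1})] / (t_k - t_1)^2

    preceded by the identity column x.
    """
    x = sympy.symbols("x")
    t = [sympy.Rational(str(v)) for v in knots]
    k = len(t)
    scale = (t[-1] - t[0]) ** 2

    def plus_cube(expr):
        return sympy.Piecewise((expr**3, expr > 0), (0, True))

    exprs = [x]
    for j in range(k - 2):
        term = (
            plus_cube(x - t[j])
            - plus_cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus_cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / scale
        exprs.append(term)
    out = np.empty((len(xs), len(exprs)))
    for i, xv in enumerate(xs):
        for j, e in enumerate(exprs):
            out[i, j] = float(e.subs(x, sympy.Rational(str(xv))))
    return out


def exponential_mle(time, event):
    """Closed-form exponential (constant-hazard) MLE and maximized loglik."""
    D = int(np.sum(event))
    T = float(np.sum(time))
    lam = D / T
    return lam, D * np.log(lam) - lam * T
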