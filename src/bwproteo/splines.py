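"""Penalized-spline smoother: the shared engine behind gestational
reference curves and group trajectory fits.

The smooth of abundance on gestational age is a B-spline basis of
dimension k (k in {3, 4, 5, 6}) with a second-difference penalty on the
coefficients; the smoothing parameter is chosen by generalized
cross-validation (GCV). For cubic splines the interior knots sit at
quantiles of the observed ages. Basis dimension k = 3 uses a quadratic
basis (a cubic basis needs at least 4 functions).

Evaluation outside the fitted age range continues linearly from the
boundary with the boundary slope, so early/late samples from the
non-reference groups get bounded extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineFit", "fit_penalized_spline", "select_best_k", "CANDIDATE_K"]

CANDIDATE_K = (3, 4, 5, 6)

# GCV search grid for the smoothing parameter (log10 scale)
_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-8, 4, 37)])


@dataclass
class SplineFit:
    """A fitted penalized spline y ~ s(x)."""

    k: int
    degree: int
    knots: np.ndarray
    coefficients: np.ndarray
    smoothing_parameter: float
    r_squared: float
    x_range: tuple[float, float]
    edf: float = field(default=np.nan)

    def predict(self, x) -> np.ndarray:
        """Evaluate the curve; linear continuation outside ``x_range``."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        lo, hi = self.x_range
        spl = BSpline(self.knots, self.coefficients, self.degree, extrapolate=False)
        der = spl.derivative()
        out = np.empty_like(x)
        inside = (x >= lo) & (x <= hi)
        out[inside] = spl(x[inside])
        below, above = x < lo, x > hi
        if below.any():
            out[below] = spl(lo) + der(lo) * (x[below] - lo)
        if above.any():
            out[above] = spl(hi) + der(hi) * (x[above] - hi)
        return out[0] if scalar else out


def _basis(x: np.ndarray, k: int, lo: float, hi: float):
    degree = min(3, k - 1)
    n_interior = k - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # nudge interior knots off the boundaries if degenerate
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = BSpline.design_matrix(x, knots, degree).toarray()
    return design, knots, degree


def _second_difference(k: int) -> np.ndarray:
    if k < 3:
        return np.zeros((0, k))
    d = np.zeros((k - 2, k))
    for i in range(k - 2):
        d[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d


def fit_penalized_spline(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    smoothing: float | None = None,
) -> SplineFit:
    """Fit y ~ s(x) with basis dimension ``k``.

    smoothing
        Penalty weight λ; ``None`` selects it by GCV over a log-spaced grid
        (λ = 0, the unpenalized regression spline, is in the grid).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct x values")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    lo, hi = float(xs[0]), float(xs[-1])
    design, knots, degree = _basis(xs, k, lo, hi)
    pen = _second_difference(design.shape[1])
    ptp = pen.T @ pen
    btb = design.T @ design
    bty = design.T @ ys
    n = len(ys)

    def solve(lam):
        a = btb + lam * ptp
        # ridge jitter keeps degenerate designs solvable
        try:
            coef = np.linalg.solve(a, bty)
        except np.linalg.LinAlgError:
            coef = np.linalg.solve(a + 1e-10 * np.eye(a.shape[0]), bty)
        fitted = design @ coef
        rss = float(np.sum((ys - fitted) ** 2))
        edf = float(np.trace(np.linalg.solve(a + 1e-12 * np.eye(a.shape[0]), btb)))
        return coef, rss, edf

    if smoothing is None:
        best = None
        for lam in _LAMBDA_GRID:
            coef, rss, edf = solve(lam)
            denom = max(n - edf, 1e-8) ** 2
            gcv = n * rss / denom
            if best is None or gcv < best[0] - 1e-15:
                best = (gcv, lam, coef, rss, edf)
        _, lam, coef, rss, edf = best
    else:
        lam = float(smoothing)
        coef, rss, edf = solve(lam)

    tss = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 0.0 if tss <= 0 else 1.0 - rss / tss
    return SplineFit(k, degree, knots, coef, lam, r2, (lo, hi), edf)


def select_best_k(
    x: np.ndarray,
    y: np.ndarray,
    candidate_k=CANDIDATE_K,
    smoothing: float | None = None,
) -> SplineFit:
    """Fit every candidate basis dimension and keep the highest-r² fit.

    Ties in r² break toward smaller k (parsimony).
    """
    best: SplineFit | None = None
    for k in sorted(candidate_k):
        try:
            fit = fit_penalized_spline(x, y, k, smoothing=smoothing)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"spline fit failed for k={k}: {exc}")
            continue
        if best is None or fit.r_squared > best.r_squared + 1e-12:
            best = fit
    if best is None:
        raise ValueError("no candidate basis dimension produced a valid fit")
    return best
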