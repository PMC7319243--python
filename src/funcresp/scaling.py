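"""Body-mass-ratio scaling of attack rates and handling times.

Bootstrapped attack-rate and handling-time draws are regressed, for each
predator species separately, on the log10 predator-prey body-mass ratio
using polynomial models of degree 1-3; the degree is chosen by AICc.
Attack rates and ratios are log10-transformed; handling times are
log10(x + 1)-transformed because the bootstrap cap can produce exact
zeros.  The fit uses an orthogonal polynomial basis internally (stable
for the cubic) and reports coefficients on the raw power basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from funcresp.estimation import BootstrapSet

__all__ = [
    "ScalingFit",
    "body_mass_ratio",
    "transform_params",
    "fit_scaling",
]


@dataclass
class ScalingFit:
    """Polynomial regression of a transformed parameter on log10 mass ratio."""

    degree: int
    coefficients: np.ndarray  # raw power basis, ascending order
    aicc_table: dict[int, float]
    peak: float | None  # location of interior maximum, if any
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coefficients)


def body_mass_ratio(pred_mass_g: float, prey_mass_g: float) -> float:
    """Predator-prey body-mass ratio (dimensionless)."""
    if pred_mass_g <= 0 or prey_mass_g <= 0:
        raise ValueError("masses must be positive")
    return pred_mass_g / prey_mass_g


def transform_params(draws: BootstrapSet) -> dict[str, np.ndarray]:
    """Transform bootstrap draws for the scaling regressions.

    Attack rates are log10-transformed with zero draws dropped (log10(0)
    is undefined; the drop count is reported), and handling times are
    log10(x + 1)-transformed so that zero draws map to 0.

    Returns a dict with keys ``log10_a``, ``log10_h1`` and
    ``n_zero_a_dropped``.
    """
    a = np.asarray(draws.a, dtype=float)
    h = np.asarray(draws.h, dtype=float)
    if (a < 0).any() or (h < 0).any():
        raise ValueError("draws must be non-negative")
    zero_a = a == 0
    if zero_a.any():
        warnings.warn(
            f"{int(zero_a.sum())} zero attack-rate draws dropped before log10",
            stacklevel=2,
        )
    return {
        "log10_a": np.log10(a[~zero_a]),
        "log10_h1": np.log10(h + 1.0),
        "n_zero_a_dropped": int(zero_a.sum()),
    }


def _gaussian_aicc(rss: float, n: int, k: int) -> float:
    # k counts the polynomial coefficients plus the residual variance
    loglik = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
    aic = 2 * k - 2 * loglik
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_scaling(
    x: np.ndarray, y: np.ndarray, degrees: tuple[int, ...] = (1, 2, 3)
) -> ScalingFit:
    """Polynomial regression with AICc degree selection.

    Fits ordinary least squares of ``y`` on polynomials of ``x`` for each
    candidate degree using an orthogonal (QR) basis, computes Gaussian
    AICc, and returns the minimum-AICc model with coefficients mapped
    back to the raw power basis.  For quadratic winners with negative
    curvature the analytic peak ``-b1/(2*b2)`` is reported; for cubic
    winners the interior maximum of the fitted curve (if one exists
    within the data range) is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    max_degree = max(degrees)
    if n <= max_degree + 3:
        raise ValueError(
            f"need more than {max_degree + 3} points to compare degrees up to {max_degree}"
        )
    if np.unique(x).size <= max_degree:
        max_feasible = np.unique(x).size - 1
        warnings.warn(
            f"only {np.unique(x).size} distinct x values: degree capped at {max_feasible}",
            stacklevel=2,
        )
        degrees = tuple(d for d in degrees if d <= max_feasible)
        if not degrees:
            raise ValueError("too few distinct x values for any candidate degree")

    # floor the RSS at round-off scale so that an exact (noise-free) fit
    # does not send the Gaussian likelihood to infinity for every degree;
    # at the floor the AICc penalty alone picks the simplest model
    rss_floor = n * (1e-12 * max(1.0, float(np.sqrt(np.mean(y**2))))) ** 2
    aicc_table: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for deg in degrees:
        # raw Vandermonde spans the same space; QR gives the stable fit
        v = np.vander(x, deg + 1, increasing=True)
        q_mat, r_mat = np.linalg.qr(v)
        beta_q = q_mat.T @ y
        resid = y - q_mat @ beta_q
        rss = max(float(resid @ resid), rss_floor)
        coef = np.linalg.solve(r_mat, beta_q)  # back to raw power basis
        aicc_table[deg] = _gaussian_aicc(rss, n, deg + 2)
        fits[deg] = coef

    best_deg = min(aicc_table, key=aicc_table.get)
    coef = fits[best_deg]
    peak = _interior_peak(coef, best_deg, x.min(), x.max())
    return ScalingFit(
        degree=best_deg,
        coefficients=coef,
        aicc_table=aicc_table,
        peak=peak,
        n=n,
    )


def _interior_peak(
    coef: np.ndarray, degree: int, lo: float, hi: float
) -> float | None:
    """Location of a strict interior maximum of the fitted polynomial."""
    if degree < 2:
        return None
    if degree == 2:
        b1, b2 = coef[1], coef[2]
        if b2 >= 0:
            return None
        peak = -b1 / (2.0 * b2)
        return float(peak) if lo < peak < hi else None
    deriv = np.polynomial.polynomial.polyder(coef)
    second = np.polynomial.polynomial.polyder(deriv)
    roots = np.polynomial.polynomial.polyroots(deriv)
    candidates = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-10
        and lo < r.real < hi
        and np.polynomial.polynomial.polyval(r.real, second) < 0
    ]
    if not candidates:
        return None
    values = [np.polynomial.polynomial.polyval(c, coef) for c in candidates]
    return candidates[int(np.argmax(values))]
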