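"""Closed-form and differential forms of the non-replacement functional response.

The central object is Rogers' random predator equation, the implicit
integral of a Holling type II response over a trial in which eaten prey
are not replaced:

    Ne = N0 * (1 - exp(a * (Ne * h - T)))

with attack rate ``a`` (cage/hr), handling time ``h`` (hr/prey) and trial
duration ``T`` (hr).  The equation is recursive in ``Ne``; its explicit
solution uses the principal branch of the Lambert W function:

    Ne = N0 - W(a*h*N0 * exp(-a*(T - h*N0))) / (a*h)

The same dynamics in differential form are

    dN/dt = -a*N*P / (1 + a*h*N)

for prey density ``N`` and predator density ``P``; for P = 1 the prey
eaten by time T, ``N0 - N(T)``, equals the Lambert-W solution exactly,
which serves as this module's internal cross-check.

Type III (Hassell) and generalized variants replace the constant attack
rate with a density-dependent coefficient ``a(N0) = b * N0**q`` evaluated
at the initial density (q = 1 for the Hassell form, q free for the
generalized form, q = 0 recovering type II).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import lambertw

__all__ = [
    "FRParams",
    "lambert_w0",
    "rogers_expected_eaten",
    "fr_expected_eaten",
    "integrate_depletion",
]

_FORMS = ("rogers_ii", "hassell_iii", "generalized")

#: Branch point of the principal Lambert W branch.
_BRANCH_POINT = -1.0 / math.e


@dataclass(frozen=True)
class FRParams:
    """Functional-response parameters.

    Parameters
    ----------
    a : float
        Attack rate in cage/hr (>= 0).  For the ``hassell_iii`` and
        ``generalized`` forms this is the coefficient ``b`` of the
        density-dependent attack rate ``a(N0) = b * N0**q``.
    h : float
        Handling time in hr/prey (>= 0).  With ``h > 0`` the maximum
        number of prey eaten over a trial of duration ``T`` is ``T/h``.
    q : float
        Density exponent (>= 0).  Must be 0 for ``rogers_ii``; fixed at
        1 for ``hassell_iii``.
    form : str
        One of ``rogers_ii``, ``hassell_iii``, ``generalized``.
    """

    a: float
    h: float
    q: float = 0.0
    form: str = "rogers_ii"

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown functional-response form {self.form!r}")
        if self.a < 0 or self.h < 0 or self.q < 0:
            raise ValueError("a, h and q must all be non-negative")
        if self.form == "rogers_ii" and self.q != 0:
            raise ValueError("q must be 0 for the rogers_ii form")
        if self.form == "hassell_iii" and self.q != 1:
            raise ValueError("q is fixed at 1 for the hassell_iii form")

    def attack_coefficient(self, n0: float) -> float:
        """Effective attack rate at initial density ``n0``."""
        if self.form == "rogers_ii":
            return self.a
        return self.a * n0 ** self.q


def lambert_w0(x: float) -> float:
    """Principal branch of the Lambert W function.

    Returns the ``w >= -1`` satisfying ``w * exp(w) = x``.  Defined for
    ``x >= -1/e``.
    """
    if x <= _BRANCH_POINT:
        # the double closest to -1/e sits marginally below the true
        # branch point, where W is -1; reject anything further out
        if x >= _BRANCH_POINT - 1e-12:
            return -1.0
        raise ValueError(f"lambert_w0 requires x >= -1/e, got {x!r}")
    w = lambertw(x, k=0)
    return float(w.real)


def _lambert_w0_of_log(log_x: float) -> float:
    """W(exp(log_x)) for log_x too large for exp(); Newton on w + ln w = log_x."""
    w = log_x - math.log(log_x)
    for _ in range(50):
        step = (w + math.log(w) - log_x) / (1.0 + 1.0 / w)
        w -= step
        if abs(step) < 1e-12 * w:
            break
    return w


def _rogers_eaten(n0: float, a: float, h: float, t: float) -> float:
    """Lambert-W solution of the random predator equation for one trial."""
    if n0 == 0.0 or a == 0.0:
        return 0.0
    if h == 0.0:
        # no handling: pure exponential depletion
        return n0 * (-math.expm1(-a * t))
    # The argument a*h*N0*exp(-a*(T - h*N0)) is always positive, so the
    # principal branch is the correct (and only real) solution.  Work
    # from its logarithm so that large a*h*N0 (steep responses during
    # optimization) cannot overflow.
    log_arg = math.log(a * h * n0) - a * (t - h * n0)
    if log_arg > 500.0:
        w = _lambert_w0_of_log(log_arg)
    else:
        w = lambert_w0(math.exp(log_arg))
    ne = n0 - w / (a * h)
    # round-off can leave dust outside [0, N0]
    return min(max(ne, 0.0), n0)


def rogers_expected_eaten(n0: float, params: FRParams, t: float) -> float:
    """Expected prey eaten under Rogers' random predator equation.

    Solves ``Ne = N0 * (1 - exp(a*(Ne*h - T)))`` for the unique
    ``Ne in [0, N0]``.  Analytic limits handle ``a = 0`` (nothing eaten)
    and ``h = 0`` (exponential depletion, ``N0*(1 - exp(-a*T))``) without
    invoking the Lambert W branch.

    Parameters
    ----------
    n0 : float
        Initial prey density (>= 0).
    params : FRParams
        Must have ``form="rogers_ii"``.
    t : float
        Trial duration in hours (> 0).
    """
    if params.form != "rogers_ii":
        raise ValueError("rogers_expected_eaten requires the rogers_ii form")
    if n0 < 0:
        raise ValueError("initial density must be non-negative")
    if t <= 0:
        raise ValueError("duration must be positive")
    return _rogers_eaten(float(n0), params.a, params.h, float(t))


def fr_expected_eaten(n0: float, params: FRParams, t: float) -> float:
    """Expected prey eaten for any supported functional-response form.

    For ``rogers_ii`` this is the random predator equation; the
    ``hassell_iii`` and ``generalized`` forms substitute the
    density-dependent attack coefficient ``a(N0) = b * N0**q`` into the
    same non-replacement integral.
    """
    if n0 < 0:
        raise ValueError("initial density must be non-negative")
    if t <= 0:
        raise ValueError("duration must be positive")
    a_eff = params.attack_coefficient(float(n0))
    return _rogers_eaten(float(n0), a_eff, params.h, float(t))


def integrate_depletion(
    n0: float,
    params: FRParams,
    t: float,
    predator_density: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Prey remaining after integrating the depletion ODE.

    Integrates ``dN/dt = -a*N*P / (1 + a*h*N)`` from ``N(0) = N0`` to
    time ``t`` and returns ``N(t)``.  For ``P = 1`` the eaten total
    ``N0 - N(t)`` matches :func:`rogers_expected_eaten` (the ODE is the
    differential form of the random predator equation).

    Uses an adaptive stiff-capable integrator (LSODA); the right-hand
    side vanishes at N = 0, so positivity is preserved by the dynamics
    rather than by clipping.

    Raises
    ------
    RuntimeError
        If the solver fails to converge.
    """
    if n0 < 0 or predator_density < 0:
        raise ValueError("densities must be non-negative")
    if t <= 0:
        raise ValueError("duration must be positive")
    if n0 == 0.0:
        return 0.0
    a, h, p = params.a, params.h, predator_density

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        n = y[0]
        return [-a * n * p / (1.0 + a * h * n)]

    sol = solve_ivp(
        rhs, (0.0, t), [float(n0)], method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"depletion ODE solver failed: {sol.message}")
    n_final = float(sol.y[0, -1])
    # solver round-off only; dynamics cannot cross zero
    return min(max(n_final, 0.0), float(n0))
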