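"""Closed-form solution chain for the SIIRR system.

Integrating the susceptible-depletion equation once gives the exact relation

    S = S(0) * exp(-tau1*R1/(rho1*N)) * exp(-tau2*R2/(rho2*N))        (*)

(with the convention R1(0) = R2(0) = 0).  In the regime where strain 2 is
negligible and tau1*R1/(rho1*N) << 1, the first exponential is replaced by
the truncated power sum S ~= S(0) * sum_{j=0}^{M} (-tau1*R1/(rho1*N))^j
(the power sum is geometric, term j = (-x)^j, which coincides with the
exponential series at M = 1, the only order solved in closed form here).
Substituting the truncation into the second-order R1 equation and
integrating once yields the scalar polynomial ODE

    dR1/dt = sum_{k=0}^{M+1} alpha_k R1^k,

which for M = 1 is a Riccati equation dR1/dt = a2 R1^2 + a1 R1 + a0 with

    a0 = C = rho1*I1(0),   a1 = tau1*S(0)/N - rho1,
    a2 = -tau1^2*S(0) / (2*rho1*N^2)  (< 0),

solved by R1(t) = -a1/(2 a2) - (theta/(2 a2)) tanh(theta (t+V)/2) where
theta^2 = a1^2 - 4 a0 a2 > 0.  The general solution adds W / v(t) with v
the solution of an auxiliary linear ODE.  R2 then satisfies a linear ODE
dR2/dt + rho2 R2 = q(R1(t)) with polynomial forcing; for the special case
W = 0, rho2 = rho1 it has the elementary solution

    R2(t) = D exp(-rho1 t) - (theta/alpha2) / (1 + exp[theta(t+V)]) + K,

and the infected classes follow from I = (1/rho) dR/dt: I1 is the
sech^2-shaped bell curve with peak -theta^2/(4 rho1 alpha2) at t = -V, and
I2 decays monotonically in the validity regime.

The integration constants V and D are fixed by the defining requirements
R1(0) = R2(0) = 0 (enforced here by a bracketed one-dimensional root solve
on a monotone function, and cross-checked against closed-form inversions).
All hyperbolic factors are evaluated through logistic sigmoids, which stay
finite for arbitrarily large |theta (t+V)|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import expit

from .errors import (
    AnalyticPoleError,
    AnalyticRegimeError,
    InvalidParameterError,
)
from .model import ModelParameters, Scenario, Trajectory
from .simulate import DEFAULT_ABS_TOL, DEFAULT_REL_TOL, integrate

__all__ = [
    "RiccatiConstants",
    "ValidityReport",
    "s_of_r",
    "s_taylor",
    "alpha_coefficients",
    "constants_from_initial_conditions",
    "r1_analytic",
    "r2_analytic",
    "i1_analytic",
    "i2_analytic",
    "riccati_polynomial",
    "q_forcing",
    "r1_plateau",
    "default_grid",
    "chain_residuals",
    "validity_metric",
    "analytic_numeric_peak_deviation",
    "r1_truncated_numeric",
]


# ---------------------------------------------------------------------------
# S as a function of the recovered counts
# ---------------------------------------------------------------------------

def s_of_r(R1, R2, params: ModelParameters, S0: float):
    """Exact susceptible count S(R1, R2) = S0 e^{-t1 R1/(r1 N)} e^{-t2 R2/(r2 N)}.

    This relation is exact along every solution of the full system (no
    truncation involved); R1(0) = R2(0) = 0 is assumed.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    x1 = params.tau1 * R1 / (params.rho1 * params.N)
    x2 = params.tau2 * R2 / (params.rho2 * params.N)
    return S0 * np.exp(-x1) * np.exp(-x2)


def s_taylor(R1, params: ModelParameters, S0: float, M: int):
    """Truncated power-sum approximation S ~= S0 * sum_{j<=M} (-x)^j.

    x = tau1*R1/(rho1*N).  The sum is the geometric partial sum (no 1/j!
    factors); it converges to S0/(1+x) for |x| < 1 with remainder bounded by
    S0 * x^{M+1}/(1-x), and agrees with the exponential form only through
    first order -- which is all the M = 1 closed-form branch uses.
    """
    if M < 0:
        raise InvalidParameterError("truncation order M must be >= 0")
    x = params.tau1 * np.asarray(R1, dtype=float) / (params.rho1 * params.N)
    out = np.ones_like(x)
    for _ in range(M):  # Horner on the geometric partial sum
        out = 1.0 + (-x) * out
    return S0 * out


# ---------------------------------------------------------------------------
# Constants of the chain
# ---------------------------------------------------------------------------

def alpha_coefficients(
    params: ModelParameters, S0: float, C: float, M: int = 1
) -> tuple[float, ...]:
    """Coefficients (alpha_0 .. alpha_{M+1}) of the polynomial R1 equation."""
    if M < 1:
        raise InvalidParameterError("M must be >= 1")
    t1, r1, N = params.tau1, params.rho1, params.N
    alpha = [C, t1 * S0 / N - r1]
    for j in range(1, M + 1):
        alpha.append(t1 * S0 / ((j + 1) * N) * (-t1 / (r1 * N)) ** j)
    return tuple(alpha)


@dataclass(frozen=True)
class RiccatiConstants:
    """Every constant of the M = 1 closed-form chain.

    ``alpha`` holds (alpha0, alpha1, alpha2); ``beta``/``gamma`` are the
    forcing coefficients of the linear R2 equation; ``K`` is the constant
    term of the R2 closed form; ``p`` is the decay constant (= rho2).
    ``D``, ``K`` are None when rho2 != rho1 (the R2 branch then has no
    elementary solution and the numerical integrator must be used).
    Cross-check fields hold the literature's printed closed forms for the
    same constants where those could be evaluated.
    """

    M: int
    C: float
    alpha: tuple[float, float, float]
    theta: float
    V: float
    W: float
    E: float
    p: float
    beta: tuple[float, float, float]
    gamma: tuple[float, ...]
    D: float | None
    K: float | None
    params: ModelParameters
    S0: float
    I1_0: float
    # cross-checks
    V_closed_form: float
    D_closed_form: float | None
    theta_printed: float | None


def _r1_special(t, alpha1: float, alpha2: float, theta: float, V: float):
    u = theta * (np.asarray(t, dtype=float) + V)
    tanh_half = 2.0 * expit(u) - 1.0  # tanh(u/2), overflow-free
    return -alpha1 / (2.0 * alpha2) - theta / (2.0 * alpha2) * tanh_half


def constants_from_initial_conditions(
    params: ModelParameters, S0: float, I1_0: float, W: float = 0.0, E: float = 1.0
) -> RiccatiConstants:
    """Build the M = 1 constants from S(0) and I1(0).

    C = rho1*I1(0) follows from dR1/dt = rho1*I1 evaluated at t = 0.  V is
    obtained by root-solving R1(0; V) = 0 (monotone in V); D by enforcing
    R2(0) = 0 on the closed form.  The printed closed-form inversions for V
    and D are evaluated alongside as cross-checks; the printed radical for
    theta is evaluated too but is not used (see the methods note).
    """
    if S0 <= 0 or I1_0 <= 0:
        raise InvalidParameterError("S(0) and I1(0) must be positive")
    if S0 + I1_0 > params.N * (1 + 1e-12):
        raise InvalidParameterError("S(0) + I1(0) exceeds the population N")
    if params.tau1 <= 0:
        raise AnalyticRegimeError("the closed-form branch requires tau1 > 0")
    t1, r1, r2, N = params.tau1, params.rho1, params.rho2, params.N
    C = r1 * I1_0
    a0, a1, a2 = alpha_coefficients(params, S0, C, M=1)
    theta_sq = a1 * a1 - 4.0 * a0 * a2
    if theta_sq <= 0:
        raise AnalyticRegimeError(
            "solution family invalid for these parameters (theta^2 <= 0)"
        )
    theta = math.sqrt(theta_sq)

    # V from R1(0) = 0: the map V -> R1(0; V) is strictly increasing.
    v_guess = (2.0 / theta) * math.atanh(max(-1 + 1e-15, min(1 - 1e-15, -a1 / theta)))
    lo, hi = v_guess - 10.0 / theta, v_guess + 10.0 / theta
    V = float(
        brentq(
            lambda v: float(_r1_special(0.0, a1, a2, theta, v)),
            lo,
            hi,
            xtol=1e-300,
            rtol=8.9e-16,
        )
    )
    V_closed_form = v_guess

    # forcing coefficients of the linear R2 equation (printed chain)
    beta = (
        -a0 * r2 / r1 + r2 * N - r2 * S0,
        -r2 * a1 / r1 - r2 - r2 * S0 * t1 / (r1 * N),
        -r2 * a2 / r1,
    )
    gamma = (r2 * S0 * t1 / (r1 * N),)

    same_rho = math.isclose(r1, r2, rel_tol=1e-12, abs_tol=0.0)
    if same_rho and W == 0.0:
        K = N - S0 + (a1 + theta) / (2.0 * a2)
        D = theta / a2 * float(expit(-theta * V)) - K
        D_closed_form = S0 - N
    else:
        K = D = D_closed_form = None

    # printed theta radical (most plausible grouping; recorded, not used)
    radicand = (
        N**2 * r2**3
        - 2.0 * N * S0 * r2**2 * t1
        + S0**2 * r2 * t1**2
        + 2.0 * C * S0 * t1**2 * r2
    ) / N**2
    theta_printed = math.sqrt(radicand) if radicand > 0 else None

    return RiccatiConstants(
        M=1,
        C=C,
        alpha=(a0, a1, a2),
        theta=theta,
        V=V,
        W=W,
        E=E,
        p=r2,
        beta=beta,
        gamma=gamma,
        D=D,
        K=K,
        params=params,
        S0=S0,
        I1_0=I1_0,
        V_closed_form=V_closed_form,
        D_closed_form=D_closed_form,
        theta_printed=theta_printed,
    )


# ---------------------------------------------------------------------------
# Closed-form curves
# ---------------------------------------------------------------------------

def riccati_polynomial(R1, constants: RiccatiConstants):
    """dR1/dt as a function of R1: alpha2 R1^2 + alpha1 R1 + alpha0."""
    a0, a1, a2 = constants.alpha
    R1 = np.asarray(R1, dtype=float)
    return a2 * R1 * R1 + a1 * R1 + a0


def q_forcing(R1, constants: RiccatiConstants):
    """Polynomial forcing q(R1) of the linear R2 equation (M = 1)."""
    b0, b1, b2 = constants.beta
    (g1,) = constants.gamma
    R1 = np.asarray(R1, dtype=float)
    return b0 + (b1 + g1) * R1 + b2 * R1 * R1


def r1_analytic(t, constants: RiccatiConstants):
    """R1(t): the tanh special solution, plus the W/v term when W != 0."""
    a0, a1, a2 = constants.alpha
    theta, V, W, E = constants.theta, constants.V, constants.W, constants.E
    base = _r1_special(t, a1, a2, theta, V)
    if W == 0.0:
        return base
    u = theta * (np.asarray(t, dtype=float) + V)
    tanh_half = 2.0 * expit(u) - 1.0
    inv_cosh_sq = 4.0 * expit(u) * expit(-u)  # 1/cosh^2(u/2)
    denom = E - (2.0 * a2 * W / theta) * tanh_half
    scale = abs(E) + abs(2.0 * a2 * W / theta)
    bad = np.abs(denom) < 1e-12 * scale
    if np.any(bad):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        t_pole = float(t_arr[np.argmax(np.atleast_1d(bad))])
        raise AnalyticPoleError(
            f"general-branch pole near t = {t_pole:g}", t_pole
        )
    return base + W * inv_cosh_sq / denom


def _require_r2_branch(constants: RiccatiConstants) -> None:
    if constants.W != 0.0:
        raise AnalyticRegimeError("the R2 closed form requires W = 0")
    if constants.D is None or constants.K is None:
        raise AnalyticRegimeError(
            "no elementary R2 solution for rho2 != rho1; integrate numerically"
        )


def r2_analytic(t, constants: RiccatiConstants):
    """R2(t) for the special case W = 0, rho2 = rho1."""
    _require_r2_branch(constants)
    a2 = constants.alpha[2]
    theta, V = constants.theta, constants.V
    t = np.asarray(t, dtype=float)
    u = theta * (t + V)
    return (
        constants.D * np.exp(-constants.params.rho1 * t)
        - theta / a2 * expit(-u)
        + constants.K
    )


def i1_analytic(t, constants: RiccatiConstants):
    """I1(t) = (1/rho1) dR1/dt: a sech^2 bell with peak at t = -V (W = 0)."""
    if constants.W != 0.0:
        raise AnalyticRegimeError("the I1 closed form requires W = 0")
    a2 = constants.alpha[2]
    theta, V = constants.theta, constants.V
    u = theta * (np.asarray(t, dtype=float) + V)
    sech_sq_half = 4.0 * expit(u) * expit(-u)
    return -(theta**2) / (4.0 * constants.params.rho1 * a2) * sech_sq_half


def i2_analytic(t, constants: RiccatiConstants):
    """I2(t) = (1/rho2) dR2/dt for the W = 0, rho2 = rho1 branch."""
    _require_r2_branch(constants)
    p = constants.params
    a2 = constants.alpha[2]
    theta, V = constants.theta, constants.V
    t = np.asarray(t, dtype=float)
    u = theta * (t + V)
    return (
        -p.rho1 * constants.D * np.exp(-p.rho1 * t)
        + theta**2 / a2 * expit(u) * expit(-u)
    ) / p.rho2


def r1_plateau(constants: RiccatiConstants) -> float:
    """Final epidemic size of strain 1: lim R1(t) = (-alpha1 - theta)/(2 alpha2)."""
    _a0, a1, a2 = constants.alpha
    return (-a1 - constants.theta) / (2.0 * a2)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def default_grid(constants: RiccatiConstants, n: int = 1000) -> np.ndarray:
    """A uniform grid covering the analytic wave (rise, peak and decay)."""
    theta = constants.theta
    t_peak = max(-constants.V, 0.0)
    span = 2.0 * t_peak + 30.0 / theta
    return np.linspace(0.0, span, n)


def _fd_derivative(f, t: np.ndarray, h: float) -> np.ndarray:
    """4th-order central difference with an explicit step (vectorized)."""
    return (f(t - 2 * h) - 8 * f(t - h) + 8 * f(t + h) - f(t + 2 * h)) / (12 * h)


def chain_residuals(
    constants: RiccatiConstants, t: np.ndarray | None = None
) -> dict[str, float]:
    """Max-abs normalized residuals of the defining ODEs of the chain.

    Finite-difference derivatives of the closed forms (4th-order central
    stencils with a step tuned to the curvature scale 1/max(theta, rho))
    are compared with the Riccati polynomial (for R1), the forced linear
    equation (for R2, when that branch exists) and the I = (1/rho) dR/dt
    relations.  This is the primary correctness surface of the analytic
    module, independent of any printed constant formulas.
    """
    if t is None:
        t = default_grid(constants)
    t = np.asarray(t, dtype=float)
    # step balancing truncation against round-off for a 4th-order stencil
    omega = max(constants.theta, constants.params.rho1)
    h = float(np.finfo(float).eps ** 0.2) / omega

    R1 = r1_analytic(t, constants)
    dR1 = _fd_derivative(lambda s: r1_analytic(s, constants), t, h)
    poly = riccati_polynomial(R1, constants)
    scale1 = float(np.max(np.abs(poly)))
    out = {"riccati": float(np.max(np.abs(dR1 - poly))) / scale1}

    I1 = i1_analytic(t, constants)
    out["i1_consistency"] = float(
        np.max(np.abs(I1 - dR1 / constants.params.rho1))
    ) / float(np.max(np.abs(I1)))

    if constants.D is not None:
        R2 = r2_analytic(t, constants)
        dR2 = _fd_derivative(lambda s: r2_analytic(s, constants), t, h)
        q = q_forcing(R1, constants)
        res2 = dR2 + constants.p * R2 - q
        out["linear_r2"] = float(np.max(np.abs(res2))) / float(np.max(np.abs(q)))
        I2 = i2_analytic(t, constants)
        out["i2_consistency"] = float(
            np.max(np.abs(I2 - dR2 / constants.params.rho2))
        ) / float(np.max(np.abs(I2)))
    return out


@dataclass(frozen=True)
class ValidityReport:
    """Smallness diagnostics of the truncation variables.

    strain1/strain2 are max_t tau*R/(rho*N); the closed-form chain is only
    quantitatively trustworthy when both stay well below 1.
    """

    strain1: float
    strain2: float
    regime_ok: bool
    threshold: float


def validity_metric(
    source: Trajectory | RiccatiConstants, threshold: float = 0.2
) -> ValidityReport:
    """Dimensionless validity diagnostics from a trajectory or constants."""
    if isinstance(source, Trajectory):
        if source.scenario is None:
            raise InvalidParameterError("validity metric needs the scenario")
        p = source.scenario.params
        x1 = float(np.max(p.tau1 * source.R1 / (p.rho1 * p.N)))
        x2 = float(np.max(p.tau2 * source.R2 / (p.rho2 * p.N)))
    else:
        p = source.params
        x1 = p.tau1 * r1_plateau(source) / (p.rho1 * p.N)
        r2_inf = source.K if source.K is not None else 0.0
        x2 = p.tau2 * r2_inf / (p.rho2 * p.N)
    return ValidityReport(x1, x2, bool(x1 < threshold and x2 < threshold), threshold)


def analytic_numeric_peak_deviation(
    eps: float,
    rho: float = 0.01,
    N: float = 1e6,
    I1_0: float = 1000.0,
    I2_0: float = 1.0,
    tau2: float = 0.005,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> float:
    """Peak-normalized sup deviation between the closed-form I1 and the
    integrated I1 for a near-threshold scenario tau1*S(0)/(rho*N) = 1 + eps.

    rho1 = rho2 = rho and I2(0) is tiny, so the scenario sits inside the
    validity regime of the chain for small eps; the deviation shrinks as
    eps does.
    """
    S0 = N - I1_0 - I2_0
    tau1 = (1.0 + eps) * rho * N / S0
    scenario = Scenario.from_counts(
        tau1=tau1, tau2=tau2, rho1=rho, rho2=rho,
        S0=S0, I1_0=I1_0, I2_0=I2_0,
        label=f"near-threshold eps={eps:g}",
    )
    traj = integrate(scenario, rel_tol=rel_tol, abs_tol=abs_tol)
    constants = constants_from_initial_conditions(scenario.params, S0, I1_0)
    i1a = i1_analytic(traj.times, constants)
    return float(np.max(np.abs(i1a - traj.I1)) / np.max(traj.I1))


def r1_truncated_numeric(
    params: ModelParameters,
    S0: float,
    I1_0: float,
    M: int,
    t: np.ndarray,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
) -> np.ndarray:
    """R1(t) of the order-M truncated scalar equation, integrated numerically.

    Orders above M = 1 have no closed form here; this integrates
    dR1/dt = sum_k alpha_k R1^k from R1(0) = 0 on the given grid.
    """
    t = np.asarray(t, dtype=float)
    alpha = alpha_coefficients(params, S0, params.rho1 * I1_0, M=M)
    coeffs = np.array(alpha[::-1])  # highest power first, for polyval

    sol = solve_ivp(
        lambda _t, y: np.polyval(coeffs, y),
        (float(t[0]), float(t[-1])),
        [0.0],
        method="DOP853",
        rtol=rel_tol,
        atol=abs_tol,
        t_eval=t,
    )
    if not sol.success:
        raise AnalyticRegimeError(f"truncated-equation integration failed: {sol.message}")
    return sol.y[0]


def general_branch(constants: RiccatiConstants, W: float, E: float) -> RiccatiConstants:
    """Constants for the general Riccati branch (W != 0); R2 chain disabled."""
    return replace(constants, W=W, E=E, D=None, K=None)
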