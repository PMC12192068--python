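"""Fixed points and linear stability of the SIIRR system.

Every state with I1 = I2 = 0 is a fixed point, giving a two-parameter
family (S*, 0, 0, R1*, N - S* - R1*).  The 5x5 Jacobian at such a point has
three structurally zero eigenvalues (the S, R1, R2 rows depend only on the
infected columns there) and two informative ones,

    lambda4 = tau2*S*/N - rho2,    lambda5 = tau1*S*/N - rho1,

so the point is marginally stable iff S* <= N*min(rho1/tau1, rho2/tau2)
(non-strict inequality) and unstable otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidStateError
from .model import ModelParameters, StateVector

__all__ = [
    "FixedPoint",
    "StabilityResult",
    "jacobian",
    "numeric_eigenvalues",
    "eigenvalues_closed_form",
    "classify_fixed_point",
    "analyze_fixed_point",
]

#: Absolute tolerance (times ||J||_max) for eigenvalues that are exactly
#: zero analytically; only float noise intervenes.
ZERO_EIG_TOL = 1e-9


@dataclass(frozen=True)
class FixedPoint:
    """A disease-free equilibrium (S*, 0, 0, R1*, R2*)."""

    S_star: float
    R1_star: float
    R2_star: float

    def __post_init__(self) -> None:
        vals = (self.S_star, self.R1_star, self.R2_star)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise InvalidStateError(f"fixed point components must be >= 0: {vals}")

    def state(self) -> StateVector:
        return StateVector(self.S_star, 0.0, 0.0, self.R1_star, self.R2_star)

    def check_population(self, params: ModelParameters, tol: float = 1e-8) -> None:
        total = self.S_star + self.R1_star + self.R2_star
        if abs(total - params.N) > tol * params.N:
            raise InvalidStateError(
                f"fixed point total {total} != N {params.N}"
            )


@dataclass(frozen=True)
class StabilityResult:
    fixed_point: FixedPoint
    eigenvalues: np.ndarray  # five values, ascending
    jacobian: np.ndarray  # 5x5
    classification: str  # "marginally_stable" | "unstable"


def jacobian(state: StateVector, params: ModelParameters) -> np.ndarray:
    """Analytic 5x5 Jacobian of the SIIRR right-hand side at ``state``."""
    S, I1, I2 = state.S, state.I1, state.I2
    t1, t2, r1, r2, N = params.tau1, params.tau2, params.rho1, params.rho2, params.N
    return np.array(
        [
            [-(t1 * I1 + t2 * I2) / N, -t1 * S / N, -t2 * S / N, 0.0, 0.0],
            [t1 * I1 / N, t1 * S / N - r1, 0.0, 0.0, 0.0],
            [t2 * I2 / N, 0.0, t2 * S / N - r2, 0.0, 0.0],
            [0.0, r1, 0.0, 0.0, 0.0],
            [0.0, 0.0, r2, 0.0, 0.0],
        ]
    )


def numeric_eigenvalues(fp: FixedPoint, params: ModelParameters) -> np.ndarray:
    """Eigenvalues of the Jacobian at a fixed point via a dense solver.

    At any disease-free fixed point the spectrum is real; a residual
    imaginary part beyond round-off raises.
    """
    J = jacobian(fp.state(), params)
    eig = np.linalg.eigvals(J)
    scale = max(np.max(np.abs(J)), np.finfo(float).tiny)
    if np.max(np.abs(eig.imag)) > 1e-9 * scale:
        raise InvalidStateError("unexpected complex eigenvalues at fixed point")
    return np.sort(eig.real)


def eigenvalues_closed_form(fp: FixedPoint, params: ModelParameters) -> np.ndarray:
    """The closed-form spectrum (0, 0, 0, tau2 S*/N - rho2, tau1 S*/N - rho1)."""
    lam4 = params.tau2 * fp.S_star / params.N - params.rho2
    lam5 = params.tau1 * fp.S_star / params.N - params.rho1
    return np.sort(np.array([0.0, 0.0, 0.0, lam4, lam5]))


def classify_fixed_point(fp: FixedPoint, params: ModelParameters) -> str:
    """'marginally_stable' iff both informative eigenvalues are <= 0.

    Equivalent to S* <= N*min(rho1/tau1, rho2/tau2); the boundary itself is
    marginal (non-strict inequality).
    """
    lam = eigenvalues_closed_form(fp, params)
    return "unstable" if lam[-1] > 0 else "marginally_stable"


def analyze_fixed_point(fp: FixedPoint, params: ModelParameters) -> StabilityResult:
    """Full numeric stability analysis at a disease-free fixed point."""
    J = jacobian(fp.state(), params)
    eig = numeric_eigenvalues(fp, params)
    scale = max(np.max(np.abs(J)), np.finfo(float).tiny)
    n_zero = int(np.sum(np.abs(eig) <= ZERO_EIG_TOL * scale))
    if n_zero < 3:
        raise InvalidStateError(
            f"expected three (near-)zero eigenvalues, found {n_zero}"
        )
    return StabilityResult(
        fixed_point=fp,
        eigenvalues=eig,
        jacobian=J,
        classification=classify_fixed_point(fp, params),
    )
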