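"""Core definitions of the two-strain SIIRR epidemic system.

The model divides a closed population of size ``N`` into five compartments:
susceptibles ``S``, carriers of strain 1 or strain 2 (``I1``, ``I2``) and
the corresponding recovered classes (``R1``, ``R2``).  Transmission is
mass-action, recovery is linear, infection with one strain excludes the
other, and recovery confers permanent immunity against both strains:

    dS/dt  = -tau1*S*I1/N - tau2*S*I2/N
    dI1/dt =  tau1*S*I1/N - rho1*I1
    dI2/dt =  tau2*S*I2/N - rho2*I2
    dR1/dt =  rho1*I1
    dR2/dt =  rho2*I2

The five right-hand sides sum to zero, so ``S+I1+I2+R1+R2 = N`` along every
solution.  In the popularity-wave reading, I1/I2 carry positive/negative
opinion about a person or idea and R1/R2 are those who have become
indifferent to it.

Compartment counts are continuous (deterministic mean-field).  ``N`` is
always computed from the initial state, never supplied independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, InvalidStateError, TrajectoryError

__all__ = [
    "ModelParameters",
    "StateVector",
    "Scenario",
    "Trajectory",
    "rhs",
    "sir_rhs",
    "reduced_residuals",
    "COMPARTMENTS",
]

#: Compartment order used by every array in the package.
COMPARTMENTS = ("S", "I1", "I2", "R1", "R2")

#: Conservation tolerance, as a fraction of N.
CONSERVATION_TOL = 1e-8
#: Positivity slack, as a fraction of N (integrator undershoot allowance).
POSITIVITY_SLACK = 1e-6
#: Monotonicity slack for S (non-increasing) and R1, R2 (non-decreasing).
MONOTONICITY_SLACK = 1e-9


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and total population of the SIIRR system.

    tau1, tau2 : per-capita transmission rates (1/time) of strain 1 and 2
    rho1, rho2 : per-capita recovery rates (1/time), strictly positive
    N          : total population (individuals, continuous), positive
    """

    tau1: float
    tau2: float
    rho1: float
    rho2: float
    N: float

    def __post_init__(self) -> None:
        vals = (self.tau1, self.tau2, self.rho1, self.rho2, self.N)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if self.tau1 < 0 or self.tau2 < 0:
            raise InvalidParameterError("transmission rates must be >= 0")
        if self.rho1 <= 0 or self.rho2 <= 0:
            raise InvalidParameterError("recovery rates must be > 0")
        if self.N <= 0:
            raise InvalidParameterError("population N must be > 0")

    def swapped(self) -> "ModelParameters":
        """Parameters with the two strains exchanged."""
        return ModelParameters(self.tau2, self.tau1, self.rho2, self.rho1, self.N)


@dataclass(frozen=True)
class StateVector:
    """Compartment counts (S, I1, I2, R1, R2) at one instant."""

    S: float
    I1: float
    I2: float
    R1: float
    R2: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidStateError(f"non-finite compartment in {tuple(arr)}")
        total = float(arr.sum())
        if np.any(arr < -POSITIVITY_SLACK * max(total, 1.0)):
            raise InvalidStateError(f"negative compartment in {tuple(arr)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I1, self.I2, self.R1, self.R2], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateVector":
        return cls(*(float(x) for x in arr))

    @property
    def total(self) -> float:
        return float(self.as_array().sum())

    def swapped(self) -> "StateVector":
        """State with the two strains exchanged."""
        return StateVector(self.S, self.I2, self.I1, self.R2, self.R1)


@dataclass(frozen=True)
class Scenario:
    """A complete simulation setup: parameters, initial state, output grid.

    ``t_end=None`` asks the simulator to choose the horizon automatically
    (integrate until both infected classes fall below one individual, with a
    hard cap).
    """

    params: ModelParameters
    initial: StateVector
    t_end: float | None = None
    n_out: int = 4001
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end is not None and not (
            np.isfinite(self.t_end) and self.t_end > 0
        ):
            raise InvalidParameterError("t_end must be positive and finite")
        if self.n_out < 2:
            raise InvalidParameterError("n_out must be >= 2")
        if abs(self.initial.total - self.params.N) > CONSERVATION_TOL * self.params.N:
            raise InvalidStateError(
                f"initial state total {self.initial.total} != N {self.params.N}"
            )

    @classmethod
    def from_counts(
        cls,
        *,
        tau1: float,
        tau2: float,
        rho1: float,
        rho2: float,
        S0: float,
        I1_0: float,
        I2_0: float,
        R1_0: float = 0.0,
        R2_0: float = 0.0,
        t_end: float | None = None,
        n_out: int = 4001,
        label: str = "",
    ) -> "Scenario":
        """Build a scenario with ``N`` computed from the initial counts."""
        N = S0 + I1_0 + I2_0 + R1_0 + R2_0
        if N <= 0:
            raise InvalidParameterError("initial counts sum to a non-positive N")
        params = ModelParameters(tau1, tau2, rho1, rho2, N)
        initial = StateVector(S0, I1_0, I2_0, R1_0, R2_0)
        return cls(params, initial, t_end=t_end, n_out=n_out, label=label)

    def swapped(self) -> "Scenario":
        """Scenario with the two strains exchanged (rates and initial counts)."""
        return dataclasses.replace(
            self,
            params=self.params.swapped(),
            initial=self.initial.swapped(),
            label=(self.label + " [strains swapped]").strip(),
        )

    def with_value(self, name: str, value: float) -> "Scenario":
        """Variant of this scenario with one knob changed.

        ``name`` is one of ``S0, I1_0, I2_0, R1_0, R2_0, tau1, tau2, rho1,
        rho2``.  Changing an initial count recomputes ``N``.
        """
        ini, p = self.initial, self.params
        counts = {"S0": ini.S, "I1_0": ini.I1, "I2_0": ini.I2,
                  "R1_0": ini.R1, "R2_0": ini.R2}
        rates = {"tau1": p.tau1, "tau2": p.tau2, "rho1": p.rho1, "rho2": p.rho2}
        if name in counts:
            counts[name] = value
        elif name in rates:
            rates[name] = value
        else:
            raise InvalidParameterError(f"unknown scenario knob {name!r}")
        return Scenario.from_counts(
            **rates, **counts, t_end=self.t_end, n_out=self.n_out,
            label=f"{self.label} [{name}={value:g}]".strip(),
        )


@dataclass(frozen=True)
class Trajectory:
    """Compartment counts over a uniform time grid.

    times  : strictly increasing, starting at 0
    states : array of shape (len(times), 5), columns in COMPARTMENTS order
    """

    times: np.ndarray
    states: np.ndarray
    scenario: Scenario | None = None

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def I1(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def I2(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def R1(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def R2(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def N(self) -> float:
        if self.scenario is not None:
            return self.scenario.params.N
        return float(self.states[0].sum())

    def compartment(self, name: str) -> np.ndarray:
        return self.states[:, COMPARTMENTS.index(name)]

    @property
    def final_state(self) -> StateVector:
        return StateVector.from_array(self.states[-1])

    def conservation_residual(self) -> float:
        """max over the grid of |S+I1+I2+R1+R2 - N|."""
        return float(np.max(np.abs(self.states.sum(axis=1) - self.N)))

    def validate(self) -> None:
        """Raise TrajectoryError unless all trajectory invariants hold."""
        t, y, N = np.asarray(self.times, float), np.asarray(self.states, float), self.N
        if t.ndim != 1 or y.shape != (t.size, 5) or t.size < 2:
            raise TrajectoryError("trajectory shape mismatch or too short")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise TrajectoryError("non-finite entries in trajectory")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise TrajectoryError("times must be strictly increasing from 0")
        if self.conservation_residual() > CONSERVATION_TOL * N:
            raise TrajectoryError(
                f"conservation violated: {self.conservation_residual():.3g}"
            )
        if np.any(y < -POSITIVITY_SLACK * N):
            raise TrajectoryError("compartment count below positivity slack")
        slack = MONOTONICITY_SLACK * N
        if np.any(np.diff(y[:, 0]) > slack):
            raise TrajectoryError("S is not non-increasing")
        if np.any(np.diff(y[:, 3]) < -slack) or np.any(np.diff(y[:, 4]) < -slack):
            raise TrajectoryError("R1/R2 is not non-decreasing")


def _rhs_array(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Vectorized right-hand side; ``y`` has shape (5,) or (n, 5)."""
    y = np.asarray(y, dtype=float)
    S, I1, I2 = y[..., 0], y[..., 1], y[..., 2]
    inf1 = p.tau1 * S * I1 / p.N
    inf2 = p.tau2 * S * I2 / p.N
    rec1 = p.rho1 * I1
    rec2 = p.rho2 * I2
    return np.stack([-inf1 - inf2, inf1 - rec1, inf2 - rec2, rec1, rec2], axis=-1)


def rhs(state: StateVector, params: ModelParameters) -> tuple[float, ...]:
    """Time derivatives (dS, dI1, dI2, dR1, dR2) of the SIIRR system."""
    arr = state.as_array() if isinstance(state, StateVector) else np.asarray(state, float)
    if arr.shape != (5,) or not np.all(np.isfinite(arr)):
        raise InvalidStateError(f"invalid state {arr!r}")
    return tuple(float(v) for v in _rhs_array(arr, params))


def sir_rhs(
    state: tuple[float, float, float], tau: float, rho: float, N: float
) -> tuple[float, float, float]:
    """Classic single-strain SIR right-hand side (reduction oracle).

    The SIIRR system with I2 = R2 = 0 reduces to this system componentwise.
    """
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise InvalidStateError(f"invalid SIR state {arr!r}")
    S, I, _R = arr
    inf = tau * S * I / N
    return (-inf, inf - rho * I, rho * I)


# ---------------------------------------------------------------------------
# Reduced three-equation system (S, R1, R2) consistency residuals
# ---------------------------------------------------------------------------

def _fd1(y: np.ndarray, h: float) -> np.ndarray:
    """4th-order central first derivative at interior points [2:-2]."""
    return (y[:-4] - 8 * y[1:-3] + 8 * y[3:-1] - y[4:]) / (12 * h)


def _fd2(y: np.ndarray, h: float) -> np.ndarray:
    """4th-order central second derivative at interior points [2:-2]."""
    return (-y[:-4] + 16 * y[1:-3] - 30 * y[2:-2] + 16 * y[3:-1] - y[4:]) / (
        12 * h * h
    )


def reduced_residuals(traj: Trajectory) -> dict[str, float]:
    """Consistency residuals of the reduced (S, R1, R2) system.

    The full five-equation system implies three equations in S, R1, R2 only:
    a recovered-balance equation, a susceptible-depletion equation (here
    multiplied through by S to stay well-conditioned in the susceptible
    tail), and a second-order equation for R1.  Derivatives are estimated by
    4th-order central finite differences on the uniform grid, so the
    residuals of an accurately integrated trajectory sit at the finite-
    difference floor; a corrupted trajectory pushes them far above it.

    Returns a dict of max-abs normalized residuals with keys
    ``recovered_balance``, ``susceptible_depletion``, ``r1_second_order``.
    """
    if traj.scenario is None:
        raise TrajectoryError("reduced residuals need the generating scenario")
    t = np.asarray(traj.times, float)
    if t.size < 7:
        raise TrajectoryError("trajectory too short for derivative estimation")
    h = float(t[1] - t[0])
    if not np.allclose(np.diff(t), h, rtol=1e-9, atol=1e-12 * max(h, 1.0)):
        raise TrajectoryError("reduced residuals require a uniform time grid")
    p = traj.scenario.params
    S, R1, R2 = traj.S, traj.R1, traj.R2
    Si, R1i, R2i = S[2:-2], R1[2:-2], R2[2:-2]
    dS, dR1, dR2 = _fd1(S, h), _fd1(R1, h), _fd1(R2, h)
    d2R1 = _fd2(R1, h)

    # (1/rho1) dR1/dt + (1/rho2) dR2/dt = N - R1 - R2 - S
    res_balance = dR1 / p.rho1 + dR2 / p.rho2 - (p.N - R1i - R2i - Si)
    # dS/dt = -(S/N) (tau1/rho1 dR1/dt + tau2/rho2 dR2/dt)
    res_depletion = dS + Si / p.N * (p.tau1 / p.rho1 * dR1 + p.tau2 / p.rho2 * dR2)
    # d2R1/dt2 = rho1 dR1/dt (tau1 S / (rho1 N) - 1)
    res_r1 = d2R1 - p.rho1 * dR1 * (p.tau1 * Si / (p.rho1 * p.N) - 1.0)

    def _norm(res: np.ndarray, scale: float) -> float:
        return float(np.max(np.abs(res)) / max(scale, np.finfo(float).tiny))

    return {
        "recovered_balance": _norm(res_balance, p.N),
        "susceptible_depletion": _norm(res_depletion, float(np.max(np.abs(dS)))),
        "r1_second_order": _norm(res_r1, float(np.max(np.abs(d2R1)))),
    }
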