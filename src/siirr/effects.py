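"""Named scenarios, popularity-wave effect detection and parameter sweeps.

The numerical phenomenology of the two-strain model is organized around
eight named effects of popularity waves:

  - bell-shaped profiles of the infected (popular) classes
  - suppression of popularity (monotone decay from t = 0)
  - faster increase - faster decrease of the bell peaks
  - peak shift in time
  - effect of forgetting (both classes vanish at long times)
  - window of dominance (one class rises while the other falls)
  - short-term win - long-term loss
  - effect of the single peak (one class bell-shaped, the other monotone)

``scenario_registry`` encodes every figure-caption parameter set of the
source study under stable names (``fig1_base``, ``fig2_S0_10000``, ...);
``detect_effects`` fills a :class:`WaveEffectReport` from a trajectory, and
``sweep`` runs one-parameter families and summarizes peak trends.

"Bell-shaped" is operationalized as an interior grid maximum exceeding the
value at t = 0.  "Forgetting" uses a finite-horizon proxy: both infected
classes below 1% of their own maxima at t_end (undetermined when the
horizon truncates the decay).  Derivative signs are taken from the model
right-hand side evaluated at the stored grid states, which is exact there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .model import Scenario, Trajectory
from .simulate import PeakResult, derivatives_on_grid, find_peak, integrate

__all__ = [
    "WaveEffectReport",
    "StwltlReport",
    "SweepResult",
    "scenario_registry",
    "detect_effects",
    "sweep",
    "FORGETTING_FRACTION",
]

#: Finite-horizon proxy threshold for the forgetting effect.
FORGETTING_FRACTION = 0.01


@dataclass(frozen=True)
class StwltlReport:
    """Short-term win - long-term loss descriptor.

    The short-term winner is the strain that peaks first (and usually
    higher); the long-term comparison uses the time each strain takes to
    fall back to half of its own peak (None when it never does within the
    horizon).  ``slower_decay`` names the strain whose wave outlives the
    other's by that measure.
    """

    first_peak: int | None
    higher_peak: int
    half_decay_time: dict[int, float | None]
    slower_decay: int | None


@dataclass(frozen=True)
class WaveEffectReport:
    peaks: dict[int, PeakResult]
    peak_order: int | None  # strain whose (refined) peak comes first
    dominance_windows: list[tuple[float, float]]
    suppression: dict[int, bool]
    single_peak: bool
    forgetting: bool | None
    stwltl: StwltlReport


@dataclass(frozen=True)
class SweepResult:
    varied_parameter: str
    values: list[float]
    reports: list[WaveEffectReport | Exception]
    trajectories: list[Trajectory] | None = None

    def summary(self) -> pd.DataFrame:
        """One row per admissible value: peak time/height/class per strain."""
        rows = []
        for v, rep in zip(self.values, self.reports):
            if isinstance(rep, Exception):
                rows.append({"value": v, "error": str(rep)})
                continue
            row: dict = {"value": v, "error": ""}
            for k in (1, 2):
                pk = rep.peaks[k]
                row[f"t_peak_I{k}"] = pk.t_peak
                row[f"peak_I{k}"] = pk.value_peak
                row[f"class_I{k}"] = pk.profile_class
            row["n_windows"] = len(rep.dominance_windows)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario registry (figure captions)
# ---------------------------------------------------------------------------

_FIG1 = dict(tau1=0.01, tau2=0.009, rho1=0.0005, rho2=0.0006,
             S0=998_990.0, I1_0=1000.0, I2_0=10.0)
_FIG9 = dict(tau1=0.01, tau2=0.009, rho1=0.0005, rho2=0.0006,
             S0=980_000.0, I1_0=10_000.0, I2_0=10_000.0)


def _tag(x: float) -> str:
    s = np.format_float_positional(x, trim="-")
    return s.replace(".", "p").replace("-", "m")


def scenario_registry() -> dict[str, Scenario]:
    """Every figure-caption parameter set under a stable name.

    Counts and rates are transcribed verbatim from the captions; N is
    recomputed from the initial counts.  Known caption inconsistencies:
    the fig5 family inherits the fig1 initial counts (its caption omits
    them); the fig6 family is registered twice, as ``*_caption`` variants
    transcribing the caption's rho1 = 0.005 verbatim and as corrected
    variants using rho1 = 0.0005 (consistent with every other figure) --
    analyses use the corrected ones.

    The S(0)-variation families (fig2, fig10, fig11) keep the basic-case
    population N = 10^6 by assigning the susceptibles removed relative to
    the basic case to an inert, evenly split recovered pool (R1(0), R2(0)).
    The described small-S(0) suppression of both waves only occurs under
    this reading: with N shrunk to S(0)+I1(0)+I2(0) the per-contact
    transmission terms rescale and the waves still grow.
    """
    reg: dict[str, Scenario] = {}

    def add(name: str, base: dict, label: str = "", pool_to: float | None = None,
            **over) -> None:
        kw = dict(base)
        kw.update(over)
        if pool_to is not None:
            pool = pool_to - kw["S0"] - kw["I1_0"] - kw["I2_0"]
            kw["R1_0"] = kw["R2_0"] = pool / 2.0
        reg[name] = Scenario.from_counts(label=label or name, **kw)

    add("fig1_base", _FIG1, label="basic case, I1(0) >> I2(0)")
    for s0 in (10_000, 50_000, 99_000, 500_000):
        add(f"fig2_S0_{s0}", _FIG1, S0=float(s0), pool_to=1e6,
            label=f"fig2 S0={s0} (N held at 1e6 via inert recovered pool)")
    for i10 in (5000, 10_000, 5_000_000):
        add(f"fig3_I10_{i10}", _FIG1, I1_0=float(i10))
    for i20 in (100, 1000, 5000):
        add(f"fig4_I20_{i20}", _FIG1, I2_0=float(i20))
    for t1 in (0.0005, 0.001, 0.005):
        add(f"fig5_tau1_{_tag(t1)}", _FIG1, tau1=t1,
            label=f"fig5 tau1={t1:g} (initial counts inherited from fig1)")
    for t2 in (0.002, 0.009, 0.011, 0.015):
        add(f"fig6_tau2_{_tag(t2)}", _FIG1, tau2=t2,
            label=f"fig6 tau2={t2:g} (corrected rho1=0.0005)")
        add(f"fig6_tau2_{_tag(t2)}_caption", _FIG1, tau2=t2, rho1=0.005,
            label=f"fig6 tau2={t2:g} (caption-verbatim rho1=0.005)")
    for r1 in (0.0005, 0.0025, 0.005, 0.0075):
        add(f"fig7_rho1_{_tag(r1)}", _FIG1, rho1=r1)
    for r2 in (0.0006, 0.000001, 0.00001):
        add(f"fig8_rho2_{_tag(r2)}", _FIG1, rho2=r2)

    add("fig9_base", _FIG9, label="basic case, I1(0) = I2(0)")
    for s0 in (50_000, 60_000, 100_000, 250_000):
        add(f"fig10_S0_{s0}", _FIG9, S0=float(s0), pool_to=1e6,
            label=f"fig10 S0={s0} (N held at 1e6 via inert recovered pool)")
    add("fig11_S0_60000", _FIG9, S0=60_000.0, pool_to=1e6,
        label="single-peak case (N held at 1e6 via inert recovered pool)")
    for r1 in (0.0002, 0.001, 0.003, 0.005):
        add(f"fig12_rho1_{_tag(r1)}", _FIG9, rho1=r1)
    for r2 in (0.0008, 0.0006, 0.0001, 0.00005):
        add(f"fig13_rho2_{_tag(r2)}", _FIG9, rho2=r2)
    for t1 in (0.03, 0.01, 0.004, 0.0001):
        add(f"fig14_tau1_{_tag(t1)}", _FIG9, tau1=t1)
    for t2 in (0.005, 0.009, 0.01, 0.03):
        add(f"fig15_tau2_{_tag(t2)}", _FIG9, tau2=t2)
    return reg


# ---------------------------------------------------------------------------
# Effect detection
# ---------------------------------------------------------------------------

def _half_decay_time(traj: Trajectory, peak: PeakResult, col: str) -> float | None:
    if peak.profile_class != "bell":
        return None
    t, y = traj.times, traj.compartment(col)
    half = 0.5 * peak.value_peak
    after = t > peak.t_peak
    below = after & (y <= half)
    if not np.any(below):
        return None
    j = int(np.argmax(below))
    # linear interpolation between the bracketing grid points
    t0, t1, y0, y1 = t[j - 1], t[j], y[j - 1], y[j]
    t_half = t0 + (y0 - half) / (y0 - y1) * (t1 - t0) if y0 != y1 else t1
    return float(t_half - peak.t_peak)


def detect_effects(
    traj: Trajectory, forgetting_fraction: float = FORGETTING_FRACTION
) -> WaveEffectReport:
    """Fill a WaveEffectReport from one integrated trajectory."""
    if traj.scenario is None:
        raise InvalidParameterError("effect detection needs the scenario")
    peaks = {1: find_peak(traj, "I1"), 2: find_peak(traj, "I2")}

    # peak order by refined peak time
    t1p, t2p = peaks[1].t_peak, peaks[2].t_peak
    peak_order = None if t1p == t2p else (1 if t1p < t2p else 2)

    # dominance windows: one strain strictly rising while the other falls.
    # Both strains must still be present (above a milli-individual floor)
    # and their derivatives above a relative floor, otherwise integrator
    # round-off in the extinct tail flips signs and fakes windows.
    d = derivatives_on_grid(traj)
    d1, d2 = d[:, 1], d[:, 2]
    f1 = 1e-9 * np.max(np.abs(d1))
    f2 = 1e-9 * np.max(np.abs(d2))
    alive = (traj.I1 > 1e-3) & (traj.I2 > 1e-3)
    opposite = alive & (((d1 > f1) & (d2 < -f2)) | ((d1 < -f1) & (d2 > f2)))
    windows: list[tuple[float, float]] = []
    t = traj.times
    i = 0
    while i < opposite.size:
        if opposite[i]:
            j = i
            while j + 1 < opposite.size and opposite[j + 1]:
                j += 1
            if j > i:
                windows.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1

    suppression = {k: peaks[k].profile_class == "monotone_decay" for k in (1, 2)}
    n_bell = sum(peaks[k].profile_class == "bell" for k in (1, 2))
    single_peak = n_bell == 1

    # forgetting: finite-horizon proxy; undetermined when the horizon is
    # too short (either class still above threshold at t_end)
    faded = all(
        traj.compartment(c)[-1] <= forgetting_fraction * peaks[k].value_peak
        for k, c in ((1, "I1"), (2, "I2"))
    )
    forgetting = True if faded else None

    higher = 1 if peaks[1].value_peak >= peaks[2].value_peak else 2
    half = {
        1: _half_decay_time(traj, peaks[1], "I1"),
        2: _half_decay_time(traj, peaks[2], "I2"),
    }
    if half[1] is not None and half[2] is not None and half[1] != half[2]:
        slower = 1 if half[1] > half[2] else 2
    else:
        slower = None
    stwltl = StwltlReport(
        first_peak=peak_order, higher_peak=higher,
        half_decay_time=half, slower_decay=slower,
    )
    return WaveEffectReport(
        peaks=peaks,
        peak_order=peak_order,
        dominance_windows=windows,
        suppression=suppression,
        single_peak=single_peak,
        forgetting=forgetting,
        stwltl=stwltl,
    )


# ---------------------------------------------------------------------------
# One-parameter sweeps
# ---------------------------------------------------------------------------

_SWEEPABLE = ("S0", "I1_0", "I2_0", "tau1", "tau2", "rho1", "rho2")


def sweep(
    base: Scenario,
    parameter_name: str,
    values,
    keep_trajectories: bool = False,
    rel_tol: float | None = None,
    abs_tol: float | None = None,
) -> SweepResult:
    """Integrate a one-parameter family of variants of ``base``.

    N is recomputed per variant from the initial counts.  Inadmissible
    values yield a per-value error entry; the sweep continues.
    """
    if parameter_name not in _SWEEPABLE:
        raise InvalidParameterError(
            f"parameter {parameter_name!r} not sweepable; use one of {_SWEEPABLE}"
        )
    kw = {}
    if rel_tol is not None:
        kw["rel_tol"] = rel_tol
    if abs_tol is not None:
        kw["abs_tol"] = abs_tol
    reports: list[WaveEffectReport | Exception] = []
    trajs: list[Trajectory] = []
    for v in values:
        try:
            variant = base.with_value(parameter_name, float(v))
            traj = integrate(variant, **kw)
            reports.append(detect_effects(traj))
            if keep_trajectories:
                trajs.append(traj)
        except Exception as exc:  # noqa: BLE001 - per-value error entries
            reports.append(exc)
            if keep_trajectories:
                trajs.append(None)  # type: ignore[arg-type]
    return SweepResult(
        varied_parameter=parameter_name,
        values=[float(v) for v in values],
        reports=reports,
        trajectories=trajs if keep_trajectories else None,
    )
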