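# Methods

## Model and assumptions

The SIIRR system is a deterministic mean-field model of two mutually
exclusive contagions in a closed, homogeneously mixing population:

    dS/dt  = −τ₁SI₁/N − τ₂SI₂/N
    dI₁/dt =  τ₁SI₁/N − ρ₁I₁
    dI₂/dt =  τ₂SI₂/N − ρ₂I₂
    dR₁/dt =  ρ₁I₁
    dR₂/dt =  ρ₂I₂

Assumptions: mass-action transmission; constant rates; absolute
cross-protection (an I₁ individual cannot acquire strain 2 and vice
versa); permanent immunity after recovery from either strain; no
demographic turnover.  The five right-hand sides sum to zero, so
N = S+I₁+I₂+R₁+R₂ is a linear first integral.  Compartments are
continuous; counts below one individual are meaningful only as mean-field
densities.

Parameters (units 1/time; time is abstract "model time"):

| parameter | meaning | default (basic case) |
|---|---|---|
| τ₁, τ₂ | per-capita transmission rates | 0.01, 0.009 |
| ρ₁, ρ₂ | per-capita recovery rates | 0.0005, 0.0006 |
| N | population size | 10⁶, always computed from the initial state |

The basic-case rates give strain reproduction-like ratios
τS(0)/(ρN) ≈ 20 and 15: strongly supercritical waves.

N is never supplied independently: every `Scenario` computes
N = S(0)+I₁(0)+I₂(0)+R₁(0)+R₂(0), which keeps the conservation law exact
by construction and rejects N = 0.

## Simulator

The system is smooth and non-stiff but runs over long horizons (the basic
case burns out near t ≈ 2.8×10⁴).  Integration uses DOP853 with
rel_tol = 10⁻⁸, abs_tol = 10⁻⁶ (state units).  Runge–Kutta steps preserve
the linear invariant exactly up to round-off; the observed conservation
residual on the basic case is ≈ 7×10⁻¹⁰ against a validation bound of
10⁻⁸·N.

The horizon, when not given, is chosen by integrating until I₁+I₂ first
falls below one individual ("effective extinction"), with a hard cap of
10⁵ time units; scenarios whose strain-2 recovery rate is extreme (e.g.
ρ₂ = 10⁻⁶) hit the cap with a still-decaying tail, and the forgetting
detector then reports "undetermined" rather than guessing.  Output is a
uniform grid of n_out = 4001 points (peak-time resolution ≲ 0.03% of the
horizon).

Peaks are located as the global grid maximum (ties broken to the earliest
time) refined by a quadratic fit through the three bracketing points;
profile classes are `bell` (interior maximum), `monotone_decay` (maximum
at t = 0; a flat trajectory lands here by convention) and
`monotone_growth_truncated` (maximum at the last point).  Off-grid state
queries use a local cubic spline over eight bracketing grid points.
The peak-threshold law S(t_peak) = Nρ/τ (from dI/dt = 0) holds on the
basic case to ≈ 0.03% for strain 1.

## Stability analysis

Every state with I₁ = I₂ = 0 is a fixed point; the family is
(S*, 0, 0, R₁*, N−S*−R₁*).  The Jacobian rows for S, R₁, R₂ depend only on
the infected columns there, which forces three structurally zero
eigenvalues; the informative pair is λ₄ = τ₂S*/N − ρ₂ and
λ₅ = τ₁S*/N − ρ₁.  A point is classified `marginally_stable` iff
S* ≤ N·min(ρ₁/τ₁, ρ₂/τ₂) with a *non-strict* inequality (the boundary
carries a zero eigenvalue, still marginal), else `unstable`.  Numeric
eigenvalues come from a dense solver and are compared to the closed form
with absolute tolerance 10⁻⁹·max|J| for the analytic zeros — only float
noise intervenes there.  No center-manifold analysis is attempted for the
degenerate directions; the analysis is linear only.

## Closed-form solution chain

Integrating the susceptible-depletion equation once gives the exact
relation S = S(0)·exp(−τ₁R₁/(ρ₁N))·exp(−τ₂R₂/(ρ₂N)) (convention
R₁(0) = R₂(0) = 0); this is checked against full integrations and holds to
integrator accuracy everywhere.  The rest of the chain is approximate and
applies to the regime "strain 2 negligible, τ₁R₁/(ρ₁N) ≪ 1":

1. S is replaced by the truncated power sum S(0)·Σⱼ₌₀ᴹ(−τ₁R₁/(ρ₁N))ʲ.
   As written this is a *geometric* partial sum, not the exponential
   series (no 1/j! factors); the two coincide through M = 1, which is the
   only order solved in closed form.  Orders M > 1 are supported by
   numerically integrating the scalar polynomial equation
   dR₁/dt = Σₖ αₖR₁ᵏ.
2. For M = 1 the R₁ equation is a Riccati equation with
   α₀ = C = ρ₁I₁(0) (forced by dR₁/dt = ρ₁I₁ at t = 0),
   α₁ = τ₁S(0)/N − ρ₁, α₂ = −τ₁²S(0)/(2ρ₁N²) < 0.  Its discriminant
   θ² = α₁² − 4α₀α₂ is positive whenever I₁(0) > 0.  The special solution
   is R₁ = −α₁/(2α₂) − (θ/(2α₂))tanh(θ(t+V)/2); the general solution adds
   W/v(t) with v from an auxiliary linear ODE (constant E), has a pole
   where the denominator E − (2α₂W/θ)tanh(·) vanishes, and is reported as
   an error carrying the offending time.
3. R₂ satisfies a forced linear equation dR₂/dt + ρ₂R₂ = q(R₁(t)).  The
   coefficient bookkeeping of q drops a term
   ρ₂S(0)τ₁R₁/(ρ₁N) relative to direct substitution of the truncated S —
   an additional silent truncation that is exactly what makes the
   elementary solution possible for W = 0, ρ₂ = ρ₁:
   R₂ = D·e^(−ρ₁t) − (θ/α₂)/(1+e^(θ(t+V))) + K with
   K = N − S(0) + (α₁+θ)/(2α₂).  A unit test pins the dropped term down as
   an algebraic identity.  For ρ₂ ≠ ρ₁ there is no elementary R₂ and the
   API directs callers to numerical integration.
4. I₁ = (1/ρ₁)dR₁/dt is the sech² bell with maximum −θ²/(4ρ₁α₂) at
   t = −V; I₂ = (1/ρ₂)dR₂/dt decays from I₂(0) = N − S(0) − I₁(0).

Constants of integration: V and D are fixed by the defining requirements
R₁(0) = R₂(0) = 0.  V is obtained by a bracketed Brent root solve on the
monotone map V ↦ R₁(0; V) and cross-checked against the exact inversion
V = (2/θ)·artanh(−α₁/θ); D against the closed form D = S(0) − N.  Both
cross-checks agree to ≈ 10⁻¹² relative.  A third printed closed form for θ
itself (a radical in N, ρ₂, τ₁, S(0), C) is evaluated and recorded on the
constants object but is *not* used: it is dimensionally inconsistent with
θ² = α₁² − 4α₀α₂ under every plausible reading (an extra overall factor of
ρ₂ and the wrong power of ρ on the C term) and disagrees numerically by an
order of magnitude.  The α-based definition is authoritative; residual
tests below make the choice verifiable.

Numerical evaluation: every tanh/sech/logistic factor is computed through
logistic sigmoids (`expit`), which stay finite for arbitrarily large
|θ(t+V)| — no explicit clamping is needed.

**Correctness surface.**  The primary check is that every closed form
satisfies its own defining ODE: finite-difference derivatives (4th-order
central stencils with step ε^{1/5}/max(θ, ρ₁), balancing truncation
against round-off) are compared with the Riccati polynomial, the forced
linear equation and the I = (1/ρ)dR/dt relations on a 1000-point grid
spanning the wave.  Residuals sit at ≈ 10⁻¹¹ relative, far below the 10⁻⁶
test bound, and the same check passes for the general (W ≠ 0) branch.

**Validity diagnostics.**  `validity_metric` reports
max τ₁R₁/(ρ₁N) and max τ₂R₂/(ρ₂N) with a configurable smallness threshold
(default 0.2).  The basic case is far outside the regime (the strain-1
variable reaches ≈ 20), so the chain is *not* expected to match the basic
case quantitatively, only near-threshold scenarios.  Against full
integrations with τ₁S(0)/(ρ₁N) = 1+ε, ρ₂ = ρ₁ and tiny I₂(0), the
peak-normalized sup deviation of the I₁ bell falls monotonically:
≈ 0.23, 0.13, 0.068, 0.033 for ε = 0.4, 0.2, 0.1, 0.05.

**Known artifact.**  The closed-form I₂ inherits the dropped forcing term:
it decays monotonically from I₂(0) through the strain-1 peak time −V but
then undershoots below zero by an O(S(0)·τ₁R₁/(ρ₁N)) amount before
relaxing to zero.  It never exceeds I₂(0), and the monotone-decay phase is
what the closed form is used for; quantitative strain-2 curves outside
the phase should come from the simulator.

## Scenario registry and conventions

The registry encodes the canonical study scenarios under stable names
(`fig1_base` … `fig15_*`), with counts and rates transcribed verbatim from
their captions and N recomputed from the initial state.  Conventions
adopted where the captions are incomplete or inconsistent:

- the `fig5` family inherits the basic-case initial counts (its caption
  omits them);
- the `fig6` family exists twice: `*_caption` variants transcribe the
  caption's ρ₁ = 0.005 verbatim, corrected variants use ρ₁ = 0.0005
  (consistent with every other scenario); analyses use the corrected ones;
- the S(0)-variation families (`fig2`, `fig10`, `fig11`) keep N = 10⁶ by
  assigning the susceptibles removed relative to the basic case to an
  inert recovered pool split evenly between R₁(0) and R₂(0).  This is the
  only reading under which shrinking S(0) suppresses the waves (the
  described behavior): recomputing N from the shrunk state rescales the
  contact terms and keeps τS(0)/(ρN) > 1, e.g. ≈ 18 at S(0) = 10⁴.
- `fig3_I10_5000000` transcribes its caption verbatim even though the
  count exceeds the basic-case population; N becomes ≈ 6×10⁶ there.

## Effect detection

- **Bell-shaped** = interior grid maximum above the t = 0 value.
- **Suppression** = `monotone_decay` from t = 0.
- **Forgetting** = both infected classes below 1% of their own maxima at
  t_end (a finite-horizon proxy for I → 0); reported as undetermined when
  the horizon truncates the decay.
- **Windows of dominance** = maximal grid runs where one strain's
  derivative is positive and the other's negative.  Derivatives are
  evaluated exactly by applying the model right-hand side to the stored
  states (at least as accurate as differentiating dense output).  Two
  floors guard the tails: both infected counts must exceed 10⁻³
  individuals and both |dI/dt| must exceed 10⁻⁹ of their own maxima —
  otherwise round-off-level counts (±10⁻⁵ and below) flip derivative
  signs and fabricate windows.
- **Short-term win–long-term loss** records which strain peaks first and
  higher, and compares decay speed by the time each wave needs to fall
  back to half its own peak (the study describes the loss verbally; a
  concrete statistic is required).

Sweeps vary one knob (`S0`, `I1_0`, `I2_0`, `tau1`, `tau2`, `rho1`,
`rho2`), recomputing N per the construction convention, report per-value
effects, tolerate inadmissible values as per-value error entries, and
summarize peak time/height/class per strain as a DataFrame.

### Trend claims the equations do not support

Two verbal trend claims in the source narrative are contradicted by the
model itself (verified with two independent integrators, DOP853 at 10⁻⁸
and LSODA at 10⁻¹⁰, agreeing to 0.1 time units):

- On the I₁(0) ≫ I₂(0) base, raising ρ₁ moves the I₁ peak *later*
  (t_peak ≈ 1054 → 1082 → 1256 → 1217 across ρ₁ = 0.0005…0.0075), not
  earlier: with a small I₁(0) and fast recovery, the susceptible depletion
  that turns the wave over is driven by strain 2, and the higher peak
  threshold Nρ₁/τ₁ is reached later.  The "earlier" claim does hold on the
  equal-waves base (I₁(0) = I₂(0) = 10⁴), where depletion is self-driven,
  and is asserted there.
- The "strain-2 peak moves later" trend under rising τ₂ (or ρ₁) reverses
  at the most extreme swept value, where strain 2 itself becomes the
  dominant driver of depletion (e.g. t_peak ≈ 1041 → 1020 between
  τ₂ = 0.011 and 0.015).

Tests assert every peak-height ordering in all four sweep families and
every peak-time ordering the equations actually support; the two
contradicted claims are documented here instead of being asserted.
Similarly, a narrative remark that the ratio I₁/I₂ falls to ≈ 30 near the
peaks is not used anywhere: with the stated rates,
d ln(I₁/I₂)/dt = (τ₁−τ₂)S/N + (ρ₂−ρ₁) > 0, so the ratio can only grow
from its initial value.

## Interface

Config files are YAML with a versioned top-level key (`siirr_config: 1`),
a scenario reference (registry name or inline parameter mapping) and
optional integrator overrides; unknown keys are rejected by name.
Trajectories serialize as CSV (`t,S,I1,I2,R1,R2`) at `%.17g`, which round
trips doubles losslessly; the reader re-validates every trajectory
invariant.  The CLI (`simulate`, `stability`, `analytic`, `effects`,
`sweep`, `list-scenarios`) is a thin layer over the library and logs one
line per stage at default verbosity.

## What the tests do and do not show

Everything here is a deterministic ODE study: there is no stochasticity,
no agent-based variant, no time-varying rates, and no fitting to observed
popularity or epidemic data.  Passing tests show that the implementation
integrates the stated equations accurately, that the closed forms solve
their own defining equations, and that the named qualitative effects are
genuine properties of the equations under the registered scenario
conventions — not that the model describes any real epidemic or any real
popularity time series.  Problem sizes throughout (4001-point grids,
10³–10⁶ populations, 10³ random spectra, four-scenario convergence
ladders) keep the full suite around a few seconds.

## Reduced-system residuals

The full system implies three equations in (S, R₁, R₂) only: a
recovered-balance identity, a susceptible-depletion equation, and a
second-order R₁ equation.  `reduced_residuals` estimates derivatives by
4th-order central differences on the uniform output grid (interior points
only), multiplies the depletion equation through by S (the susceptible
tail passes arbitrarily close to zero), and normalizes per equation.  On
the basic case the residuals sit near the finite-difference floor
(≈ 10⁻⁵ and below, bound 10⁻³); inflating R₁ by 10% drives two of the
three residuals above 0.09 — the second-order equation is homogeneous in
R₁ and blind to pure scaling, which is why all three are reported.
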