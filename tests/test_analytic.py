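"""Tests of the closed-form (Riccati) solution chain."""

import numpy as np
import pytest

from siirr.analytic import (
    alpha_coefficients,
    chain_residuals,
    constants_from_initial_conditions,
    default_grid,
    general_branch,
    i1_analytic,
    i2_analytic,
    q_forcing,
    r1_analytic,
    r1_plateau,
    r1_truncated_numeric,
    r2_analytic,
    riccati_polynomial,
    s_of_r,
    s_taylor,
    validity_metric,
)
from siirr.errors import AnalyticPoleError, AnalyticRegimeError
from siirr.model import ModelParameters, Scenario
from siirr.simulate import integrate


def near_threshold_chain(eps=0.2, rho=0.01, N=1e6, I1_0=1000.0, I2_0=1.0):
    """Constants for a mildly supercritical strain-1 wave with rho2 = rho1
    and a negligible strain 2 -- the regime the chain was built for."""
    S0 = N - I1_0 - I2_0
    tau1 = (1.0 + eps) * rho * N / S0
    params = ModelParameters(tau1, 0.005, rho, rho, N)
    return params, S0, I1_0, constants_from_initial_conditions(params, S0, I1_0)


@pytest.fixture(scope="module")
def chain():
    return near_threshold_chain()


# ---------------------------------------------------------------------------
# S(R1, R2)
# ---------------------------------------------------------------------------

def test_s_of_r_at_origin_and_limit():
    params = ModelParameters(0.01, 0.009, 0.0005, 0.0006, 1e6)
    assert s_of_r(0.0, 0.0, params, 998_990.0) == 998_990.0
    big = s_of_r(np.array([1e5, 1e6, 1e7]), 0.0, params, 998_990.0)
    assert np.all(np.diff(big) < 0) and big[-1] < 1e-10


def test_s_of_r_is_exact_along_integrated_trajectory(fig1_traj):
    """The exponential S(R1, R2) relation is exact, not approximate: it must
    reproduce the integrated S to integrator accuracy for the basic case."""
    params = fig1_traj.scenario.params
    s_rec = s_of_r(fig1_traj.R1, fig1_traj.R2, params, fig1_traj.S[0])
    assert np.max(np.abs(s_rec - fig1_traj.S)) <= 1e-6 * params.N


def test_s_taylor_is_the_printed_geometric_sum():
    """The truncation is a geometric partial sum: at x = 0.1, M = 1 it gives
    0.9*S0, and for growing M it converges to S0/(1+x) with the geometric
    remainder bound x^{M+1}/(1-x) -- not to the exponential."""
    params = ModelParameters(0.01, 0.009, 0.0005, 0.0006, 1e6)
    S0 = 5e5
    assert s_taylor(0.0, params, S0, 7) == S0
    x = 0.1
    R1 = x * params.rho1 * params.N / params.tau1
    assert s_taylor(R1, params, S0, 1) == pytest.approx(0.9 * S0, rel=1e-12)
    x = 0.5
    R1 = x * params.rho1 * params.N / params.tau1
    for M in (1, 3, 6, 12):
        err = abs(s_taylor(R1, params, S0, M) - S0 / (1 + x))
        assert err <= S0 * x ** (M + 1) / (1 - x) * (1 + 1e-12)


# ---------------------------------------------------------------------------
# constants
# ---------------------------------------------------------------------------

def test_constants_enforce_zero_initial_recovered(chain):
    params, S0, I1_0, c = chain
    assert abs(r1_analytic(0.0, c)) <= 1e-8 * params.N
    assert abs(r2_analytic(0.0, c)) <= 1e-8 * params.N


def test_constants_reproduce_initial_infected(chain):
    """I = (1/rho) dR/dt at t = 0 must return the initial infected counts;
    I2(0) is implied by conservation, N - S(0) - I1(0)."""
    params, S0, I1_0, c = chain
    assert i1_analytic(0.0, c) == pytest.approx(I1_0, rel=1e-6)
    assert i2_analytic(0.0, c) == pytest.approx(params.N - S0 - I1_0, rel=1e-6)


def test_constants_cross_checks(chain):
    """The closed-form inversions for V (atanh) and D (S0 - N) agree with
    the root-solved constants; the printed theta radical is recorded."""
    params, S0, I1_0, c = chain
    a0, a1, a2 = c.alpha
    assert c.C == params.rho1 * I1_0
    assert a1 == pytest.approx(params.tau1 * S0 / params.N - params.rho1)
    assert a2 < 0
    assert c.theta ** 2 == pytest.approx(a1 ** 2 - 4 * a0 * a2, rel=1e-12)
    assert c.V == pytest.approx(c.V_closed_form, rel=1e-10)
    assert c.D == pytest.approx(S0 - params.N, rel=1e-12)
    assert c.D == pytest.approx(c.D_closed_form, rel=1e-12)
    assert c.theta_printed is not None  # recorded for the cross-check


def test_constants_reject_degenerate_inputs():
    params = ModelParameters(0.012, 0.0, 0.01, 0.01, 1e6)
    with pytest.raises(AnalyticRegimeError):
        constants_from_initial_conditions(
            ModelParameters(0.0, 0.0, 0.01, 0.01, 1e6), 9e5, 1e3
        )
    with pytest.raises(Exception):
        constants_from_initial_conditions(params, -1.0, 1e3)


# ---------------------------------------------------------------------------
# defining-ODE residuals (primary correctness surface)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("eps", [0.05, 0.2, 1.0])
def test_chain_satisfies_its_defining_odes(eps):
    """R1 solves the Riccati equation, R2 the forced linear equation, and
    I1/I2 equal (1/rho) dR/dt, all to 1e-6 relative by finite differences."""
    _, _, _, c = near_threshold_chain(eps)
    res = chain_residuals(c)
    assert set(res) == {"riccati", "i1_consistency", "linear_r2",
                        "i2_consistency"}
    assert max(res.values()) <= 1e-6


def test_general_branch_also_solves_riccati(chain):
    """Adding the W/v term keeps the Riccati residual at the noise floor."""
    _, _, _, c = chain
    g = general_branch(c, W=5000.0, E=1.0)
    t = default_grid(c)
    h = np.finfo(float).eps ** 0.2 / max(c.theta, c.params.rho1)
    fd = (r1_analytic(t - 2 * h, g) - 8 * r1_analytic(t - h, g)
          + 8 * r1_analytic(t + h, g) - r1_analytic(t + 2 * h, g)) / (12 * h)
    poly = riccati_polynomial(r1_analytic(t, g), g)
    assert np.max(np.abs(fd - poly)) <= 1e-6 * np.max(np.abs(poly))


def test_general_branch_pole_raises_with_location(chain):
    """E = 0 puts the auxiliary denominator zero at t = -V exactly."""
    _, _, _, c = chain
    g = general_branch(c, W=1.0, E=0.0)
    with pytest.raises(AnalyticPoleError) as exc:
        r1_analytic(-c.V, g)
    assert exc.value.t_pole == pytest.approx(-c.V)


def test_r2_branch_requires_equal_recovery_rates():
    params = ModelParameters(0.012, 0.005, 0.01, 0.02, 1e6)
    c = constants_from_initial_conditions(params, 998_999.0, 1000.0)
    assert c.D is None
    with pytest.raises(AnalyticRegimeError):
        r2_analytic(1.0, c)
    with pytest.raises(AnalyticRegimeError):
        i2_analytic(1.0, c)


# ---------------------------------------------------------------------------
# curve shapes
# ---------------------------------------------------------------------------

def test_r1_is_cumulative_and_plateaus(chain):
    _, _, _, c = chain
    t = default_grid(c)
    r1 = r1_analytic(t, c)
    assert np.all(np.diff(r1) >= -1e-9)
    far = float(r1_analytic(-c.V + 200.0 / c.theta, c))
    assert far == pytest.approx(r1_plateau(c), rel=1e-9)
    assert r1_plateau(c) > 0


def test_i1_bell_peak_height_location_and_symmetry(chain):
    _, _, _, c = chain
    a2 = c.alpha[2]
    peak = -c.theta ** 2 / (4 * c.params.rho1 * a2)
    assert peak > 0
    assert i1_analytic(-c.V, c) == pytest.approx(peak, rel=1e-12)
    s = np.linspace(0.0, 3.0 / c.theta, 7)
    assert np.allclose(i1_analytic(-c.V + s, c), i1_analytic(-c.V - s, c),
                       rtol=1e-12)
    # the peak dominates any other sampled value
    t = default_grid(c)
    assert np.max(i1_analytic(t, c)) <= peak * (1 + 1e-12)


def test_i2_decays_monotonically_through_the_wave(chain):
    """In the small-strain-2 regime the closed-form I2 never exceeds its
    initial value and is non-increasing from t = 0 up to the strain-1 peak
    (beyond it the truncation error relaxes the curve back toward zero)."""
    _, _, _, c = chain
    t = np.linspace(0.0, -c.V, 800)
    i2 = i2_analytic(t, c)
    assert np.all(np.diff(i2) <= 1e-9 * abs(i2[0]))
    t_all = default_grid(c)
    assert np.all(i2_analytic(t_all, c)[1:] <= i2[0])


# ---------------------------------------------------------------------------
# validity diagnostics and truncated-equation integration
# ---------------------------------------------------------------------------

def test_validity_metric_flags_the_basic_case(fig1_traj):
    """The basic case sits far outside the truncation regime (the strain-1
    variable tau1*R1/(rho1*N) reaches ~20), and must be flagged."""
    rep = validity_metric(fig1_traj)
    assert rep.strain1 > 1.0
    assert not rep.regime_ok


def test_validity_metric_accepts_near_threshold_scenario():
    S0 = 1e6 - 1001.0
    tau1 = 1.05 * 0.01 * 1e6 / S0
    scn = Scenario.from_counts(tau1=tau1, tau2=0.005, rho1=0.01, rho2=0.01,
                               S0=S0, I1_0=1000.0, I2_0=1.0)
    rep = validity_metric(integrate(scn))
    assert rep.regime_ok
    assert rep.strain1 < 0.2 and rep.strain2 < 0.2


def test_validity_metric_zero_recovered_is_trivially_ok(chain):
    params, *_ = chain
    scn = Scenario.from_counts(tau1=params.tau1, tau2=params.tau2,
                               rho1=params.rho1, rho2=params.rho2,
                               S0=1e6, I1_0=0.0, I2_0=0.0,
                               t_end=10.0, n_out=11)
    rep = validity_metric(integrate(scn))
    assert rep.strain1 == 0.0 and rep.strain2 == 0.0 and rep.regime_ok


def test_truncated_equation_integration_matches_closed_form(chain):
    """Numerically integrating the M = 1 scalar equation reproduces the tanh
    closed form.  The M = 2 truncation adds a positive term to the
    approximated S (alternating geometric partial sums), so its cumulative
    R1 must dominate the M = 1 curve."""
    params, S0, I1_0, c = chain
    t = np.linspace(0.0, 2 * (-c.V), 200)
    r1_num = r1_truncated_numeric(params, S0, I1_0, 1, t)
    # the scalar equation starts from R1(0)=0, as does the closed form
    assert np.max(np.abs(r1_num - r1_analytic(t, c))) <= 1e-6 * r1_plateau(c)
    r1_m2 = r1_truncated_numeric(params, S0, I1_0, 2, t)
    assert np.all(r1_m2 >= r1_num - 1e-6 * r1_plateau(c))


def test_alpha_coefficients_follow_the_printed_recursion():
    params = ModelParameters(0.012, 0.0, 0.01, 0.01, 1e6)
    a = alpha_coefficients(params, 9e5, 10.0, M=3)
    assert len(a) == 5
    t1, r1, N = params.tau1, params.rho1, params.N
    for j in (1, 2, 3):
        assert a[j + 1] == pytest.approx(
            t1 * 9e5 / ((j + 1) * N) * (-t1 / (r1 * N)) ** j
        )


def test_forcing_polynomial_documents_the_extra_truncation(chain):
    """Substituting the truncated S and the Riccati dR1/dt directly into the
    recovered-balance equation gives a forcing that exceeds q(R1) by exactly
    rho2*S0*tau1/(rho1*N) * R1: the chain drops that term, which is what
    makes the elementary R2 solution possible.  This identity pins down the
    coefficient bookkeeping exactly."""
    _, S0, _, c = chain
    p = c.params
    R1 = np.linspace(0.0, r1_plateau(c), 50)
    direct = (p.rho2 * (p.N - R1 - s_taylor(R1, p, S0, 1))
              - p.rho2 / p.rho1 * riccati_polynomial(R1, c))
    dropped = (p.rho2 * S0 * p.tau1 / (p.rho1 * p.N)) * R1
    assert np.allclose(direct - q_forcing(R1, c), dropped,
                       rtol=1e-9, atol=1e-9 * p.N)
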