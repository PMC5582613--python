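"""Model core: sigmoid partition law, rate laws, stoichiometry, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meiqxkin as mk
from meiqxkin.model import SPECIES, SigmoidSpec, DistributionCoefficientSpec


# ---------------------------------------------------------------------------
# sigmoid partition law
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "spec, s, expected",
    [
        # zero amplitude: phi constant at the baseline
        (SigmoidSpec(a=0.0, b=0.3, theta=1e-6, n=5), 1e-5, 0.3),
        # at s = theta the sigmoid sits halfway: a/2 + b
        (SigmoidSpec(a=0.4, b=0.1, theta=2e-6, n=5), 2e-6, 0.3),
        # closed-form evaluation: theta^5/(theta^5 + s^5) at s = 0.4*theta
        (SigmoidSpec(a=1.0, b=0.0, theta=1.25e-6, n=5), 0.5e-6, 0.98986),
    ],
)
def test_sigmoid_phi_values(spec, s, expected):
    assert mk.sigmoid_phi(spec, s) == pytest.approx(expected, abs=5e-6)


def test_sigmoid_phi_rejects_negative_concentration():
    with pytest.raises(ValueError):
        mk.sigmoid_phi(SigmoidSpec(a=0.5, b=0.1, theta=1e-6), -1e-9)


@given(
    a=st.floats(0.0, 1.0),
    b=st.floats(0.0, 1.0),
    theta=st.floats(1e-9, 1e-4),
    n=st.floats(0.5, 10.0),
    data=st.data(),
)
@settings(max_examples=1000, derandomize=True, deadline=None)
def test_sigmoid_phi_bounded_and_monotone(a, b, theta, n, data):
    """phi stays in [b, a+b] and never increases with concentration."""
    if a + b > 1.0:
        a = 1.0 - b
    spec = SigmoidSpec(a=a, b=b, theta=theta, n=n)
    s1 = data.draw(st.floats(0.0, 1e-3))
    s2 = data.draw(st.floats(0.0, 1e-3))
    lo, hi = min(s1, s2), max(s1, s2)
    p_lo, p_hi = mk.sigmoid_phi(spec, lo), mk.sigmoid_phi(spec, hi)
    assert b - 1e-12 <= p_hi <= p_lo <= a + b + 1e-12


def test_sigmoid_invariants_rejected():
    with pytest.raises(ValueError):
        SigmoidSpec(a=0.7, b=0.5, theta=1e-6)  # a + b > 1
    with pytest.raises(ValueError):
        SigmoidSpec(a=0.1, b=0.1, theta=-1e-6)


# ---------------------------------------------------------------------------
# distribution coefficients
# ---------------------------------------------------------------------------


def test_distribution_coefficients_saturation_ignores_concentration():
    dist = DistributionCoefficientSpec.saturation(0.02, 0.9)
    for c in (0.0, 1e-7, 5e-5):
        assert mk.distribution_coefficients(dist, c) == (0.02, 0.9)


def test_distribution_coefficients_dose_dependent_asymptotes():
    # CYP1A2 coefficient spans 0.05 (low dose) to 0.005 (high dose)
    dist = DistributionCoefficientSpec.dose_dependent(
        SigmoidSpec(a=0.045, b=0.005, theta=7.5e-7, n=5),
        SigmoidSpec(a=0.4, b=0.5, theta=1.25e-6, n=5),
    )
    a0, _ = mk.distribution_coefficients(dist, 0.0)
    a_hi, _ = mk.distribution_coefficients(dist, 1e-2)
    assert a0 == pytest.approx(0.05)
    assert a_hi == pytest.approx(0.005, rel=1e-6)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------


def test_reaction_rates_zero_state(nominal_params):
    assert np.all(mk.reaction_rates(np.zeros(8), nominal_params) == 0.0)


def test_reaction_rates_saturation_limit(saturation_params):
    p = saturation_params
    state = np.zeros(8)
    state[0] = 1e4 * p.km1
    v = mk.reaction_rates(state, p)
    alpha = p.dist.alpha_fixed
    vmax1 = p.k1 * alpha * p.e_cyp1a2_total
    assert v[0] == pytest.approx(vmax1, rel=1e-4)
    assert np.all(v >= 0.0)


def test_reaction_rates_half_maximal_at_km(nominal_params):
    state = np.zeros(8)
    state[0] = nominal_params.km_so3h
    v = mk.reaction_rates(state, nominal_params)
    assert v[4] == pytest.approx(nominal_params.vm_so3h / 2, rel=1e-12)


def test_reaction_rates_rejects_negative_state(nominal_params):
    bad = np.zeros(8)
    bad[3] = -1e-9
    with pytest.raises(ValueError):
        mk.reaction_rates(bad, nominal_params)


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------


def _stoichiometry_matrix():
    """Independent species-by-reaction matrix built from the pathway map."""
    N = np.zeros((8, 7))
    sp = {name: i for i, name in enumerate(SPECIES)}
    # v1: MeIQx -> C-Hydroxy; v2: MeIQx -> HONH; v3: MeIQx -> N2-Gl
    # v4: HONH -> HON-Gl; v5: MeIQx -> SO3H; v6: MeIQx -> oxo; v7: HONH -> PGC
    reactions = [
        ("meiqx", "c_hydroxy_meiqx"),
        ("meiqx", "honh_meiqx"),
        ("meiqx", "meiqx_n2_gl"),
        ("honh_meiqx", "hon_meiqx_n2_gl"),
        ("meiqx", "meiqx_n2_so3h"),
        ("meiqx", "oxo_meiqx"),
        ("honh_meiqx", "potential_genotoxic"),
    ]
    for j, (src, dst) in enumerate(reactions):
        N[sp[src], j] = -1.0
        N[sp[dst], j] = 1.0
    return N


def test_ode_rhs_matches_stoichiometry_oracle(nominal_params, rng):
    N = _stoichiometry_matrix()
    for _ in range(25):
        state = rng.uniform(0.0, 5e-6, size=8)
        dx = mk.ode_rhs(0.0, state, nominal_params)
        oracle = N @ mk.reaction_rates(state, nominal_params)
        np.testing.assert_allclose(dx, oracle, rtol=1e-12, atol=0.0)
        # closed system: sum vanishes up to float rounding of the fluxes
        assert abs(dx.sum()) <= 1e-12 * np.abs(dx).sum()


def test_ode_rhs_meiqx_exhausted(nominal_params):
    state = np.zeros(8)
    state[5] = 1e-6  # only HONH present
    dx = mk.ode_rhs(0.0, state, nominal_params)
    assert np.all(dx[[0, 1, 2, 3, 4]] == 0.0)
    assert dx[5] < 0.0 and dx[6] > 0.0 and dx[7] > 0.0


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def test_simulate_zero_dose_is_identically_zero(nominal_params):
    traj = mk.simulate(nominal_params, 0.0, t_end=24.0)
    assert np.all(traj.states == 0.0)


def test_simulate_without_enzymes_keeps_meiqx_constant(nominal_params):
    from dataclasses import replace

    p = replace(
        nominal_params,
        e_cyp1a2_total=0.0, e_ugt_total=0.0, vm_so3h=0.0, vm_oxo=0.0, vm_pgc=0.0,
    )
    traj = mk.simulate(p, 1e-6, t_end=24.0)
    np.testing.assert_allclose(traj.species("meiqx"), 1e-6, rtol=1e-9)


def _rk4_oracle(params, dose, t_end, dt):
    """Brute-force fixed-step classical Runge-Kutta reference integrator."""
    y = np.zeros(8)
    y[0] = dose
    t = 0.0
    out = [y.copy()]
    times = [0.0]
    f = lambda x: mk.ode_rhs(0.0, np.maximum(x, 0.0), params)
    n = int(round(t_end / dt))
    for k in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        if k % (n // 24) == 0 or k == n - 1:
            times.append(t)
            out.append(y.copy())
    return np.array(times), np.array(out)


def test_simulate_agrees_with_fine_step_explicit_oracle(nominal_params):
    """Stiff implicit solution vs a 1e-3 h fixed-step RK4 integration."""
    dose = 1e-6
    times, y_ref = _rk4_oracle(nominal_params, dose, 24.0, 1e-3)
    traj = mk.simulate(nominal_params, dose, t_grid=times)
    np.testing.assert_allclose(traj.states, y_ref, rtol=1e-4, atol=1e-9 * dose)


@pytest.mark.parametrize("dose_uM", [1.0, 10.0, 50.0])
def test_trajectory_conservation_and_positivity(nominal_params, dose_uM):
    dose = dose_uM * 1e-6
    traj = mk.simulate(nominal_params, dose, t_end=24.0)
    total = traj.states.sum(axis=1)
    assert np.max(np.abs(total - dose)) / dose <= 1e-6
    assert traj.states.min() >= -1e-12 * dose
    assert traj.states[0, 0] == dose and np.all(traj.states[0, 1:] == 0.0)


def test_trajectory_monotone_species(nominal_params):
    dose = 1e-5
    traj = mk.simulate(nominal_params, dose, t_end=24.0)
    tol = 1e-9 * dose
    assert np.all(np.diff(traj.species("meiqx")) <= tol)
    for name in ("c_hydroxy_meiqx", "meiqx_n2_gl", "meiqx_n2_so3h",
                 "oxo_meiqx", "hon_meiqx_n2_gl", "potential_genotoxic"):
        assert np.all(np.diff(traj.species(name)) >= -tol)


def test_long_horizon_depletes_parent_and_intermediate(nominal_params):
    dose = 1e-6
    traj = mk.simulate(nominal_params, dose, t_end=500.0)
    assert traj.species("meiqx")[-1] <= 1e-4 * dose
    assert traj.species("honh_meiqx")[-1] <= 1e-4 * dose


def test_simulate_rejects_bad_grid(nominal_params):
    with pytest.raises(ValueError):
        mk.simulate(nominal_params, 1e-6, t_grid=np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        mk.simulate(nominal_params, -1e-6)
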