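import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from catchbond import (
    ModelParameters,
    PhysicalEnvironment,
    RateSet,
    kinetic_solution,
    large_state_duration,
    mean_lifetime,
    predict_table,
    scan_parameter,
    survival_probability,
    transition_rates,
)
from catchbond.landscape import basin_log_weights


def test_rates_positive_finite_and_arrhenius(table1):
    """Rates stay positive/finite over the working force range, and the
    small->large crossing slows as its barrier H grows."""
    params, env = table1
    prev = None
    for F in (0.0, 5.0, 15.1, 30.0, 50.0):
        r = transition_rates(F, params, env)
        for v in (r.omega_SL, r.omega_LS, r.omega_S_rup, r.omega_L_rup):
            assert np.isfinite(v) and v > 0
    for H in (15.0, 20.0, 25.0, 30.0):
        r = transition_rates(0.0, params.replace(H=H), env)
        if prev is not None:
            assert r.omega_SL < prev
        prev = r.omega_SL
    assert prev < 0.1  # H = 30 kT barrier: nearly frozen


def test_detailed_balance_against_basin_weights(table1):
    """w_SL/w_LS must reproduce the equilibrium basin ratio Z_L/Z_S."""
    params, env = table1
    for F in (0.0, 8.0, 15.1):
        r = transition_rates(F, params, env)
        lnZS, lnZL = basin_log_weights(F, params, env)
        assert r.omega_SL / r.omega_LS == pytest.approx(
            math.exp(lnZL - lnZS), rel=0.02
        )


def test_mean_lifetime_equals_survival_integral(table1):
    params, env = table1
    sol = kinetic_solution(7.0, params, env)
    t_hi = 60.0 / sol.decay_rates[0]
    tau_quad, _ = quad(
        lambda t: survival_probability(sol, t), 0.0, t_hi,
        points=[1.0 / sol.decay_rates[1], 1.0 / sol.decay_rates[0]],
        limit=200,
    )
    assert sol.mean_lifetime == pytest.approx(tau_quad, rel=1e-8)
    assert sol.mean_lifetime == pytest.approx(
        sol.amplitudes[0] / sol.decay_rates[0] + sol.amplitudes[1] / sol.decay_rates[1],
        rel=1e-12,
    )


def test_survival_normalized_and_monotone(table1):
    params, env = table1
    tgrid = np.geomspace(1e-4, 30.0, 200)
    for F in np.linspace(0.0, 33.0, 8):
        sol = kinetic_solution(F, params, env)
        sig = survival_probability(sol, tgrid)
        assert survival_probability(sol, 0.0) == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.diff(sig) <= 1e-12)
        assert abs(sum(sol.amplitudes) - 1.0) < 1e-10
        assert 0.0 <= sol.splitting_probability <= 1.0


def test_no_interconversion_limit():
    """With frozen angular exchange, every small-alpha start ruptures from
    small alpha: pi_S = p_S0 and tau is a mixture of two exponentials."""
    rates = RateSet(force=5.0, omega_SL=0.0, omega_LS=0.0,
                    omega_S_rup=2.0, omega_L_rup=0.5)
    params, env = ModelParameters(
        E0=21.8, E1=5.8, H=25.0, G=5.0, d=0.56, r0=1.7,
        alpha_min=48.0, alpha_c=53.0, alpha_max=169.0,
    ), PhysicalEnvironment()
    sol = kinetic_solution(5.0, params, env, p_S0=0.6, rates=rates, equilibrium=False)
    assert sol.splitting_probability == pytest.approx(0.6, rel=1e-12)
    assert sol.mean_lifetime == pytest.approx(0.6 / 2.0 + 0.4 / 0.5, rel=1e-12)
    assert sol.large_state_duration == pytest.approx(1 / 0.5)


def test_confluent_eigenvalues_match_matrix_exponential():
    """Degenerate decay rates take the analytic (1 - beta t) e^{-lt} form."""
    rates = RateSet(force=1.0, omega_SL=2.0, omega_LS=0.0,
                    omega_S_rup=1.0, omega_L_rup=3.0)
    params, env = ModelParameters(
        E0=21.8, E1=5.8, H=25.0, G=5.0, d=0.56, r0=1.7,
        alpha_min=48.0, alpha_c=53.0, alpha_max=169.0,
    ), PhysicalEnvironment()
    sol = kinetic_solution(1.0, params, env, p_S0=0.6, rates=rates, equilibrium=False)
    assert sol.confluent
    M = np.array([[3.0, 0.0], [-2.0, 3.0]])
    P0 = np.array([0.6, 0.4])
    for t in (0.0, 0.1, 0.7, 2.0):
        exact = expm(-M * t) @ P0
        assert survival_probability(sol, t) == pytest.approx(exact.sum(), rel=1e-10)
    tau_quad, _ = quad(lambda t: survival_probability(sol, t), 0, np.inf)
    assert sol.mean_lifetime == pytest.approx(tau_quad, rel=1e-8)


def test_catch_bond_shape(table1):
    """tau(F) has an interior maximum exceeding the low-force lifetime."""
    params, env = table1
    df = predict_table(np.linspace(0.7, 33.0, 23), params, env)
    i = df["tau_s"].idxmax()
    assert 0 < i < len(df) - 1
    assert df["tau_s"][i] > 2 * df["tau_s"].iloc[0]
    assert df["tau_s"][i] > 2 * df["tau_s"].iloc[-1]


def test_bell_limit_log_linear_slope():
    """k1 = 0, no angular barrier, full angular range: slip bond with
    log tau slope -d/kBT (checked past the angular-alignment transient)."""
    env = PhysicalEnvironment()
    bell = ModelParameters(E0=21.8, E1=0.0, H=0.0, G=0.0, d=0.56, r0=1.7,
                           alpha_min=0.1, alpha_c=90.0, alpha_max=179.9)
    Fs = np.arange(5.0, 20.1, 1.5)
    taus = [mean_lifetime(F, bell, env) for F in Fs]
    slope = np.polyfit(Fs, np.log(taus), 1)[0]
    assert slope * env.thermal_energy / bell.d == pytest.approx(-1.0, abs=0.05)


def test_bell_rate_ratio_in_aligned_cone():
    """With the bond axis confined near the force axis the rupture rate
    accelerates exactly as exp(F d / kBT)."""
    env = PhysicalEnvironment()
    cone = ModelParameters(E0=21.8, E1=0.0, H=0.0, G=0.0, d=0.56, r0=1.7,
                           alpha_min=170.5, alpha_c=175.0, alpha_max=179.0)
    base = transition_rates(0.0, cone, env).omega_S_rup
    for F in (2.0, 5.0, 10.0):
        ratio = transition_rates(F, cone, env).omega_S_rup / base
        assert ratio == pytest.approx(math.exp(F * cone.d / env.thermal_energy), rel=0.10)


def test_selectin_limit_single_exponential():
    """No angular barrier but k1 > 0: catch bond with (near) single-
    exponential survival — the minor amplitude is negligible."""
    env = PhysicalEnvironment()
    sel = ModelParameters(E0=21.8, E1=5.8, H=0.0, G=0.0, d=0.56, r0=1.7,
                          alpha_min=0.1, alpha_c=53.0, alpha_max=179.9)
    for F in (2.0, 7.0, 15.0):
        sol = kinetic_solution(F, sel, env)
        assert min(abs(a) for a in sol.amplitudes) < 1e-3


class TestMutationScan:
    def test_double_to_single_exponential_transition(self, table1):
        params, env = table1
        df = scan_parameter("H", [25.0, 20.0, 15.0], [7.0], params, env)
        ratios = {
            row.value: min(abs(row.A1), abs(row.A2)) / max(abs(row.A1), abs(row.A2))
            for row in df.itertuples()
        }
        assert ratios[25.0] > 0.05       # clearly double-exponential
        assert ratios[20.0] < 0.05       # mainly single-exponential
        assert ratios[15.0] < ratios[20.0]

    def test_large_state_collapse_without_barrier(self, table1):
        params, env = table1
        t25 = large_state_duration(10.0, params, env)
        t0 = large_state_duration(10.0, params.replace(H=0.0), env)
        assert t25 > 1.0
        assert t25 / t0 > 1e4            # at least four orders of magnitude

    def test_empty_scan(self, table1):
        params, env = table1
        df = scan_parameter("H", [], [7.0], params, env)
        assert len(df) == 0

    def test_invalid_scan_point_flagged(self, table1):
        params, env = table1
        df = scan_parameter("H", [-5.0, 25.0], [7.0], params, env)
        assert not df[df.value == -5.0].valid.any()
        assert df[df.value == 25.0].valid.all()
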