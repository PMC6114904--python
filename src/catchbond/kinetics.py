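"""Four-rate, two-state reduction of the landscape dynamics.

The two angular basins (small and large inter-domain angle alpha) exchange
population over the cusp barrier and each can rupture through the radial
channel at r = r0 + d.  With intra-well relaxation fast compared to these
four processes the occupancies obey the 2x2 master equation

    dP_S/dt = -(w_SL + w_S_rup) P_S + w_LS P_L
    dP_L/dt =  w_SL P_S - (w_LS + w_L_rup) P_L

with initial condition (p_S0, 1 - p_S0) fixed by the zero-force
equilibrium (the bond equilibrates before force is switched on).  The
survival probability is the double exponential
Sigma_F(t) = A1 exp(-lambda1 t) + A2 exp(-lambda2 t), the mean lifetime is
tau = A1/lambda1 + A2/lambda2 = integral of Sigma_F, and the splitting
probability pi_S is the fraction of ruptures that occur out of the
small-alpha basin.

Each rate is reconstructed from the landscape as an exact one-dimensional
mean-first-passage-time (MFPT) expression on the force-tilted potential of
mean force:

- angular rates: diffusion along the arc s = r0*theta in the radially
  integrated angular potential W(theta), reflecting walls at theta_min and
  theta_max, absorbing point at the *destination* basin minimum.  Placing
  the absorbing point beyond the cusp (not at it) is essential: the cusp
  sides have very different slopes, and first passage to the cusp top from
  the steep side badly overestimates the crossing rate and violates
  detailed balance.
- rupture rates: radial MFPT from the well to the absorbing point
  r0 + d, averaged over the basin's conditional angular distribution
  (force tilts theta within a basin, so a single-angle evaluation is
  biased; a ``"basin-minimum"`` variant is kept for comparison).

All integrals use an exponential-fitting rule that is exact for piecewise
linear potentials, so cusp and near-boundary layers are integrated
accurately on modest grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import (
    InvalidParametersError,
    ModelParameters,
    PhysicalEnvironment,
    angular_free_energy,
    equilibrium_small_angle_probability,
    radial_bounds,
    reduced_potential,
)

__all__ = [
    "RateSet",
    "KineticSolution",
    "transition_rates",
    "kinetic_solution",
    "survival_probability",
    "lifetime_density",
    "mean_lifetime",
    "large_state_duration",
    "scan_parameter",
    "predict_table",
]

_DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class RateSet:
    """The four first-order rates (1/s) of the reduced scheme at one force."""

    force: float
    omega_SL: float   # small -> large alpha barrier crossing
    omega_LS: float   # large -> small alpha
    omega_S_rup: float  # rupture out of the small-alpha basin
    omega_L_rup: float  # rupture out of the large-alpha basin

    def __post_init__(self) -> None:
        rates = (self.omega_SL, self.omega_LS, self.omega_S_rup, self.omega_L_rup)
        # zero angular or rupture rates are legitimate limits (e.g. H -> inf);
        # rates produced from valid parameters at finite force are positive
        if not all(np.isfinite(rates)) or any(r < 0 for r in rates):
            raise FloatingPointError(f"non-finite or negative rate in {self}")


@dataclass(frozen=True)
class KineticSolution:
    """Closed-form solution of the two-state scheme at one force."""

    force: float
    rates: RateSet
    initial_small_fraction: float      # P_S(0) = p_S0 (zero-force equilibrium)
    equilibrium_small_fraction: float  # p_S at this force
    decay_rates: tuple[float, float]   # lambda1 <= lambda2
    amplitudes: tuple[float, float]    # A1 + A2 = 1
    mean_lifetime: float               # tau = integral Sigma_F(t) dt
    large_state_duration: float        # tau_L = 1/(w_LS + w_L_rup)
    splitting_probability: float       # pi_S: rupture happens from small alpha
    confluent: bool = False
    linear_coefficient: float = 0.0    # Sigma = (1 - beta t) e^{-lambda t} if confluent


# ---------------------------------------------------------------------------
# quadrature helpers (exact for piecewise-linear exponents)
# ---------------------------------------------------------------------------

def _seg_exp_integrals(x: np.ndarray, g: np.ndarray, axis: int = 0):
    """Per-segment integrals of exp(g) for g piecewise linear on grid x.

    Returns an array with one fewer element along ``axis``.
    """
    g1 = np.take(g, range(g.shape[axis] - 1), axis=axis)
    g2 = np.take(g, range(1, g.shape[axis]), axis=axis)
    shape = [1] * g.ndim
    shape[axis] = -1
    h = np.diff(x).reshape(shape)
    dg = g2 - g1
    small = np.abs(dg) < 1e-12
    with np.errstate(over="ignore", invalid="ignore"):
        ratio = np.where(small, 1.0 + 0.5 * dg, np.expm1(dg) / np.where(small, 1.0, dg))
    return h * np.exp(g1) * ratio


def _safe_log(x: np.ndarray) -> np.ndarray:
    """log with a relative floor so downstream exp differences stay in range."""
    floor = np.max(x) * 1e-290 + 1e-300
    return np.log(np.maximum(x, floor))


def _cum_from_left(seg: np.ndarray, axis: int = 0) -> np.ndarray:
    """Cumulative integral from the left edge; same length as the grid."""
    c = np.cumsum(seg, axis=axis)
    pad = [(0, 0)] * seg.ndim
    pad[axis] = (1, 0)
    return np.pad(c, pad)


def _cum_from_right(seg: np.ndarray, axis: int = 0) -> np.ndarray:
    c = np.flip(np.cumsum(np.flip(seg, axis=axis), axis=axis), axis=axis)
    pad = [(0, 0)] * seg.ndim
    pad[axis] = (0, 1)
    return np.pad(c, pad)


# ---------------------------------------------------------------------------
# rate reconstruction
# ---------------------------------------------------------------------------

def _angular_grid(params: ModelParameters, n_per_side: int) -> np.ndarray:
    tmin = math.radians(params.theta_min)
    tc = math.radians(params.theta_c)
    tmax = math.radians(params.theta_max)
    return np.concatenate(
        [
            np.linspace(tmin, tc, n_per_side, endpoint=False),
            np.linspace(tc, tmax, n_per_side),
        ]
    )


def _angular_rate(
    theta: np.ndarray,
    W: np.ndarray,
    D_theta: float,
    from_small: bool,
    theta_c: float,
) -> float:
    """Basin-equilibrium-averaged escape rate to the other basin's minimum."""
    in_L = theta <= theta_c
    in_S = ~in_L
    dest = in_L if from_small else in_S
    i_star = np.flatnonzero(dest)[np.argmin(W[dest])]
    if from_small:
        # domain [theta*, theta_max]: absorb left, reflect right
        sl = slice(i_star, None)
        th, w = theta[sl], W[sl]
        inner = _cum_from_right(_seg_exp_integrals(th, -w))      # int_y^{b} e^-W
        outer = _cum_from_left(_seg_exp_integrals(th, w + _safe_log(inner)))
        T = outer / D_theta
        start = th >= theta_c
    else:
        # domain [theta_min, theta*]: absorb right, reflect left
        sl = slice(0, i_star + 1)
        th, w = theta[sl], W[sl]
        inner = _cum_from_left(_seg_exp_integrals(th, -w))        # int_a^y e^-W
        outer = _cum_from_right(_seg_exp_integrals(th, w + _safe_log(inner)))
        T = outer / D_theta
        start = th <= theta_c
    wstart = np.exp(-(W[sl][start] - W[sl][start].min()))
    Tbar = np.trapezoid(T[start] * wstart, th[start]) / np.trapezoid(wstart, th[start])
    return 1.0 / Tbar


def _radial_rupture_rates(
    theta: np.ndarray,
    force: float,
    params: ModelParameters,
    env: PhysicalEnvironment,
    n_r: int,
) -> np.ndarray:
    """Radial MFPT rupture rate 1/T(theta) for every angle (vectorized)."""
    r_lo, r_hi = radial_bounds(params)
    rg = np.linspace(r_lo, r_hi, n_r)
    V = reduced_potential(rg[:, None], theta[None, :], force, params, env)
    V = V - V.min(axis=0, keepdims=True)
    D = env.diffusivity(params.r0)
    seg_m = _seg_exp_integrals(rg, -V, axis=0)
    inner = _cum_from_left(seg_m, axis=0)                         # int_{r_lo}^{y} e^-V
    seg_p = _seg_exp_integrals(rg, V + _safe_log(inner), axis=0)
    T = _cum_from_right(seg_p, axis=0) / D                        # T(x0): int_{x0}^{r_hi}
    w = np.exp(-V)
    Tbar = np.trapezoid(T * w, rg, axis=0) / np.trapezoid(w, rg, axis=0)
    return 1.0 / Tbar


def transition_rates(
    force: float,
    params: ModelParameters,
    env: PhysicalEnvironment,
    *,
    n_theta: int = 600,
    n_r: int = 220,
    rupture: str = "basin-average",
) -> RateSet:
    """Reconstruct the four rates at the given force (pN).

    ``rupture`` selects how the conformation-dependent radial rupture rate
    is reduced to one number per basin: ``"basin-average"`` (default)
    averages 1/T(theta) over the basin's conditional Boltzmann weight;
    ``"basin-minimum"`` evaluates it at the force-tilted basin minimum.
    """
    if force < 0:
        raise InvalidParametersError("force must be non-negative")
    if rupture not in ("basin-average", "basin-minimum"):
        raise ValueError(f"unknown rupture mode {rupture!r}")
    theta = _angular_grid(params, n_theta)
    W = angular_free_energy(theta, force, params, env)
    W = W - W.min()
    D_theta = env.diffusivity(params.r0) / params.r0**2
    tc = math.radians(params.theta_c)
    omega_SL = _angular_rate(theta, W, D_theta, True, tc)
    omega_LS = _angular_rate(theta, W, D_theta, False, tc)

    k_rup = _radial_rupture_rates(theta, force, params, env, n_r)
    out = {}
    for name, mask in (("S", theta >= tc), ("L", theta <= tc)):
        Wb = W[mask]
        if rupture == "basin-average":
            wb = np.exp(-(Wb - Wb.min()))
            out[name] = float(
                np.trapezoid(k_rup[mask] * wb, theta[mask])
                / np.trapezoid(wb, theta[mask])
            )
        else:
            out[name] = float(k_rup[mask][np.argmin(Wb)])
    rates = RateSet(force, omega_SL, omega_LS, out["S"], out["L"])
    return rates


# ---------------------------------------------------------------------------
# two-state solution
# ---------------------------------------------------------------------------

def kinetic_solution(
    force: float,
    params: ModelParameters,
    env: PhysicalEnvironment,
    *,
    p_S0: float | None = None,
    rates: RateSet | None = None,
    equilibrium: bool = True,
    **rate_kw,
) -> KineticSolution:
    """Solve the two-state master equation in closed form at one force.

    ``p_S0`` (the zero-force equilibrium small-alpha probability) may be
    passed in to avoid recomputation across forces; by default it is
    evaluated from the landscape at F = 0.  ``equilibrium=False`` skips the
    (purely diagnostic) equilibrium fraction at this force — useful in
    likelihood loops.
    """
    if rates is None:
        rates = transition_rates(force, params, env, **rate_kw)
    if p_S0 is None:
        p_S0 = equilibrium_small_angle_probability(0.0, params, env)
    p_eq = (
        equilibrium_small_angle_probability(force, params, env)
        if equilibrium
        else float("nan")
    )

    a = rates.omega_SL + rates.omega_S_rup
    e = rates.omega_LS + rates.omega_L_rup
    b = rates.omega_LS
    c = rates.omega_SL
    P0 = np.array([p_S0, 1.0 - p_S0])

    det = a * e - b * c
    T_S = (e * P0[0] + b * P0[1]) / det
    T_L = (c * P0[0] + a * P0[1]) / det
    tau = T_S + T_L
    pi_S = rates.omega_S_rup * T_S
    tau_L = 1.0 / (rates.omega_LS + rates.omega_L_rup)

    m = 0.5 * (a + e)
    s = math.sqrt(max(0.25 * (a - e) ** 2 + b * c, 0.0))
    lam1, lam2 = m - s, m + s
    if s <= _DEGENERACY_TOL * m:
        # confluent limit: Sigma(t) = (1 - beta t) e^{-m t}
        beta = (a - m) * P0[0] - b * P0[1] + (e - m) * P0[1] - c * P0[0]
        return KineticSolution(
            force, rates, p_S0, p_eq, (m, m), (1.0, 0.0), tau, tau_L, pi_S,
            confluent=True, linear_coefficient=beta,
        )
    # Sigma satisfies Sigma'' + (a+e) Sigma' + det Sigma = 0 with Sigma(0)=1
    # and Sigma'(0) = -q, so the amplitudes follow without eigenvectors
    q = rates.omega_S_rup * P0[0] + rates.omega_L_rup * P0[1]
    A1 = (lam2 - q) / (lam2 - lam1)
    A2 = (q - lam1) / (lam2 - lam1)
    return KineticSolution(
        force, rates, p_S0, p_eq, (lam1, lam2), (float(A1), float(A2)),
        tau, tau_L, pi_S,
    )


def survival_probability(sol: KineticSolution, t) -> np.ndarray:
    """Sigma_F(t): probability the bond is intact at time t."""
    t = np.asarray(t, dtype=float)
    l1, l2 = sol.decay_rates
    if sol.confluent:
        return (1.0 - sol.linear_coefficient * t) * np.exp(-l1 * t)
    A1, A2 = sol.amplitudes
    return A1 * np.exp(-l1 * t) + A2 * np.exp(-l2 * t)


def lifetime_density(sol: KineticSolution, t) -> np.ndarray:
    """Rupture-time density -dSigma_F/dt."""
    t = np.asarray(t, dtype=float)
    l1, l2 = sol.decay_rates
    if sol.confluent:
        b = sol.linear_coefficient
        return np.exp(-l1 * t) * (l1 * (1.0 - b * t) + b)
    A1, A2 = sol.amplitudes
    return A1 * l1 * np.exp(-l1 * t) + A2 * l2 * np.exp(-l2 * t)


def mean_lifetime(
    force: float, params: ModelParameters, env: PhysicalEnvironment, **kw
) -> float:
    """Mean bond lifetime tau(F) in seconds."""
    return kinetic_solution(force, params, env, **kw).mean_lifetime


def large_state_duration(
    force: float, params: ModelParameters, env: PhysicalEnvironment, **kw
) -> float:
    """Mean duration tau_L of a visit to the large-alpha state (s).

    Measured from entry into the state until rupture or return to small
    alpha: tau_L = 1/(w_LS + w_L_rup).
    """
    rates = transition_rates(force, params, env, **kw)
    return 1.0 / (rates.omega_LS + rates.omega_L_rup)


# ---------------------------------------------------------------------------
# scans and prediction tables
# ---------------------------------------------------------------------------

def predict_table(
    forces, params: ModelParameters, env: PhysicalEnvironment, **kw
) -> pd.DataFrame:
    """Tidy table of the analytical observables on a force grid."""
    p_S0 = equilibrium_small_angle_probability(0.0, params, env)
    rows = []
    for F in np.asarray(forces, dtype=float):
        sol = kinetic_solution(F, params, env, p_S0=p_S0, **kw)
        rows.append(
            dict(
                force_pN=F,
                tau_s=sol.mean_lifetime,
                tau_L_s=sol.large_state_duration,
                lambda1=sol.decay_rates[0],
                lambda2=sol.decay_rates[1],
                A1=sol.amplitudes[0],
                A2=sol.amplitudes[1],
                p_S=sol.equilibrium_small_fraction,
                pi_S=sol.splitting_probability,
            )
        )
    return pd.DataFrame(rows)


def scan_parameter(
    param_name: str,
    values,
    forces,
    params: ModelParameters,
    env: PhysicalEnvironment,
    **kw,
) -> pd.DataFrame:
    """Scan one landscape parameter, all others fixed (mutation protocol).

    Returns a tidy table with one row per (value, force); parameter values
    that violate model constraints are flagged (``valid = False``) and the
    scan continues.
    """
    if not hasattr(params, param_name):
        raise InvalidParametersError(f"unknown parameter {param_name!r}")
    rows = []
    for v in values:
        try:
            p = params.replace(**{param_name: float(v)})
            p_S0 = equilibrium_small_angle_probability(0.0, p, env)
        except InvalidParametersError:
            for F in np.asarray(forces, dtype=float):
                rows.append({"value": v, "force_pN": F, "valid": False})
            continue
        for F in np.asarray(forces, dtype=float):
            sol = kinetic_solution(F, p, env, p_S0=p_S0, **kw)
            rows.append(
                dict(
                    value=v,
                    force_pN=F,
                    valid=True,
                    tau_s=sol.mean_lifetime,
                    tau_L_s=sol.large_state_duration,
                    lambda1=sol.decay_rates[0],
                    lambda2=sol.decay_rates[1],
                    A1=sol.amplitudes[0],
                    A2=sol.amplitudes[1],
                )
            )
    df = pd.DataFrame(rows)
    for col in ("tau_s", "tau_L_s", "lambda1", "lambda2", "A1", "A2"):
        if col not in df.columns:
            df[col] = np.nan
    return df
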