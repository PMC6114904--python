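"""Independent numerical ground truths for the analytical kinetics.

Two oracles validate the four-rate reduction without sharing any of its
approximations:

1. A finite-volume discretization of the Smoluchowski (overdamped
   Fokker-Planck) generator on the (r, s = r0*theta) rectangle, with
   reflecting walls at theta_min/theta_max/r_lo and an absorbing edge at
   r = r0 + d.  Hopping rates between neighbouring cells use
   exponential fitting (Scharfetter-Gummel), which preserves detailed
   balance with respect to the same configuration-space measure the
   landscape module uses.  Solving the backward equation gives the exact
   mean first-passage time to rupture and the committor-weighted
   probability of rupturing out of the small-alpha region.  This is the
   oracle of choice at high barriers, where direct simulation is
   hopeless (Kramers times of seconds against nanosecond steps).

2. An Euler-Maruyama Brownian-dynamics integrator of the equivalent
   overdamped Langevin equation, usable at low barriers, which also
   yields rupture-time ensembles for distribution-level checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .landscape import (
    InvalidParametersError,
    ModelParameters,
    PhysicalEnvironment,
    radial_bounds,
    reduced_potential,
)

__all__ = [
    "GridSpec",
    "RuptureEnsemble",
    "solve_mfpt",
    "simulate_rupture_times",
    "empirical_survival",
]


@dataclass(frozen=True)
class GridSpec:
    """Finite-volume grid for the Smoluchowski solver."""

    n_r: int = 96
    n_theta: int = 128
    r_lo: float | None = None   # default: landscape radial lower wall
    time_step_hint: float | None = None  # BD only

    def __post_init__(self) -> None:
        if self.n_r < 32 or self.n_theta < 32:
            raise InvalidParametersError("n_r and n_theta must be >= 32")


@dataclass(frozen=True)
class RuptureEnsemble:
    """Simulated rupture times at one force."""

    force: float
    rupture_times: np.ndarray      # s, uncensored records only
    basin_at_rupture: np.ndarray   # "small" / "large", per uncensored record
    censored_times: np.ndarray     # s, horizon hits
    seed: int
    horizon: float

    @property
    def n_ruptured(self) -> int:
        return self.rupture_times.size

    @property
    def n_censored(self) -> int:
        return self.censored_times.size

    def to_frame(self) -> pd.DataFrame:
        """Lifetime-table layout shared with the inference module."""
        f = np.full(self.n_ruptured + self.n_censored, self.force)
        t = np.concatenate([self.rupture_times, self.censored_times])
        cen = np.concatenate(
            [np.zeros(self.n_ruptured, dtype=int), np.ones(self.n_censored, dtype=int)]
        )
        basin = np.concatenate(
            [self.basin_at_rupture, np.full(self.n_censored, "", dtype=object)]
        )
        return pd.DataFrame(
            {"force_pN": f, "lifetime_s": t, "censored": cen, "basin": basin}
        )


# ---------------------------------------------------------------------------
# finite-volume Smoluchowski solver
# ---------------------------------------------------------------------------

def _grid(params: ModelParameters, grid: GridSpec):
    r_lo_default, r_hi = radial_bounds(params)
    r_lo = grid.r_lo if grid.r_lo is not None else r_lo_default
    r = np.linspace(r_lo, r_hi, grid.n_r)          # last row is the absorbing edge
    th = np.linspace(
        math.radians(params.theta_min), math.radians(params.theta_max), grid.n_theta
    )
    return r, th


def _hop_rate(dW: np.ndarray, D: float, h: float) -> np.ndarray:
    """Scharfetter-Gummel rate for a potential step dW (kT) across spacing h."""
    x = dW
    small = np.abs(x) < 1e-12
    with np.errstate(over="ignore"):
        b = np.where(small, 1.0 - 0.5 * x, x / np.expm1(np.where(small, 1.0, x)))
    return D / h**2 * b


def _generator(params, env, force, grid):
    """Sparse backward generator on interior cells + absorbing-edge bookkeeping."""
    r, th = _grid(params, grid)
    W = reduced_potential(r[:, None], th[None, :], force, params, env)
    n_r, n_th = W.shape
    hr = r[1] - r[0]
    hs = params.r0 * (th[1] - th[0])   # arc-length spacing
    D = env.diffusivity(params.r0)

    idx = np.arange(n_r * n_th).reshape(n_r, n_th)
    interior = idx[:-1, :]             # last r-row is absorbing
    rows, cols, vals = [], [], []
    diag = np.zeros(n_r * n_th)
    absorb_rate = np.zeros((n_r - 1, n_th))  # flux into the absorbing edge

    def add(face_from, face_to, rate, absorbing_mask=None):
        # backward generator: (L f)_i = sum_j w_{i->j} (f_j - f_i)
        fr = face_from.ravel()
        to = face_to.ravel()
        rt = rate.ravel()
        rows.extend(fr); cols.extend(to); vals.extend(rt)
        np.add.at(diag, fr, -rt)

    # radial hops (between rows i and i+1), for i = 0..n_r-2
    dW_up = W[1:, :] - W[:-1, :]
    up = _hop_rate(dW_up, D, hr)       # i -> i+1
    down = _hop_rate(-dW_up, D, hr)    # i+1 -> i
    # hops into the absorbing row (i = n_r-2 -> n_r-1) leave the domain
    add(idx[:-2, :], idx[1:-1, :], up[:-1, :])
    fr = idx[-2, :].ravel()
    np.add.at(diag, fr, -up[-1, :].ravel())
    absorb_rate[-1, :] = up[-1, :]
    # downward hops (i+1 -> i), skip from the absorbing row itself
    add(idx[1:-1, :], idx[:-2, :], down[:-1, :])

    # angular hops within interior rows
    dW_right = W[:-1, 1:] - W[:-1, :-1]
    right = _hop_rate(dW_right, D, hs)
    left = _hop_rate(-dW_right, D, hs)
    add(idx[:-1, :-1], idx[:-1, 1:], right)
    add(idx[:-1, 1:], idx[:-1, :-1], left)

    interior_ids = interior.ravel()
    rows.extend(interior_ids); cols.extend(interior_ids); vals.extend(diag[interior_ids])
    L = coo_matrix(
        (vals, (rows, cols)), shape=(n_r * n_th, n_r * n_th)
    ).tocsr()[interior_ids][:, interior_ids]
    return L, W[:-1, :], r, th, absorb_rate


def solve_mfpt(
    force: float,
    params: ModelParameters,
    env: PhysicalEnvironment,
    grid: GridSpec = GridSpec(),
) -> tuple[float, tuple[float, float], float]:
    """Grid MFPT to rupture and the small-basin rupture fraction.

    Returns ``(tau, (tau_from_small, tau_from_large), pi_S)`` where tau is
    averaged over the zero-force equilibrium start (the experimental
    pre-equilibration), the pair conditions the start on each basin, and
    pi_S weights the rupture-channel committor by the same start.
    """
    L, W_int, r, th, absorb = _generator(params, env, force, grid)
    n_int = W_int.size
    ones = np.ones(n_int)
    T = spsolve(L, -ones)
    if not np.all(np.isfinite(T)):
        raise FloatingPointError("MFPT linear solve failed (non-finite solution)")

    # committor onto rupture with theta >= theta_c at the moment of rupture
    tc = math.radians(params.theta_c)
    src = np.zeros_like(W_int)
    src[-1, :] = np.where(th >= tc, absorb[-1, :], 0.0)
    q = spsolve(L, -src.ravel())

    # start distribution: equilibrium at F = 0 on the same grid/measure
    W0 = reduced_potential(r[:-1, None], th[None, :], 0.0, params, env)
    p0 = np.exp(-(W0 - W0.min()))
    p0 /= p0.sum()
    small = (np.ones_like(W0) * (th[None, :] >= tc)).astype(bool)

    tau = float(np.sum(T * p0.ravel()))
    tau_S = float(np.sum(T * (p0 * small).ravel()) / p0[small].sum())
    tau_L = float(np.sum(T * (p0 * ~small).ravel()) / p0[~small].sum())
    pi_S = float(np.sum(q * p0.ravel()))
    return tau, (tau_S, tau_L), pi_S


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

def _grad_reduced_potential(r, th, force, params, env, eps=1e-6):
    """(dW/dr, dW/ds) by central differences of the shared potential."""
    Wp = reduced_potential(r + eps, th, force, params, env)
    Wm = reduced_potential(r - eps, th, force, params, env)
    dWdr = (Wp - Wm) / (2 * eps)
    eth = eps / params.r0
    Wp = reduced_potential(r, th + eth, force, params, env)
    Wm = reduced_potential(r, th - eth, force, params, env)
    dWds = (Wp - Wm) / (2 * eps)
    return dWdr, dWds


def simulate_rupture_times(
    force: float,
    params: ModelParameters,
    env: PhysicalEnvironment,
    n: int,
    seed: int,
    dt: float | None = None,
    horizon: float = 10.0,
) -> RuptureEnsemble:
    """Euler-Maruyama rupture-time ensemble at one force.

    Initial states are drawn from the zero-force equilibrium; reflecting
    boundaries are handled by reflection, rupture by absorption at
    r = r0 + d.  Trajectories that outlive ``horizon`` are recorded as
    censored, never dropped.
    """
    rng = np.random.default_rng(seed)
    D = env.diffusivity(params.r0)
    r_lo, r_hi = radial_bounds(params)
    tmin = math.radians(params.theta_min)
    tmax = math.radians(params.theta_max)
    tc = math.radians(params.theta_c)

    k_stiff = params.k0 + 2 * params.k1
    if dt is None:
        dt = 0.02 / (D * k_stiff)
    if dt * D * k_stiff >= 0.1:
        raise InvalidParametersError(
            f"dt = {dt:g} s too large: dt*D*max|k| = {dt * D * k_stiff:.3g} >= 0.1"
        )

    # rejection-sample the F=0 equilibrium start on a fine grid
    ng = 256
    rg = np.linspace(r_lo, r_hi, ng)
    tg = np.linspace(tmin, tmax, ng)
    W0 = reduced_potential(rg[:, None], tg[None, :], 0.0, params, env)
    p = np.exp(-(W0 - W0.min())).ravel()
    cells = rng.choice(p.size, size=n, p=p / p.sum())
    r = rg[cells // ng] + rng.uniform(-0.5, 0.5, n) * (rg[1] - rg[0])
    th = tg[cells % ng] + rng.uniform(-0.5, 0.5, n) * (tg[1] - tg[0])
    r = np.clip(r, r_lo, r_hi - 1e-9)
    th = np.clip(th, tmin, tmax)

    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    out_t, out_basin = [], []
    sqrt2Ddt = math.sqrt(2 * D * dt)
    # undetected between-step crossings make discrete-time absorption too
    # slow; shift the absorbing wall inward by 0.5826 sqrt(2 D dt) (the
    # standard half-order boundary correction for Euler-Maruyama)
    r_absorb = r_hi - 0.5826 * sqrt2Ddt
    n_steps = int(math.ceil(horizon / dt))
    step = 0
    while alive.any() and step < n_steps:
        # vectorized over the surviving sub-ensemble, in blocks of steps
        block = min(2000, n_steps - step)
        idx = np.flatnonzero(alive)
        rr, tt = r[idx], th[idx]
        done = np.zeros(idx.size, dtype=bool)
        t_local = np.zeros(idx.size)
        basin_small = np.zeros(idx.size, dtype=bool)
        for _ in range(block):
            act = ~done
            if not act.any():
                break
            dWdr, dWds = _grad_reduced_potential(rr[act], tt[act], force, params, env)
            noise = rng.standard_normal((2, act.sum()))
            rr_new = rr[act] - D * dWdr * dt + sqrt2Ddt * noise[0]
            ss_new = tt[act] * params.r0 - D * dWds * dt + sqrt2Ddt * noise[1]
            tt_new = ss_new / params.r0
            # reflect at the three walls
            rr_new = np.where(rr_new < r_lo, 2 * r_lo - rr_new, rr_new)
            tt_new = np.where(tt_new < tmin, 2 * tmin - tt_new, tt_new)
            tt_new = np.where(tt_new > tmax, 2 * tmax - tt_new, tt_new)
            t_local[act] += dt
            ruptured = rr_new >= r_absorb
            sub = np.flatnonzero(act)
            rr[sub] = rr_new
            tt[sub] = tt_new
            newly = sub[ruptured]
            done[newly] = True
            basin_small[newly] = tt[newly] >= tc
        r[idx], th[idx] = rr, tt
        t[idx] += t_local
        finished = idx[done]
        out_t.extend(t[finished])
        out_basin.extend(np.where(basin_small[done], "small", "large"))
        alive[finished] = False
        step += block
    censored = t[alive]
    censored[:] = horizon
    return RuptureEnsemble(
        force=force,
        rupture_times=np.asarray(out_t, dtype=float),
        basin_at_rupture=np.asarray(out_basin, dtype=object),
        censored_times=censored,
        seed=seed,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# survival estimate
# ---------------------------------------------------------------------------

def empirical_survival(ensemble: RuptureEnsemble, alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan-Meier survival estimate with a Greenwood confidence band.

    Returns a step-curve table (t, survival, ci_lower, ci_upper).
    """
    if ensemble.n_ruptured == 0:
        raise InvalidParametersError("all records censored; no survival estimate")
    from lifelines import KaplanMeierFitter

    times = np.concatenate([ensemble.rupture_times, ensemble.censored_times])
    observed = np.concatenate(
        [np.ones(ensemble.n_ruptured), np.zeros(ensemble.n_censored)]
    )
    km = KaplanMeierFitter(alpha=alpha)
    km.fit(times, event_observed=observed)
    ci = km.confidence_interval_survival_function_
    return pd.DataFrame(
        {
            "t": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        }
    )
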