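"""Maximum-likelihood estimation of landscape parameters from lifetime data.

The probability of observing a rupture at time t under force F is the
closed-form double-exponential density -dSigma_F(t)/dt of the two-state
reduction, so the log-likelihood of a dataset of (force, lifetime) records
is a sum of log-densities (censored records, if any, contribute
log Sigma_F(t) instead).  Fitting follows a two-stage protocol: with the
minimum inter-domain angle alpha_min and the offset angle phi held fixed,
the remaining eight parameters {E0, E1, H, G, d, r0, alpha_c, alpha_max}
are optimized; the outer stage repeats this over a grid of (alpha_min, phi)
and keeps the overall optimum.

The local optimization runs in transformed coordinates (logarithms for
positive quantities, log-gaps for the ordering constraints
alpha_min < alpha_c < alpha_max and G <= H), multi-started from a seeded
Latin hypercube over broad physical bounds.  Standard errors come from the
observed information (inverse Hessian of the negative log-likelihood).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .kinetics import kinetic_solution, lifetime_density, survival_probability
from .landscape import (
    InvalidParametersError,
    ModelParameters,
    PhysicalEnvironment,
    equilibrium_small_angle_probability,
)

__all__ = [
    "LifetimeDataset",
    "FitResult",
    "negative_log_likelihood",
    "fit_stage2",
    "fit_full",
]

_DENSITY_FLOOR = 1e-300

#: Broad physical bounds for multi-start initialization (natural units).
_START_BOUNDS = {
    "E0": (5.0, 40.0),
    "E1": (0.5, 20.0),
    "H": (5.0, 40.0),
    "gap_HG": (1.0, 35.0),        # H - G
    "d": (0.1, 2.0),
    "r0": (0.5, 5.0),
    "gap_c": (1.0, 30.0),         # alpha_c - alpha_min, degrees
    "gap_max": (20.0, 140.0),     # alpha_max - alpha_c, degrees
}


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifetimeDataset:
    """Ordered (force, lifetime) records from a force-spectroscopy run."""

    forces: np.ndarray          # pN
    lifetimes: np.ndarray       # s
    censored: np.ndarray        # bool; True = bond survived past `lifetime`
    provenance: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.forces, dtype=float)
        t = np.asarray(self.lifetimes, dtype=float)
        c = np.asarray(self.censored, dtype=bool)
        if not (f.shape == t.shape == c.shape) or f.ndim != 1:
            raise InvalidParametersError("forces/lifetimes/censored must be equal-length 1-d")
        if np.any(t <= 0):
            raise InvalidParametersError("lifetimes must be positive")
        if np.any(f < 0):
            raise InvalidParametersError("forces must be non-negative")
        object.__setattr__(self, "forces", f)
        object.__setattr__(self, "lifetimes", t)
        object.__setattr__(self, "censored", c)

    @classmethod
    def from_arrays(cls, forces, lifetimes, censored=None, provenance=""):
        forces = np.asarray(forces, dtype=float)
        if censored is None:
            censored = np.zeros(forces.shape, dtype=bool)
        return cls(forces, np.asarray(lifetimes, dtype=float),
                   np.asarray(censored, dtype=bool), provenance)

    def __len__(self) -> int:
        return self.forces.size

    @property
    def unique_forces(self) -> np.ndarray:
        return np.unique(self.forces)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"force_pN": self.forces, "lifetime_s": self.lifetimes,
             "censored": self.censored.astype(int)}
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def negative_log_likelihood(
    dataset: LifetimeDataset,
    params: ModelParameters,
    env: PhysicalEnvironment,
    *,
    p_S0: float | None = None,
    **rate_kw,
) -> float:
    """-log L of the dataset under the closed-form lifetime distribution.

    Densities that underflow are clipped at 1e-300 (with a warning), so the
    return value is always finite for valid parameters.
    """
    if len(dataset) == 0:
        return 0.0
    if p_S0 is None:
        p_S0 = equilibrium_small_angle_probability(0.0, params, env)
    nll = 0.0
    n_clipped = 0
    for F in dataset.unique_forces:
        mask = dataset.forces == F
        sol = kinetic_solution(
            F, params, env, p_S0=p_S0, equilibrium=False, **rate_kw
        )
        t = dataset.lifetimes[mask]
        cen = dataset.censored[mask]
        if np.any(~cen):
            dens = lifetime_density(sol, t[~cen])
            n_clipped += int(np.sum(dens < _DENSITY_FLOOR))
            nll -= float(np.sum(np.log(np.maximum(dens, _DENSITY_FLOOR))))
        if np.any(cen):
            surv = survival_probability(sol, t[cen])
            n_clipped += int(np.sum(surv < _DENSITY_FLOOR))
            nll -= float(np.sum(np.log(np.maximum(surv, _DENSITY_FLOOR))))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} record(s) hit the density floor {_DENSITY_FLOOR:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return nll


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

_FREE_NAMES = ("E0", "E1", "H", "G", "d", "r0", "alpha_c", "alpha_max")


def _to_vector(p: ModelParameters) -> np.ndarray:
    """Natural parameters -> unconstrained coordinates."""
    return np.array(
        [
            math.log(p.E0),
            math.log(max(p.E1, 1e-8)),
            math.log(max(p.H, 1e-8)),
            math.log(max(p.H - p.G, 1e-8)),
            math.log(p.d),
            math.log(p.r0),
            math.log(p.alpha_c - p.alpha_min),
            math.log(p.alpha_max - p.alpha_c),
        ]
    )


def _from_vector(x: np.ndarray, alpha_min: float, phi: float) -> ModelParameters:
    e = np.exp(x)
    alpha_c = alpha_min + e[6]
    return ModelParameters(
        E0=e[0], E1=e[1], H=e[2], G=e[2] - e[3], d=e[4], r0=e[5],
        alpha_min=alpha_min, alpha_c=alpha_c, alpha_max=alpha_c + e[7], phi=phi,
    )


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    best_params: ModelParameters
    log_likelihood: float
    standard_errors: dict[str, float]
    stage1_grid: pd.DataFrame
    convergence_report: dict
    seed: int


class FitError(RuntimeError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list):
        super().__init__(message)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# stage-2 local fit (alpha_min, phi fixed)
# ---------------------------------------------------------------------------

def _lhs_starts(n_starts: int, alpha_min: float, phi: float, seed: int):
    names = ("E0", "E1", "H", "gap_HG", "d", "r0", "gap_c", "gap_max")
    lo = np.log([_START_BOUNDS[k][0] for k in names])
    hi = np.log([_START_BOUNDS[k][1] for k in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    pts = lo + sampler.random(n_starts) * (hi - lo)
    out = []
    for x in pts:
        try:
            out.append(_from_vector(x, alpha_min, phi))
        except InvalidParametersError:
            continue
    return out


def fit_stage2(
    dataset: LifetimeDataset,
    fixed: tuple[float, float],
    env: PhysicalEnvironment,
    *,
    init: ModelParameters | None = None,
    n_starts: int = 8,
    seed: int = 0,
    maxiter: int = 4000,
    nm_restarts: int = 4,
    compute_errors: bool = True,
    **rate_kw,
) -> FitResult:
    """Maximize the likelihood over the eight free parameters.

    ``fixed`` is (alpha_min, phi) in degrees.  Starts are drawn from a
    seeded Latin hypercube over broad physical bounds; an explicit ``init``
    is prepended to the start list.  ``rate_kw`` is forwarded to the rate
    reconstruction (coarser grids make fitting faster).
    """
    alpha_min, phi = fixed
    if dataset.unique_forces.size < 2:
        raise InvalidParametersError(
            "at least 2 distinct forces required for a full fit (unidentifiable)"
        )
    starts = []
    if init is not None:
        starts.append(init)
    starts.extend(_lhs_starts(n_starts, alpha_min, phi, seed))
    if not starts:
        raise FitError("no valid starting points", [])

    theta_max_cap = 180.0 - phi - 0.5  # keep theta_min > 0

    def objective(x: np.ndarray) -> float:
        if np.any(np.abs(x) > 50):
            return 1e12
        try:
            p = _from_vector(x, alpha_min, phi)
            if p.alpha_max >= theta_max_cap:
                return 1e10 * (1.0 + p.alpha_max - theta_max_cap)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return negative_log_likelihood(dataset, p, env, **rate_kw)
        except (InvalidParametersError, FloatingPointError, OverflowError):
            return 1e12

    best = None
    diagnostics = []
    for i, p0 in enumerate(starts):
        x0 = _to_vector(p0)
        try:
            # restart the simplex from its own optimum: Nelder-Mead in 8
            # dimensions can collapse prematurely, and a fresh simplex at
            # the incumbent reliably recovers the remaining progress
            fun_prev = np.inf
            nit_total = 0
            for _ in range(nm_restarts):
                res = optimize.minimize(
                    objective, x0, method="Nelder-Mead",
                    options=dict(maxiter=maxiter, xatol=1e-4, fatol=1e-6,
                                 adaptive=True),
                )
                nit_total += int(res.nit)
                x0 = res.x
                if fun_prev - res.fun < 1e-3:
                    break
                fun_prev = res.fun
            diagnostics.append(
                dict(start=i, fun=float(res.fun), nit=nit_total,
                     status=int(res.status), success=bool(res.success))
            )
            if res.fun < 1e9 and (best is None or res.fun < best[0]):
                best = (float(res.fun), res.x, diagnostics[-1])
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append(dict(start=i, error=repr(exc)))
    if best is None:
        raise FitError("all optimization starts failed", diagnostics)

    nll_opt, x_opt, report = best
    p_opt = _from_vector(x_opt, alpha_min, phi)
    errors = (
        _observed_information_errors(dataset, p_opt, env, **rate_kw)
        if compute_errors
        else {k: float("nan") for k in _FREE_NAMES}
    )
    grid = pd.DataFrame(
        [dict(alpha_min=alpha_min, phi=phi, log_likelihood=-nll_opt)]
    )
    return FitResult(
        best_params=p_opt,
        log_likelihood=-nll_opt,
        standard_errors=errors,
        stage1_grid=grid,
        convergence_report=dict(best=report, all_starts=diagnostics),
        seed=seed,
    )


def _observed_information_errors(
    dataset: LifetimeDataset,
    p: ModelParameters,
    env: PhysicalEnvironment,
    **rate_kw,
) -> dict[str, float]:
    """Inverse-Hessian standard errors in the natural parameterization."""
    center = np.array(
        [p.E0, p.E1, p.H, p.G, p.d, p.r0, p.alpha_c, p.alpha_max]
    )
    steps = np.maximum(1e-3 * np.abs(center), 1e-4)

    def f(v: np.ndarray) -> float:
        try:
            q = ModelParameters(
                E0=v[0], E1=v[1], H=v[2], G=v[3], d=v[4], r0=v[5],
                alpha_min=p.alpha_min, alpha_c=v[6], alpha_max=v[7], phi=p.phi,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return negative_log_likelihood(dataset, q, env, **rate_kw)
        except (InvalidParametersError, FloatingPointError):
            return np.nan

    n = center.size
    Hmat = np.full((n, n), np.nan)
    f0 = f(center)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                Hmat[i, i] = (f(center + ei) - 2 * f0 + f(center - ei)) / steps[i] ** 2
            else:
                Hmat[i, j] = Hmat[j, i] = (
                    f(center + ei + ej) - f(center + ei - ej)
                    - f(center - ei + ej) + f(center - ei - ej)
                ) / (4 * steps[i] * steps[j])
    errors = {}
    try:
        cov = np.linalg.pinv(Hmat)
        diag = np.diag(cov)
        for k, v in zip(_FREE_NAMES, diag):
            errors[k] = float(math.sqrt(v)) if np.isfinite(v) and v > 0 else float("nan")
    except np.linalg.LinAlgError:
        errors = {k: float("nan") for k in _FREE_NAMES}
    return errors


# ---------------------------------------------------------------------------
# full two-stage fit
# ---------------------------------------------------------------------------

def fit_full(
    dataset: LifetimeDataset,
    alpha_min_grid,
    phi_grid,
    env: PhysicalEnvironment,
    **stage2_kw,
) -> FitResult:
    """Grid the outer (alpha_min, phi) stage and keep the overall optimum.

    Failed grid cells are flagged in the stage1 table; an empty grid or a
    grid with no successful cell raises.
    """
    alpha_min_grid = list(alpha_min_grid)
    phi_grid = list(phi_grid)
    if not alpha_min_grid or not phi_grid:
        raise InvalidParametersError("empty (alpha_min, phi) grid")
    rows = []
    best: FitResult | None = None
    compute_errors = stage2_kw.pop("compute_errors", True)
    for a in alpha_min_grid:
        for ph in phi_grid:
            try:
                fr = fit_stage2(
                    dataset, (a, ph), env, compute_errors=False, **stage2_kw
                )
                rows.append(dict(alpha_min=a, phi=ph,
                                 log_likelihood=fr.log_likelihood, ok=True))
                if best is None or fr.log_likelihood > best.log_likelihood:
                    best = fr
            except (FitError, InvalidParametersError) as exc:
                rows.append(dict(alpha_min=a, phi=ph,
                                 log_likelihood=float("nan"), ok=False,
                                 error=repr(exc)))
    if best is None:
        raise FitError("every (alpha_min, phi) grid cell failed", rows)
    if compute_errors:
        rate_kw = {k: v for k, v in stage2_kw.items()
                   if k not in ("init", "n_starts", "seed", "maxiter", "nm_restarts")}
        best.standard_errors = _observed_information_errors(
            dataset, best.best_params, env, **rate_kw
        )
    best.stage1_grid = pd.DataFrame(rows)
    return best
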