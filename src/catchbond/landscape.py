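"""Two-basin energy landscape of the cadherin-catenin-actin bond.

The bond between the F-actin binding domain (FABD) of alpha-E-catenin and
actin is described by two collective coordinates: the hinge-to-interface
distance ``r`` (nm) and the angle ``theta`` (degrees) between the
hinge-to-interface vector and the force axis.  The Hamiltonian is

    U(r, theta) = (1/2) k(theta) (r - r0)^2 - F r cos(theta) + C(theta)

with an angle-dependent bond stiffness ``k(theta) = k0 + k1 (1 + cos theta)``
and a cusp-like angular potential ``C(theta)`` that is piecewise linear in
``cos theta`` and splits the angular range into a small inter-domain-angle
basin (alpha <= alpha_c, i.e. theta >= theta_c) and a large-angle basin.
The inter-domain angle alpha of the M2-M3 bundles maps to theta through
``alpha = 180 deg - theta - phi``.

All energies are expressed in units of k_B*T, lengths in nm, forces in pN
and angles in degrees at the interface (radians internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "PhysicalEnvironment",
    "ModelParameters",
    "LandscapeState",
    "InvalidParametersError",
    "DegenerateGeometryError",
    "theta_from_alpha",
    "alpha_from_theta",
    "stiffness_from_energies",
    "energies_from_stiffness",
    "spring_constant",
    "angular_potential",
    "potential_energy",
    "log_measure",
    "reduced_potential",
    "radial_bounds",
    "angular_free_energy",
    "basin_log_weights",
    "equilibrium_small_angle_probability",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM_PER_K = 0.01380649

MEASURES = ("polar", "flat", "spherical")


class InvalidParametersError(ValueError):
    """Raised when a parameter set violates a model constraint."""


class DegenerateGeometryError(InvalidParametersError):
    """Raised when the angular geometry collapses (theta_min == theta_max)."""


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalEnvironment:
    """Solvent conditions and the configuration-space measure convention.

    Parameters
    ----------
    temperature_K:
        Absolute temperature.  The default 298.0 K gives a thermal energy
        k_B*T = 4.114 pN nm, the room-temperature value appropriate for an
        optical-tweezer experiment.
    viscosity_Pa_s:
        Solvent (water) viscosity used in the Stokes estimate of the
        domain diffusivity.
    measure:
        Configuration-space weight for equilibrium averages and for the
        one-dimensional reductions of the dynamics:

        - ``"polar"`` (default): planar polar coordinates, weight
          ``r dr dtheta``.  The applied force and the domain vector define
          the rotation plane, so the reorientation is effectively planar.
        - ``"flat"``: Cartesian weight ``dr dtheta`` (coordinates (r, s)
          with arc length s = r0*theta).
        - ``"spherical"``: full 3-d weight ``r^2 sin(theta) dr dtheta``
          with the azimuth integrated out.
    """

    temperature_K: float = 298.0
    viscosity_Pa_s: float = 8.9e-4
    measure: str = "polar"

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise InvalidParametersError("temperature_K must be positive")
        if self.viscosity_Pa_s <= 0:
            raise InvalidParametersError("viscosity_Pa_s must be positive")
        if self.measure not in MEASURES:
            raise InvalidParametersError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )

    @property
    def thermal_energy(self) -> float:
        """k_B*T in pN nm."""
        return BOLTZMANN_PN_NM_PER_K * self.temperature_K

    def diffusivity(self, r0_nm: float) -> float:
        """Stokes diffusivity D = k_B*T / (6 pi eta r0) in nm^2/s.

        The reorienting protein region has characteristic size ``r0``;
        shape prefactors are ignored (they enter fitted energies only
        logarithmically).
        """
        eta = self.viscosity_Pa_s * 1e-6  # Pa s -> pN s / nm^2
        return self.thermal_energy / (6.0 * math.pi * eta * r0_nm)


# ---------------------------------------------------------------------------
# angle and stiffness conversions
# ---------------------------------------------------------------------------

def theta_from_alpha(alpha_deg: float, phi_deg: float) -> float:
    """Convert the M2-M3 inter-domain angle alpha to the force-axis angle theta.

    Geometry: ``alpha = 180 deg - theta - phi`` where phi is the offset of
    the M2 domain relative to the force (actin) axis.
    """
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any((alpha <= 0.0) | (alpha >= 180.0)):
        raise InvalidParametersError(
            f"alpha must lie in (0, 180) degrees, got {alpha_deg!r}"
        )
    out = 180.0 - alpha - np.asarray(phi_deg, dtype=float)
    return float(out) if out.ndim == 0 else out


def alpha_from_theta(theta_deg: float, phi_deg: float) -> float:
    """Inverse of :func:`theta_from_alpha`."""
    out = 180.0 - np.asarray(theta_deg, dtype=float) - np.asarray(phi_deg, dtype=float)
    return float(out) if out.ndim == 0 else out


def stiffness_from_energies(
    E0: float, E1: float, d: float, theta_min_deg: float, theta_max_deg: float
) -> tuple[float, float]:
    """Convert rupture-barrier energies (E0, E1) to stiffness coefficients (k0, k1).

    Definitions: the zero-force rupture barrier is ``k(theta) d^2 / 2``,
    which equals E0 at theta_max (the small-angle basin floor) and E0 + E1
    at theta_min, giving

        k1 = 2 E1 / (d^2 (cos theta_min - cos theta_max))
        k0 = 2 E0 / d^2 - k1 (1 + cos theta_max)

    Units: energies in k_B*T, d in nm, output stiffness in k_B*T / nm^2.
    """
    if d <= 0:
        raise InvalidParametersError("d must be positive")
    tmin, tmax = math.radians(theta_min_deg), math.radians(theta_max_deg)
    dcos = math.cos(tmin) - math.cos(tmax)
    if math.isclose(theta_min_deg, theta_max_deg, abs_tol=1e-12):
        raise DegenerateGeometryError("theta_min == theta_max")
    if dcos <= 0:
        raise InvalidParametersError("requires theta_min < theta_max in (0, 180)")
    k1 = 2.0 * E1 / (d * d * dcos)
    k0 = 2.0 * E0 / (d * d) - k1 * (1.0 + math.cos(tmax))
    if k0 < 0:
        raise InvalidParametersError(
            f"implied k0 = {k0:.4g} k_B T/nm^2 is negative; E1 too large "
            "relative to E0 for this angular range"
        )
    return k0, k1


def energies_from_stiffness(
    k0: float, k1: float, d: float, theta_min_deg: float, theta_max_deg: float
) -> tuple[float, float]:
    """Inverse of :func:`stiffness_from_energies`."""
    tmin, tmax = math.radians(theta_min_deg), math.radians(theta_max_deg)
    E0 = (k0 + k1 * (1.0 + math.cos(tmax))) * d * d / 2.0
    E1 = k1 * (math.cos(tmin) - math.cos(tmax)) * d * d / 2.0
    return E0, E1


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Full landscape parameterization.

    Energies (E0, E1, H, G) in k_B*T, lengths (d, r0) in nm, angles in
    degrees.  E0 is the rupture barrier at alpha_min and zero force; E1 the
    extra barrier at alpha_max; H the small-to-large alpha barrier; G the
    free-energy offset of the large-alpha basin above the small-alpha one
    (the reverse barrier is H - G).
    """

    E0: float
    E1: float
    H: float
    G: float
    d: float
    r0: float
    alpha_min: float
    alpha_c: float
    alpha_max: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        checks = [
            (self.E0 > 0, "E0 > 0"),
            (self.E1 >= 0, "E1 >= 0"),
            # H - G may be negative: the mutation protocol lowers H with G
            # fixed, which simply removes the return barrier of the
            # large-angle basin (the landscape stays well defined)
            (self.H >= 0, "H >= 0"),
            (self.d > 0, "d > 0"),
            (self.r0 > 0, "r0 > 0"),
            (0.0 < self.alpha_min, "alpha_min > 0"),
            (self.alpha_min < self.alpha_c, "alpha_min < alpha_c"),
            (self.alpha_c < self.alpha_max, "alpha_c < alpha_max"),
            (self.alpha_max < 180.0, "alpha_max < 180"),
            (self.theta_min >= 0.0, "theta_min >= 0 (alpha_max + phi <= 180)"),
            (self.theta_max <= 180.0, "theta_max <= 180"),
        ]
        for ok, label in checks:
            if not ok:
                raise InvalidParametersError(f"constraint violated: {label}")
        # materialize stiffness now so invalid (E0, E1) pairs fail loudly
        _ = self.k0

    # angular geometry -----------------------------------------------------
    @property
    def theta_min(self) -> float:
        return alpha_from_theta(self.alpha_max, self.phi)  # same affine map

    @property
    def theta_c(self) -> float:
        return alpha_from_theta(self.alpha_c, self.phi)

    @property
    def theta_max(self) -> float:
        return alpha_from_theta(self.alpha_min, self.phi)

    # stiffness ------------------------------------------------------------
    @cached_property
    def _k0k1(self) -> tuple[float, float]:
        return stiffness_from_energies(
            self.E0, self.E1, self.d, self.theta_min, self.theta_max
        )

    @property
    def k0(self) -> float:
        return self._k0k1[0]

    @property
    def k1(self) -> float:
        return self._k0k1[1]

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class LandscapeState:
    """A point (r, theta) of the landscape under force F."""

    r: float
    theta: float
    force: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise InvalidParametersError("r >= 0 required")
        if self.force < 0:
            raise InvalidParametersError("force >= 0 required")


# ---------------------------------------------------------------------------
# Hamiltonian pieces
# ---------------------------------------------------------------------------

def spring_constant(theta_deg, params: ModelParameters):
    """Bond stiffness k(theta) = k0 + k1 (1 + cos theta) in k_B*T/nm^2."""
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    _check_angular_range(theta_deg, params)
    out = params.k0 + params.k1 * (1.0 + np.cos(theta))
    return float(out) if out.ndim == 0 else out


def angular_potential(theta_deg, params: ModelParameters):
    """Cusp-like angular potential C(theta) in k_B*T.

    Piecewise linear in cos(theta): C(theta_max) = 0, C(theta_c) = H from
    both sides (continuous cusp), C(theta_min) = G.
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    _check_angular_range(theta_deg, params)
    out = _angular_potential_rad(theta, params)
    return float(out) if out.ndim == 0 else out


def _angular_potential_rad(theta_rad, params: ModelParameters):
    c = np.cos(theta_rad)
    c_min = math.cos(math.radians(params.theta_min))
    c_c = math.cos(math.radians(params.theta_c))
    c_max = math.cos(math.radians(params.theta_max))
    tc = math.radians(params.theta_c)
    with np.errstate(invalid="ignore"):
        small = params.H * (c - c_max) / (c_c - c_max)  # theta >= theta_c branch
        large = (params.H - params.G) * (c - c_min) / (c_c - c_min) + params.G
    return np.where(theta_rad >= tc, small, large)


def _check_angular_range(theta_deg, params: ModelParameters, tol: float = 1e-9) -> None:
    th = np.asarray(theta_deg, dtype=float)
    if np.any(th < params.theta_min - tol) or np.any(th > params.theta_max + tol):
        raise InvalidParametersError(
            f"theta = {theta_deg!r} outside "
            f"[{params.theta_min:.6g}, {params.theta_max:.6g}] degrees"
        )


def potential_energy(
    state: LandscapeState, params: ModelParameters, env: PhysicalEnvironment
) -> float:
    """Hamiltonian U(r, theta) in k_B*T at the given state.

    Points beyond the rupture surface r > r0 + d are allowed (useful for
    plotting) but are outside the bound-state domain.
    """
    _check_angular_range(state.theta, params)
    return float(
        _reduced_hamiltonian(
            np.asarray(state.r, float),
            np.radians(state.theta),
            state.force,
            params,
            env,
        )
    )


def _reduced_hamiltonian(r, theta_rad, force_pN, params, env):
    """U / k_B*T on arrays (r in nm, theta in radians)."""
    k = params.k0 + params.k1 * (1.0 + np.cos(theta_rad))
    f = force_pN / env.thermal_energy  # 1/nm
    return (
        0.5 * k * (r - params.r0) ** 2
        - f * r * np.cos(theta_rad)
        + _angular_potential_rad(theta_rad, params)
    )


# ---------------------------------------------------------------------------
# measure and equilibrium quantities
# ---------------------------------------------------------------------------

def log_measure(r, theta_rad, params: ModelParameters, env: PhysicalEnvironment):
    """Logarithm of the configuration-space weight, up to a constant.

    polar: log(r/r0); flat: 0; spherical: 2 log(r/r0) + log sin(theta).
    Shared by the equilibrium integrals, the kinetic reductions and the
    grid solver so that all use one consistent measure.
    """
    r = np.asarray(r, dtype=float)
    theta_rad = np.asarray(theta_rad, dtype=float)
    if env.measure == "flat":
        return np.zeros(np.broadcast(r, theta_rad).shape)
    if env.measure == "polar":
        return np.broadcast_to(np.log(r / params.r0), np.broadcast(r, theta_rad).shape)
    return 2.0 * np.log(r / params.r0) + np.log(np.sin(theta_rad))


def reduced_potential(r, theta_rad, force_pN, params, env):
    """Dimensionless potential of mean force W = U/k_B*T - log(measure).

    The equilibrium density in (r, theta) is proportional to exp(-W).
    """
    return _reduced_hamiltonian(r, theta_rad, force_pN, params, env) - log_measure(
        r, theta_rad, params, env
    )


def radial_bounds(params: ModelParameters, n_sigma: float = 6.0) -> tuple[float, float]:
    """Radial integration domain [r_lo, r0 + d].

    The lower wall sits n_sigma thermal widths below r0 (widths evaluated
    at the stiffest angle so every well is covered); contributions beyond
    are negligible at the stiffnesses of interest.
    """
    k_max = params.k0 + params.k1 * (1.0 + math.cos(math.radians(params.theta_min)))
    k_soft = params.k0 + params.k1 * (1.0 + math.cos(math.radians(params.theta_max)))
    sigma = 1.0 / math.sqrt(min(k_soft, k_max))
    r_lo = max(1e-6 * params.r0, params.r0 - n_sigma * sigma)
    return r_lo, params.r0 + params.d


def _gauss_legendre(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


def angular_free_energy(
    theta_rad, force_pN, params, env, n_r: int = 128
):
    """Effective 1-d angular potential W(theta) in k_B*T (up to a constant).

    Obtained by integrating the measure-weighted Boltzmann factor over the
    bound radial domain:  exp(-W(theta)) = int dr m(r, theta) exp(-U/kT).
    """
    theta_rad = np.atleast_1d(np.asarray(theta_rad, dtype=float))
    r_lo, r_hi = radial_bounds(params)
    rg, rw = _gauss_legendre(r_lo, r_hi, n_r)
    lw = -reduced_potential(rg[:, None], theta_rad[None, :], force_pN, params, env)
    m = lw.max(axis=0)
    z = np.log(np.einsum("i,ij->j", rw, np.exp(lw - m))) + m
    return -z


def basin_log_weights(
    force_pN: float, params: ModelParameters, env: PhysicalEnvironment,
    n_theta: int = 200, n_r: int = 128,
) -> tuple[float, float]:
    """(log Z_S, log Z_L): Boltzmann weights of the small/large-alpha basins.

    Small-alpha basin: alpha <= alpha_c, i.e. theta in [theta_c, theta_max].
    """
    tmin = math.radians(params.theta_min)
    tc = math.radians(params.theta_c)
    tmax = math.radians(params.theta_max)
    out = []
    for a, b in ((tc, tmax), (tmin, tc)):
        tg, tw = _gauss_legendre(a, b, n_theta)
        W = angular_free_energy(tg, force_pN, params, env, n_r=n_r)
        m = -W.max() if not np.all(np.isfinite(W)) else W.min()
        out.append(math.log(float(np.sum(tw * np.exp(-(W - m))))) - m)
    return out[0], out[1]


def equilibrium_small_angle_probability(
    force_pN: float, params: ModelParameters, env: PhysicalEnvironment, **kw
) -> float:
    """Equilibrium probability p_S(F) of the small-alpha basin (alpha <= alpha_c).

    At F = 0 this is the pre-equilibration probability p_S0 used as the
    initial condition of the kinetic scheme.
    """
    if force_pN < 0:
        raise InvalidParametersError("force must be non-negative")
    lnZS, lnZL = basin_log_weights(force_pN, params, env, **kw)
    return float(1.0 / (1.0 + math.exp(lnZL - lnZS)))
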