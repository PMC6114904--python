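"""Experiment-like synthetic lifetime datasets.

The optical-tweezer dataset the model was fitted to (803 bond lifetimes at
forces between 0.7 and 33 pN) is not publicly deposited, so downstream
stages are exercised on synthetic data drawn *exactly* from the model: for
each measurement a force is drawn from the design, the initial basin is
Bernoulli with the zero-force equilibrium probability p_S0 (the bond
equilibrates before load is applied), and the three-state Markov chain
{small, large, ruptured} with the analytic rates at that force is
simulated by the Gillespie algorithm.  Marginal lifetimes at each force
are then distributed exactly as -dSigma_F/dt by construction, which
cleanly separates "does the likelihood machinery invert the model?" from
"is the two-state reduction itself valid?" (the oracle module's job).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import LifetimeDataset
from .kinetics import RateSet, transition_rates
from .landscape import (
    InvalidParametersError,
    ModelParameters,
    PhysicalEnvironment,
    equilibrium_small_angle_probability,
)

__all__ = ["ExperimentDesign", "default_design", "sample_dataset", "gillespie_rupture_times"]

#: Default force levels (pN): 12 levels spanning the experimental range
#: 0.7-33 pN, anchored on the published survival-curve force 15.1 pN.
DEFAULT_FORCE_LEVELS = (0.7, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 15.1, 18.0, 22.0, 27.0, 33.0)

#: Sampling weights decrease toward high force, imitating the sparser
#: high-force coverage of bead experiments (the true per-force counts are
#: unpublished, so this is an explicit, overridable design choice).
DEFAULT_LEVEL_WEIGHTS = (1.4, 1.4, 1.2, 1.2, 1.0, 1.0, 0.8, 0.8, 0.6, 0.6, 0.5, 0.5)


@dataclass(frozen=True)
class ExperimentDesign:
    """Force schedule for a synthetic force-spectroscopy run."""

    n_measurements: int = 803
    force_levels: tuple[float, ...] = DEFAULT_FORCE_LEVELS
    level_weights: tuple[float, ...] = DEFAULT_LEVEL_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_measurements <= 0:
            raise InvalidParametersError("n_measurements must be positive")
        if len(self.force_levels) != len(self.level_weights):
            raise InvalidParametersError("force_levels and level_weights length mismatch")
        if any(w < 0 for w in self.level_weights) or sum(self.level_weights) <= 0:
            raise InvalidParametersError("level_weights must be non-negative, not all zero")
        if any(f < 0 for f in self.force_levels):
            raise InvalidParametersError("forces must be non-negative")

    @property
    def probabilities(self) -> np.ndarray:
        w = np.asarray(self.level_weights, dtype=float)
        return w / w.sum()


def default_design(n: int = 803, seed: int = 0) -> ExperimentDesign:
    return ExperimentDesign(n_measurements=n, seed=seed)


def gillespie_rupture_times(
    rates: RateSet, start_small: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exact rupture times of the 3-state chain for a batch of bonds.

    Vectorized over bonds: while any bond is unruptured, draw the next
    waiting time from the current state's total rate and pick the channel.
    Returns ``(times, ruptured_from_small)``.
    """
    n = start_small.size
    t = np.zeros(n)
    small = start_small.copy()
    alive = np.ones(n, dtype=bool)
    a_S = rates.omega_SL + rates.omega_S_rup
    a_L = rates.omega_LS + rates.omega_L_rup
    p_flip_S = rates.omega_SL / a_S
    p_flip_L = rates.omega_LS / a_L
    while alive.any():
        idx = np.flatnonzero(alive)
        tot = np.where(small[idx], a_S, a_L)
        t[idx] += rng.exponential(1.0 / tot)
        flip_p = np.where(small[idx], p_flip_S, p_flip_L)
        flips = rng.random(idx.size) < flip_p
        small[idx[flips]] = ~small[idx[flips]]
        alive[idx[~flips]] = False
    return t, small


def sample_dataset(
    design: ExperimentDesign,
    params: ModelParameters,
    env: PhysicalEnvironment,
    **rate_kw,
) -> LifetimeDataset:
    """Draw a lifetime dataset exactly from the two-state model.

    Records are returned sorted by force then lifetime; the generator is
    deterministic under the design's seed.
    """
    rng = np.random.default_rng(design.seed)
    p_S0 = equilibrium_small_angle_probability(0.0, params, env)
    levels = np.asarray(design.force_levels, dtype=float)
    counts = rng.multinomial(design.n_measurements, design.probabilities)
    forces, times = [], []
    for F, m in zip(levels, counts):
        if m == 0:
            continue
        rates = transition_rates(F, params, env, **rate_kw)
        start_small = rng.random(m) < p_S0
        lt, _ = gillespie_rupture_times(rates, start_small, rng)
        forces.append(np.full(m, F))
        times.append(lt)
    F = np.concatenate(forces)
    T = np.concatenate(times)
    order = np.lexsort((T, F))
    return LifetimeDataset.from_arrays(
        F[order], T[order],
        provenance=f"synthetic Gillespie sample, seed={design.seed}, "
                   f"n={design.n_measurements}",
    )
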