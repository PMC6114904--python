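# Methods

## Model

The bound cadherin–catenin–actin complex is described by two collective
coordinates: the distance r (nm) from the M2/M3 hinge of αE-catenin to
the FABD–actin interface, and the polar angle θ between that vector and
the force axis (the actin filament direction).  The Hamiltonian

U(r, θ) = ½ k(θ)(r − r₀)² − F r cos θ + C(θ),  k(θ) = k₀ + k₁(1 + cos θ)

couples conformation to bond strength: smaller θ (larger inter-domain
angle α = 180° − θ − φ) stiffens the bond, raising the rupture barrier
k(θ)d²/2 from E₀ (at α_min) to E₀+E₁ (at α_max).  C(θ) is piecewise
linear in cos θ with a cusp of height H at the transition angle α_c and a
basin offset G, dividing configuration space into the small-α basin
(α ≤ α_c) and the large-α basin.  Rupture is absorption at r = r₀ + d;
θ_min and θ_max are reflecting.  Dynamics are overdamped diffusion with
isotropic Stokes diffusivity D = k_BT/6πηr₀ in the coordinates (r,
s = r₀θ); shape prefactors in D are ignored (they enter fitted energies
only logarithmically).

Units: energies in k_BT, lengths in nm, forces in pN, time in s, angles
in degrees at every interface (radians internally).  Defaults:
T = 298.0 K (k_BT = 4.114 pN nm — the value 4.114 fixes T at 298.0 rather
than 298.15, keeping the thermal energy exact to four significant
figures) and η = 8.9×10⁻⁴ Pa s.

## Configuration-space measure

The equilibrium weight exp(−U/k_BT)·m(r, θ) requires a measure choice
that the model statement alone does not fix.  Three are implemented
behind one switch (`PhysicalEnvironment.measure`):

- `polar` (default): m = r.  The applied force and the domain vector
  define a plane, and the hinge rotation the model pictures is a
  rotation in that plane, so the natural configuration space is the
  2-d (r, θ) polar plane.
- `flat`: m = 1, i.e. Cartesian (r, s).
- `spherical`: m = r² sin θ, the full 3-d vector with azimuth
  integrated out.

The choice is consequential.  With the published wild-type parameters the
zero-force small-α occupancy p_S0 is 0.728 (polar and flat agree to
three digits; the r-Jacobian is nearly constant over the thermal well)
versus 0.850 (spherical), and downstream the spherical sin θ factor
suppresses the large-α basin near θ_min enough to move every observable.
The polar measure was adopted because it reproduces the published
observable set best as a whole: splitting probability 0.43 (published
0.47 ± 0.05), peak lifetime 1.27 s (published ≈ 1.1 s, ±30%), large-state
duration at 10 pN 2.4 s (> 1 s), p_S(15.1 pN) ≈ 1.2×10⁻⁴ (published
10⁻⁴), while spherical misses the splitting probability and peak
lifetime on the opposite side and puts p_S0 at 0.85.

The one number no measure reproduces exactly is p_S0 = 0.77 (we compute
0.728, confirmed by independent adaptive 2-d quadrature).  The computed
value is highly sensitive to parameters that are published rounded:
within the stated uncertainties (α_c = 53(3)°, G = 5(2) k_BT,
H = 25(2) k_BT) it spans well past 0.77 — e.g. α_c = 54° alone gives
≈ 0.765.  We therefore report the exact-quadrature value for the rounded
published parameter set rather than tuning anything toward 0.77.

The radial domain is [max(0, r₀ − 6σ), r₀ + d] with σ the softest-well
thermal width (≈ 0.085 nm ≪ r₀); contributions beyond 6σ are negligible
at these stiffnesses.

## Rate reconstruction

Each of the four rates is an exact 1-d mean-first-passage-time (MFPT)
integral, not a saddle-point formula, which removes all prefactor
ambiguity for cusped and force-tilted potentials:

- **Angular rates** use the radially integrated free energy
  W(θ) = −k_BT ln ∫ dr m e^{−U/k_BT} on the arc s = r₀θ with diffusivity
  D.  The MFPT double integral runs from a basin-equilibrium-weighted
  start to an absorbing point at the *destination basin's minimum*, with
  the far wall reflecting.  Absorbing at the cusp itself would be wrong:
  a cusp has asymmetric slopes (≈ 276 vs ≈ 10 k_BT/rad here), first
  passage to the top from the steep side is fast but almost always
  recrosses, and the resulting "rates" violate detailed balance by a
  factor ≈ 27.  With the full-path formulation, ω_SL/ω_LS equals the
  basin weight ratio Z_L/Z_S to better than 10⁻³ at all forces.
- **Rupture rates** are radial MFPTs to the absorbing point r₀ + d in
  ½k(θ)(r−r₀)² − F r cos θ (plus the measure term), with
  equilibrium-averaged radial start, averaged as 1/T(θ) over the basin's
  conditional angular distribution.  Averaging matters because force
  tilts θ within a basin; an evaluate-at-the-minimum variant
  (`rupture="basin-minimum"`) is provided for comparison and changes
  observables by < 1% at the wild-type barriers.

All integrals use an exponential-fitting segment rule (exact for
piecewise-linear exponents), so boundary layers of width k_BT/|W′| are
integrated accurately on modest grids.  Defaults n_θ = 600 per basin
side and n_r = 220 are converged to ~10⁻⁵ relative; the fitting code
path uses n_θ = 100, n_r = 80 (verified 10⁻³-accurate, ~4 ms per force).

## Two-state solution

With rates in hand, the occupancies obey a 2×2 master equation with
initial condition (p_S0, 1 − p_S0) — the bond equilibrates at zero force
before load onset.  Σ_F(t) = A₁e^{−λ₁t} + A₂e^{−λ₂t} follows in closed
form; amplitudes are computed from Σ″ + (a+e)Σ′ + det·Σ = 0 via
A₁ = (λ₂ − q)/(λ₂ − λ₁) with q = ω_S^rup p_S0 + ω_L^rup (1 − p_S0),
which is robust when individual rates vanish (limits).  τ and π_S come
from the inverse rate matrix (exact regardless of eigenvalue spacing);
degenerate eigenvalues (|λ₁−λ₂| < 10⁻¹⁰λ₂) switch Σ to the confluent
form (1 − βt)e^{−λt}.  τ_L = 1/(ω_LS + ω_L^rup).

The mutation protocol (scan of H at fixed G) can make H < G; the
landscape remains well defined — the large-α basin simply loses its
return barrier — so validation permits it.

## Numerical oracles

Because the wild-type barriers (21.8–27.6 k_BT) put direct simulation out
of reach (Kramers times of seconds against ~10⁻¹² s stable steps), the
reduction is validated with two independent numerical solvers at scaled
barriers:

1. **Grid MFPT**: finite-volume discretization of the Smoluchowski
   backward operator on (r, s) with Scharfetter–Gummel hopping rates
   (detailed balance preserved on the grid for the same measure the
   landscape uses), absorbing top edge, reflecting elsewhere.  Sparse
   direct solves give the MFPT field and the small-basin rupture
   committor.  Convergence is second order; τ changes < 1% on grid
   doubling.  At Table-1 geometry with barriers scaled into 4–9 k_BT the
   closed-form τ agrees with the grid within a few percent (tolerance
   25%).
2. **Brownian dynamics**: Euler–Maruyama in (r, s) with reflection at
   walls and absorption at r₀ + d.  The absorbing wall is shifted inward
   by 0.5826·√(2DΔt) to correct the O(√Δt) bias from undetected
   between-step crossings; the default step obeys Δt·D·k_max = 0.02.
   At low barriers BD means agree with both the grid solver and the
   closed form within statistical error, and the analytic Σ_F(t) lies
   inside the Kaplan–Meier 95% band.

## Synthetic data

The experimental dataset (803 lifetimes, 0.7–33 pN) is not deposited, so
the generator emulates it: 12 force levels spanning 0.7–33 pN (anchored
on the published survival-panel force 15.1 pN) with sampling weights
decreasing toward high force, mimicking the sparser high-force coverage
of bead assays; the true per-force counts are unpublished, so the design
is explicit configuration, not hard-coded.  Each record draws its
initial basin Bernoulli(p_S0) and runs the exact Gillespie chain
{S, L, ruptured} on the analytic rates, so marginal lifetimes follow
−dΣ_F/dt *by construction*.  This cleanly separates "does maximum
likelihood invert the model?" (tested on Gillespie data) from "is the
two-state reduction valid?" (tested by the oracles).  What passing the
recovery tests does **not** show: robustness to instrument noise, force
calibration error, bead relaxation, or model misspecification — none of
which are modelled.

## Maximum likelihood

Uncensored records contribute log(−dΣ_F/dt), censored ones log Σ_F
(censoring support is an addition; the published analysis reports none;
default off).  Underflowing densities are clipped at 10⁻³⁰⁰ with a
warning, never NaN.  Fitting follows the two-stage protocol: inner
optimization over {E₀, E₁, H, G, d, r₀, α_c, α_max} with (α_min, φ)
fixed, outer grid over (α_min, φ).  The inner stage runs Nelder–Mead in
transformed coordinates — logs of positive quantities and of the ordered
gaps α_c − α_min, α_max − α_c and H − G — multi-started from a seeded
Latin hypercube over broad physical bounds (energies 5–40 k_BT, d
0.1–2 nm, r₀ 0.5–5 nm).  Standard errors are observed-information
(finite-difference Hessian, pseudo-inverse); the published uncertainty
method is unstated, so these match it only in spirit and order of
magnitude.  On synthetic n = 803 data the fit recovers E₀ to ±0.3, H to
±0.6 and d to ±0.05 (1 SE), comparable to the published "(2) in the last
digit" style uncertainties; r₀ and α_max are weakly identified (flat
likelihood directions), as expected — the published fit reports broad
optima in the angular variables as well.

### Identifiability at experimental sample size

With n = 803 lifetimes at 12 force levels the likelihood identifies E0
sharply (recovered within 2% on every synthetic realization tried) but
carries two soft ridges: (H, G) can drift together with the return
barrier H − G nearly pinned, and d can trade against r0 while alpha_max
runs toward its 180-degree limit.  On some realizations the global
optimum sits on such a ridge several log-units above the generating
parameters, displacing the recovered H or d by 10-20% even though the
local standard errors remain small (0.4-1 k_BT for H, 0.04-0.08 nm for
d, the same order as the published uncertainties — which are likewise
local quantities and do not reflect this mode-to-mode variability).
Recovery of H and d to better than ~10% per single realization is
therefore not guaranteed by the experiment-scale design; no bounds or
priors are imposed to hide this.

## Known limitations

- The exact algebraic rate expressions of the original derivation are
  not public; the reconstruction here is contract-equivalent (matches
  the printed observables and the numerical oracles) but not
  symbol-for-symbol.  τ_max = 1.27 s vs ≈ 1.1 published and π_S = 0.43
  vs 0.47 are within the stated tolerances; p_S0 = 0.728 vs 0.77 is not
  (see the measure section).
- The Bell-limit slope of ln τ(F) equals −d/k_BT only beyond the
  angular-alignment transient (cos θ spread ≈ k_BT/Fr₀); the slope check
  therefore uses F = 5–20 pN, and the pure exp(Fd/k_BT) rate-ratio check
  uses a narrow cone near θ = 0.
- Desk-scale problem sizes are used throughout the validation suite
  (BD ensembles of a few hundred trajectories at barriers ≤ 8 k_BT,
  five random parameter sets for the oracle cross-check, grids of
  ~100×130 cells); all are chosen to keep every statistical check
  comfortably resolved at those sizes.
- No instrument dead-time correction is applied to Σ_F(t); none is
  described for the published analysis.
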