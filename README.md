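# catchbond

Structure-based kinetics of the cadherin–catenin–actin (CCA) catch bond.

The adherens-junction complex of E-cadherin, β-catenin, αE-catenin and
F-actin survives *longer* under moderate tension — a catch bond.  This
package implements a quantitative model of that behaviour: force rotates
the M3 domain of αE-catenin relative to M2 over a salt-bridge energy
barrier, and the inter-domain angle α allosterically sets the strength of
the αE-catenin–actin interface.  The package is aimed at people analysing
single-molecule force-spectroscopy lifetime data who want model parameters
with structural meaning (interface energies in k_BT, barrier heights,
transition-state distances) instead of phenomenological rates.

## The model

Bond configuration is described by the hinge-to-interface distance *r*
and the angle *θ* between that vector and the pulling axis, with
Hamiltonian

    U(r, θ) = ½ k(θ) (r − r₀)² − F r cos θ + C(θ)
    k(θ)    = k₀ + k₁ (1 + cos θ)
    α       = 180° − θ − φ

`C(θ)` is piecewise linear in cos θ with a cusp at the transition angle
α_c: it splits the angular range into a small-α basin (weak actin
interface, rupture barrier E₀ at zero force) and a large-α basin (strong
interface, barrier E₀+E₁), separated by a barrier H with basin offset G.
Rupture occurs at r = r₀ + d; dynamics are overdamped diffusion with
Stokes diffusivity D = k_BT/6πηr₀.

The landscape is reduced to four first-order rates — angular crossings
ω_SL, ω_LS and rupture channels ω_S^rup, ω_L^rup — each an exact 1-d
mean-first-passage-time expression on the force-tilted potential of mean
force.  The resulting two-state master equation gives, in closed form,
the double-exponential survival probability Σ_F(t), the mean lifetime
τ(F) = ∫Σ_F dt (the catch-bond curve), the large-state duration τ_L(F)
and the splitting probability π_S (fraction of ruptures out of the
small-α state).  Lifetime datasets are fitted by maximum likelihood with
the density −dΣ_F/dt.

Two independent numerical oracles validate the reduction: a finite-volume
(Scharfetter–Gummel) solver of the full 2-d Smoluchowski backward
equation, and an Euler–Maruyama Brownian-dynamics integrator.

## Worked example

```python
import numpy as np
from catchbond import load_table1, predict_table, kinetic_solution, \
    equilibrium_small_angle_probability

params, env = load_table1()          # published wild-type parameter set
p_S0 = equilibrium_small_angle_probability(0.0, params, env)
sol = kinetic_solution(15.1, params, env, p_S0=p_S0)
df = predict_table(np.arange(0.25, 33.01, 0.25), params, env)
print(f"p_S0 = {p_S0:.4f}")
print(f"pi_S(15.1 pN) = {sol.splitting_probability:.4f}, "
      f"p_S(15.1 pN) = {sol.equilibrium_small_fraction:.2e}")
print(f"peak tau = {df.tau_s.max():.3f} s at "
      f"{df.force_pN[df.tau_s.idxmax()]:.2f} pN")
```

prints

```
p_S0 = 0.7277
pi_S(15.1 pN) = 0.4267, p_S(15.1 pN) = 1.19e-04
peak tau = 1.275 s at 7.75 pN
```

Read: before force is applied, 73% of bonds sit in the weakly bound
small-α state.  At 15.1 pN that state's equilibrium weight is ~10⁻⁴, yet
43% of bonds still rupture from it — the angular barrier traps the
initial population, which is what makes the survival law visibly
double-exponential.  The mean lifetime peaks near 1.3 s at ~8 pN, an
order of magnitude above its low-force value: the catch bond.

The same pipeline is scripted in `analysis/` (simulate → fit → predict →
mutation scan; outputs under `results/`), and a CLI mirrors it:

```bash
catchbond simulate --n 803 --seed 11 --out synth.tsv
catchbond fit --data synth.tsv --alpha-min-grid 48 --phi-grid 0 --out fit.json
catchbond predict --forces 0:33:0.25 --out curve.tsv
catchbond scan --param H --values 25,20,15,10,5,0 --out scan.tsv
catchbond validate
```

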