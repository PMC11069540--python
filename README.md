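# glefric

Non-Markovian friction and isomerization kinetics for one-dimensional
reaction coordinates.

When a small molecule isomerizes in solvent — a butane dihedral hopping
between its trans and gauche states, say — the kinetics are shaped by the
interplay of the free-energy profile U(q), the solvent viscosity η, and
the friction acting on the reaction coordinate.  That friction is not a
number but a function of time: projecting the full dynamics onto a single
coordinate q(t) yields a generalized Langevin equation (GLE)

    m q̈(t) = −∫₀ᵗ Γ(t−t′) q̇(t′) dt′ − ∇q U(q(t)) + F_R(t),

with a memory kernel Γ(t) whose running integral G(t) = ∫₀ᵗ Γ(t′)dt′
plateaus at the total friction γ = G(t→∞), and a random force obeying the
fluctuation-dissipation theorem ⟨F_R(t)F_R(t′)⟩ = k_BT Γ(t−t′).  The
familiar "τ ∝ η" rule for reaction times rests on two separate
assumptions — Stokes-Einstein (γ ∝ η) and overdamped Kramers (τ ∝ γ) —
and testing either requires measuring γ itself.  `glefric` provides the
full toolchain for doing that on scalar time series:

* **GLE simulation** (`glefric.simulate`): stationary trajectories with
  prescribed multi-exponential (+ damped-oscillating) memory kernels via
  Markovian embedding — each exponential mode becomes an overdamped
  auxiliary variable, the oscillating mode an inertial one, integrated
  with a BAOAB-style splitting with exact Ornstein-Uhlenbeck substeps.
* **Memory-kernel extraction** (`glefric.extraction`): G(t), Γ(t) and the
  plateau friction γ from a trajectory by solving the first-kind Volterra
  equation that links G to the velocity autocorrelation C_vv and the
  potential-velocity cross-correlation C_{∇U,v}.
* **Free-energy profiles and effective masses** (`glefric.profiles`):
  Boltzmann inversion U = −k_BT log ρ, stationary points, curvatures and
  barrier descriptors; equipartition mass m = k_BT/⟨v²⟩ with timestep
  bias correction.
* **First-passage kinetics** (`glefric.kinetics`): mean first-passage
  times with a renewal (alternating-event) construction that eliminates
  state recrossings, translational diffusion from MSD slopes, and tidy
  condition tables τ/τ⁰ across solvents.
* **Model fits** (`glefric.models`): the kernel model
  Γ(t) ≈ Σᵢ (γᵢ/τᵢ) e^{−t/τᵢ} + damped-oscillating term, constrained so
  the amplitudes sum exactly to γ; and the viscosity-scaling law
  τ(η) = α(η/η₀)^β + ε whose exponent β and intercept fraction ε/(α+ε)
  diagnose internal-friction-like deviations.
* **Rate theory** (`glefric.rate_theory`): overdamped Kramers
  τ_Kr = 2πγ e^{U₀/k_BT}/√|U″min U″max|, the exact overdamped MFPT
  double integral, Grote-Hynes with frequency-dependent friction, the
  diffusion time τ_D = γL²/k_BT, and memory-regime diagnostics
  (components with τ ≲ τ_D accelerate barrier crossing; much slower
  components are kinetically inert).
* **Viscosity utilities** (`glefric.viscosity`): Green-Kubo shear
  viscosity from stress autocorrelations, the super-heavy-water rule
  η/η₀ = √(m/m₀), and the Cheng empirical water-glycerol curve.
* **IO + CLI** (`glefric.io`, `glefric.cli`): plain two-column and
  GROMACS-xvg time series, config-driven pipeline, `glefric` console
  command with `simulate | profile | extract | fit-kernel | mfpt | rates
  | fit-scaling | viscosity | run` subcommands.

Internally everything is in reduced units: energies in k_BT, time in ps,
angles in rad (displayed in degrees), distances in nm.

## Worked example

Simulate a butane-like dihedral with a known two-component kernel, then
recover the kernel and compare rate predictions:

```python
import numpy as np
from glefric import (MemoryKernel, make_potential, simulate_gle,
                     extract_kernel, fit_kernel_model, first_passage_times,
                     kramers_overdamped, barrier_descriptor)

profile = make_potential("cosine_dihedral", barrier=3.5, gauche_offset=0.7)
kernel = MemoryKernel.from_components(exp=[(6.0, 0.5), (4.0, 0.05)])

traj = simulate_gle(profile, kernel, mass=1.0, dt=0.0025,
                    n_steps=20_000_000, seed=7)
est = extract_kernel(traj, profile, mass=1.0, max_lag=4000)
print(f"plateau friction gamma = {est.gamma:.2f} +- {est.gamma_stderr:.2f}")

fit = fit_kernel_model(est, n_exp=2, n_osc=0, seed=0)
for c in fit.exponentials:
    print(f"  component: gamma_i = {c.gamma:.2f}, tau_i = {c.tau:.3f} ps")
```

Output from this exact run:

```
plateau friction gamma = 10.33 +- 0.41
  component: gamma_i = 6.18, tau_i = 0.568 ps
  component: gamma_i = 4.15, tau_i = 0.051 ps
```

The extracted plateau recovers the prescribed total friction γ = 10
within its quoted uncertainty, and the constrained fit splits it into the
two prescribed modes (γᵢ = 6, 4 at τᵢ = 0.5, 0.05 ps).  Longer runs (the
acceptance suite pools 0.6–3.2×10⁸ steps per kernel) tighten the
recovery to a few percent on every component.

The same loop through the command line:

```sh
glefric simulate --config run.cfg --seed 7 --out traj.dat
glefric extract --traj traj.dat --profile auto --mass 1.0 --out kernel.dat
glefric fit-kernel --gfile kernel.dat --nexp 2 --nosc 0 --out fit.json
```

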