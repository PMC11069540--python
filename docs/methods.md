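# Methods

This note records the model assumptions, numerical choices and default
parameters behind `glefric`, and what the synthetic-data tests do and do
not establish about real trajectory data.

## The model

All analysis is organised around the one-dimensional generalized Langevin
equation (GLE)

    m q̈(t) = −∫₀ᵗ Γ(t−t′) q̇(t′) dt′ − ∇q U(q(t)) + F_R(t),

for a scalar reaction coordinate q (a dihedral angle in rad or a distance
in nm), with ⟨F_R⟩ = 0 and ⟨F_R(t)F_R(t′)⟩ = k_BT Γ(t−t′)
(fluctuation-dissipation).  The effective mass m is assumed independent
of q; this is an assumption of the whole pipeline, adopted because mild
q-dependence of the mass has little dynamical effect for the coordinate
classes targeted here.  Reduced units are used throughout: k_BT = 1, time
in ps, so friction carries k_BT·ps/unit² and mass k_BT·ps²/unit².

### Kernel model

The parametric kernel is a sum of up to three exponential modes and up to
one damped-oscillating mode:

    Γ(t) = Σᵢ (γᵢ/τᵢ) e^{−t/τᵢ}
         + ((1+ω²s²) γₒ / 2s) e^{−t/s} [cos ωt + sin(ωt)/(ωs)],  s ≡ τₒ.

Every amplitude equals the time integral of its component, so the total
friction is exactly γ = Σγᵢ + γₒ = G(∞).  The oscillating prefactor
(1+ω²s²) is fixed by this normalisation and is precisely the kernel
obtained by eliminating a damped inertial auxiliary oscillator — the two
facts are consistent by construction and are enforced by unit tests
(closed-form G(∞) = γ to 1e-9; trapezoidal re-integration of Γ matches G
to 1e-6 on the friction scale).

## GLE simulation by Markovian embedding

Each exponential mode (γₑ, τₑ) is realised by one overdamped auxiliary
coordinate y with spring k = γₑ/τₑ to q and friction γₑ; eliminating y
yields exactly (γₑ/τₑ)e^{−t/τₑ}.  The oscillating mode (γₒ, τₒ, ω) is
realised by one inertial auxiliary with mass m_y = γₒτₒ/2, friction γₒ
and spring k = γₒ(1+ω²τₒ²)/(2τₒ); its elimination yields the
damped-oscillating form with decay time τₒ and frequency ω exactly.
Noise enters only through the auxiliary friction channels, so the
composite system satisfies detailed balance and the projected dynamics
obeys the GLE.

The integrator is a symmetric BAOAB-style splitting: velocity-Verlet
backbone for (q, v) and the oscillating auxiliary, with exact
Ornstein-Uhlenbeck substeps for the overdamped auxiliaries (relaxation
toward the current q over one timestep) and for the auxiliary-velocity
thermostat.  There is no stability threshold from the OU substeps; the
timestep must resolve the deterministic frequencies.  Timesteps are
validated, not silently coarsened: Δt ≤ τᵢ/10 for every kernel time and
Δt ≤ 0.1/ω for the oscillating mode are required, and the acceptance runs
use Δt = τ_min/20.  Because correctness of the embedding is defined
operationally (no published scheme is being matched), the binding test is
kernel re-extraction: simulate → extract must return the prescribed γ and
component time scales; the suite enforces 5% and 10% respectively.

Initial conditions: q₀ at the deepest minimum (or caller-specified),
velocity and auxiliaries drawn from their conditional equilibrium at q₀.
The first max(10·τ_slowest, 1000·Δt) of each run is discarded so that
downstream estimators see a stationary series.  A single PCG64 stream
keyed by the seed drives everything; identical inputs and seed give
bitwise-identical trajectories (normals are drawn in fixed-size chunks so
chunking does not perturb the stream).

## Memory-kernel extraction

Multiplying the GLE by v(0), averaging over a stationary ensemble
(⟨F_R(t)v(0)⟩ = 0 for t ≥ 0) and integrating once in time gives the
first-kind Volterra equation

    ∫₀ᵗ G(t−s) C_vv(s) ds = m[C_vv(0) − C_vv(t)] − ∫₀ᵗ C_{∇U,v}(s) ds,

which is discretized with the trapezoidal rule and solved by forward
recursion (G₀ = 0).  This velocity-based G-direct formulation was chosen
over position-correlation variants because its output is the quantity of
interest and the recursion is stable over the tested timestep range; a
blow-up guard reports the offending lag if |Gᵢ| ever exceeds 10⁶ times
the early-lag scale.

* Velocities: central differences with minimum-image unwrapping for
  angles (a 179° → −179° step counts as 2°).
* Correlations: FFT-based, all admissible time origins, series split into
  10 contiguous blocks (block estimates feed the plateau standard error).
  Default lag cutoff: 1% of the trajectory duration.
* ∇U: analytic derivative of the profile's cubic-spline interpolant
  (periodic spline for angles), avoiding histogram-bin noise.
* Γ(t): Savitzky-Golay local-polynomial derivative of G (window 5,
  order 3 by default) — differentiation of the noisy G is deliberately
  separated from any fitting.
* Plateau friction: mean of G over the longest trailing window whose
  total drift (|regression slope| × window length) is below tol·γ, with
  tol = 0.01; stderr from the 10 block estimates.  Absence of a plateau
  is an explicit error, never an extrapolation.

## Kernel-model and scaling fits

The kernel model is fitted to G(t), not Γ(t), because differentiation
noise would dominate a Γ-space fit.  The amplitude constraint Σγᵢ = γ
(plateau) is enforced exactly through the parametrization
γᵢ = γ zᵢ²/Σzⱼ²; time scales and ω are log-parametrized; the best of 8
seeded restarts is kept.  Residual weights are uniform over log-spaced
lag bins and, when block estimates are available, divided by the per-lag
block standard error of G (with a floor of 0.002γ so the t → 0 weights
stay finite).  The extra inverse-error factor was adopted after recovery
experiments showed that the strongly lag-dependent noise of G otherwise
lets the tail distort the slow time scales by ~15%; with it, all battery
time scales recover within 10%.

The viscosity-scaling law τ(η) = α(η/η₀)^β + ε is fitted by bounded
least squares (α, ε ≥ 0, β free) with inverse-variance weights when
errors are supplied, multi-start, and a seeded bootstrap (parametric when
point errors are given, pairs otherwise; default 200 resamples) for
confidence intervals on β and on the internal-friction ratio ε/(α+ε).
The constant-τ regime is representable two ways (α → 0, or β → 0 with
ε ≈ 0); tests therefore assert flatness of the predicted curve rather
than a particular degenerate parameter corner.

## Free-energy profiles, masses, kinetics

Profiles come from Boltzmann inversion of the sampled histogram (360
bins/period for angles, Scott's rule for distances; Gaussian
pre-smoothing of counts with σ = 2 bins), shifted to min U = 0.  Outer
bins with fewer than 10 smoothed counts are trimmed; interior bins below
that threshold mean the barrier was not crossed and raise an error naming
the gap.  Stationary-point locations come from the spline; curvatures
from a local quadratic fit over the surrounding |ΔU| ≤ 0.5 k_BT window,
which is far more noise-tolerant than a pointwise spline second
derivative (the Gaussian-inversion test recovers unit curvature to 5%).

The effective mass is m = k_BT/⟨v²⟩ with a Richardson extrapolation over
velocity spacings Δt and 2Δt: on an underdamped harmonic reference the
central-difference estimator obeys ⟨v̂²⟩ = ⟨v²⟩(sin ωΔt/ωΔt)², so the
leading bias is O(Δt²) and two spacings cancel it without knowing ω.  A
warning is emitted when C_vv(Δt)/C_vv(0) < 0.5 (timestep under-resolves
the velocity).

First-passage events use a renewal construction between point targets: an
event starts at the first source crossing after the previous target
arrival and ends at the next target crossing, so rapid recrossings of the
source during an open event spawn nothing — this is the recrossing
elimination.  Crossings are interpolated linearly between bracketing
samples (reduces Δt bias; decimating a Markovian fixture by 2 changes
τ_MFP by < 2%), angles use minimum-image arithmetic, and the two gauche
positions can be pooled for symmetric dihedrals.  A core-region variant
(half-width w) is exposed for sensitivity checks because point-vs-region
conventions differ between studies.  Event-mean standard errors come from
a seeded moving-block bootstrap (200 resamples, block length ≈ n^{1/3}).

## Rate theory

* Overdamped Kramers: τ_Kr = 2πγ e^{U₀/k_BT}/√|U″min U″max|.
* Exact overdamped MFPT: double integral over the spline profile by
  nested adaptive quadrature (relative tolerance 1e-8).  The benchmark
  comparison uses a quartic double well U₀((q/L)²−1)² with U₀ = 4 k_BT,
  start at one minimum, absorption at the other, reflection far up the
  outer wall (−2.5L; moving it to −4L changes nothing at 1e-13).  The
  measured Kramers deviation is 12.4% on this well and is shape-dependent
  (a cosine double well of equal barrier gives 16.4%), which is why the
  acceptance band for the "~20%" deviation is 12–28%.
* Grote-Hynes: λ_GH solves λ² + λK̂(λ)/m = ω_b² by bracketed root
  finding on (0, ω_b]; K̂ is the kernel's Laplace transform (closed form;
  an adaptive-quadrature route is kept as an independent cross-check).
  The prefactor convention is the TST time of the starting well,
  τ_GH = (2π/ω₀)(ω_b/λ_GH)e^{U₀/k_BT}, which makes the memoryless limit
  coincide with the classical Kramers intermediate-friction result and
  the strong-friction limit with overdamped Kramers (both verified to
  1%).  No quantitative Grote-Hynes target is asserted beyond these
  limits, since frequency-dependent friction alone does not reliably
  predict measured reaction times in this problem class.
* τ_D = γL²/k_BT with L the well-to-barrier distance (60° for the
  dihedral fixtures).  Memory components are classified against τ_D:
  τ/τ_D < 0.02 near-Markovian, ≤ 1 speed-up, > 1 slow-down-proximal
  (inert when the amplitude fraction is also < 0.2).  The speed-up
  prediction is verified dynamically: at τ_mem = τ_D/10 over a 4 k_BT
  quartic barrier the simulated MFPT falls far below τ_Kr(γ), and at
  τ_mem = 10⁻³τ_D it returns to the exact Markovian value.

## Viscosity

Green-Kubo: η = (V/k_BT)∫₀^{t_c}⟨P_αβ(0)P_αβ(t)⟩dt per off-diagonal
component, averaged over the supplied components (which components and
what symmetrization to use is left to the caller).  The cutoff comes from
the plateau of the running integral: the autocorrelation's first zero
crossing t₀ marks decay into the noise floor, and the plateau is read off
as the mean of the running integral over [t₀, 3t₀].  Integrating much
further only accumulates the random walk of the correlation estimate; on
the Ornstein-Uhlenbeck fixture this estimator is unbiased to 0.1% over
20 seeds (single-seed scatter ~5% at 10⁶ samples).

The super-heavy-water rule η/η₀ = √(m/m₀) is exact for uniformly
mass-scaled solvents (equilibrium structure unchanged, dynamics slowed
diffusively).  The water-glycerol empirical curve is the Cheng mixture
correlation η = η_w^A η_g^{1−A}; its coefficients are vendored in
`data/cheng2008.json` for auditability and its water branch reproduces
η₀ ≈ 0.86 mPa·s at 300 K.

## Synthetic data: what it does and does not show

The synthetic generator produces exactly the model class the analysis
assumes: 1D GLE dynamics, Gaussian thermal noise, stationary kernels of
the parametric family, q-independent mass.  Passing the closed-loop tests
therefore establishes the internal consistency and statistical
calibration of the estimators at realistic sample sizes — it does not
establish that a given laboratory or MD coordinate obeys a GLE with a
3-exp+osc kernel, that its mass is q-independent, or that its sampling is
free of the aliasing, thermostat and constraint artifacts real MD data
carry.  The deposited-trajectory test tier exists precisely to close that
gap and activates when a local copy of the archive is present.

Problem sizes: the closed-loop battery uses runs of 6–8×10⁷ steps per
kernel at Δt = τ_min/20 with lag windows of ~8 slowest kernel times.
Single-mode kernels recover to better than 1% in one run; multi-mode
kernels pool the correlation functions of 2–4 replicate runs before the
Volterra inversion, because the slow-component recovery error scales as
(τ₁/T_total)^{1/2} and the per-run scatter (~8–10%) would otherwise eat
the 10% bound.  Replica counts were set from that variance analysis so
each bound carries roughly a 2–3σ margin.  Likewise, the
offset-dominated scaling regime (β = 1 with ε/(α+ε) = 0.85) is only
weakly identifiable at 5% noise — σ(β) ≈ 0.11 from 24 points — so its
recovery experiment uses 400 replicated measurements (σ(β) ≈ 0.03); the
well-identified sublinear and constant regimes use 6 conditions.

## Known limitations

* Exponential/damped-oscillating kernels only; no power-law memory.
* One oscillating mode; extraction itself is non-parametric, but the
  parametric refit is capped at 3 exp + 1 osc.
* Overdamped rate formulas; the inertial low-viscosity (energy-diffusion)
  regime is out of scope.
* No frequency-domain extraction route, no enhanced-sampling reweighting,
  no 3D/multidimensional coordinates, no binary MD formats.
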