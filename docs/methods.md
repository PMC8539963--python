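# Methods

## Model

All solvers integrate the same conservation-form PDE,

∂u/∂t = ∇·( D · (∇u − G) ),

per colour channel, starting from u = u₀, with Neumann (no-flux)
boundaries. They differ only in how the per-pixel 2×2 diffusion tensor D is
built:

| mode          | tensor source                          | recovers            |
|---------------|----------------------------------------|---------------------|
| `none`        | D = I                                  | Poisson descent ∂u/∂t = ∇²u − ∇·G |
| `standard`    | eigensystem of S = ∇u·∇u               | ad hoc anisotropic gradient-domain processing |
| `difference`  | eigensystem of S′ = (∇u−G)·(∇u−G)      | the variational flow of E = Σ ψ(λ′₊, λ′₋) |

The dot products are taken over colour channels (Di Zenzo), so colour
images couple through the tensor; with D = I the channels decouple exactly.
The `difference` mode is the Euler–Lagrange gradient descent of the energy
E: the derivation uses ∂λ′_p/∂S′_kl = θ′_pk θ′_pl (orthonormality of the
eigenvectors) and ∂S′_kl/∂u,iρ = δ_ik(u,lρ − v_lρ) + δ_il(u,kρ − v_kρ),
which yields a flux D′(∇u − G) with D′ sharing the eigenframe of S′.

## ψ catalogue and the diffusivity convention

Each catalogue entry ships a density ψ(λ₊, λ₋) (used for the reported
energy) and the diffusivity pair (d₊, d₋) applied in the eigenframe:

| name               | ψ                                            | d(λ)                | d_max |
|--------------------|----------------------------------------------|---------------------|-------|
| `linear`           | s/2                                          | 1                   | 1     |
| `total_variation`  | √(s+ε²) − ε                                  | 1/√(s+ε²)           | 1/ε   |
| `perona_malik_log` | K² ln(1+λ₊/K²) + K² ln(1+λ₋/K²)              | 1/(1+λ/K²)          | 1     |
| `perona_malik_exp` | K² (1−e^{−λ₊/K²}) + K² (1−e^{−λ₋/K²})        | e^{−λ/K²}           | 1     |

(s = λ₊ + λ₋; constants are chosen so ψ(0,0) = 0.) The diffusivities are
the classical edge-stopping functions. For the linear and TV entries this
equals 2∂ψ/∂λ; for the Perona–Malik entries it equals ∂ψ/∂λ — the
literature is inconsistent about a factor 2 between the Perona–Malik
Lagrangians and their diffusion coefficients, and we resolve it in favour
of the canonical diffusivities with d(0) = 1. The flow is then the energy
gradient descent up to a positive per-direction rescaling sharing the
eigenframe of the exact descent direction, so dE/dt ≤ 0 is preserved; the
practical benefit is a uniform diffusivity bound d_max = 1, hence one
stability ceiling for all defaults. The Perona–Malik forms are offered
split (independent d(λ₊), d(λ₋), the default, matching the additive form of
the density) or isotropic (d evaluated on s, the classical scalar
Perona–Malik equation); TV is inherently isotropic in 2×2. The exp
diffusivity is floored at the smallest positive normal float because
e^{−λ/K²} underflows to exact zero for λ > ~745 K², which would break
positive-definiteness.

Defaults: K = 10⁻³ for the variational (`difference`) solver and
K = 3×10⁻⁴ for the ad hoc (`standard`) one — the two tensors live on
different scales, since S′ measures the residual and S the full image
gradient; ε = 10⁻⁴ for TV. K is in intensity-gradient units (intensities in
[0,1], per pixel).

## Discretisation

* ∇ is the one-sided forward difference, zero at the last column/row
  (replicate boundary). ∇· is the backward difference with the last
  flux component zeroed, which makes it the **exact negative adjoint** of
  the gradient: Σ ∇u·V = −Σ u ∇·V holds to rounding for arbitrary fields.
  Consequences: the composite operator is the standard 5-point Neumann
  Laplacian, the per-channel image mean is conserved exactly by every
  update, and the discrete energy is non-increasing for dt within bound.
* Explicit (forward) Euler in time, dt = 0.2 by default, inside the
  stability ceiling dt ≤ 0.25/d_max of the 2-D 5-point scheme for
  unit-bounded diffusivities. A dt above the ceiling (e.g. with the TV
  model, d_max = 1/ε) triggers a warning but proceeds; a non-finite iterate
  aborts with the iteration index.
* The diffusion tensor is rebuilt from the current iterate every step
  (one-lag diffusivity). The energy trace is sampled at iteration 0 and
  every 10 iterations by default (configurable), using the configured ψ
  (the linear ψ, i.e. ½‖∇u−G‖²_F, in Poisson mode).
* Eigen-decomposition is closed-form: λ± = ½(t₁₁+t₂₂) ± ½√((t₁₁−t₂₂)²+4t₁₂²),
  with the eigenvector taken from whichever algebraic candidate has the
  larger norm. Pixels with λ₊−λ₋ ≤ 10⁻¹²·trace (including the zero tensor)
  are isotropic to working precision; they get the axis-aligned pair
  (1,0)/(0,1). θ₊'s sign is fixed (first nonzero component positive) and
  θ₋ is its +90° rotation — the sign is irrelevant in θθᵀ but makes runs
  reproducible. D is assembled as d₋ I + (d₊−d₋) θ₊θ₊ᵀ, so equal
  diffusivities give an *exactly* isotropic tensor: with the linear ψ the
  variational solver reproduces the Poisson iterate sequence bit-for-bit.
* No clipping during evolution; values are clipped to [0,1] only at image
  export (round-half-up 8-bit quantisation), so the dynamics match the
  continuous model.

## Applications

* Linear enhancement G = a∇u₀ (default a = 2, a deliberately extreme
  setting that makes Poisson halos obvious) and gamma enhancement
  G = sign(∇u₀)|∇u₀|^γ element-wise (default γ = 0.7; sign(0)·|0|^γ := 0
  keeps the map continuous and odd).
* Daltonisation: e_d is the dominant eigenvector of the **uncentred**
  second-moment matrix of per-pixel differences u₀ − sim (the differences
  are already deviations from "no loss"; centring is available as an
  option), sign-fixed on its largest component. e_c = grey × e_d,
  normalised, sign-fixed on a non-negative green component — this satisfies
  both orthogonality constraints (to e_d and to the grey axis)
  deterministically. Degenerate inputs are rejected: an all-zero difference
  ("nothing to daltonise") and e_d parallel to grey (e_c undefined).
  The CVD simulation is a linear 3×3 matrix in the working RGB space; the
  shipped Viénot-style protanopia/deuteranopia matrices are rank-2 with
  rows summing to one (grey axis fixed), and any matrix can be injected or
  loaded from a plain-text file. Images are processed as stored
  (sRGB-encoded values treated as intensities); the grey axis is taken in
  the working RGB.

## Synthetic fixtures: what they do and do not show

The generator emulates the structural features the method reacts to —
sharp edges (step, disk), smooth large-scale variation (binomially
smoothed seeded noise in [0.1, 0.9]), and chromatic content concentrated
along the red–green direction (1,−1,0)/√2 (patch chart, lightly smoothed so
edges span a few pixels). It does not emulate sensor noise, texture,
compression artefacts, or natural-image gradient statistics, so passing
tests demonstrate the mathematical properties of the scheme (exact
adjointness, oracle agreement, energy descent, halo suppression, detail
restoration under simulation) rather than perceptual quality on
photographs. The halo metric is out-of-range overshoot per channel — the
simplest faithful proxy for visible ringing — not a perceptual measure.

## Problem sizes and verification

Operator identities are exact and checked at 16×16; the Poisson solver is
verified at 24×24 against a direct dense solve of the assembled Neumann
system (the matrix path exists only as a validation reference), with the
additive gauge fixed by removing per-channel means; evolution properties
(fixed point, energy descent over 2000 steps, halo comparison at equal
1500-iteration budgets, daltonisation) run at 64×64. These sizes make every
property cheap to recompute while leaving the asymptotics untouched — all
operators are resolution-independent.

## Known limitations

* Explicit Euler only: long evolutions at tight diffusivities are slow by
  construction; no implicit stepping, multigrid or FFT path is provided.
* The pointwise structure tensor is used without Gaussian smoothing, so
  the tensor field is noisier than in smoothed-tensor formulations.
* With strong edge-stopping (λ′ ≫ K²) the residual at an edge is almost
  frozen; the method trades completeness of reintegration for absence of
  halos. This is visible in the step-edge example, where the variational
  result stays deliberately close to u₀.
* Dichromat simulation is the linear matrix model; piecewise (Brettel
  half-plane) simulation and perceptual colour spaces are out of scope.
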