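# vagrad — variational anisotropic gradient-domain image processing

Gradient-domain image processing edits an image *u₀* by processing its
gradient field into a target *G* = f(∇u₀) and reintegrating, classically by
solving the Poisson equation ∇²u = ∇·G (gradient descent
∂u/∂t = ∇²u − ∇·G). Unconstrained Poisson reintegration produces severe
halo/overshoot artefacts near strong edges — a familiar problem in
scientific and biomedical imaging whenever local contrast is amplified or
colour information is remapped.

`vagrad` implements a variational cure: define the **difference structure
tensor**

S′ = (∇u − G)·(∇u − G)   (dot over colour channels)

with eigenvalues λ′₊ ≥ λ′₋ and eigenvectors θ′₊, θ′₋, minimise the
functional

E(u) = ∫ ψ(λ′₊, λ′₋) dΩ,

and evolve the resulting Euler–Lagrange flow

∂u/∂t = ∇·( D′ · (∇u − G) ),  D′ = d₊(λ′₊) θ′₊θ′₊ᵀ + d₋(λ′₋) θ′₋θ′₋ᵀ,

by explicit finite differences (forward differences for ∇, the adjoint
backward differences for ∇·). With the Perona–Malik density
ψ = K² ln(1 + λ′₊/K²) + K² ln(1 + λ′₋/K²), diffusion is shut down *across*
a residual edge but left free *along* it, which reintegrates the edited
gradients without halos. Choosing ψ = s/2 recovers exactly the Poisson
descent; a ψ catalogue (linear, regularised total variation, two
Perona–Malik forms, split or isotropic) is included, as are the classical
baselines: Poisson (D = I) and the ad hoc anisotropic variant whose tensor
is built from the standard structure tensor S = ∇u·∇u of the evolving
image.

Application front-ends construct G for:

* **linear local contrast enhancement** — G = a ∇u₀, a > 1;
* **nonlinear gamma enhancement** — G = sign(∇u₀)|∇u₀|^γ, 0 < γ < 1,
  element-wise;
* **colour-image daltonisation** — G = ∇u₀ + (∇u₀·e_d) e_c, where e_d is
  the first principal component of original-minus-CVD-simulation
  differences and e_c a chromatic direction orthogonal to e_d and the grey
  axis; linear (Viénot-style) protanopia/deuteranopia simulation matrices
  are shipped and injectable.

Everything is testable offline: a seeded fixture generator provides step
edges, ramps, disks, red–green charts and smooth random colour fields.

## Worked example

`examples/linear_enhancement.py` doubles the gradients of a 64×64 step
edge (levels 0.2/0.8) and reintegrates 1500 iterations with dt = 0.2:

```
source range            [0.20, 0.80]
poisson range           [-0.095, 1.095]
variational range       [0.200, 0.800]
halo (poisson)          0.2954
halo (variational)      1.07e-05
```

The halo metric is the worst overshoot beyond the source's value range.
The Poisson reconstruction overshoots by ±0.295 around the edge — the
visible halo — while the variational solver (K = 10⁻³) stays inside the
original range to 10⁻⁵. `examples/daltonisation.py` runs the full
daltonisation pipeline on a red–green chart and prints the estimated basis
(e_d ≈ (0.992, −0.126, −0.004), the protan confusion direction; e_c ≈
(0.081, 0.663, −0.744), a blue–yellow direction) and a simulated
edge-structure restoration ratio of 1.038. `examples/gamma_enhancement.py`
and `examples/diffusion_catalogue.py` cover the γ = 0.7 enhancement and the
ψ catalogue.

A thin CLI wraps the same library calls:

```sh
vagrad fixtures chart.png --kind red_green_chart --seed 42
vagrad enhance-linear in.png out.png --a 2 --solver variational --K 1e-3
vagrad enhance-gamma in.png out.png --gamma 0.7 --solver poisson
vagrad daltonise in.png out.png --simulate out_sim.png
```

Each run writes `<out>.manifest`, a flat key–value record that reproduces
the run bit-for-bit via `--config`.

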