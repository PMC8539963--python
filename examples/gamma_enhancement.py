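"""Nonlinear (gamma) local contrast enhancement in the gradient domain.

Builds G = sign(grad u0) |grad u0|^0.7 element-wise on a smooth random
colour field — small gradients are expanded, large ones compressed — and
compares the three reintegration schemes at an equal iteration budget.
"""

import numpy as np

from vagrad import SolverConfig, evolve, gamma_target, generate, halo_metric, make_psi

u0 = generate("smooth_random", 64, 64, seed=42)
G = gamma_target(u0, gamma=0.7)

results = {}
for label, config in {
    "poisson": SolverConfig(tensor_source="none", iterations=1000),
    "adhoc": SolverConfig(
        tensor_source="standard", psi=make_psi("perona_malik_log", K=3e-4),
        iterations=1000,
    ),
    "variational": SolverConfig(
        tensor_source="difference", psi=make_psi("perona_malik_log", K=1e-3),
        iterations=1000,
    ),
}.items():
    results[label], _ = evolve(u0, G, config)

for label, u in results.items():
    print(
        f"{label:12s} range [{u.min():.3f}, {u.max():.3f}]  "
        f"halo {halo_metric(u, u0):.3e}  max|u-u0| {np.max(np.abs(u - u0)):.3f}"
    )
gap = np.max(np.abs(results["variational"] - results["adhoc"]))
sep = np.max(np.abs(results["variational"] - results["poisson"]))
print(f"\nmax|variational - adhoc|   {gap:.3e}")
print(f"max|variational - poisson| {sep:.3e}")
print()
print("All three solvers boost local contrast, but the two anisotropic")
print("variants stay close to each other (small gap) while deviating from")
print("the halo-prone Poisson solution where gradients are strong.")
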