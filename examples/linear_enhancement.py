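"""Linear local contrast enhancement: Poisson vs variational reintegration.

Doubles the gradient of a step-edge image (G = 2 grad u0) and reintegrates
with the Poisson baseline and the variational anisotropic solver.  The halo
metric is the worst overshoot beyond the source's value range: the Poisson
result overshoots badly at the edge, the variational one essentially not
at all.
"""

import numpy as np

from vagrad import (
    SolverConfig,
    evolve,
    generate,
    halo_metric,
    linear_target,
    make_psi,
)

u0 = generate("step_edge", 64, 64, channels=3, levels=(0.2, 0.8))
G = linear_target(u0, a=2.0)

poisson, _ = evolve(u0, G, SolverConfig(tensor_source="none", iterations=1500))
variational, trace = evolve(
    u0,
    G,
    SolverConfig(
        tensor_source="difference",
        psi=make_psi("perona_malik_log", K=1e-3),
        iterations=1500,
    ),
)

print(f"source range            [{u0.min():.2f}, {u0.max():.2f}]")
print(f"poisson range           [{poisson.min():.3f}, {poisson.max():.3f}]")
print(f"variational range       [{variational.min():.3f}, {variational.max():.3f}]")
print(f"halo (poisson)          {halo_metric(poisson, u0):.4f}")
print(f"halo (variational)      {halo_metric(variational, u0):.2e}")
print(f"energy start -> end     {trace.values[0]:.6e} -> {trace.values[-1]:.6e}")
print()
print("The Poisson reconstruction overshoots the [0.2, 0.8] source range by")
print("~0.3 on both sides of the edge (the visible halo).  The difference")
print("structure tensor shuts diffusion down across the edge, so the")
print("variational result stays inside the range; its energy creeps down")
print("only in the 6th digit because on this fixture the residual lives")
print("entirely at the edge, where diffusion is deliberately suppressed.")
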