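"""Colour-image daltonisation for a protanope observer.

A red-green patch chart is nearly invisible to a protanope: its protanope
simulation is almost flat.  The pipeline estimates the lost colour
direction e_d (first principal component of original - simulation), a
visible chromatic direction e_c (orthogonal to e_d and the grey axis),
builds the target G = grad u0 + (grad u0 . e_d) e_c, and reintegrates with
the variational anisotropic solver.  Detail restoration is measured as the
summed structure-tensor trace of the *simulated* images over edge pixels.
"""

import numpy as np

from vagrad import (
    PROTANOPIA,
    SolverConfig,
    compute_gradient,
    cvd_simulate,
    daltonisation_target,
    estimate_basis,
    evolve,
    generate,
    make_psi,
    structure_tensor,
)

chart = generate("red_green_chart", 64, 64, amplitude=0.25)
sim_orig = cvd_simulate(chart, PROTANOPIA)
basis = estimate_basis(chart, sim_orig)
print("e_d (lost direction)   ", np.round(basis.e_d, 4))
print("e_c (compensation)     ", np.round(basis.e_c, 4))

G = daltonisation_target(chart, basis)
daltonised, _ = evolve(
    chart,
    G,
    SolverConfig(
        tensor_source="difference",
        psi=make_psi("perona_malik_log", K=1e-3),
        iterations=2000,
    ),
)
sim_dalt = cvd_simulate(np.clip(daltonised, 0.0, 1.0), PROTANOPIA)

edge_trace = structure_tensor(compute_gradient(chart)).trace
edges = edge_trace > 0.25 * edge_trace.max()
t_orig = structure_tensor(compute_gradient(sim_orig)).trace[edges].sum()
t_dalt = structure_tensor(compute_gradient(sim_dalt)).trace[edges].sum()
print(f"edge pixels             {int(edges.sum())}")
print(f"simulated edge energy   original {t_orig:.3f} -> daltonised {t_dalt:.3f}")
print(f"restoration ratio       {t_dalt / t_orig:.4f}")
print()
print("e_d comes out along the protan confusion direction (mostly red);")
print("e_c is a visible blue-yellow direction.  The ratio > 1 shows the")
print("daltonised chart retains more edge structure under protanope")
print("simulation than the unprocessed chart does.")
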