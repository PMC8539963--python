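"""The psi catalogue and the diffusion tensors it induces.

Evaluates each Lagrangian density on a single edge-like difference
structure tensor (a pure x-gradient of magnitude K) and prints the
diffusivities across (d_plus) and along (d_minus) the residual edge.
"""

import numpy as np

from vagrad import diffusion_tensor, make_psi
from vagrad.tensor import PSI_NAMES, SymTensorField, eigensystem

K = 1e-3
# residual gradient (K, 0): lambda+ = K^2 across the edge, lambda- = 0 along
tensor = SymTensorField(
    t11=np.array([[K**2]]), t12=np.array([[0.0]]), t22=np.array([[0.0]])
)
eig = eigensystem(tensor)
print(f"edge tensor: lambda+ = K^2 = {eig.lambda_plus[0, 0]:.1e}, lambda- = 0\n")
print(f"{'model':20s} {'psi':>12s} {'d_across':>10s} {'d_along':>10s}")
for name in PSI_NAMES:
    psi = make_psi(name, K=K, eps=1e-4)
    d = diffusion_tensor(eig, psi)
    value = float(psi.psi(eig.lambda_plus, eig.lambda_minus)[0, 0])
    print(f"{name:20s} {value:12.3e} {d.d11[0, 0]:10.3f} {d.d22[0, 0]:10.3f}")
print()
print("The linear model diffuses equally everywhere (Poisson behaviour);")
print("total variation is isotropic but gradient-weighted; the Perona-Malik")
print("log model halves diffusion across a residual edge at lambda+ = K^2")
print("while leaving diffusion along it untouched - that asymmetry is what")
print("suppresses halos without freezing smooth regions.")
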