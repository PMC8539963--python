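"""Gradient target fields G for the application front-ends.

Three ways of manufacturing the target field that the solvers reintegrate:

* linear local contrast enhancement, ``G = a * grad(u0)`` with ``a > 1``;
* nonlinear gamma compression, ``G = sign(grad u0) |grad u0|^gamma``
  applied element-wise with ``0 < gamma < 1`` (small gradients are expanded,
  large ones compressed);
* colour-image daltonisation, ``G = grad(u0) + (grad(u0) . e_d) e_c``,
  which re-injects the gradient component lost to a colour-vision-deficient
  observer (projection onto the principal deficiency direction ``e_d``)
  along a chromatic direction ``e_c`` that remains visible.

The colour-vision-deficiency (CVD) simulation used to estimate ``e_d`` is a
linear 3x3 matrix model; the shipped protanopia/deuteranopia matrices are
the published Vienot-style sRGB dichromat projections (rank 2, rows summing
to one so the grey axis is preserved), and any alternative matrix can be
injected or loaded from a plain-text file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import as_image, compute_gradient

__all__ = [
    "PROTANOPIA",
    "DEUTERANOPIA",
    "DaltonisationBasis",
    "linear_target",
    "gamma_target",
    "cvd_simulate",
    "estimate_basis",
    "daltonisation_target",
    "load_simulation_matrix",
]

# Vienot/Brettel/Mollon-style dichromat simulation in sRGB. Rows sum to 1
# (achromatic colours are fixed points) and the first two rows coincide
# (rank 2: every colour is confused with a one-parameter family).
PROTANOPIA = np.array(
    [
        [0.11238, 0.88762, 0.00000],
        [0.11238, 0.88762, 0.00000],
        [0.00401, -0.00401, 1.00000],
    ]
)

DEUTERANOPIA = np.array(
    [
        [0.29275, 0.70725, 0.00000],
        [0.29275, 0.70725, 0.00000],
        [-0.02234, 0.02234, 1.00000],
    ]
)

_GREY_AXIS = np.full(3, 1.0) / np.sqrt(3.0)


def linear_target(u0: np.ndarray, a: float) -> np.ndarray:
    """Scalar gradient amplification ``G = a * grad(u0)``; ``a = 1`` is the
    identity (useful for fixed-point tests), ``a > 1`` enhances contrast."""
    if not a > 0:
        raise ValueError(f"enhancement factor a must be positive, got {a}")
    return a * compute_gradient(u0)


def gamma_target(u0: np.ndarray, gamma: float) -> np.ndarray:
    """Element-wise gamma compression ``G = sign(grad u0) |grad u0|^gamma``.

    ``sign(0) * |0|^gamma`` is defined as 0 so the map is continuous and
    odd; gamma = 1 returns grad(u0) exactly.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    g = compute_gradient(u0)
    if gamma == 1.0:
        return g
    return np.sign(g) * np.abs(g) ** gamma


def cvd_simulate(u0: np.ndarray, sim_matrix: np.ndarray = PROTANOPIA) -> np.ndarray:
    """Apply a linear 3x3 colour-vision-deficiency model per pixel.

    Output is clipped to [0, 1].  Greyscale input is rejected: there is
    nothing chromatic to simulate.
    """
    u = as_image(u0)
    if u.shape[2] != 3:
        raise ValueError("CVD simulation requires a 3-channel colour image")
    m = np.asarray(sim_matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"simulation matrix must be 3x3, got {m.shape}")
    return np.clip(np.einsum("dc,ijc->ijd", m, u), 0.0, 1.0)


@dataclass(frozen=True)
class DaltonisationBasis:
    """Unit colour-space directions steering the daltonisation target.

    ``e_d`` spans the information lost to the simulated observer (first
    principal component of original-minus-simulation differences); ``e_c``
    is orthogonal to both ``e_d`` and the grey axis, so re-injected detail
    is chromatic and visible.
    """

    e_d: np.ndarray
    e_c: np.ndarray
    sim_matrix: np.ndarray


def estimate_basis(
    u0: np.ndarray,
    sim: np.ndarray,
    sim_matrix: np.ndarray = PROTANOPIA,
    centred: bool = False,
) -> DaltonisationBasis:
    """Estimate the deficiency/compensation basis from an image and its
    CVD simulation.

    ``e_d`` is the dominant eigenvector of the second-moment matrix of the
    per-pixel difference vectors ``u0 - sim`` (uncentred by default: the
    differences are already deviations from "no loss"; set ``centred`` to
    subtract the mean difference first).  Its sign is fixed so the
    largest-magnitude component is positive.  ``e_c`` is the normalised
    cross product of the grey axis with ``e_d``, sign-fixed so its green
    component is non-negative.
    """
    u = as_image(u0)
    s = as_image(sim)
    if u.shape != s.shape or u.shape[2] != 3:
        raise ValueError("daltonisation basis needs two identically shaped colour images")

    diff = (u - s).reshape(-1, 3)
    if centred:
        diff = diff - diff.mean(axis=0)
    moment = diff.T @ diff / diff.shape[0]
    scale = float(np.abs(moment).max())
    if scale <= 1e-24:
        raise ValueError("nothing to daltonise: simulation equals the original")

    eigvals, eigvecs = np.linalg.eigh(moment)
    e_d = eigvecs[:, np.argmax(eigvals)]
    if e_d[np.argmax(np.abs(e_d))] < 0:
        e_d = -e_d

    chroma = np.cross(_GREY_AXIS, e_d)
    norm = np.linalg.norm(chroma)
    if norm < 1e-8:
        raise ValueError(
            "deficiency direction is parallel to the grey axis; "
            "no chromatic compensation direction exists"
        )
    e_c = chroma / norm
    if e_c[1] < 0:
        e_c = -e_c
    return DaltonisationBasis(e_d=e_d, e_c=e_c, sim_matrix=np.asarray(sim_matrix, dtype=float))


def daltonisation_target(u0: np.ndarray, basis: DaltonisationBasis) -> np.ndarray:
    """Daltonisation target ``G = grad(u0) + (grad(u0) . e_d) e_c``.

    The dot product is over colour coordinates, taken independently for
    each spatial derivative axis: the colour-gradient component along the
    lost direction is duplicated along the visible chromatic direction.
    """
    u = as_image(u0)
    if u.shape[2] != 3:
        raise ValueError("daltonisation requires a 3-channel colour image")
    if basis.e_d.shape != (3,) or basis.e_c.shape != (3,):
        raise ValueError("basis vectors must be 3-vectors")
    g = compute_gradient(u)
    lost = np.einsum("ijkc,c->ijk", g, basis.e_d)
    return g + lost[..., None] * basis.e_c


def load_simulation_matrix(path) -> np.ndarray:
    """Read a whitespace-separated row-major 3x3 matrix from a text file."""
    m = np.loadtxt(path, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"{path}: expected a 3x3 matrix, got shape {m.shape}")
    return m
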