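"""Structure tensors, closed-form 2x2 eigenanalysis and diffusion tensors.

The building blocks of anisotropic gradient-domain processing:

* per-pixel Di Zenzo structure tensor ``S = sum_rho grad(u_rho) grad(u_rho)^T``
  summed over colour channels, and its *difference* variant
  ``S' = (grad u - G) . (grad u - G)`` built from the residual between the
  evolving image gradient and a target field ``G``;
* the closed-form eigensystem (lambda_plus, lambda_minus, theta_plus,
  theta_minus) of a symmetric 2x2 tensor field;
* a catalogue of Lagrangian densities ``psi(lambda_plus, lambda_minus)``
  (linear, regularised total variation, two Perona-Malik forms) with their
  edge-stopping diffusivities;
* assembly of the per-pixel diffusion tensor
  ``D = d_plus * theta_plus theta_plus^T + d_minus * theta_minus theta_minus^T``.

Array conventions
-----------------
images       : float arrays shaped ``(H, W, C)`` with ``C`` in {1, 3}
               (a 2-D array is promoted to one channel);
gradients    : ``(H, W, 2, C)`` where axis 2 holds the spatial derivative
               along x (columns) then y (rows);
tensor fields: three per-pixel component planes ``t11, t12, t22`` (11 = xx).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "as_image",
    "compute_gradient",
    "structure_tensor",
    "difference_structure_tensor",
    "eigensystem",
    "make_psi",
    "diffusion_tensor",
    "SymTensorField",
    "EigenSystemField",
    "PsiModel",
    "DiffusionTensorField",
    "PSI_NAMES",
]

# Relative spread below which a tensor is treated as isotropic and the
# axis-aligned eigenvector pair is returned.
_DEGENERACY_RTOL = 1e-12


def as_image(values: np.ndarray) -> np.ndarray:
    """Validate and canonicalise an image to a float ``(H, W, C)`` array.

    Greyscale 2-D input gains a trailing channel axis.  Non-finite values
    and channel counts other than 1 or 3 are rejected.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"expected (H, W[, C]) image array, got shape {arr.shape}")
    if arr.shape[2] not in (1, 3):
        raise ValueError(f"images must have 1 or 3 channels, got {arr.shape[2]}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    return arr


def compute_gradient(image: np.ndarray) -> np.ndarray:
    """Forward-difference gradient of an image, shape ``(H, W, 2, C)``.

    Uses one-sided forward differences with a replicate (Neumann) boundary:
    the derivative is zero at the last column (x) and last row (y), so no
    flux ever crosses the image frame.
    """
    u = as_image(image)
    h, w, c = u.shape
    grad = np.zeros((h, w, 2, c))
    grad[:, :-1, 0, :] = u[:, 1:, :] - u[:, :-1, :]
    grad[:-1, :, 1, :] = u[1:, :, :] - u[:-1, :, :]
    return grad


@dataclass(frozen=True)
class SymTensorField:
    """Per-pixel symmetric 2x2 tensor with component planes (xx, xy, yy)."""

    t11: np.ndarray
    t12: np.ndarray
    t22: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.t11.shape

    @property
    def trace(self) -> np.ndarray:
        return self.t11 + self.t22

    @property
    def det(self) -> np.ndarray:
        return self.t11 * self.t22 - self.t12 ** 2


def _check_gradient(grad: np.ndarray) -> np.ndarray:
    grad = np.asarray(grad, dtype=float)
    if grad.ndim != 4 or grad.shape[2] != 2:
        raise ValueError(f"expected (H, W, 2, C) gradient array, got shape {grad.shape}")
    if not np.isfinite(grad).all():
        raise ValueError("gradient field contains non-finite values")
    return grad


def structure_tensor(grad: np.ndarray) -> SymTensorField:
    """Di Zenzo structure tensor: outer product of the spatial gradient,
    summed over colour channels."""
    g = _check_gradient(grad)
    gx = g[:, :, 0, :]
    gy = g[:, :, 1, :]
    return SymTensorField(
        t11=np.einsum("ijc,ijc->ij", gx, gx),
        t12=np.einsum("ijc,ijc->ij", gx, gy),
        t22=np.einsum("ijc,ijc->ij", gy, gy),
    )


def difference_structure_tensor(grad_u: np.ndarray, target: np.ndarray) -> SymTensorField:
    """Structure tensor of the residual field ``grad_u - target``.

    This is the tensor that drives the variational anisotropic solver: its
    eigenvalues measure how far, and in which spatial direction, the current
    image gradient still deviates from the target field G.
    """
    grad_u = _check_gradient(grad_u)
    target = np.asarray(target, dtype=float)
    if target.shape != grad_u.shape:
        raise ValueError(
            f"gradient/target shape mismatch: {grad_u.shape} vs {target.shape}"
        )
    return structure_tensor(grad_u - target)


@dataclass(frozen=True)
class EigenSystemField:
    """Per-pixel eigen-decomposition of a symmetric 2x2 tensor field.

    ``theta_plus``/``theta_minus`` are unit vectors shaped ``(H, W, 2)``;
    ``theta_minus`` is ``theta_plus`` rotated by +90 degrees, and ``s`` is
    the tensor trace ``lambda_plus + lambda_minus``.
    """

    lambda_plus: np.ndarray
    lambda_minus: np.ndarray
    theta_plus: np.ndarray
    theta_minus: np.ndarray

    @property
    def s(self) -> np.ndarray:
        return self.lambda_plus + self.lambda_minus


def eigensystem(tensor: SymTensorField) -> EigenSystemField:
    """Closed-form eigenvalues and eigenvectors of a symmetric 2x2 field.

    lambda_pm = (t11 + t22)/2 +- sqrt((t11 - t22)^2 + 4 t12^2)/2.

    theta_plus carries a deterministic sign (first nonzero component
    positive); theta_minus is its +90-degree rotation.  Pixels whose
    eigenvalue spread is below ``1e-12 * trace`` (including the zero tensor)
    are treated as isotropic and get the axis-aligned pair (1,0)/(0,1).
    """
    t11, t12, t22 = tensor.t11, tensor.t12, tensor.t22
    half_trace = 0.5 * (t11 + t22)
    spread = 0.5 * np.sqrt((t11 - t22) ** 2 + 4.0 * t12 ** 2)
    lam_plus = half_trace + spread
    lam_minus = half_trace - spread

    # Two algebraic eigenvector candidates for lambda_plus; pick per pixel
    # whichever has the larger norm for numerical robustness.
    v1 = np.stack([t12, lam_plus - t11], axis=-1)
    v2 = np.stack([lam_plus - t22, t12], axis=-1)
    n1 = np.einsum("ijk,ijk->ij", v1, v1)
    n2 = np.einsum("ijk,ijk->ij", v2, v2)
    theta = np.where((n1 >= n2)[..., None], v1, v2)

    degenerate = 2.0 * spread <= _DEGENERACY_RTOL * np.abs(t11 + t22)
    degenerate |= np.einsum("ijk,ijk->ij", theta, theta) == 0.0
    theta = np.where(degenerate[..., None], np.array([1.0, 0.0]), theta)
    theta = theta / np.linalg.norm(theta, axis=-1, keepdims=True)

    # Deterministic sign: first nonzero component positive.
    x, y = theta[..., 0], theta[..., 1]
    flip = (x < 0.0) | ((x == 0.0) & (y < 0.0))
    theta = np.where(flip[..., None], -theta, theta)

    theta_minus = np.stack([-theta[..., 1], theta[..., 0]], axis=-1)
    return EigenSystemField(
        lambda_plus=lam_plus,
        lambda_minus=lam_minus,
        theta_plus=theta,
        theta_minus=theta_minus,
    )


@dataclass(frozen=True)
class PsiModel:
    """A Lagrangian density psi(lambda_plus, lambda_minus) and the
    edge-stopping diffusivities it induces.

    ``d_plus``/``d_minus`` map an eigenvalue array to the diffusivity applied
    along the corresponding eigen-direction.  For ``isotropic`` models the
    diffusivity is a function of the trace ``s = lambda_plus + lambda_minus``
    and is applied equally in both directions.  ``d_max`` bounds the
    diffusivity, which sets the explicit-scheme stability ceiling
    ``dt <= 0.25 / d_max``.
    """

    name: str
    psi: Callable[[np.ndarray, np.ndarray], np.ndarray]
    d_plus: Callable[[np.ndarray], np.ndarray]
    d_minus: Callable[[np.ndarray], np.ndarray]
    isotropic: bool
    d_max: float
    params: Mapping[str, float] = field(default_factory=dict)


PSI_NAMES = ("perona_malik_log", "perona_malik_exp", "total_variation", "linear")


def make_psi(
    name: str,
    K: float = 1e-3,
    eps: float = 1e-4,
    isotropic: bool = False,
) -> PsiModel:
    """Build a catalogue Lagrangian density.

    Parameters
    ----------
    name:
        ``perona_malik_log`` -- psi = K^2 ln(1 + lambda/K^2) per eigenvalue,
        diffusivity d(lambda) = 1/(1 + lambda/K^2);
        ``perona_malik_exp`` -- psi = K^2 (1 - exp(-lambda/K^2)) per
        eigenvalue, diffusivity d(lambda) = exp(-lambda/K^2);
        ``total_variation`` -- psi = sqrt(s + eps^2) - eps with diffusivity
        1/sqrt(s + eps^2) (regularised; inherently isotropic in 2x2);
        ``linear`` -- psi = s/2 with unit diffusivity (classical diffusion).
    K:
        Edge-stopping scale in intensity-gradient units (only Perona-Malik
        forms).  Gradients with lambda >> K^2 see strongly reduced diffusion.
    eps:
        Total-variation regulariser, lifting the 1/sqrt(s) singularity at
        s = 0.
    isotropic:
        For the Perona-Malik forms, evaluate the diffusivity on the trace
        ``s`` instead of on the two eigenvalues separately, yielding the
        nonlinear-but-isotropic (classical Perona-Malik) equation rather
        than the split anisotropic form.  Default is the split form.
    """
    if name not in PSI_NAMES:
        raise ValueError(f"unknown psi model {name!r}; choose from {PSI_NAMES}")

    if name == "linear":
        return PsiModel(
            name=name,
            psi=lambda lp, lm: 0.5 * (np.asarray(lp) + np.asarray(lm)),
            d_plus=lambda lam: np.ones_like(np.asarray(lam, dtype=float)),
            d_minus=lambda lam: np.ones_like(np.asarray(lam, dtype=float)),
            isotropic=False,
            d_max=1.0,
        )

    if name == "total_variation":
        if not eps > 0:
            raise ValueError("total_variation requires eps > 0")
        eps2 = float(eps) ** 2
        return PsiModel(
            name=name,
            psi=lambda lp, lm: np.sqrt(np.asarray(lp) + np.asarray(lm) + eps2) - eps,
            d_plus=lambda s: 1.0 / np.sqrt(np.asarray(s) + eps2),
            d_minus=lambda s: 1.0 / np.sqrt(np.asarray(s) + eps2),
            isotropic=True,
            d_max=1.0 / float(eps),
            params={"eps": float(eps)},
        )

    if not K > 0:
        raise ValueError(f"{name} requires K > 0")
    K2 = float(K) ** 2

    if name == "perona_malik_log":
        d = lambda lam: 1.0 / (1.0 + np.asarray(lam) / K2)  # noqa: E731
        if isotropic:
            psi = lambda lp, lm: K2 * np.log1p((np.asarray(lp) + np.asarray(lm)) / K2)  # noqa: E731
        else:
            psi = lambda lp, lm: K2 * (  # noqa: E731
                np.log1p(np.asarray(lp) / K2) + np.log1p(np.asarray(lm) / K2)
            )
    else:  # perona_malik_exp
        # floored at the smallest normal float: exp underflows to exact zero
        # for lambda/K^2 > ~745, which would break positive-definiteness
        d = lambda lam: np.maximum(  # noqa: E731
            np.exp(-np.asarray(lam) / K2), np.finfo(float).tiny
        )
        if isotropic:
            psi = lambda lp, lm: K2 * -np.expm1(-(np.asarray(lp) + np.asarray(lm)) / K2)  # noqa: E731
        else:
            psi = lambda lp, lm: K2 * (  # noqa: E731
                -np.expm1(-np.asarray(lp) / K2) - np.expm1(-np.asarray(lm) / K2)
            )

    return PsiModel(
        name=name,
        psi=psi,
        d_plus=d,
        d_minus=d,
        isotropic=isotropic,
        d_max=1.0,
        params={"K": float(K)},
    )


@dataclass(frozen=True)
class DiffusionTensorField:
    """Per-pixel symmetric positive-definite 2x2 diffusion tensor."""

    d11: np.ndarray
    d12: np.ndarray
    d22: np.ndarray


def diffusion_tensor(eig: EigenSystemField, psi: PsiModel) -> DiffusionTensorField:
    """Assemble the diffusion tensor from an eigensystem and a psi model.

    D = d_plus(lambda_plus) theta_plus theta_plus^T
      + d_minus(lambda_minus) theta_minus theta_minus^T,

    written as d_minus * I + (d_plus - d_minus) * theta_plus theta_plus^T so
    that equal diffusivities yield an exactly isotropic tensor independently
    of the eigenvector tie-break.
    """
    if psi.isotropic:
        d = psi.d_plus(eig.s)
        zero = np.zeros_like(d)
        return DiffusionTensorField(d11=d, d12=zero, d22=d.copy())
    dp = psi.d_plus(eig.lambda_plus)
    dm = psi.d_minus(eig.lambda_minus)
    c = eig.theta_plus[..., 0]
    s = eig.theta_plus[..., 1]
    diff = dp - dm
    return DiffusionTensorField(
        d11=dm + diff * c * c,
        d12=diff * c * s,
        d22=dm + diff * s * s,
    )
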