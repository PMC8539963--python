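"""Structure tensors, eigenanalysis, psi catalogue, diffusion tensors."""

import numpy as np
import pytest

from vagrad import (
    SymTensorField,
    compute_gradient,
    difference_structure_tensor,
    diffusion_tensor,
    eigensystem,
    make_psi,
    structure_tensor,
)
from vagrad.tensor import PSI_NAMES

from conftest import random_psd_tensors, tensors_as_matrices


class TestComputeGradient:
    def test_constant_image_has_zero_gradient(self):
        u = np.full((5, 7, 3), 0.5)
        assert np.all(compute_gradient(u) == 0.0)

    def test_row_forward_differences_with_neumann_last_column(self):
        u = np.array([[0.0, 0.25, 0.5, 0.75]])
        g = compute_gradient(u)
        np.testing.assert_allclose(g[0, :, 0, 0], [0.25, 0.25, 0.25, 0.0])
        assert np.all(g[..., 1, :] == 0.0)

    def test_step_edge_gradient_is_local(self):
        c = 5
        u = np.where(np.arange(12) < c, 0.1, 0.9)[None, :].repeat(6, axis=0)
        g = compute_gradient(u)
        nonzero_cols = np.flatnonzero(np.abs(g[..., 0, 0]).max(axis=0))
        assert nonzero_cols.tolist() == [c - 1]

    def test_rejects_non_finite_input(self):
        u = np.full((4, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            compute_gradient(u)


class TestStructureTensor:
    def test_zero_gradient_gives_zero_tensor(self):
        t = structure_tensor(np.zeros((3, 3, 2, 3)))
        assert np.all(t.t11 == 0) and np.all(t.t12 == 0) and np.all(t.t22 == 0)

    def test_single_channel_outer_product(self):
        g = np.zeros((1, 1, 2, 1))
        g[0, 0, :, 0] = [1.0, 0.0]
        t = structure_tensor(g)
        assert (t.t11[0, 0], t.t12[0, 0], t.t22[0, 0]) == (1.0, 0.0, 0.0)

    def test_channel_sum_gives_identity(self):
        # per-channel gradients (1,0) and (0,1) sum to the identity tensor
        g = np.zeros((1, 1, 2, 3))
        g[0, 0, :, 0] = [1.0, 0.0]
        g[0, 0, :, 1] = [0.0, 1.0]
        t = structure_tensor(g)
        assert (t.t11[0, 0], t.t12[0, 0], t.t22[0, 0]) == (1.0, 0.0, 1.0)


class TestDifferenceStructureTensor:
    def test_matching_target_gives_zero_tensor(self, rng):
        g = rng.normal(size=(4, 5, 2, 3))
        t = difference_structure_tensor(g, g)
        assert np.all(t.t11 == 0) and np.all(t.t12 == 0) and np.all(t.t22 == 0)

    def test_zero_target_reduces_to_structure_tensor_bitwise(self, rng):
        g = rng.normal(size=(6, 6, 2, 3))
        a = difference_structure_tensor(g, np.zeros_like(g))
        b = structure_tensor(g)
        assert np.array_equal(a.t11, b.t11)
        assert np.array_equal(a.t12, b.t12)
        assert np.array_equal(a.t22, b.t22)

    def test_pixel_residual(self):
        gu = np.zeros((1, 1, 2, 1))
        gu[0, 0, 0, 0] = 2.0
        gt = np.zeros((1, 1, 2, 1))
        gt[0, 0, 0, 0] = 1.0
        t = difference_structure_tensor(gu, gt)
        assert (t.t11[0, 0], t.t12[0, 0], t.t22[0, 0]) == (1.0, 0.0, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            difference_structure_tensor(np.zeros((2, 2, 2, 1)), np.zeros((2, 3, 2, 1)))


def _field(t11, t12, t22):
    return SymTensorField(
        t11=np.array([[float(t11)]]),
        t12=np.array([[float(t12)]]),
        t22=np.array([[float(t22)]]),
    )


class TestEigensystem:
    def test_diagonal_tensor(self):
        eig = eigensystem(_field(4.0, 0.0, 1.0))
        assert eig.lambda_plus[0, 0] == 4.0
        assert eig.lambda_minus[0, 0] == 1.0
        np.testing.assert_allclose(eig.theta_plus[0, 0], [1.0, 0.0])
        np.testing.assert_allclose(eig.theta_minus[0, 0], [0.0, 1.0])

    def test_symmetric_off_diagonal(self):
        eig = eigensystem(_field(2.0, 1.0, 2.0))
        np.testing.assert_allclose(eig.lambda_plus[0, 0], 3.0)
        np.testing.assert_allclose(eig.lambda_minus[0, 0], 1.0)
        np.testing.assert_allclose(eig.theta_plus[0, 0], np.array([1.0, 1.0]) / np.sqrt(2))

    def test_isotropic_tensor_uses_axis_aligned_tie_break(self):
        for c in (0.0, 0.7):
            eig = eigensystem(_field(c, 0.0, c))
            np.testing.assert_allclose(eig.theta_plus[0, 0], [1.0, 0.0])
            np.testing.assert_allclose(eig.theta_minus[0, 0], [0.0, 1.0])
            np.testing.assert_allclose(eig.lambda_plus[0, 0], c)

    def test_matches_numerical_eigensolver(self, rng):
        field, _ = random_psd_tensors(2000, rng)
        eig = eigensystem(field)
        w, v = np.linalg.eigh(tensors_as_matrices(field))
        scale = 1.0 + field.trace.ravel()
        np.testing.assert_array_less(
            np.abs(eig.lambda_plus.ravel() - w[:, 1]) / scale, 1e-8
        )
        np.testing.assert_array_less(
            np.abs(eig.lambda_minus.ravel() - w[:, 0]) / scale, 1e-8
        )
        spread = eig.lambda_plus - eig.lambda_minus
        ok = (spread > 1e-6 * field.trace).ravel()
        align = np.abs(np.einsum("nk,nk->n", eig.theta_plus.reshape(-1, 2), v[:, :, 1]))
        assert np.all(align[ok] >= 1.0 - 1e-8)

    def test_spectral_reconstruction(self, rng):
        field, _ = random_psd_tensors(2000, rng)
        eig = eigensystem(field)
        tp, tm = eig.theta_plus, eig.theta_minus
        r11 = eig.lambda_plus * tp[..., 0] ** 2 + eig.lambda_minus * tm[..., 0] ** 2
        r12 = eig.lambda_plus * tp[..., 0] * tp[..., 1] + eig.lambda_minus * tm[..., 0] * tm[..., 1]
        r22 = eig.lambda_plus * tp[..., 1] ** 2 + eig.lambda_minus * tm[..., 1] ** 2
        scale = 1.0 + field.trace
        for rec, ref in ((r11, field.t11), (r12, field.t12), (r22, field.t22)):
            np.testing.assert_array_less(np.abs(rec - ref) / scale, 1e-8)

    def test_eigenvector_invariants(self, rng):
        field, _ = random_psd_tensors(500, rng)
        eig = eigensystem(field)
        np.testing.assert_allclose(
            np.linalg.norm(eig.theta_plus, axis=-1), 1.0, atol=1e-10
        )
        dots = np.einsum("ijk,ijk->ij", eig.theta_plus, eig.theta_minus)
        np.testing.assert_allclose(dots, 0.0, atol=1e-10)
        assert np.all(eig.lambda_plus >= eig.lambda_minus)
        assert np.all(eig.lambda_minus >= -1e-10 * (1 + field.trace))


class TestMakePsi:
    def test_perona_malik_log_diffusivity_values(self):
        K = 0.05
        psi = make_psi("perona_malik_log", K=K)
        assert psi.d_plus(0.0) == 1.0
        np.testing.assert_allclose(psi.d_plus(K**2), 0.5)

    def test_linear_has_unit_diffusivity(self, rng):
        psi = make_psi("linear")
        lam = rng.uniform(0, 10, size=20)
        assert np.all(psi.d_plus(lam) == 1.0)
        assert np.all(psi.d_minus(lam) == 1.0)

    def test_perona_malik_log_monotone_edge_stopping(self):
        psi = make_psi("perona_malik_log", K=1e-3)
        lam = np.logspace(-10, 2, 200)
        d = psi.d_plus(lam)
        assert np.all(np.diff(d) < 0)
        assert psi.d_plus(0.0) == 1.0
        assert psi.d_plus(1e12) < 1e-9

    @pytest.mark.parametrize("name", PSI_NAMES)
    @pytest.mark.parametrize("isotropic", [False, True])
    def test_psi_vanishes_at_origin_and_diffusivity_positive(self, name, isotropic):
        psi = make_psi(name, K=1e-3, eps=1e-4, isotropic=isotropic)
        np.testing.assert_allclose(psi.psi(0.0, 0.0), 0.0, atol=1e-18)
        lam = np.logspace(-8, 1, 50)
        assert np.all(psi.d_plus(lam) > 0)
        assert np.all(psi.d_minus(lam) > 0)
        assert psi.d_plus(0.0) <= psi.d_max * (1 + 1e-12)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError, match="unknown"):
            make_psi("no_such_model")
        with pytest.raises(ValueError, match="K"):
            make_psi("perona_malik_log", K=0.0)
        with pytest.raises(ValueError, match="eps"):
            make_psi("total_variation", eps=-1.0)


class TestDiffusionTensor:
    def test_linear_model_gives_exact_identity(self, rng):
        field, _ = random_psd_tensors(300, rng)
        d = diffusion_tensor(eigensystem(field), make_psi("linear"))
        assert np.all(d.d11 == 1.0) and np.all(d.d12 == 0.0) and np.all(d.d22 == 1.0)

    def test_perona_malik_log_axis_aligned_pixel(self):
        K = 0.1
        eig = eigensystem(_field(K**2, 0.0, 0.0))
        d = diffusion_tensor(eig, make_psi("perona_malik_log", K=K))
        np.testing.assert_allclose(d.d11[0, 0], 0.5)
        np.testing.assert_allclose(d.d12[0, 0], 0.0)
        np.testing.assert_allclose(d.d22[0, 0], 1.0)

    @pytest.mark.parametrize(
        "psi",
        [
            make_psi("total_variation", eps=1e-4),
            make_psi("perona_malik_log", K=1e-2, isotropic=True),
            make_psi("perona_malik_exp", K=1e-2, isotropic=True),
        ],
        ids=lambda p: p.name,
    )
    def test_isotropic_models_are_scalar_regardless_of_tie_break(self, psi, rng):
        field, _ = random_psd_tensors(300, rng)
        eig = eigensystem(field)
        d = diffusion_tensor(eig, psi)
        expected = psi.d_plus(eig.s)
        np.testing.assert_allclose(d.d11, expected, atol=1e-10)
        np.testing.assert_allclose(d.d22, expected, atol=1e-10)
        np.testing.assert_allclose(d.d12, 0.0, atol=1e-10)

    def test_eigenvalue_bounds_for_catalogue_models(self, rng):
        field, _ = random_psd_tensors(500, rng)
        eig = eigensystem(field)
        for name in PSI_NAMES:
            psi = make_psi(name, K=1e-2, eps=1e-3)
            # exact spectrum of the assembled tensor is the diffusivity pair
            assert np.all(psi.d_plus(eig.lambda_plus) > 0.0), name
            assert np.all(psi.d_minus(eig.lambda_minus) > 0.0), name
            d = diffusion_tensor(eig, psi)
            half_tr = 0.5 * (d.d11 + d.d22)
            spread = np.sqrt(0.25 * (d.d11 - d.d22) ** 2 + d.d12**2)
            # reconstructed eigenvalues may cancel at rounding level
            assert np.all(half_tr - spread >= -1e-15 * psi.d_max), name
            assert np.all(half_tr + spread <= psi.d_max * (1 + 1e-12)), name
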