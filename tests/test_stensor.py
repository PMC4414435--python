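"""Structure tensor: derivative templates, binomial pyramid, eigenanalysis."""
import numpy as np
import numpy.testing as npt
import pytest

from myolam import stats, stensor, synthetic
from myolam.core import TensorField3D, ValidityError, Volume3D
from myolam.stensor import (
    STConfig,
    binomial_kernel,
    binomial_smooth_downsample,
    compute_structure_tensor,
    derivative_kernel,
    effective_support_width,
    eigenvalue_ratio,
    feather_boundary,
    gradient,
    st_eigenanalysis,
    st_pyramid,
    st_vectors,
)


class TestDerivativeKernel:
    @pytest.mark.parametrize("width", [3, 5])
    def test_exact_on_linear_ramp(self, width):
        c, spacing = 2.5, 50.0
        data = c * np.arange(32)[:, None, None] * np.ones((1, 8, 8))
        vol = Volume3D(data, spacing)
        g = gradient(vol, width)
        half = width // 2
        interior = g[half:-half, :, :, 0]
        npt.assert_allclose(interior, c / spacing, rtol=1e-9)
        npt.assert_allclose(g[..., 1:], 0.0, atol=1e-9)

    def test_zero_on_constant_volume(self):
        vol = Volume3D(np.full((8, 8, 8), 7.0), 50.0)
        npt.assert_allclose(gradient(vol, 3), 0.0, atol=1e-12)

    @pytest.mark.parametrize("width,exact_on_cubic", [(3, False), (5, True)])
    def test_polynomial_exactness_against_symbolic_oracle(self, width, exact_on_cubic):
        """Width-5 differentiates cubics exactly; width-3 does not."""
        x = np.arange(16, dtype=float)
        f = x**3
        dfdx = 3.0 * x**2  # symbolic derivative
        k = derivative_kernel(width, 1.0)
        half = width // 2
        est = np.correlate(f, k, mode="valid")  # numpy correlate slides k forward
        err = np.max(np.abs(est - dfdx[half:-half]))
        if exact_on_cubic:
            assert err < 1e-9
        else:
            assert err > 0.5

    def test_antisymmetric_zero_sum(self):
        for width in (3, 5):
            k = derivative_kernel(width, 1.0)
            npt.assert_allclose(k, -k[::-1], atol=1e-15)
            assert abs(k.sum()) < 1e-15

    def test_invalid_width_rejected(self):
        with pytest.raises(ValidityError):
            derivative_kernel(4)


class TestStructureTensor:
    def test_constant_volume_gives_zero_tensor(self):
        vol = Volume3D(np.full((8, 8, 8), 3.0), 50.0)
        T = compute_structure_tensor(vol)
        npt.assert_allclose(T.tensors, 0.0, atol=1e-12)

    def test_ramp_gives_single_component(self):
        data = np.arange(16)[:, None, None] * np.ones((1, 8, 8))
        T = compute_structure_tensor(Volume3D(data, 1.0)).tensors
        interior = T[1:-1]
        npt.assert_allclose(interior[..., 0, 0], 1.0, rtol=1e-9)
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 0] = False
        npt.assert_allclose(interior[..., mask], 0.0, atol=1e-9)

    def test_fft_matches_direct_convolution_oracle(self, rng):
        data = rng.normal(size=(10, 11, 12))
        vol = Volume3D(data, 50.0)
        fft = compute_structure_tensor(vol, STConfig(dtw=5), use_fft=True)
        direct = compute_structure_tensor(vol, STConfig(dtw=5), use_fft=False)
        npt.assert_allclose(fft.tensors, direct.tensors, rtol=1e-8, atol=1e-12)

    def test_slab_mean_principal_axis_parallel_to_normal(self, oblique_slab_phantom):
        vol, truth = oblique_slab_phantom
        T = compute_structure_tensor(vol)
        mean_T = T.tensors[2:-2, 2:-2, 2:-2].mean(axis=(0, 1, 2))
        w, v = np.linalg.eigh(mean_T)
        principal = v[:, -1]
        assert stats.axial_angle(principal, truth.n[0, 0, 0]) < 1.0

    def test_rotation_equivariance_90deg(self, rng):
        data = rng.normal(size=(12, 12, 12))
        rot = np.rot90(data, k=1, axes=(0, 1))  # x -> y, y -> -x
        T = compute_structure_tensor(Volume3D(data, 50.0)).tensors
        T_rot = compute_structure_tensor(Volume3D(rot, 50.0)).tensors
        R = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        expected = np.einsum("ab,...bc,dc->...ad", R, T, R)
        expected = np.rot90(expected, k=1, axes=(0, 1))
        npt.assert_allclose(T_rot, expected, rtol=1e-9, atol=1e-12)


class TestBinomialPyramid:
    def test_dc_preserved_on_constant_field(self):
        T = TensorField3D(np.ones((8, 8, 8, 3, 3)), 50.0)
        out = binomial_smooth_downsample(T, 3)
        assert out.shape == (4, 4, 4)
        assert out.spacing == 100.0
        npt.assert_allclose(out.tensors, 1.0, rtol=1e-12)

    def test_kernels_normalized(self):
        assert binomial_kernel(3).sum() == pytest.approx(1.0)
        assert binomial_kernel(5).sum() == pytest.approx(1.0)

    def test_matches_dense_convolution_oracle(self, rng):
        """Separable binomial smoothing equals the dense 3D kernel product."""
        from scipy.ndimage import correlate

        field = rng.normal(size=(8, 8, 8))
        T = TensorField3D(np.einsum("...,ij->...ij", field, np.eye(3)), 50.0)
        out = binomial_smooth_downsample(T, 3, use_fft=True).tensors[..., 0, 0]
        k1 = binomial_kernel(3)
        dense = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        expected = correlate(field, dense, mode="mirror")[::2, ::2, ::2]
        npt.assert_allclose(out, expected, rtol=1e-10, atol=1e-12)

    def test_trace_linear_in_smoothing(self, oblique_slab_phantom):
        vol, _ = oblique_slab_phantom
        T = compute_structure_tensor(vol)
        sm = binomial_smooth_downsample(T, 3, use_fft=False)
        # smoothing the scalar trace directly must agree with trace-of-smoothed
        tr = TensorField3D(np.einsum("...,ij->...ij", T.trace(), np.eye(3)) / 3.0, 50.0)
        sm_tr = binomial_smooth_downsample(tr, 3, use_fft=False)
        npt.assert_allclose(sm.trace(), sm_tr.trace(), rtol=1e-10)

    def test_effective_support_width_bookkeeping(self):
        """3-pt derivative + two 3-pt binomial levels span 9 native voxels."""
        assert effective_support_width(dtw=3, stw=3, n_levels=2) == 9
        assert effective_support_width(dtw=3, stw=3, n_levels=0) == 3
        assert effective_support_width(dtw=5, stw=5, n_levels=0) == 5


class TestEigenanalysis:
    def test_diagonal_tensor(self):
        T = TensorField3D(np.broadcast_to(np.diag([3.0, 2.0, 1.0]),
                                          (2, 2, 2, 3, 3)).copy(), 50.0)
        res = st_eigenanalysis(T)
        npt.assert_allclose(res.eigvals[0, 0, 0], [3.0, 2.0, 1.0])
        v = st_vectors(res)
        npt.assert_allclose(np.abs(v["v3"][0, 0, 0]), [1, 0, 0], atol=1e-12)

    def test_slab_v3_matches_normal_and_v1_in_plane(self, slab_phantom):
        vol, truth = slab_phantom
        res = st_eigenanalysis(st_pyramid(vol, STConfig()))
        v = st_vectors(res)
        n_true = truth.n[0, 0, 0]
        dev = stats.axial_angle(v["v3"], n_true)
        interior = dev[1:-1, 1:-1, 1:-1]
        assert np.median(interior) < 3.0
        # v1 (putative myocyte) lies in the lamina plane: within 3 deg of it
        in_plane = 90.0 - stats.axial_angle(v["v1"], n_true)
        assert np.median(in_plane[1:-1, 1:-1, 1:-1]) < 3.0

    def test_sign_convention_largest_component_positive(self, rng):
        A = rng.normal(size=(4, 4, 4, 3, 3))
        T = TensorField3D(A + np.swapaxes(A, -1, -2), 50.0)
        res = st_eigenanalysis(T)
        lead = np.take_along_axis(
            res.eigvecs, np.argmax(np.abs(res.eigvecs), axis=-1)[..., None], axis=-1)
        assert np.all(lead >= 0)

    def test_orthonormal_triads(self, rng):
        A = rng.normal(size=(3, 3, 3, 3, 3))
        T = TensorField3D(A + np.swapaxes(A, -1, -2), 50.0)
        res = st_eigenanalysis(T)
        gram = np.einsum("...ik,...jk->...ij", res.eigvecs, res.eigvecs)
        npt.assert_allclose(gram, np.broadcast_to(np.eye(3), gram.shape), atol=1e-6)

    def test_degenerate_pair_flagged_by_confidence_ratio(self):
        """A two-fold symmetric tensor yields a laminar ratio of ~100%."""
        D = np.diag([2.0, 1.0, 1.0])
        T = TensorField3D(np.broadcast_to(D, (2, 2, 2, 3, 3)).copy(), 50.0)
        res = st_eigenanalysis(T)
        ratio = eigenvalue_ratio(res.eigvals[..., 2], res.eigvals[..., 1])
        npt.assert_allclose(ratio, 100.0, rtol=1e-9)


class TestEigenvalueRatio:
    def test_identity_and_zero(self):
        assert eigenvalue_ratio(2.0, 2.0) == pytest.approx(100.0)
        assert eigenvalue_ratio(0.0, 2.0) == pytest.approx(0.0)

    def test_arithmetic(self):
        assert eigenvalue_ratio(1.0, 2.0) == pytest.approx(100.0 * 1.0 / 2.0)

    def test_zero_denominator_flagged(self):
        assert np.isnan(eigenvalue_ratio(0.0, 0.0))

    def test_order_violation_rejected(self):
        with pytest.raises(ValidityError):
            eigenvalue_ratio(3.0, 2.0)


class TestFeathering:
    def test_background_near_boundary_takes_tissue_intensity(self):
        data = np.zeros((9, 9, 9))
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        data[mask] = 50.0
        out = feather_boundary(Volume3D(data, 50.0), mask, k=2)
        assert out.data[6, 4, 4] == 50.0  # one voxel outside
        assert out.data[0, 0, 0] == 0.0  # far outside untouched
        npt.assert_array_equal(out.data[mask], 50.0)
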