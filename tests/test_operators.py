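import numpy as np
import pytest
import scipy.ndimage

from epiunwarp.geometry import FieldMap, ImageVolume
from epiunwarp.operators import (
    average_pe,
    average_pe_adjoint,
    diff_pe,
    diff_pe_adjoint,
    gaussian_blur_333,
    gaussian_kernel_333,
    interp1d_pe,
    smoothness_H,
    smoothness_H_diagonal,
    solve_shifted_lap2d,
)


def dense_matrix(op, in_shape, out_shape=None):
    """Assemble the dense matrix of a linear operator by unit vectors."""
    n = int(np.prod(in_shape))
    cols = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        cols.append(op(e.reshape(in_shape)).ravel())
    return np.array(cols).T


class TestInterp1dPe:
    def test_identity_at_own_centers(self, rng):
        img = ImageVolume(rng.random((4, 5, 6)), (1.0, 1.0, 0.7))
        centers = (np.arange(6) + 0.5) * 0.7
        query = np.broadcast_to(centers, (4, 5, 6)).copy()
        np.testing.assert_allclose(interp1d_pe(img, query), img.data, atol=1e-14)

    def test_full_voxel_shift_matches_index_shift(self, rng):
        img = ImageVolume(rng.random((3, 3, 8)), (1.0, 1.0, 1.3))
        centers = (np.arange(8) + 0.5) * 1.3
        query = np.broadcast_to(centers + 1.3, (3, 3, 8)).copy()
        out = interp1d_pe(img, query)
        # away from the boundary the shifted query lands on exact centers
        np.testing.assert_allclose(out[:, :, :-2], img.data[:, :, 1:-1], atol=1e-12)

    def test_half_voxel_shift_hand_case(self):
        img = ImageVolume(np.broadcast_to([0.0, 2.0, 4.0], (2, 2, 3)).copy())
        centers = np.arange(3) + 0.5
        out = interp1d_pe(img, np.broadcast_to(centers + 0.5, (2, 2, 3)).copy())
        np.testing.assert_allclose(out[:, :, :2], np.broadcast_to([1.0, 3.0], (2, 2, 2)))

    def test_outside_domain_is_zero(self, rng):
        img = ImageVolume(rng.random((2, 2, 5)) + 1.0)
        query = np.full((2, 2, 5), 100.0)
        np.testing.assert_array_equal(interp1d_pe(img, query), 0.0)

    def test_nan_query_rejected(self):
        img = ImageVolume(np.ones((2, 2, 4)))
        q = np.full((2, 2, 4), np.nan)
        with pytest.raises(ValueError):
            interp1d_pe(img, q)

    def test_derivative_is_segment_slope(self):
        img = ImageVolume(np.broadcast_to([0.0, 2.0, 6.0], (2, 2, 3)).copy(),
                          (1.0, 1.0, 2.0))
        q = np.full((2, 2, 3), 2.2)  # inside segment between centers 1,3
        vals, slope = interp1d_pe(img, q, derivative=True)
        np.testing.assert_allclose(slope, 1.0)  # (2-0)/2mm


class TestAverageDiff:
    def test_hand_cases(self):
        b = np.broadcast_to([0.0, 1.0, 2.0], (2, 2, 3)).copy()
        np.testing.assert_allclose(average_pe(b), np.broadcast_to([0.5, 1.5], (2, 2, 2)))
        np.testing.assert_allclose(diff_pe(b, 0.5), np.broadcast_to([2.0, 2.0], (2, 2, 2)))
        c = np.full((3, 3, 4), 7.0)
        np.testing.assert_allclose(average_pe(c), 7.0)
        np.testing.assert_allclose(diff_pe(c, 1.0), 0.0)

    def test_matches_dense_operator(self, rng):
        shape = (3, 4, 6)
        b = rng.standard_normal(shape)
        h3 = 0.8
        A = dense_matrix(average_pe, shape)
        D = dense_matrix(lambda x: diff_pe(x, h3), shape)
        np.testing.assert_allclose(average_pe(b).ravel(), A @ b.ravel(), atol=1e-13)
        np.testing.assert_allclose(diff_pe(b, h3).ravel(), D @ b.ravel(), atol=1e-13)
        # adjoints really are the transposes
        At = dense_matrix(average_pe_adjoint, (3, 4, 5))
        Dt = dense_matrix(lambda y: diff_pe_adjoint(y, h3), (3, 4, 5))
        np.testing.assert_allclose(At, A.T, atol=1e-13)
        np.testing.assert_allclose(Dt, D.T, atol=1e-13)

    def test_linearity(self, rng):
        x = rng.standard_normal((3, 3, 5))
        y = rng.standard_normal((3, 3, 5))
        np.testing.assert_allclose(
            average_pe(2.5 * x + y), 2.5 * average_pe(x) + average_pe(y), atol=1e-12
        )
        np.testing.assert_allclose(
            diff_pe(2.5 * x + y, 1.1), 2.5 * diff_pe(x, 1.1) + diff_pe(y, 1.1),
            atol=1e-12,
        )

    def test_slice_independence(self, rng):
        b = rng.standard_normal((4, 4, 5))
        perm = [2, 0, 1, 3]
        np.testing.assert_allclose(average_pe(b[perm]), average_pe(b)[perm])
        np.testing.assert_allclose(diff_pe(b[perm], 1.0), diff_pe(b, 1.0)[perm])

    def test_bad_h3(self):
        with pytest.raises(ValueError):
            diff_pe(np.zeros((2, 2, 3)), 0.0)


class TestSmoothnessH:
    VS = (1.0, 1.3, 0.7)

    def test_constant_in_null_space(self):
        b = np.full((4, 5, 6), 3.0)
        np.testing.assert_allclose(smoothness_H(b, self.VS), 0.0, atol=1e-12)

    def test_quadratic_form_equals_difference_norms(self, rng):
        shape = (4, 4, 5)
        b = rng.standard_normal(shape)
        hb = smoothness_H(b, self.VS)
        quad = float(np.vdot(b, hb))
        expected = sum(
            np.sum((np.diff(b, axis=ax) / h) ** 2) for ax, h in enumerate(self.VS)
        )
        assert abs(quad - expected) / expected < 1e-10

    def test_symmetry_random_vectors(self, rng):
        shape = (3, 4, 5)
        x, y = rng.standard_normal((2,) + shape)
        xhy = float(np.vdot(x, smoothness_H(y, self.VS)))
        yhx = float(np.vdot(y, smoothness_H(x, self.VS)))
        assert abs(xhy - yhx) <= 1e-10 * max(abs(xhy), 1.0)

    def test_null_space_is_exactly_constants(self):
        shape = (3, 3, 4)
        H = dense_matrix(lambda x: smoothness_H(x, self.VS), shape)
        w = np.linalg.eigvalsh(H)
        assert abs(w[0]) < 1e-10
        assert w[1] > 1e-3

    def test_diagonal_extractor(self, rng):
        shape = (3, 4, 5)
        H = dense_matrix(lambda x: smoothness_H(x, self.VS), shape)
        np.testing.assert_allclose(
            np.diag(H), smoothness_H_diagonal(shape, self.VS).ravel(), atol=1e-12
        )


class TestGaussianBlur:
    def test_constant_preserved(self):
        f = FieldMap(np.full((5, 5, 6), 4.2))
        np.testing.assert_allclose(gaussian_blur_333(f).values, 4.2, atol=1e-12)

    def test_delta_gives_kernel(self):
        v = np.zeros((9, 9, 9))
        v[4, 4, 4] = 1.0
        out = gaussian_blur_333(FieldMap(v)).values
        kernel = gaussian_kernel_333()
        np.testing.assert_allclose(out[3:6, 3:6, 3:6], kernel, atol=1e-12)
        flat = np.sort(kernel.ravel())
        assert flat[-1] == kernel[1, 1, 1] and flat[-1] > flat[-2]

    def test_fft_matches_spatial_convolution(self, rng):
        v = rng.standard_normal((6, 7, 8))
        out = gaussian_blur_333(FieldMap(v)).values
        ref = scipy.ndimage.convolve(v, gaussian_kernel_333(), mode="wrap")
        np.testing.assert_allclose(out, ref, atol=1e-8)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur_333(FieldMap(np.zeros((2, 5, 5))))


class TestShiftedLap2d:
    def test_identity_system(self, rng):
        rhs = rng.standard_normal((4, 4, 3))
        np.testing.assert_allclose(
            solve_shifted_lap2d(rhs, 0.0, 2.0), rhs / 2.0, atol=1e-12
        )

    def test_constant_rhs(self):
        rhs = np.full((6, 6, 2), 3.0)
        np.testing.assert_allclose(
            solve_shifted_lap2d(rhs, 5.0, 1.5), 2.0, atol=1e-10
        )

    def test_matches_dense_periodic_solve(self, rng):
        n1, n2, n3 = 8, 8, 3
        h1, h2 = 1.1, 0.9
        lap_c, shift_c = 2.3, 0.7
        rhs = rng.standard_normal((n1, n2, n3))

        def lap1d(n, h):
            L = np.zeros((n, n))
            for i in range(n):
                L[i, i] = 2.0 / h**2
                L[i, (i - 1) % n] -= 1.0 / h**2
                L[i, (i + 1) % n] -= 1.0 / h**2
            return L

        L = np.kron(lap1d(n1, h1), np.eye(n2)) + np.kron(np.eye(n1), lap1d(n2, h2))
        A = lap_c * L + shift_c * np.eye(n1 * n2)
        z = solve_shifted_lap2d(rhs, lap_c, shift_c, spacings=(h1, h2))
        for k in range(n3):
            expected = np.linalg.solve(A, rhs[:, :, k].ravel())
            err = np.linalg.norm(z[:, :, k].ravel() - expected) / np.linalg.norm(expected)
            assert err < 1e-10

    def test_nonpositive_shift_rejected(self):
        with pytest.raises(ValueError):
            solve_shifted_lap2d(np.zeros((4, 4, 2)), 1.0, 0.0)
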