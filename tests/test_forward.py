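"""Forward model: dipole kernels, field computation, intravoxel dephasing."""

import numpy as np
import pytest
from scipy import ndimage

from boldpert import (
    AcquisitionParams,
    FieldMap,
    SusceptibilitySeries,
    SusceptibilityVolume,
    VoxelGrid,
    chi_to_field,
    dephase_to_complex,
    dipole_kernel_kspace,
    dipole_kernel_spatial,
    magnitude_first_order,
    phase_taylor,
    simulate_t2star_series,
    sphere_field_analytic,
    wrap_phase,
)
from boldpert.forward import _field_from_chi_array
from boldpert.phantom import BlobSpec, make_background_chi


class TestSpatialKernel:
    def test_printed_formula_values(self):
        assert dipole_kernel_spatial((0.0, 0.0, 1.0)) == pytest.approx(1 / (2 * np.pi))
        assert dipole_kernel_spatial((1.0, 0.0, 0.0)) == pytest.approx(-1 / (4 * np.pi))

    def test_magic_angle_zero(self):
        # z^2/r^2 = 1/3 kills 3z^2 - r^2
        z = 1.0
        rho = np.sqrt(2.0) * z  # then r^2 = 3 z^2
        assert dipole_kernel_spatial((rho, 0.0, z)) == pytest.approx(0.0, abs=1e-15)

    def test_singular_at_origin(self):
        with pytest.raises(ValueError, match="singular"):
            dipole_kernel_spatial((0.0, 0.0, 0.0))

    def test_oblique_b0_is_a_rotation(self):
        # field along an oblique axis equals the on-axis value
        d = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        val = dipole_kernel_spatial(2.0 * d, b0_direction=tuple(d))
        assert val == pytest.approx(dipole_kernel_spatial((0.0, 0.0, 2.0)))


class TestKSpaceKernel:
    def test_bounds_and_axis_values(self, grid32):
        kernel = dipole_kernel_kspace(grid32).values
        assert kernel.min() == pytest.approx(-2 / 3)
        assert kernel.max() == pytest.approx(1 / 3)
        assert kernel.flat[0] == 0.0
        # k purely along z -> -2/3 ; purely transverse -> 1/3
        assert kernel[0, 0, 1] == pytest.approx(-2 / 3)
        assert kernel[1, 0, 0] == pytest.approx(1 / 3)

    def test_smooth_source_matches_direct_spatial_convolution(self):
        """Fourier multiplication vs. brute-force spatial summation of the
        printed kernel, on a smooth source where both discretizations
        approximate the same continuum field."""
        n = 17
        grid = VoxelGrid((n, n, n))
        acq = AcquisitionParams(supersample=1)
        xx, yy, zz = grid.coordinate_arrays_mm()
        src = np.exp(-((xx + 1) ** 2 + (yy - 2) ** 2 + zz**2) / (2 * 1.5**2))
        fourier = chi_to_field(SusceptibilityVolume(grid, src), acq).values_tesla

        m = 2 * n - 1
        off = (np.arange(m) - (n - 1)).astype(float)
        ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
        rr2 = ox**2 + oy**2 + oz**2
        kernel = np.zeros((m, m, m))
        nz = rr2 > 0
        kernel[nz] = (3 * oz[nz] ** 2 - rr2[nz]) / (4 * np.pi * rr2[nz] ** 2.5)
        spatial = ndimage.convolve(src, kernel[::-1, ::-1, ::-1], mode="constant")
        spatial = acq.b0_tesla * 1e-6 * spatial
        spatial -= spatial.mean()

        rel = np.linalg.norm(fourier - spatial) / np.linalg.norm(spatial)
        assert rel < 0.05

    def test_point_response_matches_kernel_off_axis(self):
        """Away from the coordinate axes (where band-limitation ringing of a
        1-voxel source concentrates) the FFT point response equals the
        spatial kernel."""
        n = 33
        grid = VoxelGrid((n, n, n))
        acq = AcquisitionParams(supersample=1)
        src = np.zeros((n, n, n))
        c = n // 2
        src[c, c, c] = 1.0
        fld = chi_to_field(SusceptibilityVolume(grid, src), acq).values_tesla
        for d in (3, 5, 8):
            got = fld[c + d, c + d, c]
            want = acq.b0_tesla * 1e-6 * dipole_kernel_spatial((d, d, 0.0))
            assert got == pytest.approx(want, rel=0.05)


class TestChiToField:
    def test_uniform_chi_gives_zero_field(self, grid32, acq):
        # D(0) = 0: a uniform offset is unobservable (periodic operator;
        # with padding a uniform box is a susceptibility cube, not uniform)
        chi = SusceptibilityVolume(grid32, np.full(grid32.shape, 0.3))
        fld = chi_to_field(chi, acq, zero_pad=False)
        assert np.max(np.abs(fld.values_tesla)) < 1e-20

    def test_linearity_to_machine_precision(self, grid32, acq):
        rng = np.random.default_rng(0)
        a = rng.normal(size=grid32.shape)
        b = rng.normal(size=grid32.shape)
        f_sum = chi_to_field(SusceptibilityVolume(grid32, a + b), acq).values_tesla
        f_a = chi_to_field(SusceptibilityVolume(grid32, a), acq).values_tesla
        f_b = chi_to_field(SusceptibilityVolume(grid32, b), acq).values_tesla
        np.testing.assert_allclose(f_sum, f_a + f_b, atol=1e-18)

    def test_nonfinite_chi_rejected(self, grid32, acq):
        bad = np.zeros(grid32.shape)
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            _field_from_chi_array(bad, grid32, acq.b0_tesla, True)

    def test_sphere_exterior_on_axis_value(self, acq):
        # on-axis exterior field at r = 2a is B0 * dchi_si / 12; odd grid so
        # voxel centres land on integer coordinates and r = 2a is exact
        grid = VoxelGrid((65, 65, 65))
        a = 6.0
        chi = make_background_chi(
            grid,
            [BlobSpec((0.0, 0.0, 0.0), a, 1.0)],
            envelope_semiaxes_mm=(30.0, 30.0, 30.0),
        )
        fld = chi_to_field(chi, acq)
        c = 32  # centre voxel index
        want = acq.b0_tesla * 1e-6 / 12.0
        assert fld.values_tesla[c, c, c + 12] == pytest.approx(want, rel=0.1)


class TestSphereAnalytic:
    def test_closed_form_values(self, acq):
        grid = VoxelGrid((65, 65, 65))  # odd: voxel centres on integers
        fld = sphere_field_analytic(grid, (0.0, 0.0, 0.0), 6.0, 1.0, acq)
        c = 32
        b0si = acq.b0_tesla * 1e-6
        assert fld.values_tesla[c, c, c + 12] == pytest.approx(b0si / 12.0, rel=1e-6)
        assert fld.values_tesla[c + 12, c, c] == pytest.approx(-b0si / 24.0, rel=1e-6)

    def test_magic_angle_exterior_zero(self, acq):
        grid = VoxelGrid((64, 64, 64))
        fld = sphere_field_analytic(grid, (0.0, 0.0, 0.0), 4.0, 1.0, acq)
        xx, yy, zz = grid.coordinate_arrays_mm()
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        with np.errstate(invalid="ignore"):
            cos2 = np.where(r > 0, (zz / np.where(r > 0, r, 1)) ** 2, 0)
        near_magic = (np.abs(cos2 - 1 / 3) < 1e-3) & (r > 8.0)
        assert near_magic.any()
        assert np.max(np.abs(fld.values_tesla[near_magic])) < 1e-3 * np.max(
            np.abs(fld.values_tesla)
        )

    def test_nonpositive_radius_rejected(self, grid32, acq):
        with pytest.raises(ValueError, match="radius"):
            sphere_field_analytic(grid32, (0, 0, 0), 0.0, 1.0, acq)


class TestDephasing:
    def test_blockwise_uniform_field_gives_unit_magnitude(self, acq):
        coarse = VoxelGrid((8, 8, 8))
        fine = coarse.supersampled(2)
        rng = np.random.default_rng(1)
        per_voxel = rng.normal(0, 1e-8, coarse.shape)
        per_voxel -= per_voxel.mean()
        field_fine = np.repeat(
            np.repeat(np.repeat(per_voxel, 2, 0), 2, 1), 2, 2
        )
        c = dephase_to_complex(FieldMap(fine, field_fine), acq, coarse)
        np.testing.assert_allclose(np.abs(c), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            np.angle(c), wrap_phase(acq.gamma_te * per_voxel), atol=1e-9
        )

    def test_symmetric_pair_gives_real_cosine(self):
        # half the voxel at +phi, half at -phi -> C = cos(phi), phase 0
        acq = AcquisitionParams(supersample=2)
        coarse = VoxelGrid((8, 8, 8))
        fine = coarse.supersampled(2)
        phi = 0.7
        pattern = np.empty(fine.shape)
        pattern[::2, :, :] = +phi / acq.gamma_te
        pattern[1::2, :, :] = -phi / acq.gamma_te
        c = dephase_to_complex(FieldMap(fine, pattern), acq, coarse)
        np.testing.assert_allclose(c.real, np.cos(phi), atol=1e-12)
        np.testing.assert_allclose(c.imag, 0.0, atol=1e-12)

    def test_magnitude_never_exceeds_one(self, acq):
        coarse = VoxelGrid((8, 8, 8))
        fine = coarse.supersampled(3)
        rng = np.random.default_rng(2)
        field = rng.normal(0, 5e-8, fine.shape)
        field -= field.mean()
        acq3 = AcquisitionParams(supersample=3)
        c = dephase_to_complex(FieldMap(fine, field), acq3, coarse)
        assert np.all(np.abs(c) <= 1 + 1e-9)

    def test_zero_echo_time_limit_gives_unity(self):
        acq0 = AcquisitionParams(te_s=1e-15, supersample=2)
        coarse = VoxelGrid((8, 8, 8))
        fine = coarse.supersampled(2)
        rng = np.random.default_rng(3)
        field = rng.normal(0, 1e-7, fine.shape)
        field -= field.mean()
        c = dephase_to_complex(FieldMap(fine, field), acq0, coarse)
        np.testing.assert_allclose(c, 1.0, atol=1e-9)

    def test_non_integer_supersample_rejected(self, acq):
        coarse = VoxelGrid((8, 8, 8))
        fine = VoxelGrid((12, 12, 12))
        with pytest.raises(ValueError, match="integer multiple"):
            dephase_to_complex(
                FieldMap(fine, np.zeros(fine.shape)), acq, coarse
            )


class TestSimulateSeries:
    def test_static_source_gives_identical_frames(self, grid32, acq):
        chi0 = make_background_chi(
            grid32,
            [BlobSpec((0, 0, 0), 5.0, 0.4)],
            envelope_semiaxes_mm=(14, 14, 14),
        )
        series = SusceptibilitySeries(
            grid32, np.repeat(chi0.values_ppm[..., None], 3, axis=3), tr_s=3.0
        )
        t2s = simulate_t2star_series(series, acq)
        for t in (1, 2):
            np.testing.assert_array_equal(
                t2s.complex_values[..., t], t2s.complex_values[..., 0]
            )

    def test_supersample_one_phase_is_wrapped_linear_map(self, grid32):
        acq = AcquisitionParams(supersample=1)
        chi0 = make_background_chi(
            grid32,
            [BlobSpec((0, 0, 0), 5.0, 0.4)],
            envelope_semiaxes_mm=(14, 14, 14),
        )
        series = SusceptibilitySeries(grid32, chi0.values_ppm[..., None], tr_s=3.0)
        t2s = simulate_t2star_series(series, acq)
        fld = chi_to_field(chi0, acq)
        np.testing.assert_allclose(
            t2s.phase[..., 0], wrap_phase(acq.gamma_te * fld.values_tesla), atol=1e-9
        )
        np.testing.assert_allclose(t2s.magnitude, 1.0, atol=1e-12)

    def test_7t_demo_phase_is_severely_wrapped(self, grid64, acq):
        from boldpert.phantom import default_background_specs

        chi0 = make_background_chi(grid64, default_background_specs(grid64))
        series = SusceptibilitySeries(grid64, chi0.values_ppm[..., None], tr_s=3.0)
        t2s = simulate_t2star_series(series, acq)
        # raw 7T phase spans essentially the full [-pi, pi) interval
        assert t2s.phase.min() < -0.95 * np.pi
        assert t2s.phase.max() > 0.95 * np.pi

    def test_seeded_noise_is_reproducible(self, grid32, acq):
        chi = SusceptibilitySeries(grid32, np.zeros(grid32.shape + (2,)), tr_s=3.0)
        a = simulate_t2star_series(chi, acq, noise_sd=0.01, seed=5)
        b = simulate_t2star_series(chi, acq, noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a.complex_values, b.complex_values)


class TestTaylorDiagnostics:
    def _fine_field(self, values):
        coarse = VoxelGrid((8, 8, 8))
        fine = coarse.supersampled(2)
        return coarse, FieldMap(fine, values)

    def test_zero_field_gives_unit_magnitude_and_zero_phase(self, acq):
        acq2 = AcquisitionParams(supersample=2)
        coarse, fld = self._fine_field(np.zeros((16, 16, 16)))
        assert np.all(magnitude_first_order(fld, acq2, coarse) == 1.0)
        assert np.all(phase_taylor(fld, acq2, coarse, order=1) == 0.0)
        assert np.all(phase_taylor(fld, acq2, coarse, order=2) == 0.0)

    def test_printed_magnitude_formula_and_its_sign_discrepancy(self):
        # two subvoxel fields at +/-0.1 rad: printed formula gives 1.005,
        # exact dephasing gives cos(0.1) ~ 0.995 -- opposite side of 1
        acq2 = AcquisitionParams(supersample=2)
        coarse = VoxelGrid((8, 8, 8))
        fine = coarse.supersampled(2)
        pattern = np.empty(fine.shape)
        pattern[::2, :, :] = +0.1 / acq2.gamma_te
        pattern[1::2, :, :] = -0.1 / acq2.gamma_te
        fld = FieldMap(fine, pattern)
        approx = magnitude_first_order(fld, acq2, coarse)
        np.testing.assert_allclose(approx, 1.005, atol=1e-12)
        exact = np.abs(dephase_to_complex(fld, acq2, coarse))
        np.testing.assert_allclose(exact, np.cos(0.1), atol=1e-12)
        assert np.all(approx >= 1.0) and np.all(exact <= 1.0)

    def _mirrored_pair_field(self, acq2):
        # voxels in the first x-half hold subvoxel phases {0.05, 0.15} rad,
        # the second half the negated pair, keeping the volume mean-free
        coarse = VoxelGrid((8, 8, 8))
        fine = coarse.supersampled(2)
        pattern = np.empty(fine.shape)
        pattern[0::2, :, :] = 0.05 / acq2.gamma_te
        pattern[1::2, :, :] = 0.15 / acq2.gamma_te
        pattern[8:, :, :] *= -1.0
        return coarse, FieldMap(fine, pattern)

    def test_first_order_phase_is_subvoxel_mean(self):
        acq2 = AcquisitionParams(supersample=2)
        coarse, fld = self._mirrored_pair_field(acq2)
        phase1 = phase_taylor(fld, acq2, coarse, order=1)
        np.testing.assert_allclose(phase1[:4], 0.1, atol=1e-12)
        np.testing.assert_allclose(phase1[4:], -0.1, atol=1e-12)

    def test_symmetric_pair_exact_phase_equals_first_order(self):
        # {0.05, 0.15} rad pair: exact phasor-average phase is also the mean
        acq2 = AcquisitionParams(supersample=2)
        coarse, fld = self._mirrored_pair_field(acq2)
        exact = np.angle(dephase_to_complex(fld, acq2, coarse))
        first = phase_taylor(fld, acq2, coarse, order=1)
        np.testing.assert_allclose(exact, first, atol=1e-12)

    def test_invalid_order_rejected(self, acq):
        coarse, fld = self._fine_field(np.zeros((16, 16, 16)))
        with pytest.raises(ValueError, match="order"):
            phase_taylor(fld, AcquisitionParams(supersample=2), coarse, order=3)


def test_field_series_invariants(grid32, acq, regressor_7t):
    from boldpert import chi_series_to_field
    from boldpert.phantom import default_bold_blobs, make_bold_perturbation

    dchi = make_bold_perturbation(
        grid32, default_bold_blobs(grid32), regressor_7t, 0.0, seed=0
    )
    sub = SusceptibilitySeries(grid32, dchi.values_ppm[..., :3], tr_s=3.0)
    fs = chi_series_to_field(sub, acq)
    assert fs.n_t == 3
    # frame-wise equality with the single-volume path
    f0 = chi_to_field(SusceptibilityVolume(grid32, sub.values_ppm[..., 2]), acq)
    np.testing.assert_array_equal(fs.values_tesla[..., 2], f0.values_tesla)
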