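"""Reflectance calibration, kernel construction and least-squares inversion."""

import numpy as np
import pytest

import ppixmap as pm
from ppixmap.containers import (
    EMISSION_BAND_NM,
    EmissionBasis,
    ROIPatch,
    ReflectanceField,
    ScalarField,
    SpectralCube,
    WavelengthGrid,
)

from _oracles import ls_1d_brute_force


def _cube(data, grid=None, illum="white", exposure=100.0):
    grid = grid or WavelengthGrid.default()
    return SpectralCube(np.asarray(data, float), grid, illum, exposure)


def _flat_refl(value, shape=(3, 3), grid=None):
    grid = grid or WavelengthGrid.default()
    vals = np.full(shape + (len(grid),), float(value))
    return ReflectanceField(vals, np.ones(shape, bool), grid)


class TestNormalizeReflectance:
    def test_identity_when_meas_equals_ref(self, rng):
        data = rng.uniform(10, 100, (4, 4, 33))
        meas = _cube(data)
        ref = _cube(data.copy())
        out = pm.normalize_reflectance(meas, ref)
        assert out.mask.all()
        np.testing.assert_allclose(out.values, 1.0)

    def test_zero_reference_pixel_masked(self, rng):
        data = rng.uniform(10, 100, (4, 4, 33))
        ref = data.copy()
        ref[2, 1, :] = 0.0
        out = pm.normalize_reflectance(_cube(data), _cube(ref), floor=1e-6)
        assert not out.mask[2, 1]
        assert out.mask.sum() == 15
        assert np.isnan(out.values[2, 1]).all()
        np.testing.assert_allclose(out.values[out.mask], 1.0)

    def test_elementwise_ratio_oracle(self, rng):
        m = rng.uniform(1, 50, (4, 4, 33))
        r = rng.uniform(1, 50, (4, 4, 33))
        out = pm.normalize_reflectance(_cube(m), _cube(r), floor=0.0)
        np.testing.assert_allclose(out.values, m / r, rtol=0, atol=1e-12)

    def test_exposure_compensation(self, rng):
        m = rng.uniform(1, 50, (3, 3, 33))
        r = rng.uniform(1, 50, (3, 3, 33))
        out = pm.normalize_reflectance(
            _cube(m, exposure=50.0), _cube(r, exposure=100.0), floor=0.0
        )
        np.testing.assert_allclose(out.values, (m / 50.0) / (r / 100.0), atol=1e-12)

    def test_rejections_name_the_axis(self, rng):
        m = _cube(rng.uniform(1, 2, (3, 3, 33)))
        with pytest.raises(ValueError, match="wavelength"):
            pm.normalize_reflectance(
                m, _cube(rng.uniform(1, 2, (3, 3, 13)), WavelengthGrid.emission())
            )
        with pytest.raises(ValueError, match="spatial"):
            pm.normalize_reflectance(m, _cube(rng.uniform(1, 2, (4, 3, 33))))
        with pytest.raises(ValueError, match="illumination"):
            pm.normalize_reflectance(m, _cube(rng.uniform(1, 2, (3, 3, 33)), illum="uv"))


class TestMeanExcitationReflectance:
    def test_constant_field(self):
        out = pm.mean_excitation_reflectance(_flat_refl(0.2))
        np.testing.assert_allclose(out.values, 0.2)

    def test_three_band_mean(self):
        grid = WavelengthGrid.default()
        refl = _flat_refl(0.0, (2, 2))
        for nm, v in ((430.0, 0.1), (440.0, 0.2), (450.0, 0.3)):
            refl.values[:, :, grid.index_of(nm)] = v
        np.testing.assert_allclose(pm.mean_excitation_reflectance(refl).values, 0.2)

    def test_random_field_matches_mean_oracle(self, rng):
        grid = WavelengthGrid.default()
        vals = rng.uniform(0, 1, (5, 5, 33))
        refl = ReflectanceField(vals, np.ones((5, 5), bool), grid)
        idx = [grid.index_of(nm) for nm in (430.0, 440.0, 450.0)]
        expected = vals[:, :, idx].mean(axis=2)
        np.testing.assert_allclose(
            pm.mean_excitation_reflectance(refl).values, expected, atol=1e-12
        )

    def test_missing_band_rejected(self):
        grid = WavelengthGrid.emission()
        refl = ReflectanceField(
            np.ones((2, 2, 13)), np.ones((2, 2), bool), grid
        )
        with pytest.raises(ValueError, match="430"):
            pm.mean_excitation_reflectance(refl)


class TestBuildKernel:
    def test_neutral_reflectance_yields_basis(self, basis):
        rbar = ScalarField(np.zeros((3, 3)))
        rem = _flat_refl(1.0, (3, 3), basis.grid)
        k = pm.build_kernel(rbar, rem, basis, q=2.6)
        assert k.q == 2.6
        np.testing.assert_allclose(
            k.values, np.broadcast_to(basis.values, (3, 3, 13)), atol=1e-12
        )

    def test_zero_exponent_ignores_rem(self, basis, rng):
        rbar = ScalarField(rng.uniform(0, 0.9, (3, 3)))
        rem = ReflectanceField(
            rng.uniform(0.1, 2.0, (3, 3, 13)), np.ones((3, 3), bool), basis.grid
        )
        k = pm.build_kernel(rbar, rem, basis, q=0.0)
        expected = (1 - rbar.values)[:, :, None] * basis.values[None, None, :]
        np.testing.assert_allclose(k.values, expected, atol=1e-12)

    def test_default_q_recorded(self, basis):
        k = pm.build_kernel(
            ScalarField(np.zeros((2, 2))), _flat_refl(0.5, (2, 2), basis.grid), basis
        )
        assert k.q == pytest.approx(2.6)

    def test_specular_pixels_clamped_not_negative(self, basis):
        rbar = ScalarField(np.array([[1.3, 0.2]]))
        rem = _flat_refl(0.5, (1, 2), basis.grid)
        k = pm.build_kernel(rbar, rem, basis, q=1.0)
        assert k.mask.all()
        assert (k.values[0, 0] >= 0).all()

    def test_negative_rem_masked_under_noninteger_q(self, basis):
        vals = np.full((1, 2, 13), 0.5)
        vals[0, 1, 4] = -0.1
        rem = ReflectanceField(
            np.abs(vals), np.ones((1, 2), bool), basis.grid
        )
        rem.values[0, 1, 4] = -0.1  # bypass constructor positivity on masked path
        k = pm.build_kernel(ScalarField(np.zeros((1, 2))), rem, basis, q=2.6)
        assert k.mask[0, 0] and not k.mask[0, 1]


class TestLsConcentration:
    def _kernel(self, basis, shape=(2, 2)):
        rbar = ScalarField(np.full(shape, 0.3))
        rem = _flat_refl(0.6, shape, basis.grid)
        return pm.build_kernel(rbar, rem, basis, q=2.6)

    def test_exact_multiple_recovered(self, basis):
        k = self._kernel(basis)
        fluo = SpectralCube(3.0 * k.values, basis.grid, "uv")
        c = pm.ls_concentration(fluo, k)
        np.testing.assert_allclose(c.values, 3.0, atol=1e-12)

    def test_orthogonal_signal_gives_zero(self, basis, rng):
        # kernel supported on the red half of the band, signal on the blue half
        from ppixmap.containers import KernelField

        h = np.zeros(13)
        h[7:] = rng.uniform(0.5, 1.0, 6)
        k = KernelField(h[None, None, :], 2.6, np.ones((1, 1), bool))
        f = np.zeros(13)
        f[:7] = rng.uniform(0.5, 1.0, 7)
        fluo = SpectralCube(f[None, None, :], basis.grid, "uv")
        c = pm.ls_concentration(fluo, k)
        assert c.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_minimizer(self, basis, rng):
        k = self._kernel(basis, (1, 1))
        h = k.values[0, 0]
        f = rng.uniform(0, 1, 13)
        fluo = SpectralCube(f[None, None, :], basis.grid, "uv")
        c = pm.ls_concentration(fluo, k).values[0, 0]
        oracle = ls_1d_brute_force(f, h, -10.0, 10.0)
        assert c == pytest.approx(oracle, abs=1e-6)

    def test_linearity_superposition(self, basis, rng):
        k = self._kernel(basis, (3, 3))
        f1 = rng.uniform(0, 1, (3, 3, 13))
        f2 = rng.uniform(0, 1, (3, 3, 13))
        a, b = 1.7, 0.4
        c1 = pm.ls_concentration(SpectralCube(f1, basis.grid, "uv"), k).values
        c2 = pm.ls_concentration(SpectralCube(f2, basis.grid, "uv"), k).values
        c12 = pm.ls_concentration(
            SpectralCube(a * f1 + b * f2, basis.grid, "uv"), k
        ).values
        np.testing.assert_allclose(c12, a * c1 + b * c2, atol=1e-10)

    def test_all_zero_kernel_rejected(self, basis):
        from ppixmap.containers import KernelField

        k = KernelField(np.zeros((2, 2, 13)), 2.6, np.ones((2, 2), bool))
        fluo = SpectralCube(np.ones((2, 2, 13)), basis.grid, "uv")
        with pytest.raises(ValueError, match="no valid pixels"):
            pm.ls_concentration(fluo, k)

    def test_printed_variant_scales_by_kernel_norm(self, basis, rng):
        k = self._kernel(basis, (2, 2))
        f = rng.uniform(0, 1, (2, 2, 13))
        fluo = SpectralCube(f, basis.grid, "uv")
        exact = pm.ls_concentration(fluo, k).values
        printed = pm.ls_concentration(fluo, k, variant="printed").values
        norm = np.sqrt(np.einsum("ijk,ijk->ij", k.values, k.values))
        np.testing.assert_allclose(printed, exact * norm, atol=1e-10)


class TestCorrectedSpectrum:
    def test_neutral_correction_is_identity(self, basis, rng):
        f = rng.uniform(0, 1, (2, 2, 13))
        fluo = SpectralCube(f, basis.grid, "uv")
        out = pm.corrected_spectrum(
            fluo, ScalarField(np.zeros((2, 2))), _flat_refl(1.0, (2, 2), basis.grid), q=2.6
        )
        np.testing.assert_allclose(out.data, f, atol=1e-12)

    def test_zero_exponent_with_zero_rbar_is_identity(self, basis, rng):
        f = rng.uniform(0, 1, (2, 2, 13))
        fluo = SpectralCube(f, basis.grid, "uv")
        out = pm.corrected_spectrum(
            fluo,
            ScalarField(np.zeros((2, 2))),
            _flat_refl(0.37, (2, 2), basis.grid),
            q=0.0,
        )
        np.testing.assert_allclose(out.data, f, atol=1e-12)

    def test_equalizes_phantoms_differing_in_hemoglobin(self, basis, simulate_uniform):
        """Two noiseless phantoms, same PpIX, different Hb: the corrected
        640-nm peaks coincide although the raw peaks differ."""
        from ppixmap.pipeline import reconstruct_ls  # noqa: F401  (pipeline helpers below)
        from ppixmap.spectral import (
            corrected_spectrum,
            mean_excitation_reflectance,
            normalize_reflectance,
        )

        peaks_raw, peaks_corr = [], []
        for hb in (0.75, 2.0):
            _, cubes = simulate_uniform(pm.PhantomRecipe(1.5, hb, 0.5), size=8)
            rex = normalize_reflectance(
                cubes["fluo_uv"].restrict(430, 450), cubes["ref_uv"].restrict(430, 450)
            )
            rbar = mean_excitation_reflectance(rex)
            rem = normalize_reflectance(
                cubes["refl_white"].restrict(*EMISSION_BAND_NM),
                cubes["ref_white"].restrict(*EMISSION_BAND_NM),
            )
            fl = normalize_reflectance(
                cubes["fluo_uv"].restrict(*EMISSION_BAND_NM),
                cubes["ref_uv"].restrict(*EMISSION_BAND_NM),
            )
            fcube = SpectralCube(
                np.where(fl.mask[:, :, None], fl.values, 0.0), fl.grid, "uv"
            )
            corr = corrected_spectrum(fcube, rbar, rem, q=2.6)
            peaks_raw.append(np.nanmean(fcube.band(640.0)))
            peaks_corr.append(np.nanmean(corr.band(640.0)))
        assert abs(peaks_raw[0] - peaks_raw[1]) / peaks_raw[0] > 0.05
        assert abs(peaks_corr[0] - peaks_corr[1]) / peaks_corr[0] <= 1e-6


class TestValdesCorrection:
    def _refl(self, ex_level, em_level, shape=(2, 2)):
        grid = WavelengthGrid.default()
        vals = np.full(shape + (33,), 1.0)
        for nm in (460.0, 470.0, 480.0):
            vals[:, :, grid.index_of(nm)] = ex_level
        for nm in (620.0, 630.0, 640.0):
            vals[:, :, grid.index_of(nm)] = em_level
        return ReflectanceField(vals, np.ones(shape, bool), grid)

    def test_unit_integrals_identity(self, rng):
        # trapezoid over three 10-nm-spaced bands has width 20: level 0.05 -> 1
        refl = self._refl(0.05, 0.05)
        f = rng.uniform(0, 1, (2, 2, 33))
        fluo = _cube(f, illum="uv")
        for alpha in (0.0, 0.7, 1.4):
            out = pm.valdes_correction(fluo, refl, alpha)
            np.testing.assert_allclose(out.data, f, atol=1e-12)

    def test_scalar_division(self, rng):
        refl = self._refl(0.1, 0.05)  # phi_ex = 2, phi_em = 1
        f = rng.uniform(0, 1, (2, 2, 33))
        out = pm.valdes_correction(_cube(f, illum="uv"), refl, alpha=1.0)
        np.testing.assert_allclose(out.data, f / 2.0, atol=1e-12)

    def test_random_reflectance_formula_oracle(self, rng):
        grid = WavelengthGrid.default()
        vals = rng.uniform(0.01, 1.0, (3, 3, 33))
        refl = ReflectanceField(vals, np.ones((3, 3), bool), grid)
        f = rng.uniform(0, 1, (3, 3, 33))
        alpha = 0.7
        out = pm.valdes_correction(_cube(f, illum="uv"), refl, alpha)
        idx_ex = [grid.index_of(nm) for nm in (460.0, 470.0, 480.0)]
        idx_em = [grid.index_of(nm) for nm in (620.0, 630.0, 640.0)]
        phi_ex = np.trapezoid(vals[:, :, idx_ex], dx=10.0, axis=2)
        phi_em = np.trapezoid(vals[:, :, idx_em], dx=10.0, axis=2)
        expected = f / (phi_ex * phi_em**alpha)[:, :, None]
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_agrees_with_model_correction_in_flat_limit(self, basis, rng):
        """With spatially constant reflectance, flat over the emission band,
        and alpha = q, the two corrections differ by a global scalar."""
        r_em = 0.45
        q = 2.6
        grid_full = WavelengthGrid.default()
        vals = np.full((2, 2, 33), r_em)
        refl = ReflectanceField(vals, np.ones((2, 2), bool), grid_full)
        f = rng.uniform(0.1, 1.0, (2, 2, 33))
        fluo = _cube(f, illum="uv")
        v_out = pm.valdes_correction(fluo, refl, alpha=q)

        rbar = ScalarField(np.full((2, 2), 0.45))
        rem = _flat_refl(r_em, (2, 2), basis.grid)
        _, em_sel = grid_full.subgrid(*EMISSION_BAND_NM)
        fluo_em = SpectralCube(f[:, :, em_sel], basis.grid, "uv")
        c_out = pm.corrected_spectrum(fluo_em, rbar, rem, q=q)

        ratio = v_out.data[:, :, em_sel] / c_out.data
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-10)


class TestRgbComposite:
    def test_single_band_is_pure_green(self):
        grid = WavelengthGrid.default()
        data = np.zeros((2, 2, 33))
        data[:, :, grid.index_of(540.0)] = 7.0
        img = pm.rgb_composite(_cube(data))
        np.testing.assert_allclose(img[:, :, 1], 1.0)
        np.testing.assert_allclose(img[:, :, [0, 2]], 0.0)

    def test_equal_bands_are_gray(self):
        img = pm.rgb_composite(_cube(np.full((2, 2, 33), 5.0)))
        np.testing.assert_allclose(img, 1.0)

    def test_channels_match_named_bands(self, rng):
        data = rng.uniform(0, 9, (3, 4, 33))
        cube = _cube(data)
        img = pm.rgb_composite(cube)
        grid = cube.grid
        sel = [grid.index_of(nm) for nm in (630.0, 540.0, 470.0)]
        peak = data[:, :, sel].max()
        np.testing.assert_allclose(img, data[:, :, sel] / peak, atol=1e-12)

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError, match="540"):
            pm.rgb_composite(
                _cube(np.ones((2, 2, 13)), WavelengthGrid.emission())
            )


class TestCalibrateScale:
    def test_known_ratio(self):
        cmap = ScalarField(np.full((4, 4), 2.0))
        assert pm.calibrate_scale(cmap, ROIPatch(0, 0, 4, 4), 1.0) == pytest.approx(0.5)

    def test_identity(self):
        cmap = ScalarField(np.full((4, 4), 0.8))
        assert pm.calibrate_scale(cmap, ROIPatch(1, 1, 2, 2), 0.8) == pytest.approx(1.0)

    def test_noisy_map_direct_mean_oracle(self, rng):
        cmap = ScalarField(rng.uniform(0.5, 1.5, (6, 6)))
        roi = ROIPatch(1, 2, 3, 3)
        m = roi.extract(cmap.values).mean()
        assert pm.calibrate_scale(cmap, roi, 2.0) == pytest.approx(2.0 / m, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        cmap = ScalarField(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pm.calibrate_scale(cmap, ROIPatch(0, 0, 3, 3), 1.0)


def test_masks_only_shrink_along_pipeline(basis, simulate_uniform):
    """No stage marks a masked pixel valid again."""
    _, cubes = simulate_uniform(pm.PhantomRecipe(1.5, 1.0, 1.0), size=16, sigma=0.01, seed=3)
    rex = pm.normalize_reflectance(
        cubes["fluo_uv"].restrict(430, 450), cubes["ref_uv"].restrict(430, 450)
    )
    rbar = pm.mean_excitation_reflectance(rex)
    assert np.all(rex.mask | ~rbar.mask)  # rbar.mask subset of rex.mask
    rem = pm.normalize_reflectance(
        cubes["refl_white"].restrict(*EMISSION_BAND_NM),
        cubes["ref_white"].restrict(*EMISSION_BAND_NM),
    )
    kernel = pm.build_kernel(rbar, rem, basis, q=2.6)
    assert np.all((rbar.mask & rem.mask) | ~kernel.mask)
    fluo = SpectralCube(
        np.where(kernel.mask[:, :, None], np.ones((16, 16, 13)), 0.0),
        basis.grid,
        "uv",
    )
    c = pm.ls_concentration(fluo, kernel)
    assert np.all(kernel.mask | ~c.mask)
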