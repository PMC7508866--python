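"""Surface-topology mathematics: gradients, wavelengths, sectors, indices."""

import numpy as np
import pytest

from cartopo import (
    HeightMap,
    NyquistError,
    PairSpec,
    SurfaceSpec,
    UndefinedWavelengthError,
    ValidationError,
    cohesion_index,
    compute_gradient,
    deformation_ratio,
    extract_line_spacings,
    generate_pair,
    generate_surface,
    mean_wavelengths,
    sector_decompose,
    sector_wavelengths,
    surface_wavelengths,
)
from cartopo.topology import GradientField, SectorWavelengths, WavelengthPair


def _grid(n=64, step=1.0):
    x = np.arange(n) * step
    return np.meshgrid(x, x)


class TestGradient:
    def test_affine_surface_is_exact_everywhere(self):
        X, Y = _grid()
        gf = compute_gradient(HeightMap(2.0 * X + 3.0 * Y))
        assert np.allclose(gf.dz_dx, 2.0)
        assert np.allclose(gf.dz_dy, 3.0)

    def test_constant_surface_has_zero_gradient(self):
        gf = compute_gradient(HeightMap(np.full((32, 32), 5.0)))
        assert np.all(gf.dz_dx == 0) and np.all(gf.dz_dy == 0)

    def test_sinusoid_matches_closed_form_derivative(self):
        # central differences attenuate a sinusoid by sinc(kh): at λ=16 µm,
        # h=1 µm the max deviation from the analytic derivative is ~2.6% of peak
        lam = 16.0
        X, _ = _grid(n=256)
        gf = compute_gradient(HeightMap(np.sin(2 * np.pi * X / lam)))
        expected = (2 * np.pi / lam) * np.cos(2 * np.pi * X / lam)
        peak = 2 * np.pi / lam
        assert np.max(np.abs(gf.dz_dx[:, 1:-1] - expected[:, 1:-1])) < 0.03 * peak

    def test_nonfinite_heights_rejected(self):
        z = np.zeros((16, 16))
        z[3, 3] = np.nan
        with pytest.raises(ValidationError):
            HeightMap(z)


class TestLineSpacings:
    def test_pure_cosine_spacings_all_equal_period(self):
        lam = 16.0
        X, _ = _grid(n=128)
        gf = GradientField(dz_dx=np.cos(2 * np.pi * X / lam),
                           dz_dy=np.cos(2 * np.pi * X / lam).T, step=1.0)
        ls = extract_line_spacings(gf)
        for row in ls.spacings_x:
            assert np.all(row == lam)

    def test_monotone_ramp_has_no_maxima(self):
        ramp = np.tile(np.arange(32.0), (32, 1))
        gf = GradientField(dz_dx=ramp, dz_dy=ramp.T, step=1.0)
        ls = extract_line_spacings(gf)
        assert ls.n_maxima_x == 0
        assert all(s.size == 0 for s in ls.spacings_x)

    def test_two_peak_line_gives_single_spacing(self):
        line = np.zeros(64)
        line[10] = 1.0
        line[42] = 1.0
        gf = GradientField(dz_dx=np.tile(line, (4, 1)), dz_dy=np.tile(line, (4, 1)).T,
                           step=1.0)
        ls = extract_line_spacings(gf)
        assert all(s.tolist() == [32.0] for s in ls.spacings_x)

    def test_plateau_contributes_midpoint(self):
        line = np.zeros(32)
        line[10:13] = 1.0  # 3-sample plateau, midpoint at 11
        line[20] = 1.0
        gf = GradientField(dz_dx=line[None, :], dz_dy=line[:, None], step=1.0)
        ls = extract_line_spacings(gf)
        assert ls.spacings_x[0].tolist() == [9.0]


class TestMeanWavelengths:
    def test_equal_spacings_recover_wavelength(self):
        ls_x = [np.array([16.0, 16.0])] * 3
        from cartopo.topology import LineSpacings

        wl = mean_wavelengths(LineSpacings(ls_x, ls_x, 6, 6))
        assert wl.lambda_x == 16.0

    def test_mean_over_line_means(self):
        from cartopo.topology import LineSpacings

        ls = LineSpacings([np.array([10.0]), np.array([20.0])],
                          [np.array([10.0]), np.array([20.0])], 4, 4)
        wl = mean_wavelengths(ls)
        assert wl.lambda_x == 15.0 and wl.lambda_y == 15.0

    def test_no_spacings_raises_with_axis_name(self):
        from cartopo.topology import LineSpacings

        with pytest.raises(UndefinedWavelengthError, match="axis x"):
            mean_wavelengths(LineSpacings([np.array([])], [np.array([10.0])], 0, 2))

    def test_synthetic_surface_ground_truth(self):
        hm = generate_surface(SurfaceSpec(base_wavelength_x=16.0, base_wavelength_y=16.0,
                                          noise_sd=0.0, seed=1))
        wl = surface_wavelengths(hm)
        assert abs(wl.lambda_x - 16.0) <= 1.0
        assert abs(wl.lambda_y - 16.0) <= 1.0


class TestDeformationRatio:
    def test_identity(self):
        wl = WavelengthPair(12.0, 15.0)
        eps = deformation_ratio(wl, wl)
        assert eps.eps_x == 0.0 and eps.eps_y == 0.0

    def test_extension_mirrors_printed_group_mean(self):
        eps = deformation_ratio(WavelengthPair(10.0, 14.17), WavelengthPair(10.0, 10.0))
        assert eps.eps_y == pytest.approx(0.417)

    def test_negative_ratio_is_compression(self):
        eps = deformation_ratio(WavelengthPair(8.0, 10.0), WavelengthPair(10.0, 10.0))
        assert eps.eps_x == pytest.approx(-0.2)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            deformation_ratio(WavelengthPair(10.0, 10.0), WavelengthPair(0.0, 10.0))

    @pytest.mark.parametrize("k", [0.7, 0.85, 1.25, 1.5])
    def test_scaling_law(self, k):
        # stretching the noise-free surface by k forces eps = k - 1
        spec = SurfaceSpec(base_wavelength_x=14.0, base_wavelength_y=14.0,
                           noise_sd=0.0, seed=3)
        pr = generate_pair(PairSpec(healthy=spec, stretch_x=k, stretch_y=k))
        eps = deformation_ratio(surface_wavelengths(pr.oa), surface_wavelengths(pr.healthy))
        assert eps.eps_x == pytest.approx(k - 1, rel=0.05, abs=1e-12)
        assert eps.eps_y == pytest.approx(k - 1, rel=0.05, abs=1e-12)


class TestSectorDecomposition:
    def test_axis_aligned_energy_goes_to_first_sector(self):
        X, _ = _grid(n=64)
        s1, s2 = sector_decompose(HeightMap(np.sin(2 * np.pi * X / 16.0)))
        e1 = float(np.sum(s1.heights**2))
        e2 = float(np.sum(s2.heights**2))
        assert e2 < 1e-18 * e1

    def test_rotation_symmetric_surface_splits_energy_evenly(self, d4_symmetric_surface):
        for seed in range(5):
            hm = d4_symmetric_surface(seed)
            s1, s2 = sector_decompose(hm)
            e1, e2 = float(np.sum(s1.heights**2)), float(np.sum(s2.heights**2))
            assert abs(e1 - e2) < 0.01 * (e1 + e2)

    def test_pure_sinusoid_has_undefined_wavelength_named_by_sector(self):
        # an axis-aligned sinusoid has a defined x-wavelength only in the
        # 0-90° sector; the error carries the failing sector/axis
        X, Y = _grid(n=64)
        with pytest.raises(UndefinedWavelengthError, match="sector"):
            sector_wavelengths(HeightMap(np.sin(2 * np.pi * X / 16.0)))
        # the plaid's x-wavelength itself is measurable in its own sector
        s1, _ = sector_decompose(HeightMap(np.sin(2 * np.pi * X / 16.0)))
        from cartopo.topology import compute_gradient, extract_line_spacings

        ls = extract_line_spacings(compute_gradient(s1))
        line_means = [s.mean() for s in ls.spacings_x if s.size]
        assert np.mean(line_means) == pytest.approx(16.0, abs=1.0)

    def test_isotropic_surface_sector_wavelengths_agree(self, d4_symmetric_surface):
        ratios = []
        for seed in range(10):
            sw = sector_wavelengths(d4_symmetric_surface(seed, n=128))
            ratios.append(sw.lambda_x_s1 / sw.lambda_x_s2)
        assert abs(np.median(ratios) - 1.0) < 0.05


class TestCohesionIndex:
    def test_equal_sector_means_score_zero(self):
        ci = cohesion_index(SectorWavelengths(10.0, 10.0, 12.0, 12.0))
        assert ci.I_x == 0.0 and ci.I_y == 0.0

    def test_min_denominator_convention(self):
        ci = cohesion_index(SectorWavelengths(12.0, 10.0, 10.0, 12.0))
        assert ci.I_x == pytest.approx(0.2)
        assert ci.I_y == pytest.approx(0.2)
        assert ci.lambda_min_x == 10.0

    def test_invariant_under_sector_label_swap(self):
        a = cohesion_index(SectorWavelengths(12.0, 10.0, 15.0, 11.0))
        b = cohesion_index(SectorWavelengths(10.0, 12.0, 11.0, 15.0))
        assert a.I_x == b.I_x and a.I_y == b.I_y

    def test_imbalanced_member_less_cohesive_than_balanced_twin(self):
        # the closer to zero, the more cohesive: injecting spectral-sector
        # imbalance must raise the index relative to the untouched twin
        wins = 0
        for seed in range(10):
            base = PairSpec(healthy=SurfaceSpec(seed=seed), sector_imbalance=0.0)
            imb = PairSpec(healthy=SurfaceSpec(seed=seed), sector_imbalance=0.5)
            I0 = cohesion_index(sector_wavelengths(generate_pair(base).oa, "auto")).I_x
            I1 = cohesion_index(sector_wavelengths(generate_pair(imb).oa, "auto")).I_x
            wins += I1 > I0
        assert wins == 10


class TestValidation:
    def test_nyquist_guard(self):
        with pytest.raises(NyquistError):
            SurfaceSpec(base_wavelength_x=1.5, step=1.0)

    def test_stretch_below_nyquist_rejected(self):
        spec = SurfaceSpec(base_wavelength_x=8.0, base_wavelength_y=8.0, noise_sd=0.0)
        with pytest.raises(NyquistError):
            generate_pair(PairSpec(healthy=spec, stretch_x=0.2))
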