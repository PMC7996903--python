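"""Synthetic beamline: spectra, radial profiles, dose fields, organ doses."""

import numpy as np
import pytest
from scipy import stats

from bnctbeam import (
    BeamModelParams,
    CylinderPhantomSpec,
    DoseComponentField,
    DoseKernelParams,
    OrganSpec,
    band_integrals,
    default_organ_specs,
    deposit_dose_cylinder,
    generate_beam_spectrum,
    generate_organ_doses,
    radial_flux_profile,
    spectral_mode_ev,
)
from bnctbeam.synthetic import default_grid, make_energy_grid
from bnctbeam.spectrum import THERMAL_MAX_EV


class TestGenerateBeamSpectrum:
    def test_band_fractions_match_request_within_one_percent(self, grid):
        params = BeamModelParams(
            fraction_thermal=0.05, fraction_epithermal=0.80, fraction_fast=0.15
        )
        s = generate_beam_spectrum(grid, params, seed=3)
        phi_th, phi_epi, phi_fast, _ = band_integrals(s)
        total = s.total_flux
        assert phi_th / total == pytest.approx(0.05, rel=0.01)
        assert phi_epi / total == pytest.approx(0.80, rel=0.01)
        assert phi_fast / total == pytest.approx(0.15, rel=0.01)

    def test_band_fractions_hold_on_any_grid_with_50_bins(self, beam_params):
        for n_bins in (50, 77, 160):
            g = make_energy_grid(1e-3, 1e7, n_bins)
            s = generate_beam_spectrum(g, beam_params, seed=0)
            phi_th, phi_epi, phi_fast, _ = band_integrals(s)
            fr = np.array([phi_th, phi_epi, phi_fast]) / s.total_flux
            np.testing.assert_allclose(fr, beam_params.fractions, rtol=0.01)

    def test_spectral_mode_in_therapeutic_window(self, spectrum):
        # epithermal-dominated beam peaked at 1 keV -> mode in [1, 10] keV
        mode = spectral_mode_ev(spectrum)
        assert 1e3 * (1.0 - 1e-9) <= mode <= 1e4

    def test_pure_thermal_mixture_puts_all_flux_below_half_ev(self, grid):
        params = BeamModelParams(
            fraction_thermal=1.0, fraction_epithermal=0.0, fraction_fast=0.0
        )
        s = generate_beam_spectrum(grid, params, seed=0)
        above = s.flux_per_bin[s.grid.centers >= THERMAL_MAX_EV]
        assert np.all(above == 0.0)
        assert s.total_flux == pytest.approx(params.total_flux)

    def test_band_fractions_seed_invariant_even_with_noise(self, grid, beam_params):
        a = generate_beam_spectrum(grid, beam_params, seed=1, noise_sigma=0.3)
        b = generate_beam_spectrum(grid, beam_params, seed=2, noise_sigma=0.3)
        fa = np.array(band_integrals(a)[:3]) / a.total_flux
        fb = np.array(band_integrals(b)[:3]) / b.total_flux
        np.testing.assert_allclose(fa, fb, rtol=1e-9)

    def test_current_is_directionality_times_flux(self, spectrum, beam_params):
        np.testing.assert_allclose(
            spectrum.current_per_bin,
            beam_params.mean_directionality * spectrum.flux_per_bin,
            rtol=1e-12,
        )

    def test_fraction_normalisation_and_validation(self):
        p = BeamModelParams(fraction_thermal=9.0, fraction_epithermal=990.0, fraction_fast=1.0)
        assert sum(p.fractions) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            BeamModelParams(total_flux=0.0)
        with pytest.raises(ValueError):
            BeamModelParams(mean_directionality=1.5)


class TestRadialProfile:
    def test_on_axis_normalisation(self, beam_params):
        assert radial_flux_profile(beam_params, [0.0])[0] == pytest.approx(1.0)

    def test_in_beam_ripple_bound(self, beam_params):
        # flux variation within 20% inside the 6 cm port
        r = np.linspace(0.0, beam_params.port_radius_cm, 200)
        f = radial_flux_profile(beam_params, r)
        assert f.max() / f.min() <= 1.0 + beam_params.in_beam_ripple + 1e-12
        assert f[-1] / f[0] >= 0.8

    def test_strictly_decreasing_beyond_port(self, beam_params):
        r = np.linspace(beam_params.port_radius_cm, 40.0, 300)
        f = radial_flux_profile(beam_params, r)
        assert np.all(np.diff(f) < 0.0)
        assert radial_flux_profile(beam_params, [12.0])[0] < radial_flux_profile(
            beam_params, [6.0]
        )[0]

    def test_values_in_unit_interval_and_negative_radius_rejected(self, beam_params):
        f = radial_flux_profile(beam_params, np.linspace(0.0, 50.0, 100))
        assert np.all((f > 0.0) & (f <= 1.0))
        with pytest.raises(ValueError):
            radial_flux_profile(beam_params, [-1.0])


class TestDepositDoseCylinder:
    def test_zero_source_gives_all_zero_field(self, spectrum, phantom, kernels):
        fld = deposit_dose_cylinder(spectrum.scaled(0.0), phantom, kernels)
        for arr in fld.components().values():
            assert np.all(arr == 0.0)

    def test_field_scales_linearly_with_beam_intensity(self, spectrum, phantom, kernels):
        base = deposit_dose_cylinder(spectrum, phantom, kernels)
        double = deposit_dose_cylinder(spectrum.scaled(2.0), phantom, kernels)
        for name in DoseComponentField.COMPONENTS:
            np.testing.assert_allclose(
                getattr(double, name), 2.0 * getattr(base, name), rtol=1e-12
            )

    def test_all_components_nonnegative(self, spectrum, phantom, kernels):
        fld = deposit_dose_cylinder(spectrum, phantom, kernels)
        for arr in fld.components().values():
            assert np.all(arr >= 0.0)

    def test_thermal_buildup_argmax_matches_closed_form(self, spectrum, kernels):
        phantom = CylinderPhantomSpec(voxel_size_cm=0.25)
        fld = deposit_dose_cylinder(spectrum, phantom, kernels)
        z, profile = fld.on_axis_profile("thermal_n")
        z_num = z[int(np.argmax(profile))]
        z_closed = kernels.thermal_peak_depth_cm()
        assert abs(z_num - z_closed) <= phantom.voxel_size_cm

    def test_fast_component_monotone_decreasing_with_depth(self, spectrum, phantom, kernels):
        fld = deposit_dose_cylinder(spectrum, phantom, kernels)
        _, profile = fld.on_axis_profile("fast_n")
        assert np.all(np.diff(profile) < 0.0)

    def test_thermal_rises_then_falls(self, spectrum, phantom, kernels):
        fld = deposit_dose_cylinder(spectrum, phantom, kernels)
        _, profile = fld.on_axis_profile("thermal_n")
        k = int(np.argmax(profile))
        assert 0 < k < profile.size - 1
        assert np.all(np.diff(profile[: k + 1]) > 0.0)
        assert np.all(np.diff(profile[k:]) < 0.0)

    def test_too_coarse_grid_rejected(self, spectrum, kernels):
        phantom = CylinderPhantomSpec(voxel_size_cm=2.5)
        with pytest.raises(ValueError, match="coarse"):
            deposit_dose_cylinder(spectrum, phantom, kernels)

    def test_container_round_trip(self, tmp_path, spectrum, phantom, kernels):
        fld = deposit_dose_cylinder(spectrum, phantom, kernels)
        fld.save(tmp_path / "field")
        back = DoseComponentField.load(tmp_path / "field")
        assert back.phantom == phantom
        for name in DoseComponentField.COMPONENTS:
            np.testing.assert_array_equal(getattr(back, name), getattr(fld, name))

    def test_tumor_sphere_must_fit_inside_cylinder(self):
        with pytest.raises(ValueError):
            CylinderPhantomSpec(tumor_center_depth_cm=1.0)  # protrudes through face
        with pytest.raises(ValueError):
            CylinderPhantomSpec(tumor_radius_cm=11.0)

    def test_kernel_params_require_buildup_ordering(self):
        with pytest.raises(ValueError):
            DoseKernelParams(lambda_rise_cm=6.0, lambda_fall_cm=0.8)


class TestGenerateOrganDoses:
    def test_closer_organ_receives_more_in_every_component(self, spectrum, kernels):
        organs = [OrganSpec("near", 0.0), OrganSpec("far", 50.0)]
        near, far = generate_organ_doses(spectrum, organs, kernels, seed=0)
        for attr in ("boron_per_ppm", "thermal_n", "fast_n", "gamma"):
            assert getattr(near, attr) > getattr(far, attr)

    def test_deterministic_without_noise(self, spectrum, kernels):
        organs = default_organ_specs()
        a = generate_organ_doses(spectrum, organs, kernels, seed=11)
        b = generate_organ_doses(spectrum, organs, kernels, seed=99)
        assert a == b  # noise off: seed must not matter

    def test_distance_dose_rank_correlation_is_minus_one(self, spectrum, kernels):
        organs = default_organ_specs()
        assert len(organs) == 19
        raw = generate_organ_doses(spectrum, organs, kernels, seed=0)
        distances = [r.distance_cm for r in raw]
        totals = [r.boron_per_ppm * 15.0 + r.thermal_n + r.fast_n + r.gamma for r in raw]
        rho, _ = stats.spearmanr(distances, totals)
        assert rho == pytest.approx(-1.0)

    def test_neutron_energy_softens_with_distance(self, spectrum, kernels):
        raw = generate_organ_doses(spectrum, default_organ_specs(), kernels, seed=0)
        energies = [r.mean_neutron_energy_ev for r in sorted(raw, key=lambda r: r.distance_cm)]
        assert np.all(np.diff(energies) < 0.0)
        assert energies[-1] > 0.02  # never below the thermal floor

    def test_noise_is_reproducible_from_seed(self, spectrum, kernels):
        organs = default_organ_specs()
        a = generate_organ_doses(spectrum, organs, kernels, seed=5, noise_sigma=0.2)
        b = generate_organ_doses(spectrum, organs, kernels, seed=5, noise_sigma=0.2)
        c = generate_organ_doses(spectrum, organs, kernels, seed=6, noise_sigma=0.2)
        assert a == b
        assert a != c

    def test_empty_organ_list_rejected(self, spectrum, kernels):
        with pytest.raises(ValueError):
            generate_organ_doses(spectrum, [], kernels, seed=0)
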