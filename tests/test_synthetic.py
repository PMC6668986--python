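"""Generators: sphere projection, DualEELS cubes, micrographs, curves."""

import numpy as np
import pytest

from encapquant.constants import BARN_TO_NM2, FE_CROSS_SECTION_BARNS
from encapquant.curves import KineticsParams, simulate_kinetics
from encapquant.synthetic import (
    BeamSpec,
    PhantomSpec,
    make_eels_cube,
    make_melt_curve,
    make_micrograph,
    make_progress_curve,
    project_sphere,
)

SIGMA_NM2 = FE_CROSS_SECTION_BARNS * BARN_TO_NM2


class TestProjectSphere:
    def test_central_chord_equals_diameter(self):
        # projection through the center is rho * d = 3.4 * 20 = 68
        spec = PhantomSpec(diameter_nm=20.0, volumetric_density=3.4, pixel_size_nm=0.4)
        m = project_sphere(spec, (61, 61))
        assert m[30, 30] == pytest.approx(68.0, rel=1e-3)

    def test_zero_outside_radius(self):
        spec = PhantomSpec(diameter_nm=10.0, pixel_size_nm=1.0)
        m = project_sphere(spec, (21, 21))
        yy, xx = np.mgrid[0:21, 0:21]
        outside = (xx - 10.0) ** 2 + (yy - 10.0) ** 2 > 6.0**2
        assert np.all(m[outside] == 0.0)

    def test_integral_matches_closed_form(self):
        # summed map x pixel area vs (pi/6) d^3 rho at pixel <= d/50
        spec = PhantomSpec(diameter_nm=23.6, volumetric_density=3.385, pixel_size_nm=0.4)
        m = project_sphere(spec, (75, 75))
        total = m.sum() * 0.4**2
        closed = (np.pi / 6.0) * 23.6**3 * 3.385
        assert total == pytest.approx(closed, rel=0.01)

    def test_grid_too_small_names_required_size(self):
        spec = PhantomSpec(diameter_nm=30.0, pixel_size_nm=1.0)
        with pytest.raises(ValueError, match="at least"):
            project_sphere(spec, (21, 21))


class TestEelsCube:
    def test_injected_edge_counts(self):
        # N = 68 atoms/nm^2 at I0 = 1e8 -> 1e8 * 68 * 2.6649e-7 = 1812.1 counts
        beam = BeamSpec(noise="none")
        cube = make_eels_cube(np.full((1, 1), 68.0), beam, 1.0, seed=0)
        e = cube.coreloss_axis_ev
        sel = (e >= beam.edge_onset_ev) & (e <= 780.0)
        bg = (
            beam.background_amplitude
            * (beam.i0_per_pixel / 1e8)
            * (e / beam.coreloss_offset_ev) ** (-beam.background_exponent)
        )
        edge_counts = np.sum(cube.coreloss[0, 0, sel] - bg[sel])
        assert edge_counts == pytest.approx(1e8 * 68.0 * SIGMA_NM2, rel=1e-9)
        assert edge_counts == pytest.approx(1812.1, abs=0.1)

    def test_zero_density_gives_pure_background(self):
        beam = BeamSpec(noise="none")
        cube = make_eels_cube(np.zeros((2, 2)), beam, 1.0, seed=0)
        e = cube.coreloss_axis_ev
        bg = (
            beam.background_amplitude
            * (beam.i0_per_pixel / 1e8)
            * (e / beam.coreloss_offset_ev) ** (-beam.background_exponent)
        )
        assert np.allclose(cube.coreloss, bg[None, None, :])

    def test_zlp_integral_is_i0(self):
        cube = make_eels_cube(np.zeros((1, 1)), BeamSpec(noise="none"), 1.0, seed=0)
        assert cube.lowloss[0, 0].sum() == pytest.approx(1e8, rel=1e-12)

    def test_seeded_determinism(self):
        m = np.full((3, 3), 40.0)
        c1 = make_eels_cube(m, BeamSpec(), 1.0, seed=7)
        c2 = make_eels_cube(m, BeamSpec(), 1.0, seed=7)
        assert np.array_equal(c1.coreloss, c2.coreloss)
        assert np.array_equal(c1.lowloss, c2.lowloss)
        c3 = make_eels_cube(m, BeamSpec(), 1.0, seed=8)
        assert not np.array_equal(c1.coreloss, c3.coreloss)

    def test_range_not_covering_edge_errors(self):
        beam = BeamSpec(n_channels=100)  # 600-625 eV only
        with pytest.raises(ValueError, match="does not cover"):
            make_eels_cube(np.zeros((1, 1)), beam, 1.0, seed=0)

    def test_negative_map_rejected(self):
        with pytest.raises(ValueError):
            make_eels_cube(np.full((1, 1), -1.0), BeamSpec(), 1.0, seed=0)


class TestMicrograph:
    def test_disk_area(self):
        img, truth = make_micrograph(
            [((50.0, 50.0), 23.0, 0.5)], (101, 101), 1.0, 30000.0, 0.0, seed=0
        )
        dark = img < 30000.0
        assert dark.sum() == pytest.approx(np.pi * 11.5**2, rel=0.02)
        assert truth.diameter_nm.iloc[0] == 23.0

    def test_noise_free_has_two_gray_levels(self):
        img, _ = make_micrograph(
            [((30.0, 30.0), 20.0, 0.5)], (64, 64), 1.0, 30000.0, 0.0, seed=0
        )
        assert set(np.unique(img)) == {15000.0, 30000.0}

    def test_seeded_repeat_identical(self):
        args = ([((30.0, 30.0), 20.0, 0.5)], (64, 64), 1.0, 30000.0, 500.0)
        img1, _ = make_micrograph(*args, seed=3)
        img2, _ = make_micrograph(*args, seed=3)
        assert np.array_equal(img1, img2)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            make_micrograph([((30.0, 30.0), 0.0, 0.5)], (64, 64))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            make_micrograph([((2.0, 2.0), 20.0, 0.5)], (64, 64))


class TestProgressCurves:
    def test_no_seed_no_enzyme_stays_flat(self):
        # autocatalysis alone cannot start from zero mineral
        params = KineticsParams(vmax=0.0, k_auto=1e-3, s0=100.0, seed_fraction=0.0)
        noisy, clean = make_progress_curve("autocatalytic", params, 600.0, 50)
        assert np.allclose(clean.ordinate, 0.0)

    def test_hyperbolic_plateau_at_substrate_exhaustion(self):
        params = KineticsParams(vmax=2.0, km=20.0, k_auto=0.0, s0=100.0)
        _, clean = make_progress_curve("hyperbolic", params, 4000.0, 200)
        # plateau = extinction_scale * s0
        assert clean.ordinate[-1] == pytest.approx(1e-3 * 100.0, rel=1e-3)

    def test_solver_matches_fine_step_oracle(self):
        # independent fixed-step RK4 at 10x finer resolution
        params = KineticsParams(vmax=1.0, km=50.0, k_auto=0.0, s0=100.0)
        t = np.linspace(0.0, 300.0, 61)
        _, clean = make_progress_curve("hyperbolic", params, 300.0, 61)

        def rhs(p):
            s = params.s0 - p
            return params.vmax * s / (params.km + s)

        dt = (t[1] - t[0]) / 10.0
        p, oracle = 0.0, [0.0]
        for k in range(len(t) - 1):
            for _ in range(10):
                k1 = rhs(p)
                k2 = rhs(p + dt / 2 * k1)
                k3 = rhs(p + dt / 2 * k2)
                k4 = rhs(p + dt * k3)
                p += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            oracle.append(p)
        oracle = 1e-3 * np.asarray(oracle)
        assert np.allclose(clean.ordinate[1:], oracle[1:], rtol=1e-3)

    def test_clean_curve_monotone(self):
        for model in ("hyperbolic", "autocatalytic"):
            _, clean = make_progress_curve(model)
            assert np.all(np.diff(clean.ordinate) >= -1e-12)

    def test_seeded_noise_reproducible(self):
        n1, _ = make_progress_curve("hyperbolic", noise_sd=1e-3, seed=5)
        n2, _ = make_progress_curve("hyperbolic", noise_sd=1e-3, seed=5)
        assert np.array_equal(n1.ordinate, n2.ordinate)


class TestMeltCurves:
    def test_derivative_peak_at_construction_tm(self):
        curve = make_melt_curve(86.6)
        d = np.gradient(curve.ordinate, curve.abscissa)
        assert curve.abscissa[np.argmax(d)] == pytest.approx(86.6, abs=0.3)

    def test_tm_outside_ramp_rejected(self):
        with pytest.raises(ValueError):
            make_melt_curve(30.0)
        with pytest.raises(ValueError):
            make_melt_curve(95.0)

    def test_zero_steepness_rejected(self):
        with pytest.raises(ValueError):
            make_melt_curve(80.0, steepness_c=0.0)

    def test_seeded_repeat_identical(self):
        c1 = make_melt_curve(88.9, noise_sd=0.02, seed=9)
        c2 = make_melt_curve(88.9, noise_sd=0.02, seed=9)
        assert np.array_equal(c1.ordinate, c2.ordinate)


def test_kinetics_mass_conservation():
    """S + P = S0 along the whole trajectory, to solver tolerance."""
    params = KineticsParams(vmax=0.5, km=30.0, k_auto=2e-3, s0=80.0)
    t = np.linspace(0.0, 2000.0, 100)
    curve = simulate_kinetics(params, t)
    p = curve.ordinate / params.extinction_scale
    s = params.s0 - p
    assert np.all(s >= -1e-6)
    assert np.all(p <= params.s0 + 1e-6)
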