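"""Step-index fiber mode solver and physical fingerprint model."""

import numpy as np
import pytest

from fiberdemix.fiber import (
    SCALED_FIBER,
    FiberSpec,
    SourcePosition,
    azimuthal_symmetry_score,
    fiber_geometry_summary,
    fingerprint_physical,
    ring_radius_of,
    solve_lp_modes,
)


class TestLPModes:
    def test_single_mode_below_lp11_cutoff(self):
        # V = 2.0 < 2.405 (first root of J0): only LP01 guided
        fiber = FiberSpec(numerical_aperture=0.1, core_radius=1.648)
        assert 1.99 < fiber.v_number() < 2.01
        modes = solve_lp_modes(fiber)
        assert len(modes) == 1
        assert (modes[0].l, modes[0].m) == (0, 1)

    def test_v_number_formula(self):
        fiber = FiberSpec(numerical_aperture=0.22, core_radius=10.0, center_wavelength=0.518)
        assert fiber.v_number() == pytest.approx(2 * np.pi * 10 * 0.22 / 0.518)
        assert fiber.v_number() == pytest.approx(26.7, abs=0.1)

    def test_degenerate_wavelength_rejected(self):
        with pytest.raises(ValueError):
            solve_lp_modes(SCALED_FIBER, wavelength=0.0)

    def test_ceiling_guards_desk_scale(self):
        big = FiberSpec(numerical_aperture=0.39, core_radius=100.0)
        with pytest.raises(ValueError, match="scale"):
            solve_lp_modes(big)

    def test_mode_count_scales_like_v_squared(self):
        # guided LP count (with l>0 orientation pairs) approaches V^2/4
        V = SCALED_FIBER.v_number()
        modes = solve_lp_modes(SCALED_FIBER)
        n_with_orientations = sum(1 if m.l == 0 else 2 for m in modes)
        assert 0.6 * V**2 / 4 < n_with_orientations < 1.4 * V**2 / 4

    def test_propagation_parameters_guided(self):
        for m in solve_lp_modes(SCALED_FIBER):
            assert 0 < m.b < 1
            assert m.u**2 + m.w**2 == pytest.approx(SCALED_FIBER.v_number() ** 2, rel=1e-9)


class TestPhysicalFingerprint:
    def test_on_axis_pattern_azimuthally_symmetric(self):
        fp = fingerprint_physical(SCALED_FIBER, SourcePosition(d=0))
        # on-axis sources excite only l=0 modes; relative azimuthal variance
        # of subpixel circle samples stays tiny
        score = azimuthal_symmetry_score(fp.image)
        relvar = 1.0 / score - 1.0
        assert relvar < 0.05

    def test_ring_radius_grows_with_offset(self):
        fp_near = fingerprint_physical(SCALED_FIBER, SourcePosition(d=20))
        fp_far = fingerprint_physical(SCALED_FIBER, SourcePosition(d=60))
        assert fp_near.ring_radius < fp_far.ring_radius

    def test_ring_radius_monotone_within_core(self):
        rhos = [
            fingerprint_physical(SCALED_FIBER, SourcePosition(d=d)).ring_radius
            for d in range(0, 91, 15)
        ]
        assert all(a <= b for a, b in zip(rhos, rhos[1:]))

    def test_azimuth_rotation_rotates_pattern(self):
        # ideal fiber is cylindrically symmetric: quarter-turn of the source
        # azimuth is an exact quarter-turn of the pattern
        a = fingerprint_physical(SCALED_FIBER, SourcePosition(d=40, azimuth=0.0))
        b = fingerprint_physical(SCALED_FIBER, SourcePosition(d=40, azimuth=np.pi / 2))
        back = np.rot90(b.image, 1)
        corr = np.corrcoef(a.image.ravel(), back.ravel())[0, 1]
        assert corr > 0.99

    def test_far_outside_fov_near_zero_and_flagged(self):
        fp_in = fingerprint_physical(SCALED_FIBER, SourcePosition(d=30))
        fp_out = fingerprint_physical(SCALED_FIBER, SourcePosition(d=130))
        assert fp_out.out_of_fov
        assert fp_out.image.max() < 1e-6 * fp_in.image.max()

    def test_nonnegative_everywhere(self):
        fp = fingerprint_physical(SCALED_FIBER, SourcePosition(d=55, azimuth=1.0))
        assert (fp.image >= 0).all()

    def test_phase_screen_breaks_on_axis_symmetry(self):
        # a random phase screen at the distal facet models a scattering layer
        from scipy import ndimage

        from fiberdemix._rng import substream

        screen = ndimage.gaussian_filter(substream(3, "layer").standard_normal((64, 64)), 3.0)
        screen *= 2.0 / screen.std()
        clean = fingerprint_physical(SCALED_FIBER, SourcePosition(d=0), n_wavelengths=3)
        scattered = fingerprint_physical(
            SCALED_FIBER, SourcePosition(d=0), n_wavelengths=3, phase_screen=screen
        )
        assert azimuthal_symmetry_score(scattered.image) < azimuthal_symmetry_score(clean.image)


class TestGeometrySummary:
    def test_distal_power_arithmetic(self):
        fiber = FiberSpec(numerical_aperture=0.39, core_radius=100.0)
        out = fiber_geometry_summary(fiber, power_at_distal=9.5, bead_diameter=10.0)
        assert out["intensity_mw_per_mm2"] == pytest.approx(0.30, abs=0.005)
        assert out["power_per_bead_mw"] == pytest.approx(2.4e-5, rel=0.02)

    def test_zero_power(self):
        out = fiber_geometry_summary(SCALED_FIBER, power_at_distal=0.0)
        assert out["intensity_mw_per_mm2"] == 0.0
        assert out["power_per_bead_mw"] == 0.0

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            fiber_geometry_summary(SCALED_FIBER, power_at_distal=-1.0)
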