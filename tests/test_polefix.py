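import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nlinvpp as nv
from nlinvpp import polefix
from nlinvpp.forward import SobolevWeights, apply_weighting, apply_weighting_pinv


def azimuthal_field(grid, r0, sign):
    return polefix.phase_vortex(grid, r0, sign)


class TestPhaseVortex:
    def test_axis_values(self):
        g = nv.Grid2D(64, 64)
        # place the vortex exactly on a pixel center so neighbours lie on axes
        x0, y0 = g.pixel_to_pos(32, 32)
        v = polefix.phase_vortex(g, (x0, y0), +1)
        assert v.values[40, 32] == pytest.approx(1.0)  # +x direction
        assert v.values[32, 40] == pytest.approx(1j)  # +y direction
        assert v.values[32, 32] == 1.0  # value at the pole pixel

    def test_unit_magnitude_everywhere(self):
        g = nv.Grid2D(32, 32)
        v = polefix.phase_vortex(g, (0.123, -0.077), -1)
        assert np.max(np.abs(np.abs(v.values) - 1)) < 1e-12

    @pytest.mark.parametrize("sign", [+1, -1])
    def test_winding_equals_sign(self, sign):
        g = nv.Grid2D(64, 64)
        v = polefix.phase_vortex(g, (0.05, -0.1), sign)
        px = g.pos_to_pixel(0.05, -0.1)
        crv = polefix.circle_curve(px, 8, g)
        assert polefix.winding_number(nv.ComplexImage(g, v.values), crv) == sign


class TestCircleCurve:
    def test_loop_encircles_center(self):
        g = nv.Grid2D(64, 64)
        crv = polefix.circle_curve((32, 32), 4, g)
        assert not crv.clipped
        assert len(np.unique(crv.points, axis=0)) >= 8
        # all points within the rounding bound of the center
        d = np.max(np.abs(crv.points - np.array([32, 32])))
        assert d <= int(np.ceil(4 / 2)) + 1

    def test_boundary_clipping_flagged(self):
        g = nv.Grid2D(64, 64)
        crv = polefix.circle_curve((1, 32), 8, g)
        assert crv.clipped
        field = azimuthal_field(g, g.pixel_to_pos(1, 32), +1)
        assert polefix.winding_number(nv.ComplexImage(g, field.values), crv) == 0

    def test_one_pixel_loop_is_four_neighbours(self):
        g = nv.Grid2D(8, 8)
        crv = polefix.circle_curve((4, 4), 1, g)
        assert {tuple(p) for p in crv.points} == {(5, 4), (4, 5), (3, 4), (4, 3)}


class TestWindingNumber:
    def test_enclosing_loop_counts_one(self):
        g = nv.Grid2D(64, 64)
        v = azimuthal_field(g, (0.0, 0.0), +1)
        crv = polefix.circle_curve(g.pos_to_pixel(0.0, 0.0), 8, g)
        assert polefix.winding_number(nv.ComplexImage(g, v.values), crv) == 1

    def test_non_enclosing_loop_counts_zero(self):
        g = nv.Grid2D(64, 64)
        v = azimuthal_field(g, (0.0, 0.0), +1)
        crv = polefix.circle_curve(g.pos_to_pixel(0.25, 0.25), 8, g)
        assert polefix.winding_number(nv.ComplexImage(g, v.values), crv) == 0

    def test_zero_amplitude_point_gives_zero(self):
        g = nv.Grid2D(64, 64)
        v = azimuthal_field(g, (0.0, 0.0), +1).values.copy()
        crv = polefix.circle_curve((32, 32), 8, g)
        v[tuple(crv.points[3])] = 0.0
        assert polefix.winding_number(nv.ComplexImage(g, v), crv) == 0

    def test_constant_field_and_conjugation_symmetry(self):
        g = nv.Grid2D(64, 64)
        crv = polefix.circle_curve((32, 32), 8, g)
        const = nv.ComplexImage(g, np.full(g.shape, 2.0 - 1j))
        assert polefix.winding_number(const, crv) == 0
        v = azimuthal_field(g, (0.0, 0.0), +1).values
        plus = polefix.winding_number(nv.ComplexImage(g, v), crv)
        minus = polefix.winding_number(nv.ComplexImage(g, np.conj(v)), crv)
        assert minus == -plus

    def test_open_curve_rejected(self):
        g = nv.Grid2D(8, 8)
        field = nv.ComplexImage(g, np.ones(g.shape, complex))
        with pytest.raises(ValueError):
            polefix.winding_number(field, np.array([[1, 1], [1, 2]]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        cx=st.integers(16, 47),
        cy=st.integers(16, 47),
        diameter=st.sampled_from([4, 8, 16]),
        sign=st.sampled_from([-1, 1]),
    )
    def test_matches_analytic_winding_on_sampled_vortices(self, cx, cy, diameter, sign):
        g = nv.Grid2D(64, 64)
        r0 = g.pixel_to_pos(cx, cy)
        v = polefix.phase_vortex(g, (float(r0[0]), float(r0[1])), sign)
        crv = polefix.circle_curve((cx, cy), diameter, g)
        assert polefix.winding_number(nv.ComplexImage(g, v.values), crv) == sign


class TestCoilWindingMaps:
    def test_shared_conjugate_pole_detected_with_unit_average(
        self, grid64, phantom64, ring_coils64
    ):
        r0 = (0.05, 0.1)
        _, coils_p = nv.plant_artificial_pole(phantom64, ring_coils64, r0, +1)
        pm = polefix.coil_winding_maps(coils_p, polefix.DetectConfig())
        px = grid64.pos_to_pixel(*r0)
        assert abs(pm.s_avg[px]) == pytest.approx(1.0)

    def test_single_coil_pole_suppressed_below_threshold(self, grid64, ring_coils64):
        vals = ring_coils64.values.copy()
        vals[3] *= polefix.phase_vortex(grid64, (0.1, -0.05), +1).values
        coils = nv.CoilSet(grid64, vals, "natural")
        pm = polefix.coil_winding_maps(coils, polefix.DetectConfig())
        px, py = grid64.pos_to_pixel(0.1, -0.05)
        neighborhood = np.abs(pm.s_avg[px - 3 : px + 4, py - 3 : py + 4])
        assert neighborhood.max() <= 1 / 8

    def test_zero_coils_give_zero_average(self):
        g = nv.Grid2D(16, 16)
        coils = nv.CoilSet(g, np.zeros((2, 16, 16), complex), "natural")
        pm = polefix.coil_winding_maps(coils, polefix.DetectConfig())
        assert np.all(pm.s_avg == 0)

    def test_rejects_preconditioned_input(self, grid64):
        ct = nv.CoilSet(grid64, np.ones((2, 64, 64), complex), "preconditioned")
        with pytest.raises(ValueError):
            polefix.coil_winding_maps(ct, polefix.DetectConfig())


class TestDetectPoles:
    def test_planted_pole_localized_with_sign(self, grid64, phantom64, ring_coils64):
        cfg = polefix.DetectConfig()
        r0, sign = (-0.08, 0.14), -1
        _, coils_p = nv.plant_artificial_pole(phantom64, ring_coils64, r0, sign)
        poles = polefix.detect_poles(polefix.coil_winding_maps(coils_p, cfg), cfg)
        assert poles.count == 1
        assert np.hypot(*(poles.locations[0] - r0)) <= cfg.circle_diameter / 2
        assert poles.signs[0] == -sign  # coil maps carry the conjugate winding

    def test_empty_map_gives_no_poles(self, grid64):
        pm = polefix.PoleMap(
            grid64,
            np.zeros((2, 64, 64), int),
            np.ones((2, 64, 64)),
            np.zeros((64, 64)),
        )
        assert polefix.detect_poles(pm, polefix.DetectConfig()).count == 0

    def test_nearby_components_merged_by_closing(self, grid64):
        s = np.zeros((64, 64))
        s[30:32, 30:32] = 1.0
        s[34:36, 30:32] = 1.0  # 2 px gap < closing diameter (3.2 px)
        pm = polefix.PoleMap(grid64, s[None].astype(int).repeat(2, 0), np.ones((2, 64, 64)), s)
        poles = polefix.detect_poles(pm, polefix.DetectConfig())
        assert poles.count == 1

    def test_external_mode_skips_closing(self, grid64):
        s = np.zeros((64, 64))
        s[30, 30] = 1.0
        s[34, 30] = 1.0
        pm = polefix.PoleMap(grid64, s[None].astype(int).repeat(2, 0), np.ones((2, 64, 64)), s)
        poles = polefix.detect_poles(pm, polefix.DetectConfig(external_mode=True))
        assert poles.count == 2


class TestGlobalPhase:
    def test_constant_theta_maps_to_identity(self, grid64, phantom64):
        theta = polefix.CorrectionField(grid64, np.exp(0.9j) * np.ones(grid64.shape))
        out = polefix.global_phase(theta, phantom64)
        assert np.max(np.abs(out.values - 1.0)) < 1e-12

    def test_inner_product_real_positive(self, grid64, phantom64):
        theta = polefix.phase_vortex(grid64, (0.07, 0.03), +1)
        out = polefix.global_phase(theta, phantom64)
        z = np.sum(np.abs(phantom64.values) ** 2 * np.conj(out.values))
        assert abs(z.imag) / abs(z) < 1e-10
        assert z.real > 0

    def test_idempotent(self, grid64, phantom64):
        theta = polefix.phase_vortex(grid64, (0.07, 0.03), +1)
        once = polefix.global_phase(theta, phantom64)
        twice = polefix.global_phase(once, phantom64)
        assert np.max(np.abs(once.values - twice.values)) < 1e-12

    def test_zero_inner_product_warns_and_passes_through(self, grid64):
        zero = nv.ComplexImage(grid64, np.zeros(grid64.shape, complex))
        theta = polefix.phase_vortex(grid64, (0.0, 0.0), +1)
        with pytest.warns(UserWarning):
            out = polefix.global_phase(theta, zero)
        assert np.array_equal(out.values, theta.values)


class TestBuildAndApplyCorrection:
    def test_single_pole_winding_and_unit_magnitude(self, grid64, phantom64):
        poles = polefix.PoleSet(np.array([[0.1, -0.1]]), np.array([-1]))
        theta = polefix.build_correction(poles, grid64, phantom64)
        assert np.max(np.abs(np.abs(theta.values) - 1)) < 1e-12
        crv = polefix.circle_curve(grid64.pos_to_pixel(0.1, -0.1), 8, grid64)
        assert polefix.winding_number(nv.ComplexImage(grid64, theta.values), crv) == -1

    def test_opposite_poles_cancel_on_enclosing_loop(self, grid64, phantom64):
        poles = polefix.PoleSet(np.array([[0.05, 0.0], [-0.05, 0.0]]), np.array([1, -1]))
        theta = polefix.build_correction(poles, grid64, phantom64)
        crv = polefix.circle_curve((32, 32), 24, grid64)
        assert polefix.winding_number(nv.ComplexImage(grid64, theta.values), crv) == 0

    def test_no_poles_is_identity_field(self, grid64, phantom64):
        empty = polefix.PoleSet(np.empty((0, 2)), np.empty(0, int))
        theta = polefix.build_correction(empty, grid64, phantom64)
        assert np.array_equal(theta.values, np.ones(grid64.shape, complex))

    def test_identity_theta_bounded_by_pinv_roundtrip(self, grid64, phantom64, ring_coils64):
        w = SobolevWeights(grid64)
        ct = apply_weighting_pinv(ring_coils64, w)
        theta = polefix.CorrectionField(grid64, np.ones(grid64.shape, complex))
        rho2, ct2 = polefix.apply_correction(phantom64, ct, theta, w)
        assert np.array_equal(rho2.values, phantom64.values)
        # with theta = 1 the coil update is exactly the W+ W composition
        expected = apply_weighting_pinv(apply_weighting(ct, w), w)
        assert np.max(np.abs(ct2.values - expected.values)) < 1e-10
        c_before = apply_weighting(ct, w).values
        c_after = apply_weighting(ct2, w).values
        rel = np.linalg.norm(c_after - c_before) / np.linalg.norm(c_before)
        assert rel < 0.05  # bounded round-trip error on smooth coils

    def test_correction_removes_planted_pole(self, grid64, phantom64, ring_coils64):
        cfg = polefix.DetectConfig()
        w = SobolevWeights(grid64)
        rho_p, coils_p = nv.plant_artificial_pole(phantom64, ring_coils64, (0.08, -0.06), +1)
        ct = apply_weighting_pinv(coils_p, w)
        c_round = apply_weighting(ct, w)
        poles = polefix.detect_poles(polefix.coil_winding_maps(c_round, cfg), cfg)
        assert poles.count == 1
        theta = polefix.build_correction(poles, grid64, rho_p)
        rho_c, ct_c = polefix.apply_correction(rho_p, ct, theta, w)
        c_c = apply_weighting(ct_c, w)
        assert polefix.detect_poles(polefix.coil_winding_maps(c_c, cfg), cfg).count == 0
        # the image-side vortex is cancelled as well
        px = grid64.pos_to_pixel(0.08, -0.06)
        crv = polefix.circle_curve(px, 4, grid64)
        assert polefix.winding_number(rho_c, crv) == 0

    def test_same_sign_double_pole_resolved_by_repetition(self, grid64, phantom64, ring_coils64):
        """Two same-sign poles merge into one detection; repeating the
        detect/correct round removes both within two rounds."""
        cfg = polefix.DetectConfig()
        w = SobolevWeights(grid64)
        rho_p, coils_p = nv.plant_artificial_pole(phantom64, ring_coils64, (0.06, 0.0), +1)
        rho_p, coils_p = nv.plant_artificial_pole(rho_p, coils_p, (0.09, 0.0), +1)
        ct = apply_weighting_pinv(coils_p, w)
        counts = []
        for _ in range(3):
            c_nat = apply_weighting(ct, w)
            poles = polefix.detect_poles(polefix.coil_winding_maps(c_nat, cfg), cfg)
            counts.append(poles.count)
            if poles.count == 0:
                break
            theta = polefix.build_correction(poles, grid64, rho_p)
            rho_p, ct = polefix.apply_correction(rho_p, ct, theta, w)
        assert counts[0] >= 1
        assert counts[-1] == 0
        assert len(counts) <= 3


class TestExternalMode:
    def test_common_pole_removed_and_products_exact(self, grid64, phantom64, ring_coils64):
        comb, coils_p = nv.plant_artificial_pole(phantom64, ring_coils64, (0.1, -0.04), +1)
        c2, comb2, found = polefix.correct_external_coils(coils_p, comb)
        assert found.count == 1
        cfg = polefix.DetectConfig(external_mode=True)
        assert polefix.detect_poles(polefix.coil_winding_maps(c2, cfg), cfg).count == 0
        before = coils_p.values * comb.values[None]
        after = c2.values * comb2.values[None]
        assert np.max(np.abs(before - after)) < 1e-12

    def test_pole_free_stack_is_identity(self, phantom64, ring_coils64):
        c2, comb2, found = polefix.correct_external_coils(ring_coils64, phantom64)
        assert found.count == 0
        assert c2 is ring_coils64 and comb2 is phantom64

    def test_requires_external_mode_config(self, ring_coils64):
        with pytest.raises(ValueError, match="external"):
            polefix.correct_external_coils(ring_coils64, None, polefix.DetectConfig())
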