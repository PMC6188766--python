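"""Kernel depth curves, lateral profiles, ray-march oracle and calibration."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnctshift.beam import (BeamConfig, KernelParams, advantage_depth,
                            air_gap_attenuation, calibrate_engine,
                            compute_dose_components, depth_curve,
                            off_axis_profile, thermal_peak_depth)
from bnctshift.phantom import build_cylinder_phantom


class TestDepthCurves:
    def test_thermal_vanishes_at_surface(self):
        p = KernelParams()
        assert depth_curve("thermal", 0.0, p) == pytest.approx(0.0, abs=1e-15)
        assert depth_curve("boron", 0.0, p) == pytest.approx(0.0, abs=1e-15)

    def test_fast_channel_monotone_decreasing(self):
        p = KernelParams()
        d = np.linspace(0, 15, 200)
        vals = depth_curve("fast", d, p)
        assert np.all(np.diff(vals) < 0)

    def test_thermal_argmax_matches_closed_form(self):
        p = KernelParams(thermal_lambda1=4.7, thermal_lambda2=1.1)
        grid = np.arange(0.0, 15.0, 0.01)
        vals = depth_curve("thermal", grid, p)
        closed = thermal_peak_depth(p)
        assert abs(grid[np.argmax(vals)] - closed) <= 0.01

    def test_all_channels_decay_to_zero(self):
        p = KernelParams()
        for c in ("thermal", "fast", "photon", "boron"):
            assert depth_curve(c, 500.0, p) < 1e-12

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            depth_curve("thermal", -0.1, KernelParams())

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            depth_curve("muon", 1.0, KernelParams())

    def test_lambda_order_enforced(self):
        with pytest.raises(ValueError):
            KernelParams(thermal_lambda1=1.0, thermal_lambda2=2.0)


class TestOffAxisProfile:
    def test_on_axis_normalization_exact(self, beam):
        p = KernelParams()
        for d in (0.0, 2.5, 6.5):
            for g in (0.0, 2.0):
                assert off_axis_profile(0.0, d, g, beam, p) == pytest.approx(
                    1.0, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(depth=st.floats(0, 12), gap=st.floats(0, 5))
    def test_monotone_non_increasing_in_radius(self, depth, gap):
        beam, p = BeamConfig(), KernelParams()
        r = np.linspace(0, 12, 120)
        vals = off_axis_profile(r, np.full_like(r, depth),
                                np.full_like(r, gap), beam, p)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_deep_profile_flatter_in_central_3cm(self, beam):
        # the greater depth is less sensitive to small off-axis distances
        p = KernelParams()
        flat = {d: off_axis_profile(1.5, d, 0.0, beam, p) for d in (2.5, 6.5)}
        assert flat[6.5] > flat[2.5]

    def test_penumbra_widens_with_depth_and_gap(self, beam):
        p = KernelParams()

        def width(d, g):
            # 60% -> 20% fall distance of the field-edge factor (the
            # documented centre-peak fluence term divided out)
            r = np.linspace(0, 14, 2801)
            v = off_axis_profile(r, np.full_like(r, d), np.full_like(r, g),
                                 beam, p)
            rho = p.flatness_radius0 + p.flatness_growth * d
            edge = v / np.exp(-(r**2) / (2 * rho**2))
            edge = edge / edge[0]
            r60 = r[np.argmax(edge < 0.6)]
            r20 = r[np.argmax(edge < 0.2)]
            return r20 - r60

        assert width(6.5, 0.0) > width(2.5, 0.0)
        assert width(2.5, 3.0) > width(2.5, 0.0)

    def test_forward_peaked_beam_has_narrower_penumbra_growth(self):
        sharp = KernelParams(current_to_flux_ratio=0.9)
        blunt = KernelParams(current_to_flux_ratio=0.6)
        assert sharp.penumbra_growth < blunt.penumbra_growth

    def test_negative_arguments_rejected(self, beam):
        with pytest.raises(ValueError):
            off_axis_profile(-1.0, 1.0, 0.0, beam, KernelParams())


class TestAirGap:
    def test_unit_at_zero_gap(self, beam):
        assert air_gap_attenuation(0.0, beam, KernelParams()) == 1.0

    def test_strictly_decreasing(self, beam):
        p = KernelParams()
        vals = [air_gap_attenuation(g, beam, p) for g in (0, 1, 2, 3)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestDoseComponents:
    def test_all_air_phantom_warns_and_returns_zero(self, beam):
        from bnctshift.phantom import AIR, VoxelPhantom

        empty = VoxelPhantom(np.zeros((4, 4, 4), dtype=np.int16),
                             np.full((4, 4, 4), AIR.density),
                             (1.0, 1.0, 1.0), (-2.0, 0.0, -2.0), {0: AIR})
        with pytest.warns(UserWarning):
            comps = compute_dose_components(empty, beam, KernelParams())
        assert not comps.thermal.any()
        assert not comps.boron_per_ppm.any()

    def test_linearity_in_exit_amplitude(self, beam, tiny_phantom):
        from dataclasses import replace

        p = KernelParams()
        doubled = replace(p, fast_amplitude=2 * p.fast_amplitude)
        c1 = compute_dose_components(tiny_phantom, beam, p)
        c2 = compute_dose_components(tiny_phantom, beam, doubled)
        np.testing.assert_allclose(c2.fast, 2 * c1.fast, rtol=1e-12)
        np.testing.assert_array_equal(c2.photon, c1.photon)

    def test_matches_ray_march_oracle(self, beam, tiny_phantom):
        """Independent straight-line march recomputing tissue depth, radius
        and gap voxel by voxel."""
        p = KernelParams()
        comps = compute_dose_components(tiny_phantom, beam, p)
        got = {"thermal": comps.thermal, "fast": comps.fast,
               "photon": comps.photon, "boron": comps.boron_per_ppm}
        nx, ny, nz = tiny_phantom.shape
        dx, dy, dz = tiny_phantom.spacing
        ox, oy, oz = tiny_phantom.origin
        tissue = tiny_phantom.material_grid != 0
        for i in range(nx):
            x = ox + (i + 0.5) * dx
            for k in range(nz):
                z = oz + (k + 0.5) * dz
                r = math.hypot(x, z)
                first = None
                for j in range(ny):
                    if tissue[i, j, k]:
                        first = j
                        break
                gap = max(oy + first * dy, 0.0) if first is not None else 0.0
                walked = 0.0
                for j in range(ny):
                    if not tissue[i, j, k]:
                        for c in got:
                            assert got[c][i, j, k] == 0.0
                        continue
                    depth = walked + 0.5 * dy
                    walked += dy
                    lateral = (off_axis_profile(r, depth, gap, beam, p)
                               * air_gap_attenuation(gap, beam, p))
                    for c in got:
                        want = depth_curve(c, depth, p) * lateral
                        assert got[c][i, j, k] == pytest.approx(
                            want, rel=1e-9, abs=1e-300)


class TestAdvantageDepthAndCalibration:
    def test_calibrated_advantage_depth_on_target(self, params, weighting):
        ad = advantage_depth(params, weighting)
        assert 8.3 <= ad <= 8.7

    def test_balanced_boron_weighting_returns_normal_peak_depth(
            self, params, weighting):
        # when the tumor's CBE-weighted boron concentration equals the
        # normal tissue's, the two on-axis curves coincide and the
        # crossing collapses onto the normal-dose maximum
        tn = weighting.cbe_normal / weighting.cbe_tumor
        ad = advantage_depth(params, weighting, tn_ratio=tn)
        depths = np.arange(0, 25, 0.01)
        from bnctshift.beam import _axis_gyeq_rates

        _, normal = _axis_gyeq_rates(params, weighting, depths, tn_ratio=tn)
        assert ad == pytest.approx(depths[np.argmax(normal)], abs=0.02)

    def test_advantage_depth_increases_with_tn_ratio(self, params, weighting):
        ad2 = advantage_depth(params, weighting, tn_ratio=2.0)
        ad35 = advantage_depth(params, weighting, tn_ratio=3.5)
        assert ad35 > ad2

    def test_calibration_is_deterministic(self, beam, weighting, calibration):
        again = calibrate_engine(beam, weighting)
        assert again.params == calibration.params
        assert again.calibration_id == calibration.calibration_id

    def test_calibration_report_soft_envelopes(self, beam, weighting):
        report = calibrate_engine(beam, weighting, check_soft=True)
        assert report.soft_checks["outward_3cm_deep_loss"]["pass"]
        assert report.soft_checks["lateral_1cm_deep_loss"]["pass"]

    def test_infeasible_target_raises(self, beam, weighting):
        from bnctshift.beam import CalibrationTargets

        with pytest.raises(RuntimeError):
            calibrate_engine(beam, weighting,
                             CalibrationTargets(advantage_depth=40.0),
                             check_soft=False)
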