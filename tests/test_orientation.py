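"""Molecular frames, relative angles and binding-position densities."""

import math

import numpy as np
import pytest

from dimerscope import orientation as ori
from dimerscope import synthetic
from dimerscope.orientation import (
    FrameError,
    OrientationSample,
    binding_position_density,
    build_frame,
    helix_angular_map,
    relative_angles,
)


def rot_z(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestFrame:
    def test_reference_pose_x_axis(self, bundle):
        model, coords = bundle
        f = build_frame(model, coords)
        np.testing.assert_allclose(f.x_axis, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(f.origin[:2], [0, 0], atol=1e-9)

    @pytest.mark.parametrize("theta", [90.0, 37.0, -120.0, 179.0])
    def test_rotation_equivariance(self, bundle, theta):
        model, coords = bundle
        f = build_frame(model, coords @ rot_z(theta).T)
        expected = rot_z(theta) @ np.array([1.0, 0, 0])
        np.testing.assert_allclose(f.x_axis, expected, atol=1e-6)

    def test_translation_invariance(self, bundle):
        model, coords = bundle
        f0 = build_frame(model, coords)
        f1 = build_frame(model, coords + np.array([5.0, 5.0, 0.0]))
        np.testing.assert_allclose(f1.x_axis, f0.x_axis, atol=1e-12)
        np.testing.assert_allclose(f1.origin, f0.origin + [5, 5, 0], atol=1e-12)

    def test_isotropic_projection_rejected(self, bundle):
        model, coords = bundle
        iso = coords.copy()
        # collapse the ellipse onto a circle: the in-plane axes become ambiguous
        iso[:, 0] *= 1.5 / 2.0
        with pytest.raises(FrameError, match="principal axes"):
            build_frame(model, iso)

    def test_orthonormal(self, bundle):
        model, coords = bundle
        f = build_frame(model, coords @ rot_z(33.0).T)
        for a, b in [(f.x_axis, f.y_axis), (f.x_axis, f.z_axis), (f.y_axis, f.z_axis)]:
            assert abs(a @ b) < 1e-12
            assert np.linalg.norm(a) == pytest.approx(1.0)


class TestRelativeAngles:
    def test_identical_orientation_on_x_axis(self, bundle):
        model, coords = bundle
        a, b, truth = synthetic.place_dimer(model, coords, model, coords,
                                            beta=0.0, phi=0.0)
        s = relative_angles(build_frame(model, a), build_frame(model, b))
        assert (s.beta, s.phi, s.chi) == pytest.approx((0, 0, 180), abs=1e-6)

    def test_chi_formula_example(self):
        s = OrientationSample(time=0, beta=200.0, phi=50.0, chi=330.0)
        assert s.chi == 330.0  # (180 + 200 - 50) mod 360

    def test_inconsistent_chi_rejected(self):
        with pytest.raises(ValueError, match="chi"):
            OrientationSample(time=0, beta=200.0, phi=50.0, chi=100.0)

    def test_generator_placement_recovered(self, bundle):
        model, coords = bundle
        a, b, truth = synthetic.place_dimer(model, coords, model, coords,
                                            beta=45.0, phi=90.0)
        s = relative_angles(build_frame(model, a), build_frame(model, b))
        assert (s.beta, s.phi, s.chi) == pytest.approx((45, 90, 135), abs=1e-6)

    def test_random_placements_recovered(self, bundle, rng):
        model, coords = bundle
        for _ in range(100):
            beta, phi = rng.uniform(0, 360, 2)
            _, b, truth = synthetic.place_dimer(model, coords, model, coords,
                                                beta=beta, phi=phi)
            s = relative_angles(build_frame(model, coords), build_frame(model, b))
            for got, want in zip((s.beta, s.phi, s.chi), truth):
                assert abs((got - want + 180) % 360 - 180) < 1e-6

    def test_chi_equals_measured_reverse_azimuth(self, bundle, rng):
        # the reciprocal-angle formula against direct measurement in B's frame
        model, coords = bundle
        worst = 0.0
        for _ in range(1000):
            beta, phi = rng.uniform(0, 360, 2)
            a, b, _ = synthetic.place_dimer(model, coords, model, coords,
                                            beta=beta, phi=phi)
            fa, fb = build_frame(model, a), build_frame(model, b)
            s = relative_angles(fa, fb)
            measured = fb.azimuth_of(fa.origin)
            worst = max(worst, abs((s.chi - measured + 180) % 360 - 180))
        assert worst < 1e-6

    def test_swap_symmetry(self, bundle, rng):
        model, coords = bundle
        for _ in range(20):
            beta, phi = rng.uniform(0, 360, 2)
            a, b, _ = synthetic.place_dimer(model, coords, model, coords,
                                            beta=beta, phi=phi)
            fa, fb = build_frame(model, a), build_frame(model, b)
            s = relative_angles(fa, fb)
            r = relative_angles(fb, fa)
            assert abs((r.beta - s.chi + 180) % 360 - 180) < 1e-6
            assert abs((r.phi - (-s.phi) % 360 + 180) % 360 - 180) < 1e-6
            assert abs((r.chi - s.beta + 180) % 360 - 180) < 1e-6

    def test_coincident_origins_rejected(self, bundle):
        model, coords = bundle
        f = build_frame(model, coords)
        with pytest.raises(FrameError):
            f.azimuth_of(f.origin)


class TestHelixAngularMap:
    def test_intervals_match_construction(self, bundle):
        model, coords = bundle
        hmap = helix_angular_map(model, coords)
        a, b = 2.0, 1.5  # generator ellipse semi-axes
        for i in range(7):
            theta = 2 * math.pi * i / 7
            expected = math.degrees(math.atan2(b * math.sin(theta),
                                               a * math.cos(theta))) % 360
            lo, hi = hmap.intervals[f"TM{i + 1}"]
            assert lo == pytest.approx(expected, abs=1e-6)
            assert hi == pytest.approx(expected, abs=1e-6)

    def test_counterclockwise_order(self, bundle):
        model, coords = bundle
        hmap = helix_angular_map(model, coords)
        centers = [hmap.intervals[f"TM{i}"][0] for i in range(1, 8)]
        assert centers[0] == pytest.approx(0.0, abs=1e-6)
        assert all(x < y for x, y in zip(centers, centers[1:]))

    def test_occluded_inner_helix_unexposed(self):
        model, coords = synthetic.gen_bundle()
        # park TM2 on TM1's ray but closer to the axis; shift TM6 by the
        # opposite amount so the frame origin stays at zero
        tm2 = [model.backbone_bead_index[r] for r in model.helix_residues("TM2")]
        tm6 = [model.backbone_bead_index[r] for r in model.helix_residues("TM6")]
        coords = coords.copy()
        delta = coords[tm2[0], :2] - np.array([1.0, 0.0])
        coords[tm2, :2] = [1.0, 0.0]
        coords[tm6, :2] += delta
        hmap = helix_angular_map(model, coords)
        assert "TM2" not in set(hmap.exposure)
        tm1_bin = int(round(hmap.intervals["TM1"][0])) % 360
        assert hmap.exposure[tm1_bin] == "TM1"


class TestBindingPositionDensity:
    def samples(self, betas, phis):
        return [OrientationSample(time=0, beta=b, phi=p,
                                  chi=(180 + b - p) % 360)
                for b, p in zip(betas, phis)]

    def test_homodimer_pools_beta_and_chi(self):
        # all binding at beta=90 with phi=0 -> chi=270; pooled density bimodal
        s = self.samples([90.0] * 50, [0.0] * 50)
        grid, dens = binding_position_density(s, homodimer=True)
        peaks = np.sort(np.argsort(dens)[-2:])
        assert set(peaks) == {90, 270}

    def test_heterodimer_separate_densities(self):
        s = self.samples([10.0] * 40, [190.0] * 40)  # chi = 0 for all
        grid, dens = binding_position_density(s, homodimer=False)
        assert int(np.argmax(dens["A"])) == 10
        assert int(np.argmax(dens["B"])) == 0

    def test_wrapped_mode_is_single(self):
        s = self.samples([359.0, 1.0] * 25, [179.0, 181.0] * 25)
        grid, dens = binding_position_density(s, homodimer=False)
        assert int(np.argmax(dens["A"])) == 0
        # periodic continuity: the ends of the grid join smoothly
        assert dens["A"][0] == pytest.approx(dens["A"][-1], rel=0.05)

    def test_normalised(self):
        s = self.samples(np.linspace(0, 350, 36), np.linspace(0, 350, 36))
        grid, dens = binding_position_density(s, homodimer=True)
        assert np.trapezoid(np.append(dens, dens[0]),
                            np.append(grid, 360.0)) == pytest.approx(1.0, abs=1e-6)
        assert (dens >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binding_position_density([], homodimer=True)

    def test_label_swap_leaves_pooled_density_invariant(self, bundle, rng):
        model, coords = bundle
        betas = rng.uniform(0, 360, 30)
        phis = rng.uniform(0, 360, 30)
        fwd = self.samples(betas, phis)
        # swapped labelling: (beta, phi, chi) -> (chi, -phi, beta)
        rev = self.samples([(180 + b - p) % 360 for b, p in zip(betas, phis)],
                           [(-p) % 360 for p in phis])
        _, d1 = binding_position_density(fwd, homodimer=True)
        _, d2 = binding_position_density(rev, homodimer=True)
        np.testing.assert_allclose(d1, d2, atol=1e-12)
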