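"""Synthetic fiber phantom generators and their ground truth."""

import numpy as np
import pytest

from fiborient import (
    PhantomSpec,
    generate,
    generate_curvy_fibers_2d,
    generate_fibers_3d,
    generate_straight_fibers_2d,
)
from fiborient.phantoms import (
    PlacementError,
    _capsule_pixels_2d,
    angles_to_axis,
    axis_to_angles,
    write_phantom,
)


def small_spec(**kw):
    base = dict(dims=(128, 128), diameters=(5.0, 9.0), seed=3,
                fiber_extent="capsule", min_gap=2.0)
    base.update(kw)
    return PhantomSpec(**base)


class TestSpecValidation:
    def test_rejects_oversized_diameter(self):
        with pytest.raises(ValueError):
            PhantomSpec(dims=(64, 64), diameters=(40.0,))

    def test_rejects_small_dims(self):
        with pytest.raises(ValueError):
            PhantomSpec(dims=(16, 64), diameters=(3.0,))

    @pytest.mark.parametrize("field,value", [
        ("noise_sd", -1.0), ("curvature_period", 0.0), ("fiber_model", "zigzag"),
        ("overlap_policy", "maybe"), ("n_fibers_per_diameter", 0),
    ])
    def test_rejects_bad_fields(self, field, value):
        with pytest.raises(ValueError):
            small_spec(**{field: value})


class TestStraight2D:
    def test_determinism(self):
        a_img, a_truth = generate_straight_fibers_2d(small_spec())
        b_img, b_truth = generate_straight_fibers_2d(small_spec())
        assert np.array_equal(a_img.values, b_img.values)
        assert np.array_equal(a_truth.mask, b_truth.mask)
        assert np.array_equal(a_truth.theta, b_truth.theta, equal_nan=True)

    def test_different_seed_differs(self):
        a, _ = generate_straight_fibers_2d(small_spec(seed=1))
        b, _ = generate_straight_fibers_2d(small_spec(seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_truth_invariants(self):
        img, truth = generate_straight_fibers_2d(small_spec())
        assert np.array_equal(truth.mask, truth.thickness > 0)
        th = truth.theta[truth.mask]
        assert np.all(np.isfinite(th)) and np.all((th >= 0) & (th < 180))
        assert np.all(np.isnan(truth.theta[~truth.mask]))
        assert set(np.unique(truth.thickness[truth.mask])) == {5.0, 9.0}

    def test_noiseless_image_nonzero_exactly_on_mask(self):
        img, truth = generate_straight_fibers_2d(small_spec(noise_sd=0.0))
        assert np.array_equal(img.values != 0, truth.mask)

    def test_noise_changes_background(self):
        img, truth = generate_straight_fibers_2d(small_spec(noise_sd=5.0))
        assert img.values[~truth.mask].std() > 1.0

    def test_forbid_policy_separates_fibers(self):
        from scipy import ndimage as ndi

        _, truth = generate_straight_fibers_2d(small_spec(diameters=(5.0, 8.0, 11.0)))
        n_comp = ndi.label(truth.mask, structure=np.ones((3, 3)))[1]
        assert n_comp == 3  # one component per fiber, never touching

    def test_placement_error_when_unsatisfiable(self):
        spec = small_spec(dims=(96, 96), diameters=(20.0,), n_fibers_per_diameter=8,
                          min_gap=6.0)
        with pytest.raises(PlacementError):
            generate_straight_fibers_2d(spec)

    def test_rasterization_inscribed_diameter(self):
        # rendered straight band: maximal inscribed disc diameter == D within 1 px
        from scipy.spatial import cKDTree

        for ang, D in [(33.0, 8.0), (71.0, 12.0)]:
            rr, cc, _, _, _ = _capsule_pixels_2d(ang, 63.5, 63.5, 1000, 0.0, 150, 0.0,
                                                 D, (128, 128))
            mask = np.zeros((128, 128), bool)
            mask[rr, cc] = True
            bg = np.argwhere(~mask)
            tree = cKDTree(bg)
            fg = np.argwhere(mask)
            inner = fg[(np.abs(fg - 63.5) < 30).all(axis=1)]
            dmax = tree.query(inner)[0].max()
            assert abs(2 * dmax - D) <= 2.0  # center-sampling quantization


class TestCurvy2D:
    def test_zero_amplitude_equals_straight(self):
        s_straight = small_spec(fiber_model="straight")
        s_curvy = small_spec(fiber_model="curvy", curvature_amplitude=0.0)
        a_img, a_truth = generate_straight_fibers_2d(s_straight)
        b_img, b_truth = generate_curvy_fibers_2d(s_curvy)
        assert np.array_equal(a_img.values, b_img.values)
        assert np.array_equal(a_truth.theta, b_truth.theta, equal_nan=True)

    def test_determinism(self):
        s = small_spec(fiber_model="curvy", curvature_amplitude=6.0,
                       curvature_period=60.0)
        a, ta = generate_curvy_fibers_2d(s)
        b, tb = generate_curvy_fibers_2d(s)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ta.theta, tb.theta, equal_nan=True)

    def test_tangent_truth_matches_numeric_derivative(self):
        # single sinusoidal fiber: stored tangents vs finite differences of
        # the parametric centerline, within 0.5 deg away from endpoints
        amp, period, phase, ang = 8.0, 80.0, 0.3, 20.0
        rr, cc, tang, dists, ed = _capsule_pixels_2d(
            ang, 99.5, 99.5, 70.0, amp, period, phase, 6.0, (200, 200)
        )
        keep = (ed > 10) & (dists < 1.0)  # near-centerline, away from ends
        th = np.radians(ang)
        a = np.array([np.cos(th), np.sin(th)])
        n = np.array([-np.sin(th), np.cos(th)])
        t = np.linspace(-70, 70, 4001)
        px = 99.5 + t * a[0] + amp * np.sin(2 * np.pi * t / period + phase) * n[0]
        py = 99.5 + t * a[1] + amp * np.sin(2 * np.pi * t / period + phase) * n[1]
        num_ang = np.degrees(np.arctan2(np.gradient(py, t), np.gradient(px, t))) % 180
        from scipy.spatial import cKDTree

        tree = cKDTree(np.column_stack([px, py]))
        idx = tree.query(np.column_stack([cc[keep], rr[keep]]))[1]
        d = np.abs(tang[keep] - num_ang[idx])
        d = np.minimum(d, 180 - d)
        assert d.max() < 0.5


class TestFibers3D:
    def test_determinism_and_truth_ranges(self):
        spec = PhantomSpec(dims=(48, 48, 48), diameters=(6.0,), seed=9,
                           fiber_extent="capsule", min_gap=2.0)
        a_img, a_truth = generate_fibers_3d(spec)
        b_img, b_truth = generate_fibers_3d(spec)
        assert np.array_equal(a_img.values, b_img.values)
        assert np.array_equal(a_truth.phi, b_truth.phi, equal_nan=True)
        th = a_truth.theta[a_truth.mask]
        ph = a_truth.phi[a_truth.mask]
        assert np.all((th >= 0) & (th < 180))
        assert np.all((ph >= 0) & (ph < 180))

    def test_axis_angle_round_trip(self, rng):
        for _ in range(50):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            th, ph = axis_to_angles(u)
            v = angles_to_axis(th, ph)
            assert abs(abs(u @ v) - 1.0) < 1e-9  # same axis up to sign

    def test_inplane_axis_convention(self):
        th, ph = axis_to_angles(angles_to_axis(30.0, 90.0))
        assert th == pytest.approx(30.0, abs=1e-9)
        assert ph == pytest.approx(90.0, abs=1e-9)

    def test_z_axis_phi_zero(self):
        th, ph = axis_to_angles((0.0, 0.0, 1.0))
        assert ph == 0.0


class TestDispatchAndSidecar:
    def test_generate_dispatch(self):
        img2, _ = generate(small_spec())
        assert img2.values.ndim == 2
        img3, _ = generate(PhantomSpec(dims=(40, 40, 40), diameters=(5.0,), seed=1,
                                       fiber_extent="capsule"))
        assert img3.values.ndim == 3

    def test_write_phantom_sidecar(self, tmp_path):
        spec = small_spec()
        img, truth = generate_straight_fibers_2d(spec)
        write_phantom(tmp_path / "ph", img, truth, spec)
        files = {p.name for p in (tmp_path / "ph").iterdir()}
        assert {"image.tif", "truth_thickness.tif", "truth_theta.tif",
                "params.txt"} <= files
        text = (tmp_path / "ph" / "params.txt").read_text()
        assert "seed = 3" in text and "diameters" in text
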