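"""Rfd computation, geometric amplification, mesh mapping, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codedlight import synthetic as syn
from codedlight.calibration import optical_axis
from codedlight.fluorescence import (
    FluorescenceFrames,
    angle_factor,
    attach_fluorescence,
    cosine_correct,
    map_to_mesh,
    rfd,
    whole_plant_summary,
)
from codedlight.reconstruction import SurfaceMesh


class TestRfd:
    def test_equal_frames_give_zero(self):
        assert rfd(3.0, 3.0) == 0.0

    def test_doubled_peak_gives_one(self):
        assert rfd(2.0, 1.0) == 1.0

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0), st.floats(0.01, 1000.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, fp, fs, c):
        assert np.isclose(rfd(c * fp, c * fs), rfd(fp, fs), rtol=1e-9)

    def test_zero_steady_state_flagged_not_raised(self):
        out = rfd(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        assert np.isnan(out[0]) and out[1] == 1.0

    def test_zero_iff_equal(self):
        fp = np.array([1.0, 2.0, 3.0])
        fs = np.array([1.0, 1.0, 3.0])
        out = rfd(fp, fs)
        assert np.array_equal(out == 0, fp == fs)


class TestAngleFactor:
    def test_forty_five_degrees_is_41_percent_amplification(self):
        assert np.isclose(angle_factor(45.0) - 1.0, 0.414, atol=5e-4)

    def test_perpendicular_is_unity(self):
        assert angle_factor(0.0) == 1.0

    def test_sixty_degrees_doubles(self):
        assert np.isclose(angle_factor(60.0), 2.0)

    def test_grazing_and_negative_rejected(self):
        with pytest.raises(ValueError):
            angle_factor(90.0)
        with pytest.raises(ValueError):
            angle_factor(-1.0)

    def test_strictly_increasing_and_inverse_of_cosine(self):
        phi = np.linspace(0, 89.9, 200)
        f = angle_factor(phi)
        assert np.all(np.diff(f) > 0)
        assert np.allclose(f * np.cos(np.radians(phi)), 1.0)


class TestCosineCorrect:
    def test_perpendicular_surface_unchanged(self):
        vals = np.array([2.0, 3.0])
        normals = np.array([[0, 0, 1.0], [0, 0, 1.0]])
        corrected, phi = cosine_correct(vals, normals, [0, 0, 1.0])
        assert np.allclose(corrected, vals)
        assert np.allclose(phi, 0.0)

    def test_correction_inverts_angle_factor(self):
        phi_true = 38.0
        normals = np.array([[np.sin(np.radians(phi_true)), 0, np.cos(np.radians(phi_true))]])
        amplified = np.array([1.0]) * angle_factor(phi_true)
        corrected, phi = cosine_correct(amplified, normals, [0, 0, 1.0])
        assert np.isclose(phi[0], phi_true)
        assert np.isclose(corrected[0], 1.0)

    def test_edge_on_surface_not_correctable(self):
        corrected, _ = cosine_correct(np.array([1.0]), np.array([[1.0, 0, 0]]), [0, 0, 1.0])
        assert np.isnan(corrected[0])


class TestMapToMesh:
    def test_constant_frame_maps_to_constant(self, mats_full):
        mesh = SurfaceMesh(
            np.array([[0, 0, 80.0], [20, 0, 80.0], [0, 20, 80.0]]),
            np.array([[0, 1, 2]]),
        )
        frame = np.full((512, 512), 0.7)
        values, visible = map_to_mesh(mesh, frame, mats_full["fluor_cam"])
        assert visible.all()
        assert np.allclose(values, 0.7)

    def test_vertex_behind_a_leaf_is_invisible(self, mats_full):
        fluor = mats_full["fluor_cam"]
        axis = optical_axis(fluor)
        near = np.array([0, 0, 80.0])
        far = near + 60.0 * axis  # directly behind along the optical axis
        e1 = np.cross(axis, [0, 0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)

        def quad(center, half):
            v = np.array(
                [center - half * e1 - half * e2, center + half * e1 - half * e2,
                 center - half * e1 + half * e2, center + half * e1 + half * e2]
            )
            return v, np.array([[0, 1, 2], [1, 3, 2]])

        v1, f1 = quad(near, 30.0)
        v2, f2 = quad(far, 10.0)
        mesh = SurfaceMesh(np.vstack([v1, v2]), np.vstack([f1, f2 + 4]))
        _, visible = map_to_mesh(mesh, np.ones((512, 512)), fluor)
        assert visible[:4].all()
        assert not visible[4:].any()

    def test_outside_frame_is_invisible(self, mats_full):
        mesh = SurfaceMesh(
            np.array([[5000.0, 0, 80.0], [5020, 0, 80.0], [5000, 20, 80.0]]),
            np.array([[0, 1, 2]]),
        )
        values, visible = map_to_mesh(mesh, np.ones((512, 512)), mats_full["fluor_cam"])
        assert not visible.any()
        assert np.isnan(values).all()

    def test_two_leaf_yields_recovered(self, mats_full, rig_full):
        scene = syn.make_plant(seed=21, n_leaves=4)
        for i, leaf in enumerate(scene.leaves):
            leaf.fs_yield = 0.1 + 0.1 * i
        frames, leafmap = syn.render_fluorescence(
            scene, rig_full, amplification=False, noise_sd=0.0, seed=0
        )
        mesh = scene.leaf_surface_mesh()
        inner = SurfaceMesh(
            mesh.vertices.copy(), mesh.faces, dict(mesh.vertex_attrs)
        )
        # shrink each leaf toward its own center so samples are interior
        labels = mesh.vertex_attrs["label"].astype(int)
        for i in np.unique(labels):
            sel = labels == i
            c = inner.vertices[sel].mean(axis=0)
            inner.vertices[sel] = c + 0.85 * (inner.vertices[sel] - c)
        values, visible = map_to_mesh(inner, frames.fs, mats_full["fluor_cam"])
        for i, leaf in enumerate(scene.leaves):
            sel = (labels == i) & visible
            if sel.sum() < 5:
                continue
            assert np.nanmedian(values[sel]) == pytest.approx(leaf.fs_yield, abs=0.02)


class TestClosure:
    def test_cosine_correction_closes_at_38_degrees(self, rig_full, mats_full):
        """Uniform-yield leaf at 38 deg: ~27% apparent amplification is
        removed by the cosine renormalization."""
        axis = optical_axis(mats_full["fluor_cam"])
        perp = np.cross(-axis, [0, 0, 1.0])
        perp /= np.linalg.norm(perp)
        c, s = np.cos(np.radians(38.0)), np.sin(np.radians(38.0))
        normal = c * (-axis) + s * np.cross(perp, -axis)
        scene = syn.make_single_leaf_scene(0.0, normal=normal, area_cm2=20.0)
        frames, _ = syn.render_fluorescence(
            scene, rig_full, amplification=True, noise_sd=0.002, seed=5
        )
        mesh = scene.leaf_surface_mesh()
        centroid = mesh.vertices.mean(axis=0)
        inner = SurfaceMesh(centroid + 0.9 * (mesh.vertices - centroid), mesh.faces, {})
        vf = attach_fluorescence(inner, frames, mats_full["fluor_cam"])
        true_fs = scene.leaves[0].fs_yield
        uncorrected = np.nanmean(vf.fs[vf.visible])
        corrected = np.nanmean(vf.fs_corrected[vf.visible])
        assert uncorrected / true_fs - 1 == pytest.approx(0.269, abs=0.03)
        assert abs(corrected / true_fs - 1) < 0.01

    def test_distance_does_not_change_the_signal(self, rig_full):
        # surface-per-pixel and flux terms both scale with distance^2 and
        # cancel: the same leaf nearer or farther reads the same
        readings = []
        for z in (80.0, 280.0):
            scene = syn.make_single_leaf_scene(10.0, area_cm2=15.0, center_z=z)
            frames, leafmap = syn.render_fluorescence(
                scene, rig_full, amplification=True, noise_sd=0.0, seed=0
            )
            readings.append(frames.fs[leafmap == 0].mean())
        assert abs(readings[1] / readings[0] - 1) < 0.02


class TestWholePlantSummary:
    def _flat_mesh_with_rfd(self, rfd_by_z):
        verts, faces, rvals = [], [], []
        for k, (z, val) in enumerate(rfd_by_z):
            base = 4 * k
            verts += [[0, 0, z], [10, 0, z], [0, 10, z], [10, 10, z]]
            faces += [[base, base + 1, base + 2], [base + 1, base + 3, base + 2]]
            rvals += [val] * 4
        mesh = SurfaceMesh(np.array(verts, float), np.array(faces))
        return mesh, np.array(rvals, float)

    def _vf(self, mesh, rvals):
        from codedlight.fluorescence import VertexFluorescence

        n = len(rvals)
        ones = np.ones(n)
        return VertexFluorescence(
            fp=ones * 2,
            fs=ones,
            rfd=rvals,
            phi_deg=np.zeros(n),
            fp_corrected=ones * 2,
            fs_corrected=ones,
            visible=np.ones(n, bool),
        )

    def test_uniform_field_mean_and_zero_sd(self):
        mesh, rvals = self._flat_mesh_with_rfd([(10, 1.2), (50, 1.2)])
        summary = whole_plant_summary(self._vf(mesh, rvals), mesh)
        assert np.isclose(summary.mean_rfd, 1.2)
        assert np.isclose(summary.sd_rfd, 0.0)

    def test_vertical_gradient_shows_in_band_profile(self):
        # water stress first lowers Rfd in the top leaves
        layers = [(z, 1.5 - 0.01 * z) for z in (10, 40, 70, 100)]
        mesh, rvals = self._flat_mesh_with_rfd(layers)
        summary = whole_plant_summary(self._vf(mesh, rvals), mesh, n_bands=4)
        bands = summary.band_mean_rfd[np.isfinite(summary.band_mean_rfd)]
        assert np.all(np.diff(bands) < 0)

    def test_no_visible_surface_is_an_error(self):
        mesh, rvals = self._flat_mesh_with_rfd([(10, 1.0)])
        vf = self._vf(mesh, rvals)
        vf.visible[:] = False
        with pytest.raises(ValueError, match="visible"):
            whole_plant_summary(vf, mesh)

    def test_refinement_stability_of_the_area_weighted_mean(self):
        def gridded_mesh(n):
            xs = np.linspace(0, 30, n)
            xx, yy = np.meshgrid(xs, xs)
            verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
            faces = []
            for r in range(n - 1):
                for c in range(n - 1):
                    a = r * n + c
                    faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
            return SurfaceMesh(verts, np.array(faces))

        means = []
        for n in (10, 20):
            mesh = gridded_mesh(n)
            rvals = 1.0 + 0.02 * mesh.vertices[:, 0]  # smooth spatial field
            summary = whole_plant_summary(self._vf(mesh, rvals), mesh)
            means.append(summary.mean_rfd)
        assert abs(means[1] - means[0]) / means[0] < 0.005


class TestFrames:
    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceFrames(np.zeros((4, 4)), np.zeros((5, 4)))
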