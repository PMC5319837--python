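"""Planar-contour and mesh geometry primitives."""

import math

import numpy as np
import pytest
import trimesh

from spindleshape import (
    Contour2D,
    InvalidShapeError,
    LabeledMesh,
    MeshLabelError,
    SpindleAxis,
    apical_surface_ratio,
    area_centroid,
    axial_difference,
    extract_apical_plane,
    load_labeled_mesh,
    make_labeled_mesh,
    mesh_volume_area,
    principal_axes,
    ray_to_boundary,
    save_labeled_mesh,
    sphericity,
)
from spindleshape.geometry import points_inside_mesh

from conftest import make_ellipse


class TestContour:
    def test_unit_square_area_centroid(self, unit_square):
        area, centroid = area_centroid(unit_square)
        assert area == pytest.approx(1.0)
        assert centroid == pytest.approx((0.5, 0.5))

    def test_clockwise_input_is_normalized(self, unit_square):
        cw = Contour2D(unit_square.vertices[::-1])
        assert area_centroid(cw) == area_centroid(unit_square)
        # orientation normalized to CCW (positive shoelace)
        x, y = cw.vertices[:, 0], cw.vertices[:, 1]
        assert (x * np.roll(y, -1) - np.roll(x, -1) * y).sum() > 0

    def test_duplicate_closing_vertex_dropped(self):
        sq = Contour2D(
            np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
        )
        assert sq.n_vertices == 4

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0, 0], [1, 0], [1, 1]], dtype=float),  # too few
            np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float),  # bowtie
            np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float),  # zero area
        ],
    )
    def test_invalid_contours_rejected(self, bad):
        with pytest.raises(InvalidShapeError):
            Contour2D(bad)

    def test_area_matches_monte_carlo(self):
        rng = np.random.default_rng(42)
        # random simple 12-gon from jittered radii around a circle
        t = np.linspace(0, 2 * math.pi, 12, endpoint=False)
        r = 10.0 * (1.0 + 0.25 * rng.uniform(-1, 1, 12))
        poly = Contour2D(np.column_stack((r * np.cos(t), r * np.sin(t))))
        area, _ = area_centroid(poly)
        pts = rng.uniform(-14, 14, size=(1_000_000, 2))
        frac = poly.contains(pts).mean()
        assert area == pytest.approx(frac * 28.0**2, rel=0.01)

    def test_csv_round_trip(self, tmp_path, unit_square):
        path = tmp_path / "contour.csv"
        unit_square.to_csv(path)
        back = Contour2D.from_csv(path)
        np.testing.assert_allclose(back.vertices, unit_square.vertices)


class TestPrincipalAxes:
    def test_rectangle_axes(self):
        rect = Contour2D(np.array([[-1, -0.5], [1, -0.5], [1, 0.5], [-1, 0.5]]))
        axes = principal_axes(rect)
        assert axes.angle_major == pytest.approx(0.0, abs=1e-9)
        assert axes.aspect_ratio == pytest.approx(2.0)
        assert not axes.degenerate

    def test_circle_is_degenerate(self, circle_64):
        assert principal_axes(circle_64).degenerate

    def test_rotated_ellipse_angle_and_lengths(self):
        ell = make_ellipse(30.0, 15.0, angle_deg=37.0, center=(4.0, -2.0))
        axes = principal_axes(ell)
        assert axial_difference(axes.angle_major, 37.0) < 0.5
        # polygonal ellipse converges to the true full axis lengths
        assert axes.length_major == pytest.approx(60.0, rel=0.01)
        assert axes.length_minor == pytest.approx(30.0, rel=0.01)
        assert axes.aspect_ratio == pytest.approx(2.0, rel=0.01)

    def test_rigid_motion_and_scale_invariance(self):
        base = make_ellipse(20.0, 9.0, angle_deg=10.0)
        moved = make_ellipse(20.0, 9.0, angle_deg=10.0 + 90.0, center=(7.0, 3.0))
        a0, a1 = principal_axes(base), principal_axes(moved)
        assert axial_difference(a1.angle_major, a0.angle_major + 90.0) < 1e-6
        assert a1.aspect_ratio == pytest.approx(a0.aspect_ratio, rel=1e-6)
        scaled = Contour2D(base.vertices * 3.5)
        a2 = principal_axes(scaled)
        assert a2.aspect_ratio == pytest.approx(a0.aspect_ratio, rel=1e-6)
        assert axial_difference(a2.angle_major, a0.angle_major) < 1e-6


class TestRayCasting:
    def test_unit_square_axis_ray(self, unit_square):
        assert ray_to_boundary(unit_square, (0.5, 0.5), (1.0, 0.0)) == pytest.approx(0.5)

    def test_circle_closed_form(self, circle_64):
        # |o + L d| = r for the polygonal circle, any interior origin
        o = np.array([3.0, -2.0])
        d = np.array([1.0, 2.0]) / math.sqrt(5.0)
        L = ray_to_boundary(circle_64, o, d)
        hit = o + L * d
        # radius of the 64-gon at the hit angle
        assert np.linalg.norm(hit) == pytest.approx(10.0, rel=5e-3)

    def test_origin_outside_rejected(self, unit_square):
        with pytest.raises(InvalidShapeError):
            ray_to_boundary(unit_square, (2.0, 2.0), (1.0, 0.0))

    def test_nonconvex_first_hit(self):
        # L-shaped hexagon; ray crossing the notch must stop at the first wall
        lshape = Contour2D(
            np.array([[0, 0], [4, 0], [4, 1], [1, 1], [1, 4], [0, 4]], dtype=float)
        )
        o = np.array([0.5, 3.5])
        L = ray_to_boundary(lshape, o, (1.0, 0.0))
        assert L == pytest.approx(0.5)  # stops at x=1, not at x=4

    def test_chord_matches_edge_intersection_oracle(self):
        poly = make_ellipse(12.0, 7.0, angle_deg=25.0, n=48)
        _, centroid = area_centroid(poly)
        o = np.asarray(centroid)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ang = rng.uniform(0, 2 * math.pi)
            d = np.array([math.cos(ang), math.sin(ang)])
            chord = ray_to_boundary(poly, o, d) + ray_to_boundary(poly, o, -d)
            # brute-force all segment intersections of the full line
            v = poly.vertices
            hits = []
            for k in range(len(v)):
                p0, p1 = v[k], v[(k + 1) % len(v)]
                e = p1 - p0
                den = d[0] * e[1] - d[1] * e[0]
                if abs(den) < 1e-14:
                    continue
                w = p0 - o
                t = (w[0] * e[1] - w[1] * e[0]) / den
                u = (w[0] * d[1] - w[1] * d[0]) / den
                if 0.0 <= u < 1.0:
                    hits.append(t)
            assert chord == pytest.approx(max(hits) - min(hits), abs=1e-9)


class TestSpindleAxis:
    def test_angle_center_length(self):
        ax = SpindleAxis((0.0, 0.0), (2.0, 2.0))
        assert ax.angle == pytest.approx(45.0)
        assert ax.length == pytest.approx(math.sqrt(8.0))
        np.testing.assert_allclose(ax.center, [1.0, 1.0])

    def test_axial_angle_is_undirected(self):
        assert SpindleAxis((0, 0), (-1, -1)).angle == pytest.approx(45.0)

    def test_coincident_poles_rejected(self):
        with pytest.raises(InvalidShapeError):
            SpindleAxis((1.0, 1.0), (1.0, 1.0))


class TestMeshMetrics:
    def test_unit_cube_volume_area_sphericity(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        lm = LabeledMesh(box, np.array(["apical"] * len(box.faces), dtype=object))
        vol, area = mesh_volume_area(lm)
        assert vol == pytest.approx(1.0)
        assert area == pytest.approx(6.0)
        assert sphericity(lm) == pytest.approx((math.pi / 6.0) ** (1.0 / 3.0), abs=1e-9)

    def test_icosphere_near_unity(self):
        lm, _ = make_labeled_mesh("icosphere", "hemisphere", radius=1.0)
        vol, area = mesh_volume_area(lm)
        assert vol == pytest.approx(4.0 * math.pi / 3.0, rel=0.01)
        assert area == pytest.approx(4.0 * math.pi, rel=0.01)
        assert sphericity(lm) >= 0.995

    def test_ellipsoid_volume_and_flattening_monotonicity(self):
        ell, _ = make_labeled_mesh("ellipsoid", "hemisphere", radius=1.0)
        vol, _ = mesh_volume_area(ell)
        assert vol == pytest.approx(2.0 * 4.0 * math.pi / 3.0, rel=0.01)
        flat, _ = make_labeled_mesh("flattened", "hemisphere", radius=1.0)
        sphere, _ = make_labeled_mesh("icosphere", "hemisphere", radius=1.0)
        assert sphericity(flat) < sphericity(sphere)
        assert sphericity(ell) < sphericity(sphere)

    def test_sphericity_scale_invariant(self):
        small, _ = make_labeled_mesh("flattened", "hemisphere", radius=1.0)
        big, _ = make_labeled_mesh("flattened", "hemisphere", radius=42.0)
        assert sphericity(big) == pytest.approx(sphericity(small), rel=1e-6)

    def test_non_watertight_reports_open_edges(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        holed = trimesh.Trimesh(
            vertices=box.vertices, faces=box.faces[:-1], process=False
        )
        lm = LabeledMesh(holed, np.array(["apical"] * len(holed.faces), dtype=object))
        with pytest.raises(InvalidShapeError, match="open edges"):
            mesh_volume_area(lm)

    def test_apical_ratio_cube_one_face(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        top = box.triangles_center[:, 2] > 0.49
        labels = np.where(top, "apical", "basolateral").astype(object)
        lm = LabeledMesh(box, labels)
        assert apical_surface_ratio(lm) == pytest.approx(1.0 / 6.0)

    def test_apical_ratio_hemisphere_and_all(self):
        lm, _ = make_labeled_mesh("icosphere", "hemisphere")
        assert apical_surface_ratio(lm) == pytest.approx(0.5, abs=0.01)
        allap = LabeledMesh(
            lm.mesh, np.array(["apical"] * len(lm.mesh.faces), dtype=object)
        )
        assert apical_surface_ratio(allap) == 1.0

    def test_label_validation(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        with pytest.raises(MeshLabelError):
            LabeledMesh(box, np.array(["apical"] * 3, dtype=object))
        with pytest.raises(MeshLabelError):
            LabeledMesh(box, np.array(["apical"] * 11 + ["junk"], dtype=object))

    def test_points_inside_mesh(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        pts = np.array([[0, 0, 0], [1.5, 0, 0], [2.5, 0, 0], [0, 0, -3.0]])
        np.testing.assert_array_equal(
            points_inside_mesh(sphere, pts), [True, True, False, False]
        )


class TestApicalPlane:
    def test_equatorial_plane_recovered(self):
        lm, truth = make_labeled_mesh("icosphere", "hemisphere", radius=10.0)
        poles = np.array([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        plane, contour, poles2d = extract_apical_plane(lm, poles)
        cosang = abs(np.dot(plane.normal, truth.normal))
        assert math.degrees(math.acos(min(cosang, 1.0))) < 2.0
        assert plane.separation_score > 0.99
        # cross-section of the sphere through the center is a great circle
        area, _ = area_centroid(contour)
        assert area == pytest.approx(math.pi * 100.0, rel=0.02)
        assert np.asarray(poles2d.pole_a) == pytest.approx([-5.0, 0.0], abs=1e-6)

    def test_rotated_labels_recover_rotated_plane(self):
        lm, _ = make_labeled_mesh("icosphere", "hemisphere", radius=10.0)
        rot = trimesh.transformations.rotation_matrix(
            math.radians(30.0), [1.0, 0.0, 0.0]
        )
        # rotate labels about the pole axis: relabel by rotated-frame z
        normal = rot[:3, :3] @ np.array([0.0, 0.0, 1.0])
        apical = lm.mesh.triangles_center @ normal > 0
        lm2 = LabeledMesh(
            lm.mesh, np.where(apical, "apical", "basolateral").astype(object)
        )
        poles = np.array([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        plane, _, _ = extract_apical_plane(lm2, poles)
        cosang = abs(np.dot(plane.normal, normal))
        assert math.degrees(math.acos(min(cosang, 1.0))) < 2.0
        assert plane.separation_score > 0.99

    def test_random_labels_have_no_planar_signal(self):
        lm, _ = make_labeled_mesh("icosphere", "random", seed=7, radius=10.0)
        poles = np.array([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="separation"):
            plane, _, _ = extract_apical_plane(lm, poles)
        assert plane.separation_score < 0.6

    def test_coincident_and_outside_poles_rejected(self):
        lm, _ = make_labeled_mesh("icosphere", "hemisphere", radius=10.0)
        with pytest.raises(InvalidShapeError):
            extract_apical_plane(lm, np.array([[1.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(InvalidShapeError):
            extract_apical_plane(lm, np.array([[0, 0, 0], [20.0, 0, 0]]))


class TestMeshIO:
    def test_off_with_sidecar_round_trip(self, tmp_path):
        lm, _ = make_labeled_mesh("icosphere", "cap_fraction", subdivisions=2)
        path = tmp_path / "cell.off"
        label_path = save_labeled_mesh(lm, path)
        back = load_labeled_mesh(path, labels=label_path)
        np.testing.assert_allclose(back.mesh.vertices, lm.mesh.vertices, atol=1e-5)
        np.testing.assert_array_equal(back.mesh.faces, lm.mesh.faces)
        assert (back.face_label == lm.face_label).all()

    def test_missing_labels_rejected(self, tmp_path):
        lm, _ = make_labeled_mesh("icosphere", "hemisphere", subdivisions=2)
        path = tmp_path / "cell.off"
        save_labeled_mesh(lm, path)
        with pytest.raises(MeshLabelError):
            load_labeled_mesh(path)
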