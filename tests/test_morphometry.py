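"""Cross-sections, centroid splines, canal splitting and the nine parameters."""

import numpy as np
import pytest
import trimesh

from sccmorph import morphometry as mm
from sccmorph import phantom as ph
from sccmorph import segment as sg
from sccmorph.sections import slice_loops


def tube_mesh(radius_fn, length=16.0, n_axial=400, n_circ=96):
    """Parametric tube along +z with a varying radius profile."""
    z = np.linspace(0, length, n_axial)
    th = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    r = np.atleast_1d(radius_fn(z / length))
    verts = np.array([
        [ri * np.cos(t), ri * np.sin(t), zi]
        for zi, ri in zip(z, np.broadcast_to(r, z.shape))
        for t in th
    ])
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces += [[a, b, d], [a, d, c]]
    return trimesh.Trimesh(verts, np.array(faces), process=False)


class TestResliceDivisions:
    def test_cylinder_sections_match_circle_area(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=20.0, sections=256)
        path = np.stack([np.zeros(9), np.zeros(9), np.linspace(-8, 8, 9)], 1)
        secs = mm.reslice_divisions(cyl, path, spacing=0.5)
        areas = np.array([s.area_mm2 for s in secs])
        assert np.allclose(areas, np.pi, rtol=0.02)

    def test_oblique_cut_gives_ellipse_area(self):
        # a 60-degree oblique plane through a cylinder: area pi / cos(60)
        cyl = trimesh.creation.cylinder(radius=1.0, height=20.0, sections=256)
        n = np.array([0.0, np.sin(np.radians(60)), np.cos(np.radians(60))])
        loops = slice_loops(cyl.vertices, cyl.faces, np.zeros(3), n)
        assert len(loops) == 1
        assert loops[0].area == pytest.approx(2 * np.pi, rel=0.02)

    def test_division_count_follows_arc_length(self):
        tor = trimesh.creation.torus(major_radius=3.2, minor_radius=0.6,
                                     major_sections=256, minor_sections=48)
        th = np.linspace(0, 1.5 * np.pi, 60)
        path = np.stack([3.2 * np.cos(th), 3.2 * np.sin(th),
                         np.zeros_like(th)], 1)
        secs = mm.reslice_divisions(tor, path, spacing=0.25)
        L = 3.2 * 1.5 * np.pi
        assert len(secs) == int(np.floor(L / 0.25)) + 1

    def test_too_many_misses_raise(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=4.0, sections=64)
        path = np.stack([np.zeros(9), np.zeros(9), np.linspace(-10, 10, 9)], 1)
        with pytest.raises(ValueError, match="divisions missed"):
            mm.reslice_divisions(cyl, path, spacing=2.0)

    def test_polygon_is_closed_planar_loop(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=8.0, sections=128)
        path = np.stack([np.zeros(5), np.zeros(5), np.linspace(-3, 3, 5)], 1)
        secs = mm.reslice_divisions(cyl, path, spacing=1.5,
                                    return_polygons=True)
        poly = secs[0].polygon
        assert poly is not None and len(poly) >= 8
        # planar within tolerance
        z = poly @ secs[0].normal
        assert np.ptp(z) < 1e-6


class TestCentroidSpline:
    def test_straight_tube_centerline_on_axis(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=20.0, sections=256)
        path = np.stack([np.zeros(9), np.zeros(9), np.linspace(-8, 8, 9)], 1)
        secs = mm.reslice_divisions(cyl, path, spacing=0.5)
        line, _ = mm.centroid_spline(secs, spacing=0.5)
        assert np.abs(line.samples[:, :2]).max() < 1e-3

    def test_sample_spacing_is_uniform(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=20.0, sections=256)
        path = np.stack([np.zeros(9), np.zeros(9), np.linspace(-8, 8, 9)], 1)
        secs = mm.reslice_divisions(cyl, path, spacing=0.5)
        line, _ = mm.centroid_spline(secs, spacing=0.25)
        d = np.linalg.norm(np.diff(line.samples, axis=0), axis=1)
        assert np.allclose(d, 0.25, atol=0.01)

    def test_torus_centerline_radius(self, labyrinth_028, segmented_028,
                                     approx_paths_028):
        # centroid spline of the voxelized lateral canal lies on the ring
        mesh = segmented_028["mesh"]
        lab = labyrinth_028["lab"]
        g = lab.canals["lateral"]
        segs = mm.split_canals(mesh, {"lateral": approx_paths_028["lateral"]},
                               "R", mm.MorphometryConfig())
        samples = segs["lateral"].centerline.samples
        radii = np.linalg.norm(
            (samples - g.ring_center) - np.outer((samples - g.ring_center)
                                                 @ g.plane_normal,
                                                 g.plane_normal), axis=1)
        # junction-adjacent samples genuinely bend toward the vestibule
        # mouth; the canal proper must track the ring within half a voxel
        assert np.abs(radii[4:-4] - g.ring_radius_mm).max() < 0.5 * 0.28

    def test_refinement_improves_perturbed_path(self, labyrinth_028,
                                                segmented_028):
        mesh = segmented_028["mesh"]
        lab = labyrinth_028["lab"]
        g = lab.canals["lateral"]
        t = np.linspace(0.1, 0.9, 25)
        truth_pts = g.points(t)
        # perturb the operator path by a smooth 0.4 mm wobble
        wob = 0.4 * np.sin(6 * np.pi * t)
        path = truth_pts + wob[:, None] * g.plane_normal

        def deviation(refine):
            secs = mm.reslice_divisions(mesh, path, 0.25)
            line, _ = mm.centroid_spline(secs, 0.25, mesh=mesh, refine=refine)
            d, tt = g.distance_to_arc(line.samples)
            return d.mean()

        assert deviation(2) <= deviation(0) + 0.02

    def test_self_intersecting_path_rejected(self):
        cyl = trimesh.creation.cylinder(radius=3.0, height=4.0, sections=128)
        th = np.linspace(0, 4 * np.pi, 60)  # loops twice over itself
        secs = [mm.CrossSection(np.array([2 * np.cos(a), 2 * np.sin(a),
                                          0.001 * a]),
                                np.array([0, 0, 1.0]), 1.0)
                for a in th]
        with pytest.raises(ValueError, match="self-intersect"):
            mm.centroid_spline(secs, spacing=0.25)


class TestSplitCanals:
    def test_endpoints_near_truth_junctions(self, labyrinth_028,
                                            segmented_028, approx_paths_028):
        mesh = segmented_028["mesh"]
        truth = labyrinth_028["truth"]
        segs = mm.split_canals(mesh, approx_paths_028, "R",
                               mm.MorphometryConfig())
        for canal, seg in segs.items():
            tj = truth.canals[("R", canal)].junction_points
            ends = np.array(seg.endpoints)
            d = np.linalg.norm(ends[:, None] - tj[None], axis=-1)
            # each detected endpoint matches one truth junction crossing;
            # the area-threshold rule fires where the lumen merges with the
            # junction mouth, up to ~1 mm before the blob-surface crossing
            assert d.min(axis=1).max() < 1.0

    def test_superior_posterior_share_common_crus(self, segmented_028,
                                                  approx_paths_028):
        segs = mm.split_canals(segmented_028["mesh"], approx_paths_028, "R",
                               mm.MorphometryConfig())
        es = np.array(segs["superior"].endpoints)
        ep = np.array(segs["posterior"].endpoints)
        d = np.linalg.norm(es[:, None] - ep[None], axis=-1)
        assert d.min() < 0.5

    def test_isolated_tubes_raise_no_junction(self):
        cyl = trimesh.creation.cylinder(radius=0.6, height=12.0, sections=64)
        path = np.stack([np.zeros(9), np.zeros(9), np.linspace(-5, 5, 9)], 1)
        with pytest.raises(ValueError, match="no junction"):
            mm.split_canals(cyl, {"lateral": path}, "R",
                            mm.MorphometryConfig(division_spacing=0.5))


class TestMinCsa:
    def test_constant_radius_tube(self):
        mesh = tube_mesh(lambda s: np.full_like(s, 0.6))
        path = np.stack([np.zeros(9), np.zeros(9), np.linspace(1, 15, 9)], 1)
        secs = mm.reslice_divisions(mesh, path, 0.25)
        line, secs = mm.centroid_spline(secs, 0.25)
        seg = mm.CanalSegment("lateral", "R", line, secs,
                              (secs[0].center_mm, secs[-1].center_mm))
        assert mm.min_csa(seg) == pytest.approx(np.pi * 0.36, rel=0.02)

    def test_sinusoidal_radius_minimum(self):
        mesh = tube_mesh(lambda s: 0.7 + 0.3 * np.sin(2 * np.pi * s))
        path = np.stack([np.zeros(17), np.zeros(17), np.linspace(0.5, 15.5, 17)], 1)
        secs = mm.reslice_divisions(mesh, path, 0.25)
        line, secs = mm.centroid_spline(secs, 0.25)
        seg = mm.CanalSegment("lateral", "R", line, secs,
                              (secs[0].center_mm, secs[-1].center_mm))
        assert mm.min_csa(seg) == pytest.approx(np.pi * 0.16, rel=0.05)

    def test_dilated_end_does_not_change_minimum(self):
        base = tube_mesh(lambda s: np.full_like(s, 0.6))
        flared = tube_mesh(lambda s: 0.6 + 1.2 * np.clip(s - 0.85, 0, None) / 0.15)
        for mesh in (base, flared):
            path = np.stack([np.zeros(9), np.zeros(9), np.linspace(1, 12, 9)], 1)
            secs = mm.reslice_divisions(mesh, path, 0.25)
            line, secs2 = mm.centroid_spline(secs, 0.25)
            seg = mm.CanalSegment("lateral", "R", line, secs2,
                                  (secs2[0].center_mm, secs2[-1].center_mm))
            assert mm.min_csa(seg) == pytest.approx(np.pi * 0.36, rel=0.03)


class TestMidlineDistance:
    def test_max_abs_x(self):
        pts = np.array([[1.0, 0, 0], [-43.8, 2, 1], [42.0, 0, 0]])
        assert mm.midline_distance(pts) == pytest.approx(43.8)

    def test_translation_shifts_distance_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3)) + [40, 0, 0]
        d0 = mm.midline_distance(pts)
        d1 = mm.midline_distance(pts + [1.0, 0, 0])
        assert d1 - d0 == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def bilateral():
    """Mirror-symmetric bilateral phantom, measured end to end."""
    labs = {
        "R": ph.make_labyrinth("R", [39.5, 0, 0], 3.2, 0.6,
                               lateral_inclination_deg=5.0),
        "L": ph.make_labyrinth("L", [-39.5, 0, 0], 3.2, 0.6,
                               lateral_inclination_deg=5.0),
    }
    meshes, masks, intens, paths = {}, {}, {}, {}
    for side, lab in labs.items():
        spec = ph.PhantomSpec({side: lab}, voxel_spacing_mm=0.28,
                              noise_sd=0.0, seed=1)
        img, _ = ph.generate_intensity_phantom(spec)
        mesh, mask = sg.two_pass_surface(img, return_mask=True)
        meshes[side], masks[side], intens[side] = mesh, mask, img
        paths[side] = {n: g.points(np.linspace(0, 1, 25))
                       for n, g in lab.canals.items()}
    table = mm.measure_subject(meshes, paths, "phantom", masks=masks,
                               intensities=intens)
    return table.pivot(index="parameter", columns="side", values="value")

class TestMeasureSubject:
    def test_symmetric_phantom_has_no_side_differences(self, bilateral):
        diff = bilateral["R"] - bilateral["L"]
        for p in ("angle_lateral_superior", "angle_superior_posterior",
                  "angle_lateral_posterior", "lateral_inclination"):
            assert abs(diff[p]) < 0.5
        # the two sides are voxelized on independent lattices, so mirror
        # symmetry holds to about half a voxel
        for p in ("midline_distance_lateral", "midline_distance_posterior"):
            assert abs(diff[p]) < 0.15
        for p in ("min_csa_lateral", "min_csa_superior", "min_csa_posterior"):
            assert abs(diff[p]) / bilateral.loc[p, "R"] < 0.05

    def test_orthogonal_canal_angles_near_90(self, bilateral):
        # the default triad is orthogonal; the 5-degree lateral tilt moves
        # the lateral-superior / lateral-posterior angles off 90 by
        # +-5/sqrt(2) degrees
        off = 5.0 / np.sqrt(2)
        assert bilateral.loc["angle_superior_posterior", "R"] == pytest.approx(
            90.0, abs=1.0)
        assert bilateral.loc["angle_lateral_superior", "R"] == pytest.approx(
            90.0 + off, abs=1.0)
        assert bilateral.loc["angle_lateral_posterior", "R"] == pytest.approx(
            90.0 - off, abs=1.0)

    def test_inclination_recovered_within_one_degree(self, bilateral):
        for side in ("R", "L"):
            assert bilateral.loc["lateral_inclination", side] == pytest.approx(
                5.0, abs=1.0)

    def test_min_csa_within_10pct(self, bilateral):
        for p in ("min_csa_lateral", "min_csa_superior", "min_csa_posterior"):
            for side in ("R", "L"):
                assert bilateral.loc[p, side] == pytest.approx(
                    np.pi * 0.36, rel=0.10)

    def test_midline_distance_within_one_voxel(self, bilateral, ):
        labs = ph.make_labyrinth("R", [39.5, 0, 0], 3.2, 0.6,
                                 lateral_inclination_deg=5.0)
        spec = ph.PhantomSpec({"R": labs}, voxel_spacing_mm=0.28)
        _, truth = ph.generate_canal_phantom(spec)
        for p, canal in (("midline_distance_lateral", "lateral"),
                         ("midline_distance_posterior", "posterior")):
            expect = truth.canals[("R", canal)].max_abs_x_mm
            assert bilateral.loc[p, "R"] == pytest.approx(expect, abs=0.28)


class TestMeasuredTiltDifference:
    def test_lateral_tilt_asymmetry_recovered(self):
        # left lateral canal 4.1 deg more horizontal than the right
        meshes, masks, intens, paths = {}, {}, {}, {}
        for side, tilt in (("R", 5.0), ("L", 0.9)):
            sgn = 1.0 if side == "R" else -1.0
            lab = ph.make_labyrinth(side, [sgn * 39.5, 0, 0], 3.2, 0.6,
                                    lateral_inclination_deg=tilt)
            spec = ph.PhantomSpec({side: lab}, voxel_spacing_mm=0.28,
                                  noise_sd=0.0, seed=2)
            img, _ = ph.generate_intensity_phantom(spec)
            mesh, mask = sg.two_pass_surface(img, return_mask=True)
            meshes[side], masks[side], intens[side] = mesh, mask, img
            paths[side] = {n: g.points(np.linspace(0, 1, 25))
                           for n, g in lab.canals.items()}
        table = mm.measure_subject(meshes, paths, "tilted", masks=masks,
                                   intensities=intens)
        w = table.pivot(index="parameter", columns="side", values="value")
        diff = w.loc["lateral_inclination", "R"] - w.loc["lateral_inclination", "L"]
        assert diff == pytest.approx(4.1, abs=1.0)
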