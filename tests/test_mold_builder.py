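"""Smoothing, iso-surfacing, mesh simplification, slice plans and carving."""

import numpy as np
import pytest
import trimesh

from renalmold.mold_builder import (
    MoldSpec,
    SlicePlan,
    build_slice_plan,
    carve_mold,
    decimate_mesh,
    export_stl,
    extract_surface,
    laplacian_smooth,
    simplify_mesh,
    smooth_outline,
    taubin_smooth,
)
from conftest import sphere_mask


class TestSmoothOutline:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(1)
        mask = rng.random((10, 10, 10)) < 0.3
        _, out = smooth_outline(mask, 1.0, 0.0)
        assert np.array_equal(out, mask)

    @pytest.mark.parametrize("radius,sigma", [(20.0, 2.0), (15.0, 1.0)])
    def test_sphere_volume_matches_curvature_flow_prediction(self, radius, sigma):
        """Gaussian blur + 0.5 threshold shrinks a sphere's radius by about
        sigma^2/R (mean-curvature motion); the measured volume must match
        that continuum prediction within 1%, and the op's 10% contract."""
        mask, _ = sphere_mask(radius, 1.0)
        _, out = smooth_outline(mask, 1.0, sigma)
        analytic = 4 / 3 * np.pi * radius**3
        predicted = 4 / 3 * np.pi * (radius - sigma**2 / radius) ** 3
        assert abs(out.sum() - predicted) / analytic < 0.015
        assert abs(out.sum() - analytic) / analytic < 0.10

    def test_well_separated_spheres_stay_two_components(self):
        from scipy import ndimage
        f = np.zeros((40, 80, 40), bool)
        X, Y, Z = np.mgrid[0:40, 0:80, 0:40]
        f |= (X - 20) ** 2 + (Y - 25) ** 2 + (Z - 20) ** 2 <= 8**2
        f |= (X - 20) ** 2 + (Y - 55) ** 2 + (Z - 20) ** 2 <= 8**2
        _, out = smooth_outline(f, 1.0, 2.0)  # separation 30 mm > 6 sigma
        assert ndimage.label(out)[1] == 2

    def test_annihilation_raises(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[10, 10, 10] = True
        with pytest.raises(ValueError, match="sigma"):
            smooth_outline(mask, 1.0, 5.0)


class TestExtractSurface:
    def test_single_voxel_cube_supersampled_volume(self):
        """Plain marching cubes renders one voxel as a 1/6 mm^3 octahedron;
        order-0 supersampling recovers the voxel cube volume."""
        f = np.zeros((5, 5, 5))
        f[2, 2, 2] = 1.0
        octa = extract_surface(f, 1.0, 0.5)
        assert octa.is_watertight
        assert abs(octa.volume - 1 / 6) < 1e-9
        cube = extract_surface(f, 1.0, 0.5, supersample=4)
        assert cube.is_watertight
        assert abs(cube.volume - 1.0) < 0.1

    def test_sphere_volume_within_5pct(self):
        mask, _ = sphere_mask(15.0, 1.0)
        mesh = extract_surface(mask.astype(float), 1.0, 0.5)
        analytic = 4 / 3 * np.pi * 15.0**3
        assert abs(mesh.volume - analytic) / analytic < 0.05
        assert mesh.is_watertight

    def test_smoothed_sphere_area_within_5pct(self):
        mask, _ = sphere_mask(15.0, 1.0)
        fld, _ = smooth_outline(mask, 1.0, 1.5)
        mesh = extract_surface(fld, 1.0, 0.5)
        analytic = 4 * np.pi * 15.0**2
        assert abs(mesh.area - analytic) / analytic < 0.05

    def test_genus_zero_topology(self):
        mask, _ = sphere_mask(8.0, 1.0)
        mesh = extract_surface(mask.astype(float), 1.0, 0.5)
        assert mesh.euler_number == 2  # V - E + F of a topological sphere

    def test_empty_iso_surface_raises(self):
        with pytest.raises(ValueError, match="iso"):
            extract_surface(np.zeros((4, 4, 4)), 1.0, 0.5)

    def test_world_placement_honors_origin_and_spacing(self):
        mask, aff = sphere_mask(10.0, 2.0)
        mesh = extract_surface(mask.astype(float), 2.0, 0.5, origin=aff[:3, 3])
        c = mesh.vertices.mean(axis=0)
        assert np.max(np.abs(c)) < 0.5  # centered sphere stays centered


class TestSimplify:
    def test_all_zero_passes_are_identity(self):
        mesh = trimesh.creation.icosphere(3, radius=10.0)
        out = simplify_mesh(mesh, target_faces=len(mesh.faces),
                            laplacian_iters=0, taubin_iters=0)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_taubin_preserves_volume_while_laplacian_shrinks(self):
        mask, _ = sphere_mask(15.0, 1.0)
        mesh = extract_surface(mask.astype(float), 1.0, 0.5)
        t = taubin_smooth(mesh, 0.5, -0.53, 50)
        l = laplacian_smooth(mesh, 0.5, 50)
        assert abs(t.volume - mesh.volume) / mesh.volume < 0.02
        shrink = (mesh.volume - l.volume) / mesh.volume
        assert shrink > abs(t.volume - mesh.volume) / mesh.volume
        assert shrink > 0.05

    def test_taubin_parameter_scheme_enforced(self):
        mesh = trimesh.creation.icosphere(2)
        with pytest.raises(ValueError, match="mu"):
            taubin_smooth(mesh, 0.5, 0.53, 5)
        with pytest.raises(ValueError, match="mu"):
            taubin_smooth(mesh, 0.5, -0.4, 5)

    def test_decimation_stays_on_the_sphere(self):
        """20k-face sphere to 500 faces: every point of the decimated mesh
        stays within 1 mm of the analytic surface (brute-force point
        sampling oracle), watertight throughout."""
        mesh = trimesh.creation.icosphere(5, radius=15.0)
        dec = decimate_mesh(mesh, 500)
        assert len(dec.faces) <= 500
        assert dec.is_watertight
        pts = np.vstack([
            dec.vertices,
            dec.triangles_center,
            dec.vertices[dec.edges_unique].mean(axis=1),
        ])
        assert np.abs(np.linalg.norm(pts, axis=1) - 15.0).max() < 1.0


class TestSlicePlan:
    def test_seven_planes_bracketing_28mm_tumor(self):
        mask = np.zeros((29, 3, 3), bool)
        mask[:, 1, 1] = True  # tumor spanning [-14, +14] at origin -14
        plan = build_slice_plan(mask, -14.0, 1.0, 7.0, 0.0)
        assert np.allclose(plan.positions, [-21, -14, -7, 0, 7, 14, 21])
        assert np.array_equal(plan.labels, np.arange(1, 8))

    def test_offset_shifts_all_planes(self):
        # translating the tumor and the alignment offset together translates
        # the whole plan
        mask = np.zeros((29, 3, 3), bool)
        mask[:, 1, 1] = True
        plan = build_slice_plan(mask, -14.0 + 3.5, 1.0, 7.0, 3.5)
        assert np.allclose(plan.positions,
                           np.array([-21, -14, -7, 0, 7, 14, 21]) + 3.5)

    def test_random_extents_covered_with_exact_spacing(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            h = float(rng.uniform(2.0, 9.0))
            off = float(rng.uniform(-5, 5))
            o = float(rng.uniform(-40, 0))
            mask = np.zeros((n, 2, 2), bool)
            mask[:, 0, 0] = True
            smin, smax = o, o + (n - 1) * 1.0
            plan = build_slice_plan(mask, o, 1.0, h, off)
            if len(plan.positions) == 1:
                continue
            d = np.diff(plan.positions)
            assert np.allclose(d, h, atol=1e-9)
            # direct recomputation: planes bracket the extent
            assert plan.positions[0] < smin + 1e-9
            assert plan.positions[-1] > smax - 1e-9
            interior = plan.positions[1:-1]
            assert np.all(interior >= smin - 1e-9)
            assert np.all(interior <= smax + 1e-9)

    def test_thin_tumor_gets_single_central_plane_with_warning(self):
        mask = np.zeros((3, 2, 2), bool)
        mask[:, 0, 0] = True
        with pytest.warns(UserWarning, match="single central plane"):
            plan = build_slice_plan(mask, 2.0, 1.0, 10.0, 0.0)
        assert len(plan.positions) == 1
        assert plan.positions[0] == pytest.approx(3.0)  # mid-extent of [2, 4]

    def test_unequal_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            SlicePlan(positions=[0.0, 5.0, 11.0], spacing=5.0)


def _sphere_mold(radius=16.0, spacing=1.0, spec=None, plan=None, **kw):
    mask, aff = sphere_mask(radius, spacing, pad_mm=4.0)
    origin = np.full(3, aff[0, 3])
    spec = spec or MoldSpec()
    if plan is None:
        plan = build_slice_plan(mask, origin[0], spacing, spec.slice_spacing_mm)
    lm = {"hilum": np.array([-9.0, -6.0, -radius]),
          "tumor_contact": np.array([9.0, 6.0, -radius])}
    kw.setdefault("build_mesh", False)
    return carve_mold(mask, lm, spec, plan, origin=origin, spacing_mm=spacing,
                      **kw), mask, origin


class TestCarveMold:
    def test_cavity_is_vertical_shadow_of_smoothed_outline(self):
        model, mask, origin = _sphere_mold(sigma_mm=2.0)
        _, sm = smooth_outline(mask, 1.0, 2.0)
        occ = model.cavity_occupancy
        # brute-force constructive oracle inside the outline bounding box
        idx = np.argwhere(sm)
        lo = idx.min(axis=0)
        off = np.rint((origin + lo - model.origin)).astype(int)
        sub = sm[lo[0]:idx[:, 0].max() + 1, lo[1]:idx[:, 1].max() + 1,
                 lo[2]:idx[:, 2].max() + 1]
        for i in range(0, sub.shape[0], 3):
            for j in range(0, sub.shape[1], 3):
                col = sub[i, j]
                if not col.any():
                    continue
                zlow = int(np.argmax(col))
                mold_col = occ[i + off[0], j + off[1]]
                # empty from the outline's lowest surface to the top
                assert not mold_col[off[2] + zlow:].any()
                # solid base right below the cavity floor
                assert mold_col[off[2] + zlow - 1]

    def test_base_opening_is_two_cm_disc(self):
        model, _, _ = _sphere_mold()
        base = model.cavity_occupancy[:, :, 0] & ~model.occupancy[:, :, 0]
        from scipy import ndimage
        lab, n = ndimage.label(base)
        assert n == 2
        for h in range(1, 3):
            area = (lab == h).sum()
            d_eq = 2 * np.sqrt(area / np.pi)
            assert abs(d_eq - 20.0) <= 1.0  # 2 cm within one voxel

    def test_slot_scan_empty_above_bridge_intact_below(self):
        spec = MoldSpec()
        model, _, _ = _sphere_mold(spec=spec)
        sp = model.spacing
        bridge = round(spec.slot_bridge_mm / sp)
        # columns drilled by the landmark holes are exempt below the bridge
        holes2d = model.cavity_occupancy[:, :, 0] & ~model.occupancy[:, :, 0]
        for pos in model.plan.positions:
            i = int(round((pos - spec.slot_width_mm / 2 - model.origin[0]) / sp))
            band = slice(i, i + round(spec.slot_width_mm / sp))
            # direct voxel scan: nothing above the bridge, bridge intact
            assert not model.occupancy[band, :, bridge:].any()
            keep = ~holes2d[band]
            below = model.occupancy[band, :, :bridge]
            ref = model.cavity_occupancy[band, :, :bridge]
            assert np.array_equal(below[keep], ref[keep])
            assert below.any()

    def test_interslot_spacing_exact(self):
        model, _, _ = _sphere_mold()
        d = np.diff(model.slot_centers)
        assert np.allclose(d, model.plan.spacing, atol=1e-9)

    def test_conservation_mold_disjoint_from_outline(self):
        model, mask, origin = _sphere_mold(sigma_mm=2.0)
        _, sm = smooth_outline(mask, 1.0, 2.0)
        idx = np.argwhere(sm)
        off = np.rint(origin - model.origin).astype(int)
        occ_at_outline = model.occupancy[tuple((idx + off).T)]
        assert not occ_at_outline.any()

    def test_landmark_hole_outside_block_rejected(self):
        mask, aff = sphere_mask(16.0, 1.0, pad_mm=4.0)
        origin = np.full(3, aff[0, 3])
        spec = MoldSpec()
        plan = build_slice_plan(mask, origin[0], 1.0, spec.slice_spacing_mm)
        lm = {"hilum": np.array([-6.0, -4.0, -16.0]),
              "tumor_contact": np.array([80.0, 0.0, -16.0])}
        with pytest.raises(ValueError, match="tumor_contact"):
            carve_mold(mask, lm, spec, plan, origin=origin, spacing_mm=1.0,
                       build_mesh=False)

    def test_guide_comb_notches_count_teeth(self):
        spec = MoldSpec()
        model, _, _ = _sphere_mold(spec=spec)
        sp = model.spacing
        top = model.occupancy.shape[2] - 1
        n_slot = round(spec.slot_width_mm / sp)
        edges = [int(round((p + spec.slot_width_mm / 2 - model.origin[0]) / sp))
                 for p in model.plan.positions]
        # the tooth after slot k carries k tick marks along the comb depth
        for k in (1, 2, 3):
            start = edges[k - 1]
            end = edges[k] - n_slot if k < len(edges) else model.occupancy.shape[0]
            row = (start + end - 1) // 2
            cols = np.flatnonzero(model.guide_region[row])
            strip = model.occupancy[row, cols, top]
            runs = int(np.sum(np.diff(np.concatenate(
                [[0], (~strip).astype(int), [0]])) == 1))
            assert runs == k

    def test_mesh_volume_close_to_occupancy(self, small_mold):
        model = small_mold.model
        assert model.mesh.is_watertight
        assert abs(model.mesh.volume - model.voxel_volume_mm3) \
            / model.voxel_volume_mm3 < 0.05


class TestExportStl:
    def test_unit_cube_round_trip(self, tmp_path):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        p = tmp_path / "cube.stl"
        export_stl(cube, p)
        back = trimesh.load(str(p))
        assert len(back.faces) == 12
        assert abs(back.volume - 1.0) < 1e-9

    def test_binary_round_trip_volume_exact(self, tmp_path, small_mold):
        mesh = small_mold.model.mesh
        p = tmp_path / "mold.stl"
        export_stl(mesh, p)
        back = trimesh.load(str(p))
        assert abs(back.volume - mesh.volume) / mesh.volume < 1e-6

    def test_ascii_and_binary_have_identical_vertex_multisets(self, tmp_path):
        mesh = trimesh.creation.icosphere(2, radius=7.0)
        pb = tmp_path / "b.stl"
        pa = tmp_path / "a.stl"
        export_stl(mesh, pb)
        export_stl(mesh, pa, ascii_format=True)
        vb = trimesh.load(str(pb), process=False).triangles.reshape(-1, 3)
        va = trimesh.load(str(pa), process=False).triangles.reshape(-1, 3)
        vb = np.array(sorted(map(tuple, np.round(vb, 5))))
        va = np.array(sorted(map(tuple, np.round(va, 5))))
        assert np.allclose(vb, va, atol=1e-4)

    def test_non_watertight_refused(self, tmp_path):
        mesh = trimesh.creation.icosphere(2)
        open_mesh = trimesh.Trimesh(mesh.vertices, mesh.faces[:-5],
                                    process=False)
        with pytest.raises(ValueError, match="watertight"):
            export_stl(open_mesh, tmp_path / "bad.stl")
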