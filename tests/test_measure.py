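import numpy as np
import pytest
import trimesh

from acroplan import corridor, measure, screw_fit
from acroplan.errors import AcroplanError, DegenerateInputError
from acroplan.measure import LandmarkSet, ReferencePlane


def flat_top_mesh(noise=0.0, seed=0):
    """Box subdivided so its top face carries a proper vertex patch."""
    mesh = trimesh.creation.box(extents=(10, 10, 4))
    for _ in range(3):
        mesh = mesh.subdivide()
    if noise:
        rng = np.random.default_rng(seed)
        top = mesh.vertices[:, 2] > 1.99
        v = mesh.vertices.copy()
        v[top, 2] += rng.uniform(-noise, noise, top.sum())
        mesh = trimesh.Trimesh(v, mesh.faces, process=False)
    patch = np.nonzero(mesh.vertices[:, 2] > 1.9)[0]
    lm = LandmarkSet(ac_facet=[-5, 0, 0], anterior_edge=[5, 0, 0], superior_patch=patch)
    return mesh, lm


def make_screw(entry, direction, diameter=4.0, length=40.0, side="medial"):
    return screw_fit.ScrewPlan(side=side, entry=np.asarray(entry, float),
                               direction=corridor.unitize(direction),
                               diameter=diameter, length=length,
                               center_uv=np.zeros(2))


class TestFitPlaneA:
    def test_flat_patch_exact(self):
        mesh, lm = flat_top_mesh()
        plane = measure.fit_plane_A(mesh, lm)
        assert abs(plane.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert plane.normal[2] > 0  # oriented outward (superior)

    def test_noisy_patch_within_one_degree(self):
        mesh, lm = flat_top_mesh(noise=0.1, seed=1)
        plane = measure.fit_plane_A(mesh, lm)
        ang = np.degrees(np.arccos(abs(plane.normal @ [0, 0, 1])))
        assert ang <= 1.0

    def test_tiny_patch_rejected(self):
        mesh, lm = flat_top_mesh()
        lm2 = LandmarkSet(lm.ac_facet, lm.anterior_edge, lm.superior_patch[:2])
        with pytest.raises(DegenerateInputError):
            measure.fit_plane_A(mesh, lm2)

    def test_collinear_patch_rejected(self):
        mesh, lm = flat_top_mesh()
        verts = mesh.vertices[lm.superior_patch]
        on_line = lm.superior_patch[np.abs(verts[:, 1]) < 1e-9]
        if len(on_line) >= 3:
            lm2 = LandmarkSet(lm.ac_facet, lm.anterior_edge, on_line)
            with pytest.raises(DegenerateInputError):
                measure.fit_plane_A(mesh, lm2)


class TestPlaneB:
    def frame(self, d, spacing=0.5):
        d = corridor.unitize(d)
        u, v = corridor._orthonormal_basis(d)
        return corridor.ProjectionFrame(center=np.zeros(3), u=u, v=v, d=d,
                                        spacing=spacing, u0=-5, v0=-5, nu=20, nv=20)

    def zone(self, frame):
        from shapely.geometry import Point
        return screw_fit.SafeZone(polygon=Point(0, 0).buffer(3.0), frame=frame)

    def test_canonical_construction(self):
        plane_a = ReferencePlane(point=np.zeros(3), normal=[0, 0, 1])
        frame = self.frame([0, 1, 0])
        plane_b = measure.define_plane_B(plane_a, self.zone(frame), frame)
        assert abs(plane_b.normal @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_equivariance(self):
        R = trimesh.transformations.rotation_matrix(0.8, [1, 0.4, 0.2])[:3, :3]
        plane_a = ReferencePlane(point=np.zeros(3), normal=[0, 0, 1])
        frame = self.frame([0, 1, 0])
        nb = measure.define_plane_B(plane_a, self.zone(frame), frame).normal

        plane_a2 = ReferencePlane(point=np.zeros(3), normal=R @ [0, 0, 1])
        f = frame
        frame2 = corridor.ProjectionFrame(center=R @ f.center, u=R @ f.u, v=R @ f.v,
                                          d=R @ f.d, spacing=f.spacing,
                                          u0=f.u0, v0=f.v0, nu=f.nu, nv=f.nv)
        nb2 = measure.define_plane_B(plane_a2, self.zone(frame2), frame2).normal
        assert abs(nb2 @ (R @ nb)) == pytest.approx(1.0, abs=1e-9)

    def test_pathological_direction_rejected(self):
        plane_a = ReferencePlane(point=np.zeros(3), normal=[0, 0, 1])
        frame = self.frame([0, 0, 1])
        with pytest.raises(DegenerateInputError):
            measure.define_plane_B(plane_a, self.zone(frame), frame)

    def test_reference_axis_sets_beta(self):
        """With the anatomical axis as reference, beta is the mediolateral tilt."""
        plane_a = ReferencePlane(point=np.zeros(3), normal=[0, 0, 1])
        tilt = np.radians(7.0)
        d = corridor.unitize([np.sin(tilt), np.cos(tilt), 0])
        frame = self.frame(d)
        plane_b = measure.define_plane_B(plane_a, self.zone(frame), frame,
                                         reference_dir=[0, 1, 0])
        assert measure.screw_plane_angle(d, plane_b) == pytest.approx(7.0, abs=1e-6)
        # default reference (the corridor itself) makes beta vanish
        plane_b0 = measure.define_plane_B(plane_a, self.zone(frame), frame)
        assert measure.screw_plane_angle(d, plane_b0) == pytest.approx(0.0, abs=1e-9)


class TestAnglesAndDistances:
    def test_screw_plane_angles(self):
        plane = ReferencePlane(point=np.zeros(3), normal=[0, 0, 1])
        assert measure.screw_plane_angle([1, 0, 0], plane) == pytest.approx(0.0)
        assert measure.screw_plane_angle([0, 0, 1], plane) == pytest.approx(90.0)
        assert measure.screw_plane_angle([0, 1, 1], plane) == pytest.approx(45.0)

    def test_landmark_distances(self):
        lm = LandmarkSet(ac_facet=[0, 0, 0], anterior_edge=[10, 0, 0],
                         superior_patch=np.arange(30))
        med = make_screw([3, 4, 0], [0, 0, 1], side="medial")
        lat = make_screw([0, 0, 0], [0, 0, 1], side="lateral")
        L1, L2, L3, L4 = measure.landmark_distances((med, lat), lm)
        assert L1 == pytest.approx(5.0)
        assert L3 == pytest.approx(0.0)
        assert L2 == pytest.approx(np.hypot(7, 4))
        assert L4 == pytest.approx(10.0)
        # swapping the screws swaps the (L1, L2) and (L3, L4) roles
        L1s, L2s, L3s, L4s = measure.landmark_distances((lat, med), lm)
        assert (L1s, L2s) == (L3, L4) and (L3s, L4s) == (L1, L2)

    def test_measurement_invariants_enforced(self):
        with pytest.raises(AcroplanError):
            measure.SubjectMeasurement("s", "M", ms_length=-1, ms_diameter=4,
                                       ls_length=40, ls_diameter=4, L1=1, L2=1,
                                       L3=1, L4=1, alpha=10, beta=5)
        with pytest.raises(AcroplanError):
            measure.SubjectMeasurement("s", "M", ms_length=40, ms_diameter=4,
                                       ls_length=40, ls_diameter=4, L1=1, L2=1,
                                       L3=1, L4=1, alpha=95, beta=5)


class TestMeasureSubject:
    def test_axial_screws_have_zero_downdip(self):
        mesh, lm = flat_top_mesh()
        plane_a = measure.fit_plane_A(mesh, lm)
        screws = (make_screw([0, 0, -2], [0, 1, 0], side="medial"),
                  make_screw([2, 0, -2], [0, 1, 0], side="lateral"))
        plane_b = ReferencePlane(point=np.zeros(3), normal=[1, 0, 0])
        row = measure.measure_subject(mesh, lm, screws, plane_a, plane_b)
        assert row.alpha == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        mesh, lm = flat_top_mesh()
        plane_a = measure.fit_plane_A(mesh, lm)
        screws = (make_screw([1, -5, 0], [0, 1, 0.1], side="medial"),
                  make_screw([-2, -5, 0], [0, 1, 0.1], side="lateral"))
        plane_b = ReferencePlane(point=np.zeros(3), normal=[1, 0, 0])
        row = measure.measure_subject(mesh, lm, screws, plane_a, plane_b)

        T = trimesh.transformations.rotation_matrix(1.1, [0.2, 1, 0.5], [3, -1, 2])
        R, t = T[:3, :3], T[:3, 3]
        mesh2 = mesh.copy()
        mesh2.apply_transform(T)
        lm2 = LandmarkSet(R @ lm.ac_facet + t, R @ lm.anterior_edge + t,
                          lm.superior_patch)
        screws2 = tuple(
            make_screw(R @ s.entry + t, R @ s.direction, s.diameter, s.length, s.side)
            for s in screws)
        pa2 = ReferencePlane(R @ plane_a.point + t, R @ plane_a.normal)
        pb2 = ReferencePlane(R @ plane_b.point + t, R @ plane_b.normal)
        row2 = measure.measure_subject(mesh2, lm2, screws2, pa2, pb2)
        for k in ("L1", "L2", "L3", "L4", "alpha", "beta"):
            assert getattr(row2, k) == pytest.approx(getattr(row, k), abs=1e-6)

    def test_alpha_recovers_generator_tilt(self, acromion_subject):
        """End-to-end alpha within 2 degrees of the generator's downdip."""
        import acroplan as ap

        subj = acromion_subject
        cfg = ap.PlannerConfig(spacing=0.5, search_spacing=0.8,
                               cone_half_angle=15, refine_tol=1.0)
        res = ap.ScrewPlanner(subj.mesh, subj.landmarks,
                              init_direction=np.asarray(subj.truth["hint_dir"]),
                              config=cfg).fit()
        assert res.measurement.alpha == pytest.approx(
            subj.truth["alpha_true_deg"], abs=2.0)


class TestLandmarkIO:
    def test_json_roundtrip(self, tmp_path):
        lm = LandmarkSet(ac_facet=[1, 2, 3], anterior_edge=[4, 5, 6],
                         superior_patch=np.arange(40))
        p = tmp_path / "lm.json"
        lm.save_json(p)
        back = LandmarkSet.load_json(p)
        assert np.allclose(back.ac_facet, lm.ac_facet)
        assert np.array_equal(back.superior_patch, lm.superior_patch)

    def test_invalid_file(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"ac_facet": [0,0,0]}')
        with pytest.raises(Exception):
            LandmarkSet.load_json(p)

    def test_validate_against_mesh(self, cylinder):
        mesh, lm = cylinder
        lm.validate(mesh)  # generator landmarks lie on the surface
        bad = LandmarkSet([50, 50, 50], lm.anterior_edge, lm.superior_patch)
        with pytest.raises(DegenerateInputError):
            bad.validate(mesh)
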