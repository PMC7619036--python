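"""Tests of the electrophysiology pipeline: surfaces, meshing, fibers,
Eikonal activation and pseudo-ECG synthesis."""

import numpy as np
import pytest
from scipy.spatial import Delaunay, cKDTree

from cardiovae import ep_pipeline as ep, synthetic_anatomy as sa


def sphere_cloud(n, radius, seed=0, center=(0, 0, 0)):
    u = np.random.default_rng(seed).normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return radius * u + np.asarray(center, dtype=float)


@pytest.fixture(scope="module")
def anatomy():
    p = sa.sample_population_params(1, 0.0, seed=1)[0]
    return sa.build_anatomy(p, 1024, seed=0)


@pytest.fixture(scope="module")
def surfaces(anatomy):
    lv_endo = ep.surface_from_cloud(anatomy.ed, sa.LV_ENDO)
    lv_epi = ep.surface_from_cloud(anatomy.ed, sa.LV_EPI)
    rv_endo = ep.surface_from_cloud(anatomy.ed, sa.RV_ENDO)
    rv_epi = ep.offset_rv_epicardium(rv_endo, 3.0)
    return lv_endo, lv_epi, rv_endo, rv_epi


@pytest.fixture(scope="module")
def assembly(surfaces):
    return ep.assemble_biventricular(*surfaces)


@pytest.fixture(scope="module")
def heart_mesh(assembly):
    mesh = ep.tetrahedralize(assembly, target_edge=3.5, seed=0)
    return ep.assign_fibers(mesh)


def slab_mesh(h=1.5, dims=(40, 20, 10), jitter=0.05, seed=0,
              fibers=((1, 0, 0), (0, 1, 0), (0, 0, 1))):
    """BCC-lattice Delaunay slab with constant fiber frames."""
    rng = np.random.default_rng(seed)
    ax = [np.arange(0, d + 1e-9, h) for d in dims]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), -1).reshape(-1, 3)
    ctr = grid + h / 2
    ctr = ctr[np.all(ctr < np.asarray(dims, dtype=float), axis=1)]
    pts = np.vstack([grid, ctr])
    pts = pts + rng.uniform(-jitter, jitter, pts.shape) * h
    tets = ep._orient_tets(pts, Delaunay(pts).simplices)
    v = pts[tets]
    vol = np.einsum("ij,ij->i", v[:, 1] - v[:, 0],
                    np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])) / 6
    tets = tets[vol > 1e-9 * h**3]
    tets = tets[ep._max_edge_lengths(pts, tets) <= 2.5 * h]
    mesh = ep.TetMesh(nodes=pts, tets=tets)
    m = len(mesh.tets)
    f, s, n = (np.tile(np.asarray(d, dtype=float), (m, 1)) for d in fibers)
    mesh.fibers, mesh.sheets, mesh.normals = f, s, n
    mesh.node_tags = {}
    return mesh


class TestSurfaceFromCloud:
    def test_sphere_area_within_10pct(self):
        pts = sphere_cloud(1500, 30.0)
        surf = ep.surface_from_cloud(pts)
        assert surf.area() == pytest.approx(4 * np.pi * 30**2, rel=0.10)

    def test_vertices_are_input_points(self, anatomy):
        surf = ep.surface_from_cloud(anatomy.ed, sa.LV_ENDO)
        np.testing.assert_array_equal(surf.vertices,
                                      anatomy.ed.points_of_class(sa.LV_ENDO))

    def test_open_base_preserved(self, surfaces):
        lv_endo, lv_epi, rv_endo, _ = surfaces
        for s in (lv_endo, lv_epi, rv_endo):
            assert s.boundary_edge_count() > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="500"):
            ep.surface_from_cloud(sphere_cloud(100, 30.0))

    def test_alpha_fallback_covers_sphere(self):
        pts = sphere_cloud(1500, 30.0, seed=2)
        surf = ep.surface_from_cloud(pts, method="alpha")
        assert surf.area() == pytest.approx(4 * np.pi * 30**2, rel=0.10)

    def test_remeshing_own_vertices_is_stable(self):
        pts = sphere_cloud(1500, 30.0, seed=3)
        s1 = ep.surface_from_cloud(pts)
        s2 = ep.surface_from_cloud(s1.vertices)
        assert s2.area() == pytest.approx(s1.area(), rel=0.05)


class TestOffsetRV:
    def test_sphere_offset_radius(self):
        surf = ep.surface_from_cloud(sphere_cloud(2000, 30.0, seed=1))
        out = ep.offset_rv_epicardium(surf, 3.0)
        r = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(r - 33.0).max() < 0.1

    def test_zero_thickness_identity(self, surfaces):
        rv_endo = surfaces[2]
        out = ep.offset_rv_epicardium(rv_endo, 0.0)
        np.testing.assert_allclose(out.vertices, rv_endo.vertices, atol=1e-12)

    def test_displacement_norm_equals_thickness(self, surfaces):
        rv_endo = surfaces[2]
        out = ep.offset_rv_epicardium(rv_endo, 3.0, relax=False)
        d = np.linalg.norm(out.vertices - rv_endo.vertices, axis=1)
        np.testing.assert_allclose(d, 3.0, atol=1e-6)


class TestAssembly:
    def test_watertight_zero_boundary_edges(self, assembly):
        assert assembly.boundary_edge_count() == 0

    def test_multi_shell_euler_characteristic(self, assembly):
        # three closed genus-0 shells: chi = 3 * 2
        assert assembly.euler_characteristic() == 6

    def test_positive_myocardial_volume(self, assembly):
        vol_ml = assembly.myocardial_volume() / 1000
        assert 50 < vol_ml < 400

    def test_cavities_inside_outer(self, assembly):
        for shell in (assembly.lv_cavity, assembly.rv_cavity):
            sample = shell.vertices[::20]
            # cavity boundary points shrunk toward their center stay inside
            inner = shell.center + 0.9 * (sample - shell.center)
            assert ep._StarShell.contains(assembly.outer, inner).all()


class TestTetrahedralize:
    def test_box_volume_within_1pct(self):
        box = _box_surface(np.array([30.0, 20.0, 12.0]), h=2.0)
        mesh = ep.tetrahedralize(box, target_edge=1.8, seed=0)
        assert mesh.element_volumes().sum() == pytest.approx(
            30 * 20 * 12, rel=0.01)

    def test_all_volumes_positive(self, heart_mesh):
        assert np.all(heart_mesh.element_volumes() > 0)

    def test_coarser_target_reduces_node_count(self, assembly):
        fine = ep.tetrahedralize(assembly, target_edge=3.5, seed=0)
        coarse = ep.tetrahedralize(assembly, target_edge=7.0, seed=0)
        assert len(coarse.nodes) < len(fine.nodes)

    def test_boundary_close_to_input_surface(self, assembly, heart_mesh):
        import trimesh

        bnodes = np.unique(heart_mesh.boundary_faces())
        samples = []
        for shell in (assembly.outer, assembly.lv_cavity,
                      assembly.rv_cavity):
            m = trimesh.Trimesh(vertices=shell.vertices, faces=shell.faces,
                                process=False)
            pts, _ = trimesh.sample.sample_surface(m, 60000, seed=0)
            samples.append(np.asarray(pts))
        d = cKDTree(np.vstack(samples)).query(heart_mesh.nodes[bnodes])[0]
        assert np.quantile(d, 0.99) < 3.5

    def test_median_edge_near_target(self, heart_mesh):
        e = heart_mesh.edges()
        lens = np.linalg.norm(heart_mesh.nodes[e[:, 0]]
                              - heart_mesh.nodes[e[:, 1]], axis=1)
        assert 0.5 * 3.5 <= np.median(lens) <= 2.0 * 3.5


def _box_surface(dims, h):
    """Closed triangulated box with faces subdivided at spacing h."""
    import trimesh

    box = trimesh.creation.box(extents=dims)
    box = box.subdivide_to_size(max_edge=h)
    return ep.TriSurface(box.vertices + dims / 2, box.faces)


class TestFibers:
    def test_orthonormal_frames(self, heart_mesh):
        f, s, n = heart_mesh.fibers, heart_mesh.sheets, heart_mesh.normals
        for v in (f, s, n):
            np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0,
                                       atol=1e-6)
        assert np.abs(np.einsum("ij,ij->i", f, s)).max() < 1e-6
        assert np.abs(np.einsum("ij,ij->i", f, n)).max() < 1e-6
        assert np.abs(np.einsum("ij,ij->i", s, n)).max() < 1e-6

    def test_helix_angle_varies_transmurally(self, heart_mesh):
        t = heart_mesh.transmural[heart_mesh.tets].mean(axis=1)
        k = heart_mesh.long_axis
        # signed helix angle = atan2(f . l, f . c) in the local wall frame
        s = heart_mesh.sheets
        c0 = np.cross(np.broadcast_to(k, s.shape), s)
        c0 /= np.linalg.norm(c0, axis=1, keepdims=True)
        l0 = np.cross(s, c0)
        ang = np.degrees(np.arctan2(
            np.einsum("ij,ij->i", heart_mesh.fibers, l0),
            np.einsum("ij,ij->i", heart_mesh.fibers, c0)))
        endo = t < 0.15
        epi = t > 0.85
        mid = np.abs(t - 0.5) < 0.1
        assert np.median(ang[endo]) == pytest.approx(60 * (1 - 2 * t[endo].mean()),
                                                     abs=8)
        assert np.median(ang[epi]) < -30
        assert abs(np.median(ang[mid])) < 15

    def test_missing_coordinates_rejected(self):
        mesh = slab_mesh()
        mesh.transmural = None
        with pytest.raises(ValueError, match="coordinates"):
            ep.assign_fibers(mesh)


class TestActivationSites:
    def test_four_lv_three_rv_on_endocardium(self, heart_mesh):
        sites = ep.default_activation_sites(heart_mesh)
        assert len(sites) == 7
        lv = heart_mesh.node_tags["lv_endo"]
        rv = heart_mesh.node_tags["rv_endo"]
        assert lv[sites[:4]].all()
        assert rv[sites[4:]].all()

    def test_deterministic(self, heart_mesh):
        a = ep.default_activation_sites(heart_mesh)
        b = ep.default_activation_sites(heart_mesh)
        np.testing.assert_array_equal(a, b)

    def test_missing_tags_rejected(self):
        mesh = slab_mesh()
        with pytest.raises(ValueError, match="tag"):
            ep.default_activation_sites(mesh)


class TestEikonal:
    def test_isotropic_slab_matches_distance_over_speed(self):
        mesh = slab_mesh()
        cfg = ep.EikonalConfig(cv_fiber=1, cv_sheet=1, cv_normal=1,
                               cv_endo=1, root_nodes=(0,))
        act = ep.solve_eikonal(mesh, cfg)
        d = np.linalg.norm(mesh.nodes - mesh.nodes[0], axis=1)
        far = d > 10  # beyond the near-source discretisation zone
        rel = np.abs(act.times[far] - d[far]) / d[far]
        assert rel.max() < 0.05

    def test_matches_graph_dijkstra_oracle(self):
        mesh = slab_mesh()
        cfg = ep.EikonalConfig(cv_fiber=1, cv_sheet=1, cv_normal=1,
                               cv_endo=1, root_nodes=(0,))
        act = ep.solve_eikonal(mesh, cfg)
        dij = ep.dijkstra_activation(mesh, cfg, ring=2)
        d = np.linalg.norm(mesh.nodes - mesh.nodes[0], axis=1)
        far = d > 10
        rel = np.abs(act.times[far] - dij[far]) / dij[far]
        assert rel.max() < 0.05

    def test_two_roots_is_pointwise_min(self):
        """Adding a source can only lower arrival times, and the two-source
        solution matches the pointwise min of single-source solutions up to
        the local O(h) discretisation error where the two fronts collide."""
        h = 2.0
        mesh = slab_mesh(h=h, dims=(30, 15, 8))
        roots = (0, len(mesh.nodes) - 1)
        base = dict(cv_fiber=1, cv_sheet=1, cv_normal=1, cv_endo=1)
        both = ep.solve_eikonal(mesh, ep.EikonalConfig(root_nodes=roots,
                                                       **base))
        singles = [ep.solve_eikonal(mesh, ep.EikonalConfig(root_nodes=(r,),
                                                           **base))
                   for r in roots]
        expect = np.minimum(singles[0].times, singles[1].times)
        assert np.all(both.times <= expect + 1e-6)
        seam_tol = 1.5 * h / base["cv_fiber"]  # one-edge travel time
        assert np.all(both.times >= expect - seam_tol)
        # away from the collision seam the solutions coincide
        seam = np.abs(singles[0].times - singles[1].times) < 3 * h
        np.testing.assert_allclose(both.times[~seam], expect[~seam],
                                   atol=1e-6)

    def test_anisotropy_ratio(self):
        """A rod conducts ~4x faster along the fiber than across it."""
        base = dict(cv_fiber=0.67, cv_sheet=0.30, cv_normal=0.17, cv_endo=0.67)
        mesh = slab_mesh(h=1.5, dims=(40, 8, 8))
        src = int(np.argmin(np.linalg.norm(mesh.nodes - [0, 4, 4], axis=1)))
        probe = int(np.argmin(np.linalg.norm(mesh.nodes - [30, 4, 4], axis=1)))
        along = ep.solve_eikonal(mesh, ep.EikonalConfig(
            root_nodes=(src,), **base)).times[probe]
        across_mesh = slab_mesh(h=1.5, dims=(40, 8, 8),
                                fibers=((0, 1, 0), (0, 0, 1), (1, 0, 0)))
        across = ep.solve_eikonal(across_mesh, ep.EikonalConfig(
            root_nodes=(src,), **base)).times[probe]
        assert along / across == pytest.approx(0.17 / 0.67, rel=0.10)

    def test_velocity_monotonicity(self):
        """Raising any conduction velocity never delays any node."""
        mesh = slab_mesh(h=2.5, dims=(30, 15, 8))
        rng = np.random.default_rng(5)
        for _ in range(5):
            cvs = dict(cv_fiber=rng.uniform(0.3, 1.0),
                       cv_sheet=rng.uniform(0.2, 0.6),
                       cv_normal=rng.uniform(0.1, 0.4), cv_endo=1.2)
            t0 = ep.solve_eikonal(mesh, ep.EikonalConfig(
                root_nodes=(0,), **cvs)).times
            name = rng.choice(["cv_fiber", "cv_sheet", "cv_normal"])
            cvs2 = {**cvs, name: cvs[name] * 1.5}
            t1 = ep.solve_eikonal(mesh, ep.EikonalConfig(
                root_nodes=(0,), **cvs2)).times
            assert np.all(t1 <= t0 + 1e-6)

    def test_heart_activation_finite_everywhere(self, heart_mesh):
        sites = ep.default_activation_sites(heart_mesh)
        act = ep.solve_eikonal(heart_mesh, ep.EikonalConfig(
            root_nodes=tuple(sites)))
        assert not act.unreachable.any()
        assert act.times.min() == 0.0
        assert 20 < act.times.max() < 200


class TestElectrodesAndECG:
    def test_nine_electrodes_translate_with_mesh(self, heart_mesh):
        e1 = ep.default_electrodes(heart_mesh)
        assert e1.shape == (9, 3)
        import dataclasses

        shifted = dataclasses.replace(heart_mesh,
                                      nodes=heart_mesh.nodes + [10, -5, 3])
        e2 = ep.default_electrodes(shifted)
        np.testing.assert_allclose(e2 - e1, np.tile([10, -5, 3], (9, 1)),
                                   atol=1e-9)

    def test_precordial_order_left_to_right(self, heart_mesh):
        e = ep.default_electrodes(heart_mesh)
        v_x = e[3:, 0]
        assert np.all(np.diff(v_x) > 0)

    @pytest.fixture(scope="class")
    def activation(self, heart_mesh):
        sites = ep.default_activation_sites(heart_mesh)
        return ep.solve_eikonal(heart_mesh, ep.EikonalConfig(
            root_nodes=tuple(sites)))

    def test_rigid_translation_invariance(self, heart_mesh, activation):
        import dataclasses

        e = ep.default_electrodes(heart_mesh)
        tr1 = ep.pseudo_ecg(activation, heart_mesh, e)
        shifted = dataclasses.replace(heart_mesh,
                                      nodes=heart_mesh.nodes + [25, 0, -10])
        tr2 = ep.pseudo_ecg(activation, shifted, e + [25, 0, -10])
        np.testing.assert_allclose(tr1.leads, tr2.leads, atol=1e-9)

    def test_einthoven_lead_iii_identity(self, heart_mesh, activation):
        """Lead III computed from raw electrode potentials (LL - LA)
        equals II - I computed from the assembled leads."""
        e = ep.default_electrodes(heart_mesh)
        tr, phi = ep.pseudo_ecg(activation, heart_mesh, e,
                                return_potentials=True)
        lead_iii_direct = phi[2] - phi[1]          # LL - LA
        lead_iii_derived = tr.leads[1] - tr.leads[0]
        np.testing.assert_allclose(lead_iii_direct, lead_iii_derived,
                                   atol=1e-12)

    def test_doubling_speed_halves_qrs_duration(self, heart_mesh):
        sites = tuple(ep.default_activation_sites(heart_mesh))
        e = ep.default_electrodes(heart_mesh)
        base = ep.EikonalConfig(root_nodes=sites)
        fast = ep.EikonalConfig(cv_fiber=2 * 0.67, cv_sheet=2 * 0.30,
                                cv_normal=2 * 0.17, cv_endo=2 * 1.20,
                                root_nodes=sites)
        tr1 = ep.pseudo_ecg(ep.solve_eikonal(heart_mesh, base), heart_mesh,
                            e, dt=0.5)
        tr2 = ep.pseudo_ecg(ep.solve_eikonal(heart_mesh, fast), heart_mesh,
                            e, dt=0.5)
        assert tr2.qrs_duration() / tr1.qrs_duration() == pytest.approx(
            0.5, rel=0.10)


class TestPopulationCompare:
    def _fake_traces(self, n, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        times = np.arange(0, 80.0, 1.0)
        out = []
        for _ in range(n):
            base = np.sin(2 * np.pi * (times[None, :] / 80.0
                                       + rng.normal(0, 0.05, (8, 1)))) + shift
            out.append(ep.ECGTrace(times=times, leads=base))
        return out

    def test_identical_populations_near_zero(self):
        real = self._fake_traces(12, seed=0)
        df = ep.qrs_population_compare(real, real, seed=0)
        assert len(df) == 8
        assert (df["mmd_proposed"] < 1e-10).all()

    def test_eight_leads_reported(self):
        df = ep.qrs_population_compare(self._fake_traces(12, 0),
                                       self._fake_traces(12, 1), seed=0)
        assert list(df["lead"]) == ["I", "II", "V1", "V2", "V3", "V4",
                                    "V5", "V6"]

    def test_seeded_split_reproducible(self):
        real = self._fake_traces(14, seed=2)
        virt = self._fake_traces(14, seed=3)
        a = ep.qrs_population_compare(real, virt, seed=5)
        b = ep.qrs_population_compare(real, virt, seed=5)
        assert (a["mmd_gold_standard"] == b["mmd_gold_standard"]).all()

    def test_too_few_traces_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            ep.qrs_population_compare(self._fake_traces(5, 0),
                                      self._fake_traces(12, 1))
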