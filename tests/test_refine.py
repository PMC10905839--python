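import numpy as np
import pytest
import trimesh

from craniowrap.grids import BinaryMask, VoxelGrid
from craniowrap.refine import (RefineConfig, balloon_force, distance_force,
                               edge_force, estimate_tissue_fluid,
                               refine_surface, smoothing_force)
from craniowrap.surface import signed_edt


@pytest.fixture(scope="module")
def ball_sedt(ball_mask):
    mask, center, R = ball_mask
    return signed_edt(mask), center, R


def _sphere(center, r, sub=3):
    s = trimesh.creation.icosphere(sub, radius=r)
    s.apply_translation(center)
    return s


class TestDistanceForce:
    def test_zero_on_level_set_and_inside_leash(self, ball_sedt):
        sedt, center, R = ball_sedt
        mesh = _sphere(center, R)
        F = distance_force(mesh, sedt, leash=3.0)
        assert np.linalg.norm(F, axis=1).max() < 0.15

    def test_saturates_beyond_leash(self, ball_sedt):
        sedt, center, R = ball_sedt
        mesh = _sphere(center, R + 6.0)  # d = +6 = 2x leash
        F = distance_force(mesh, sedt, leash=3.0)
        mags = np.linalg.norm(F, axis=1)
        assert mags.min() > 0.95  # full magnitude
        # pulls inward: force opposes the outward radial direction
        radial = (mesh.vertices - center)
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        assert ((F * radial).sum(axis=1) < 0).all()

    def test_radial_direction_inside_and_outside(self, ball_sedt):
        sedt, center, R = ball_sedt
        rng = np.random.default_rng(0)
        for r, sign in ((R + 5.0, -1.0), (R - 5.0, +1.0)):
            mesh = _sphere(center, r, sub=2)
            F = distance_force(mesh, sedt, leash=2.0)
            radial = mesh.vertices - center
            radial /= np.linalg.norm(radial, axis=1)[:, None]
            proj = (F * radial).sum(axis=1)
            assert (np.sign(proj) == sign).all()


class TestBalloonForce:
    def _image(self, ball_mask, tissue=0.4, fluid=1.0):
        mask, center, R = ball_mask
        data = np.where(mask.data > 0, tissue, fluid).astype(np.float32)
        return VoxelGrid(data=data, spacing=mask.spacing,
                         origin=mask.origin), center, R

    def test_inflates_inside_tissue(self, ball_mask):
        image, center, R = self._image(ball_mask)
        mesh = _sphere(center, R - 6.0)
        F = balloon_force(mesh, image, tissue=0.4, fluid=1.0)
        radial = mesh.vertices - center
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        assert ((F * radial).sum(axis=1) > 0.9).all()

    def test_zero_in_fluid(self, ball_mask):
        image, center, R = self._image(ball_mask)
        mesh = _sphere(center, R + 5.0)
        F = balloon_force(mesh, image, tissue=0.4, fluid=1.0)
        assert np.abs(F).max() == 0.0

    def test_two_class_estimate(self, ball_mask):
        image, _, _ = self._image(ball_mask)
        tissue, fluid = estimate_tissue_fluid(image)
        assert tissue == pytest.approx(0.4, abs=0.05)
        assert fluid == pytest.approx(1.0, abs=0.05)


class TestEdgeForce:
    def _step_image(self, R_edge, n=64, tissue=0.3, fluid=1.0):
        ax = np.arange(n, dtype=float)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        c = (n - 1) / 2.0
        r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
        data = np.where(r <= R_edge, tissue, fluid).astype(np.float32)
        return VoxelGrid(data=data), np.array([c, c, c])

    def test_step_edge_targeted(self):
        image, center = self._step_image(R_edge=20.0)
        mesh = _sphere(center, 18.5)  # edge at +1.5 mm along the normal
        F = edge_force(mesh, image, search_mm=3.0, grad_floor=0.05)
        radial = mesh.vertices - center
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        proj = (F * radial).sum(axis=1)
        assert proj.mean() == pytest.approx(1.5, abs=0.5)
        # a single full application lands within one voxel of the step
        moved = mesh.vertices + F
        r = np.linalg.norm(moved - center, axis=1)
        assert np.abs(r - 20.0).max() <= 1.0

    def test_uniform_image_gives_zero(self, ball_mask):
        mask, center, R = ball_mask
        image = VoxelGrid(data=np.full(mask.shape, 0.5, np.float32),
                          spacing=mask.spacing, origin=mask.origin)
        F = edge_force(_sphere(center, R), image, 3.0, 0.05)
        assert np.abs(F).max() == 0.0

    def test_wrong_polarity_edge_ignored(self):
        # bright inside, dark outside: with fluid_brighter polarity this
        # tissue->fluid gradient points the wrong way -> no force
        image, center = self._step_image(R_edge=20.0, tissue=1.0, fluid=0.3)
        mesh = _sphere(center, 18.5)
        F = edge_force(mesh, image, 3.0, 0.05, fluid_brighter=True)
        assert np.abs(F).max() == 0.0

    def test_stronger_of_two_edges_wins(self):
        n = 64
        ax = np.arange(n, dtype=float)
        X, _, _ = np.meshgrid(ax, ax, ax, indexing="ij")
        # weak near step at x = 32.5, strong far step at x = 36.5
        data = np.full((n, n, n), 0.3, np.float32)
        data[X > 32.4] = 0.45
        data[X > 36.4] = 1.0
        image = VoxelGrid(data=data)
        mesh = _sphere(np.array([30.0, 31.5, 31.5]), 0.5, sub=1)
        F = edge_force(mesh, image, search_mm=8.0, grad_floor=0.05)
        vx = mesh.vertex_normals[:, 0] > 0.9
        proj = F[vx, 0] / mesh.vertex_normals[vx, 0]
        assert np.median(proj) > 4.0  # targets the far, stronger edge

    def test_exact_tie_resolved_to_nearest(self):
        from craniowrap.refine import _select_edge_targets
        s = np.array([-3.0, -1.5, 0.0, 1.5, 3.0])
        qual = np.full((2, 5), -np.inf)
        qual[0, [0, 3]] = 0.7   # equal strength at -3.0 and +1.5
        # row 1: nothing qualifies
        targets = _select_edge_targets(qual, s)
        assert targets[0] == 1.5
        assert targets[1] == 0.0


class TestSmoothingForce:
    def test_zero_on_symmetric_ring(self):
        # regular hexagonal fan: interior vertex force ~ 0
        angles = np.linspace(0, 2 * np.pi, 7)[:-1]
        V = np.vstack([[0, 0, 0], np.c_[np.cos(angles), np.sin(angles),
                                        np.zeros(6)]])
        F = np.array([[0, i + 1, 1 + (i + 1) % 6] for i in range(6)])
        mesh = trimesh.Trimesh(V, F, process=False)
        force = smoothing_force(mesh)
        assert np.linalg.norm(force[0]) < 1e-12

    def test_displaced_vertex_pulled_back(self):
        angles = np.linspace(0, 2 * np.pi, 7)[:-1]
        V = np.vstack([[0, 0, 0.5], np.c_[np.cos(angles), np.sin(angles),
                                          np.zeros(6)]])
        F = np.array([[0, i + 1, 1 + (i + 1) % 6] for i in range(6)])
        mesh = trimesh.Trimesh(V, F, process=False)
        force = smoothing_force(mesh)
        assert force[0][2] == pytest.approx(-0.5)

    def test_reduces_curvature_of_staircase_sphere(self, ball_mask):
        from skimage.measure import marching_cubes
        mask, _, _ = ball_mask
        verts, faces, _, _ = marching_cubes(mask.data.astype(np.float32), 0.5)
        mesh = trimesh.Trimesh(verts, faces, process=True)

        def total_mean_curvature(m):
            # integral |H| proxy: sum of edge length x dihedral angle
            angles = m.face_adjacency_angles
            edges = m.face_adjacency_edges
            lengths = np.linalg.norm(np.diff(m.vertices[edges], axis=1)
                                     .squeeze(1), axis=1)
            return float((lengths * np.abs(angles)).sum())

        before = total_mean_curvature(mesh)
        m = mesh
        for _ in range(10):
            m = trimesh.Trimesh(m.vertices + 0.5 * smoothing_force(m),
                                m.faces, process=False)
        assert total_mean_curvature(m) < before


class TestRefineLoop:
    def test_smooth_only_fixed_point(self, ball_mask):
        """With only the smoothing force active, a fine, already-smooth
        sphere is a fixed point: the first update falls below the
        convergence tolerance, so the surface barely moves."""
        mask, center, R = ball_mask
        sedt = signed_edt(mask)
        image = VoxelGrid(data=np.where(mask.data > 0, 0.4, 1.0)
                          .astype(np.float32), spacing=mask.spacing)
        mesh = _sphere(center, R, sub=4)
        cfg = RefineConfig(w_dist=0, w_balloon=0, w_edge=0, w_smooth=0.4,
                           max_iters=30, remesh_every=0, converge_tol=0.02)
        log = []
        out = refine_surface(mesh, image, sedt, cfg, log=log)
        d = np.linalg.norm(out.vertices - mesh.vertices, axis=1)
        assert len(log) <= 2  # converged immediately
        assert d.max() < 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RefineConfig(w_dist=0, w_balloon=0, w_edge=0, w_smooth=0)
        with pytest.raises(ValueError):
            RefineConfig(w_dist=-1)
        with pytest.raises(ValueError):
            RefineConfig(normal_search_mm=0)
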