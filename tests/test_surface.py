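import itertools

import numpy as np
import pytest
import trimesh

from craniowrap.grids import BinaryMask
from craniowrap.remeshing import remesh
from craniowrap.surface import (WrapConfig, extract_surface,
                                init_bounding_sphere, shrink_wrap, signed_edt)


def brute_force_sedt(mask, spacing):
    """All-pairs distance oracle for tiny grids."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    sp = np.asarray(spacing, dtype=float)
    out = np.zeros(mask.shape)
    for ijk in itertools.product(*(range(s) for s in mask.shape)):
        p = np.array(ijk) * sp
        d_fg = np.min(np.linalg.norm(fg * sp - p, axis=1))
        d_bg = np.min(np.linalg.norm(bg * sp - p, axis=1))
        out[ijk] = d_fg - d_bg
    return out


class TestSignedEDT:
    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.8, 0.8, 0.8)])
    def test_matches_brute_force_on_small_grids(self, spacing):
        rng = np.random.default_rng(0)
        data = rng.random((5, 5, 5)) > 0.6
        data[2, 2, 2] = True  # ensure non-empty
        mask = BinaryMask(data=data, spacing=spacing)
        got = signed_edt(mask).data
        want = brute_force_sedt(data, spacing)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_single_voxel_sign_convention(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        s = 0.8
        sedt = signed_edt(BinaryMask(data=data, spacing=(s, s, s))).data
        assert sedt[2, 2, 2] == pytest.approx(-s)
        assert sedt[3, 2, 2] == pytest.approx(+s)

    def test_mask_inversion_negates_field(self):
        rng = np.random.default_rng(1)
        data = rng.random((6, 6, 6)) > 0.5
        data[0, 0, 0], data[5, 5, 5] = True, False
        a = signed_edt(BinaryMask(data=data)).data
        b = signed_edt(BinaryMask(data=~data)).data
        np.testing.assert_allclose(a, -b, atol=1e-6)

    def test_ball_interior_minimum_near_minus_radius(self, ball_mask):
        mask, _, R = ball_mask
        sedt = signed_edt(mask)
        assert sedt.data.min() == pytest.approx(-R, abs=1.0)

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            signed_edt(BinaryMask(data=np.zeros((3, 3, 3))))
        with pytest.raises(ValueError):
            signed_edt(BinaryMask(data=np.ones((3, 3, 3))))


class TestBoundingSphere:
    def test_encloses_all_foreground(self, ball_mask):
        mask, center, R = ball_mask
        sphere = init_bounding_sphere(mask, 2)
        pts = mask.world_coords(np.argwhere(mask.data > 0).astype(float))
        c = sphere.vertices.mean(axis=0)
        r = np.linalg.norm(sphere.vertices - c, axis=1).mean()
        assert (np.linalg.norm(pts - c, axis=1) < r).all()

    @pytest.mark.parametrize("sub,faces", [(0, 20), (1, 80), (2, 320)])
    def test_icosphere_counts(self, ball_mask, sub, faces):
        mask, _, _ = ball_mask
        sphere = init_bounding_sphere(mask, sub)
        assert len(sphere.faces) == faces
        assert sphere.euler_number == 2


class TestRemesh:
    def test_within_bounds_unchanged(self):
        ico = trimesh.creation.icosphere(2, radius=10.0)
        el = ico.edges_unique_length
        out = remesh(ico, (el.min() * 0.9, el.max() * 1.1))
        assert len(out.faces) == len(ico.faces)

    def test_split_long_edges_preserves_topology(self):
        ico = trimesh.creation.icosphere(1, radius=10.0)
        stretched = ico.copy()
        stretched.vertices[:, 2] *= 3.0  # ellongate: some edges > 2x max
        el = stretched.edges_unique_length
        out = remesh(stretched, (el.min() * 0.8, np.median(el)))
        assert len(out.faces) > len(stretched.faces)
        assert out.euler_number == 2
        assert out.is_watertight

    def test_collapse_short_edges_preserves_topology(self):
        ico = trimesh.creation.icosphere(3, radius=10.0)
        el = ico.edges_unique_length
        out = remesh(ico, (np.median(el) * 1.5, np.median(el) * 4.0))
        assert len(out.faces) < len(ico.faces)
        assert out.euler_number == 2
        assert out.is_watertight

    def test_repeated_remesh_keeps_watertight(self, ball_mask):
        mask, _, _ = ball_mask
        mesh = extract_surface(mask, WrapConfig(
            step_size=0.5, max_iters=120, edge_length_bounds=(1.0, 2.5)),
            subdivisions=3)
        rng = np.random.default_rng(0)
        for _ in range(25):
            lo = rng.uniform(0.8, 1.8)
            mesh = remesh(mesh, (lo, lo * rng.uniform(2.0, 3.0)), max_passes=2)
            assert mesh.is_watertight
            assert mesh.euler_number == 2


class TestShrinkWrap:
    def test_ball_radius_recovered(self, ball_mask):
        mask, center, R = ball_mask
        sedt = signed_edt(mask)
        sphere = init_bounding_sphere(mask, 3)
        cfg = WrapConfig(step_size=0.5, max_iters=200,
                         edge_length_bounds=(1.0, 2.5))
        mesh = shrink_wrap(sphere, sedt, cfg)
        r = np.linalg.norm(mesh.vertices - center, axis=1)
        assert np.abs(r - R).max() <= 1.0  # within one voxel
        assert mesh.euler_number == 2
        assert mesh.is_watertight

    def test_vertices_on_zero_level_set(self, ball_mask):
        mask, _, _ = ball_mask
        sedt = signed_edt(mask)
        mesh = shrink_wrap(init_bounding_sphere(mask, 3), sedt,
                           WrapConfig(step_size=0.5, max_iters=200,
                                      edge_length_bounds=(1.0, 2.5)))
        d = np.abs(sedt.sample_world(mesh.vertices))
        frac = (d <= max(mask.spacing)).mean()
        assert frac >= 0.99

    def test_marching_cubes_equivalence_oracle(self, ball_mask):
        """Independent extraction of the same mask via marching cubes:
        symmetric surface distance must stay below one voxel."""
        from skimage.measure import marching_cubes
        from craniowrap.metrics import surface_distance

        mask, _, _ = ball_mask
        mesh = extract_surface(mask, WrapConfig(
            step_size=0.5, max_iters=200, edge_length_bounds=(1.0, 2.5)),
            subdivisions=3)
        verts, faces, _, _ = marching_cubes(
            mask.data.astype(np.float32), 0.5, spacing=mask.spacing)
        mc = trimesh.Trimesh(verts + np.asarray(mask.origin), faces,
                             process=False)
        mean_d, _, _ = surface_distance(mesh, mc, n_samples=4000)
        assert mean_d <= 1.0
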