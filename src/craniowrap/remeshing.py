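"""Incremental isotropic remeshing of watertight triangle meshes.

The deformable stages repeatedly split edges that have grown too long,
collapse edges that have shrunk too short, and tangentially relax
vertices -- the classical local remeshing loop that lets a wrapped
surface expand or contract while staying well-conditioned and keeping
its spherical topology.  Splits and collapses are purely combinatorial
(midpoint insertion, link-condition-guarded midpoint collapse) so the
Euler characteristic never changes.

Meshes are exchanged as :class:`trimesh.Trimesh`; the editing itself
runs on dict-based adjacency rebuilt per pass, which is ample for the
10^4-10^5-face meshes this pipeline produces.
"""

from __future__ import annotations

import numpy as np
import trimesh


def _build_editor(mesh: trimesh.Trimesh):
    verts = [tuple(v) for v in mesh.vertices]
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    return verts, faces


def _edge_map(faces: dict):
    """Undirected edge -> list of face ids."""
    em = {}
    for fid, (a, b, c) in faces.items():
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            em.setdefault(key, []).append(fid)
    return em


def _split_pass(verts, faces, max_len):
    """Bisect every edge longer than ``max_len`` (longest first)."""
    em = _edge_map(faces)
    V = np.asarray(verts)
    lengths = {}
    for (u, v) in em:
        lengths[(u, v)] = np.linalg.norm(V[u] - V[v])
    queue = sorted((l, e) for e, l in lengths.items() if l > max_len)
    queue.reverse()
    next_fid = max(faces) + 1 if faces else 0
    n_split = 0
    for _, (u, v) in queue:
        fids = [f for f in em.get((u, v), []) if f in faces]
        if len(fids) != 2:
            continue  # edge vanished in an earlier split of this pass
        mid = tuple((np.asarray(verts[u]) + np.asarray(verts[v])) / 2.0)
        m = len(verts)
        verts.append(mid)
        for fid in fids:
            tri = faces.pop(fid)
            # order tri so the split edge is (tri[0], tri[1])
            for r in range(3):
                a, b, c = tri[r], tri[(r + 1) % 3], tri[(r + 2) % 3]
                if {a, b} == {u, v}:
                    break
            f1, f2 = (a, m, c), (m, b, c)
            for fnew in (f1, f2):
                faces[next_fid] = fnew
                for uu, vv in ((fnew[0], fnew[1]), (fnew[1], fnew[2]),
                               (fnew[2], fnew[0])):
                    key = (uu, vv) if uu < vv else (vv, uu)
                    em.setdefault(key, []).append(next_fid)
                next_fid += 1
        del em[(u, v)]
        n_split += 1
    return n_split


def _vertex_faces(faces: dict):
    vf = {}
    for fid, tri in faces.items():
        for v in tri:
            vf.setdefault(v, set()).add(fid)
    return vf


def _collapse_pass(verts, faces, min_len, max_len):
    """Collapse edges shorter than ``min_len`` to their midpoint.

    A collapse is skipped unless the link condition holds (the one-ring
    intersection of the endpoints is exactly the two opposite vertices),
    or if it would create an edge longer than ``max_len``, flip a face
    normal, or touch a vertex already modified in this pass.
    """
    em = _edge_map(faces)
    vf = _vertex_faces(faces)
    V = np.asarray(verts, dtype=float)
    cand = [(np.linalg.norm(V[u] - V[v]), (u, v)) for (u, v), fl in em.items()
            if len(fl) == 2 and np.linalg.norm(V[u] - V[v]) < min_len]
    cand.sort()
    touched = set()
    n_collapsed = 0
    for _, (u, v) in cand:
        if u in touched or v in touched:
            continue
        fids = [f for f in em.get((u, v), []) if f in faces]
        if len(fids) != 2:
            continue
        ring_u = set(x for f in vf.get(u, ()) if f in faces
                     for x in faces[f]) - {u}
        ring_v = set(x for f in vf.get(v, ()) if f in faces
                     for x in faces[f]) - {v}
        opposite = set(x for f in fids for x in faces[f]) - {u, v}
        if ring_u & ring_v != opposite or len(opposite) != 2:
            continue  # link condition: collapse would pinch the surface
        mid = (V[u] + V[v]) / 2.0
        # validity of the post-collapse one-ring
        ok = True
        affected = [f for f in (vf.get(u, set()) | vf.get(v, set()))
                    if f in faces and f not in fids]
        for f in affected:
            tri = [mid if x in (u, v) else V[x] for x in faces[f]]
            old = [V[x] for x in faces[f]]
            n_new = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            if np.linalg.norm(n_new) < 1e-12 or np.dot(n_new, n_old) <= 0:
                ok = False
                break
            for x, y in ((0, 1), (1, 2), (2, 0)):
                if np.linalg.norm(np.asarray(tri[x]) - tri[y]) > max_len:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        verts[u] = tuple(mid)
        V[u] = mid
        for fid in fids:
            tri = faces.pop(fid)
        for f in list(vf.get(v, ())):
            if f not in faces:
                continue
            tri = faces[f]
            faces[f] = tuple(u if x == v else x for x in tri)
            vf.setdefault(u, set()).add(f)
        vf[u] = {f for f in vf.get(u, set()) if f in faces}
        vf.pop(v, None)
        touched.update(opposite | {u, v})
        n_collapsed += 1
    return n_collapsed


def _compact(verts, faces: dict):
    used = sorted({v for tri in faces.values() for v in tri})
    remap = {v: i for i, v in enumerate(used)}
    V = np.asarray([verts[v] for v in used], dtype=float)
    F = np.asarray([[remap[x] for x in tri] for tri in faces.values()],
                   dtype=np.int64)
    return V, F


def tangential_relax(mesh: trimesh.Trimesh, weight: float = 0.5,
                     iterations: int = 1) -> trimesh.Trimesh:
    """Move vertices toward their one-ring centroid, tangentially only
    (the normal component is removed, so the shape is preserved)."""
    V = mesh.vertices.copy()
    F = mesh.faces
    from scipy.sparse import coo_matrix

    e = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    e = np.vstack([e, e[:, ::-1]])
    e = np.unique(e, axis=0)
    n = len(V)
    A = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1
    for _ in range(iterations):
        m = trimesh.Trimesh(V, F, process=False)
        normals = m.vertex_normals
        centroid = A @ V / deg[:, None]
        d = (centroid - V) * weight
        d -= (d * normals).sum(axis=1)[:, None] * normals
        V = V + d
    return trimesh.Trimesh(V, F, process=False)


def remesh(mesh: trimesh.Trimesh, bounds, relax_weight: float = 0.5,
           max_passes: int = 10) -> trimesh.Trimesh:
    """Drive all edge lengths into ``bounds = (min, max)``.

    Alternates split and collapse passes with tangential relaxation
    until the mesh is within bounds (up to collapses blocked by the
    link/quality guards) or ``max_passes`` is reached.  Topology is
    preserved: V - E + F is invariant under both operations.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("invalid edge-length bounds")
    out = mesh
    for _ in range(max_passes):
        el = out.edges_unique_length
        if ((el >= lo) & (el <= hi)).all():
            break
        verts, faces = _build_editor(out)
        n_s = _split_pass(verts, faces, hi)
        n_c = _collapse_pass(verts, faces, lo, hi)
        V, F = _compact(verts, faces)
        out = trimesh.Trimesh(V, F, process=False)
        if relax_weight > 0:
            out = tangential_relax(out, relax_weight)
        if n_s == 0 and n_c == 0:
            break
    return out
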