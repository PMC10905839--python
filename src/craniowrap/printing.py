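"""Print-ready geometry: STL export, resolution resampling, and the
display stand.

The stand is the published support: a 2 cm tall cylindrical stand on a
2 cm thick, 6 cm diameter cylindrical base, with a 0.3 cm x 1 cm
rectangular cut-out (0.1 cm offset) through the stand wall for
attachment to a laser-cut baseplate.  No mesh-boolean backend is
needed: the solid is a stack of constant-cross-section prisms, so it is
assembled from 2D polygon operations (shapely) plus ear-clipping
triangulation, which yields the published dimensions exactly and a
watertight mesh by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
import trimesh
from shapely.geometry import Point, box

from .remeshing import remesh

# published stand dimensions, mm
STAND_HEIGHT = 20.0
BASE_HEIGHT = 20.0
BASE_DIAMETER = 60.0
STAND_DIAMETER = 20.0
CUTOUT_WIDTH = 3.0     # 0.3 cm
CUTOUT_LENGTH = 10.0   # 1 cm
CUTOUT_OFFSET = 1.0    # 0.1 cm from the stand axis
N_SEGMENTS = 128


# -- STL I/O --------------------------------------------------------------

def write_stl(mesh: trimesh.Trimesh, path) -> None:
    """Binary STL in mm with outward normals from the face winding.

    Non-watertight meshes are written anyway (printers tolerate small
    defects) but flagged with a warning.
    """
    if not mesh.is_watertight:
        warnings.warn("writing a non-watertight mesh to STL")
    mesh.export(str(path), file_type="stl")


def read_stl(path) -> trimesh.Trimesh:
    """Load an STL and merge duplicated vertices (STL stores a triangle
    soup) so topological checks are meaningful."""
    m = trimesh.load(str(path), file_type="stl", process=True)
    return m


# -- resolution resampling ------------------------------------------------

def resample_mesh(mesh: trimesh.Trimesh,
                  target_resolution_mm: float) -> trimesh.Trimesh:
    """Remesh so the median edge length approximates the target
    resolution (0.1 mm for printing), preserving topology and staying
    within ``target_resolution_mm`` of the input surface."""
    if target_resolution_mm < 1e-3:
        raise ValueError("target resolution below 1 micron is not supported")
    lo = 0.6 * target_resolution_mm
    hi = 1.5 * target_resolution_mm
    out = mesh
    # uniform 4:1 subdivision while above the band: exact planar
    # refinement (geometry and enclosed volume unchanged), cheap at any
    # mesh size; the incremental remesher then only tidies outliers
    while np.median(out.edges_unique_length) > hi and len(out.faces) < 4e6:
        out = trimesh.Trimesh(*trimesh.remesh.subdivide(out.vertices,
                                                        out.faces),
                              process=False)
    return remesh(out, (lo, hi), relax_weight=0.3, max_passes=4)


# -- polygon triangulation ------------------------------------------------

def _poly_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ear_clip(pts: np.ndarray) -> list:
    """Triangulate a simple CCW polygon (ear clipping, O(n^2))."""
    n = len(pts)
    idx = list(range(n))
    tris = []

    def cross(o, a, b):
        return ((a[0] - o[0]) * (b[1] - o[1])
                - (a[1] - o[1]) * (b[0] - o[0]))

    def in_tri(p, a, b, c, eps=1e-12):
        d1 = cross(a, b, p)
        d2 = cross(b, c, p)
        d3 = cross(c, a, p)
        return d1 > eps and d2 > eps and d3 > eps

    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        ear_found = False
        m = len(idx)
        for pos in range(m):
            i, j, k = idx[(pos - 1) % m], idx[pos], idx[(pos + 1) % m]
            a, b, c = pts[i], pts[j], pts[k]
            if cross(a, b, c) <= 1e-12:
                continue  # reflex or collinear corner
            ok = True
            for other in idx:
                if other in (i, j, k):
                    continue
                p = pts[other]
                if (np.allclose(p, a) or np.allclose(p, b)
                        or np.allclose(p, c)):
                    continue  # duplicated bridge vertex
                if in_tri(p, a, b, c):
                    ok = False
                    break
            if ok:
                tris.append((i, j, k))
                idx.pop(pos)
                ear_found = True
                break
        guard += 1
        if not ear_found:
            # numerically degenerate corner; clip it anyway
            tris.append((idx[0], idx[1], idx[2]))
            idx.pop(1)
    tris.append(tuple(idx))
    return tris


def _bridge_hole(outer: np.ndarray, hole: np.ndarray) -> np.ndarray:
    """Join a hole (CW) into a CCW outer ring via a mutually visible
    vertex pair, producing one simple polygon."""

    def seg_blocked(p, q, ring):
        # does segment p-q properly cross any edge of ring?
        for i in range(len(ring)):
            a, b = ring[i], ring[(i + 1) % len(ring)]
            if (np.allclose(a, p) or np.allclose(b, p)
                    or np.allclose(a, q) or np.allclose(b, q)):
                continue
            if _segments_cross(p, q, a, b):
                return True
        return False

    mi = int(np.argmax(hole[:, 0]))
    m = hole[mi]
    order = np.argsort(np.linalg.norm(outer - m, axis=1))
    for oi in order:
        p = outer[oi]
        if p[0] <= m[0]:
            continue  # bridge must head away from the hole interior
        if not seg_blocked(m, p, hole) and not seg_blocked(m, p, outer):
            break
    else:  # pragma: no cover - cannot happen for a convex outer ring
        raise RuntimeError("no visible bridge found")
    merged = np.vstack([outer[:oi + 1],
                        np.roll(hole, -mi, axis=0), hole[mi:mi + 1],
                        outer[oi:]])
    return merged


def _segments_cross(p, q, a, b, eps=1e-12):
    def d(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

    d1, d2 = d(p, q, a), d(p, q, b)
    d3, d4 = d(a, b, p), d(a, b, q)
    return (d1 * d2 < -eps) and (d3 * d4 < -eps)


def _triangulate_polygon(outer: np.ndarray, hole: np.ndarray | None = None):
    """Triangulate outer (CCW) with an optional hole; returns (points,
    triangle index triples) with CCW triangles."""
    if _poly_area(outer) < 0:
        outer = outer[::-1]
    if hole is None:
        pts = outer
    else:
        if _poly_area(hole) > 0:
            hole = hole[::-1]  # holes are clockwise
        pts = _bridge_hole(outer, hole)
    tris = _ear_clip(pts)
    return pts, tris


# -- stand construction ---------------------------------------------------

def _ring(poly) -> np.ndarray:
    pts = np.asarray(poly.exterior.coords)[:-1]
    if _poly_area(pts) < 0:
        pts = pts[::-1]
    return pts


def _stand_profile():
    """2D cross-sections: base circle and slotted stand circle (CCW)."""
    base = Point(0, 0).buffer(BASE_DIAMETER / 2.0, quad_segs=N_SEGMENTS // 4)
    stand_circle = Point(0, 0).buffer(STAND_DIAMETER / 2.0,
                                      quad_segs=N_SEGMENTS // 4)
    # slot: radial, from CUTOUT_OFFSET off-axis out through the wall
    slot = box(CUTOUT_OFFSET, -CUTOUT_WIDTH / 2.0,
               CUTOUT_OFFSET + CUTOUT_LENGTH, CUTOUT_WIDTH / 2.0)
    stand = stand_circle.difference(slot)
    stand = shapely.geometry.polygon.orient(stand, sign=1.0)
    return _ring(base), _ring(stand)


class _MeshBuilder:
    def __init__(self):
        self.verts = []
        self.index = {}
        self.faces = []

    def vid(self, p):
        key = (round(float(p[0]), 9), round(float(p[1]), 9),
               round(float(p[2]), 9))
        if key not in self.index:
            self.index[key] = len(self.verts)
            self.verts.append(key)
        return self.index[key]

    def tri(self, a, b, c):
        ia, ib, ic = self.vid(a), self.vid(b), self.vid(c)
        if len({ia, ib, ic}) == 3:
            self.faces.append((ia, ib, ic))

    def cap(self, pts2d, tris, z, up=True):
        for (i, j, k) in tris:
            a = (*pts2d[i], z)
            b = (*pts2d[j], z)
            c = (*pts2d[k], z)
            if up:
                self.tri(a, b, c)
            else:
                self.tri(a, c, b)

    def wall(self, ring, z0, z1):
        """Extrude a CCW cross-section boundary with outward normals."""
        n = len(ring)
        for i in range(n):
            p, q = ring[i], ring[(i + 1) % n]
            p0, q0 = (*p, z0), (*q, z0)
            p1, q1 = (*p, z1), (*q, z1)
            self.tri(p0, q0, q1)
            self.tri(p0, q1, p1)

    def build(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(np.asarray(self.verts, dtype=float),
                               np.asarray(self.faces, dtype=np.int64),
                               process=False)


def make_stand() -> trimesh.Trimesh:
    """Watertight stand assembly with the published dimensions.

    z = 0 .. 20 mm: 60 mm diameter base; z = 20 .. 40 mm: 20 mm diameter
    stand carrying the radial slot.  Total height 40 mm.
    """
    base_ring, stand_ring = _stand_profile()
    b = _MeshBuilder()
    # bottom disc (down)
    pts, tris = _triangulate_polygon(base_ring)
    b.cap(pts, tris, 0.0, up=False)
    # base wall
    b.wall(base_ring, 0.0, BASE_HEIGHT)
    # annulus at the base top: base circle minus stand footprint (up)
    pts, tris = _triangulate_polygon(base_ring, hole=stand_ring)
    b.cap(pts, tris, BASE_HEIGHT, up=True)
    # stand wall
    b.wall(stand_ring, BASE_HEIGHT, BASE_HEIGHT + STAND_HEIGHT)
    # stand top (up)
    pts, tris = _triangulate_polygon(stand_ring)
    b.cap(pts, tris, BASE_HEIGHT + STAND_HEIGHT, up=True)
    return b.build()
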