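"""Route planning on a sphere via multiple planar maps.

The sphere is tessellated by the 20 faces of a regular icosahedron whose
12 vertices carry the landmarks.  A planner that stores only local
planar maps answers "which way to the target?" by (1) selecting the
chain of faces crossed by a route, (2) developing (unfolding) that chain
isometrically onto a plane, hinging each face about the shared edge,
(3) drawing a straight line from the start's planar image to the
target's, and (4) executing the resulting direction and distance back on
the sphere.  With the face chain along the true great circle the plan is
nearly exact; a detour chain (the map "aligned suboptimally") produces
larger, but still bounded, errors.

Flattening of a single spherical face uses the azimuthal-equidistant
projection about the face centroid followed by the exact similarity that
places the three projected vertices on an equilateral planar triangle
with side equal to the icosahedral edge arc (63.435 degree units); the
per-face scale factor of that similarity is ~0.98, so within-face
distortion is small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    SPHERE,
    Geometry,
    GeometryError,
    Pose,
    advance,
    angular_separation,
    geodesic_distance,
    initial_bearing,
)

__all__ = [
    "EDGE_ARC_DEG",
    "IcosahedralAtlas",
    "FaceChain",
    "UnfoldedChain",
    "PlanErrorRecord",
    "build_atlas",
    "locate_face",
    "geodesic_face_chain",
    "detour_face_chain",
    "default_detour_vertex",
    "unfold_chain",
    "plan_and_execute",
    "simulate_route_planning",
]

#: Arc between edge-adjacent icosahedron vertices: arccos(1/sqrt(5)).
EDGE_ARC_DEG = math.degrees(math.acos(1.0 / math.sqrt(5.0)))

_TOL = 1e-12


@dataclass(frozen=True)
class IcosahedralAtlas:
    """The 12-vertex / 20-face icosahedral tessellation of the sphere.

    Vertex 0 is the orientation anchor (the "north pole" landmark);
    faces are stored as consistently outward-oriented (counter-clockwise
    seen from outside) vertex triples.
    """

    vertices: np.ndarray          # (12, 3) unit vectors
    faces: tuple[tuple[int, int, int], ...]   # 20 oriented triples
    edge_faces: dict              # frozenset{vi, vj} -> (face_a, face_b)
    face_neighbors: tuple[tuple[int, ...], ...]
    north_pole: int = 0

    def face_vertices(self, f: int) -> np.ndarray:
        return self.vertices[list(self.faces[f])]

    def face_centroid(self, f: int) -> np.ndarray:
        c = self.face_vertices(f).sum(axis=0)
        return c / np.linalg.norm(c)

    def vertex_faces(self, v: int) -> list[int]:
        return [i for i, f in enumerate(self.faces) if v in f]

    def shared_edge(self, fa: int, fb: int) -> frozenset:
        e = frozenset(self.faces[fa]) & frozenset(self.faces[fb])
        if len(e) != 2:
            raise GeometryError(f"faces {fa}, {fb} are not edge-adjacent")
        return e

    def adjacent_vertices(self, v: int) -> set[int]:
        out: set[int] = set()
        for e in self.edge_faces:
            if v in e:
                out |= e
        out.discard(v)
        return out


@dataclass(frozen=True)
class FaceChain:
    """Ordered sequence of pairwise edge-adjacent faces."""

    faces: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.faces)

    def validate(self, atlas: IcosahedralAtlas) -> None:
        for a, b in zip(self.faces, self.faces[1:]):
            if a == b:
                raise GeometryError("chain repeats a face consecutively")
            atlas.shared_edge(a, b)  # raises if not adjacent


@dataclass
class UnfoldedChain:
    """Planar development of a face chain, with start/target images.

    ``placed``: per chain position, a dict vertex id -> planar xy of that
    face's copy of the vertex (a vertex revisited later in the chain may
    receive a different image there — the development is per-face rigid,
    not globally injective).
    """

    chain: FaceChain
    placed: list[dict]
    face_maps: list["_FaceMap"]
    start_image: np.ndarray
    target_image: np.ndarray


@dataclass
class PlanErrorRecord:
    start: np.ndarray
    target: np.ndarray
    start_target_distance: float
    direction_error: float
    position_error: float
    arrangement: str
    chain_length: int = 0
    seed: int | None = None


# ---------------------------------------------------------------- atlas

def build_atlas(rotation: np.ndarray | None = None) -> IcosahedralAtlas:
    """Construct the icosahedral atlas, optionally rotated by a 3x3 matrix.

    Vertex 0 sits at the north pole, vertices 1-5 on the upper ring
    (latitude arctan(1/2)), 6-10 on the lower ring, 11 at the south pole.
    """
    lat = math.atan(0.5)
    verts = [np.array([0.0, 0.0, 1.0])]
    for i in range(5):
        lon = math.radians(72.0 * i)
        verts.append(
            np.array([math.cos(lat) * math.cos(lon),
                      math.cos(lat) * math.sin(lon),
                      math.sin(lat)])
        )
    for i in range(5):
        lon = math.radians(36.0 + 72.0 * i)
        verts.append(
            np.array([math.cos(lat) * math.cos(lon),
                      math.cos(lat) * math.sin(lon),
                      -math.sin(lat)])
        )
    verts.append(np.array([0.0, 0.0, -1.0]))
    V = np.array(verts)
    if rotation is not None:
        V = V @ np.asarray(rotation, dtype=float).T

    faces = []
    for i in range(5):
        j = (i + 1) % 5
        faces.append((0, 1 + i, 1 + j))                 # polar cap
    for i in range(5):
        j = (i + 1) % 5
        faces.append((1 + i, 6 + i, 1 + j))             # band, down-pointing
        faces.append((6 + i, 6 + j, 1 + j))             # band, up-pointing
    for i in range(5):
        j = (i + 1) % 5
        faces.append((11, 6 + j, 6 + i))                # south cap

    oriented = []
    for (a, b, c) in faces:
        if np.linalg.det(np.array([V[a], V[b], V[c]])) < 0:
            a, b, c = a, c, b
        oriented.append((a, b, c))

    edge_faces: dict = {}
    for fi, f in enumerate(oriented):
        for k in range(3):
            e = frozenset((f[k], f[(k + 1) % 3]))
            edge_faces.setdefault(e, []).append(fi)
    edge_faces = {e: tuple(sorted(fs)) for e, fs in edge_faces.items()}

    neighbors: list[tuple[int, ...]] = []
    for fi, f in enumerate(oriented):
        nb = []
        for k in range(3):
            e = frozenset((f[k], f[(k + 1) % 3]))
            nb.extend(x for x in edge_faces[e] if x != fi)
        neighbors.append(tuple(nb))

    return IcosahedralAtlas(
        vertices=V,
        faces=tuple(oriented),
        edge_faces=edge_faces,
        face_neighbors=tuple(neighbors),
    )


def _edge_normals(atlas: IcosahedralAtlas) -> np.ndarray:
    """(20, 3, 3) inward edge-plane normals; p inside face f iff all three
    dot products are >= 0 (faces are CCW from outside)."""
    N = np.empty((20, 3, 3))
    for fi, (a, b, c) in enumerate(atlas.faces):
        V = atlas.vertices
        N[fi, 0] = np.cross(V[a], V[b])
        N[fi, 1] = np.cross(V[b], V[c])
        N[fi, 2] = np.cross(V[c], V[a])
    return N


def locate_face(p: np.ndarray, atlas: IcosahedralAtlas, tol: float = 1e-12) -> int:
    """Face whose spherical triangle contains p; edge/vertex ties broken
    by the lowest face id."""
    p = np.asarray(p, dtype=float)
    normals = _cached_normals(atlas)
    dots = normals @ p                         # (20, 3)
    inside = np.all(dots >= -tol, axis=1)
    ids = np.nonzero(inside)[0]
    if len(ids) == 0:                          # numeric edge case: relax
        worst = dots.min(axis=1)
        return int(np.argmax(worst))
    return int(ids[0])


def _locate_faces(P: np.ndarray, atlas: IcosahedralAtlas, tol: float = 1e-12) -> np.ndarray:
    """Vectorised locate_face over an (n, 3) array of unit points."""
    normals = _cached_normals(atlas)           # (20, 3, 3)
    dots = np.einsum("fki,ni->nfk", normals, P)
    inside = np.all(dots >= -tol, axis=2)      # (n, 20)
    out = np.argmax(inside, axis=1)            # first True = lowest id
    missing = ~inside.any(axis=1)
    if missing.any():
        worst = dots[missing].min(axis=2)
        out[missing] = np.argmax(worst, axis=1)
    return out


_NORMAL_CACHE: dict = {}


def _cached_normals(atlas: IcosahedralAtlas) -> np.ndarray:
    key = id(atlas)
    if key not in _NORMAL_CACHE:
        if len(_NORMAL_CACHE) > 32:
            _NORMAL_CACHE.clear()
        _NORMAL_CACHE[key] = _edge_normals(atlas)
    return _NORMAL_CACHE[key]


# ----------------------------------------------------------- face chains

def _slerp_arc(p: np.ndarray, q: np.ndarray, n: int) -> np.ndarray:
    ang = math.atan2(np.linalg.norm(np.cross(p, q)), float(p @ q))
    t = np.linspace(0.0, 1.0, n)
    if ang < 1e-12:
        return np.tile(p, (n, 1))
    A = np.sin((1 - t) * ang)[:, None] * p + np.sin(t * ang)[:, None] * q
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    return A


def _rotate_about(v: np.ndarray, axis: np.ndarray, ang: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * math.cos(ang)
        + np.cross(axis, v) * math.sin(ang)
        + axis * float(axis @ v) * (1 - math.cos(ang))
    )


def geodesic_face_chain(
    start: np.ndarray, target: np.ndarray, atlas: IcosahedralAtlas
) -> FaceChain:
    """Ordered faces crossed by the shortest great-circle arc start→target.

    Arcs that pass exactly through a vertex are perturbed by a tiny
    rotation (1e-9 rad, growing if needed) toward the target's face so
    the traced chain is edge-adjacent and deterministic.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if float(start @ target) < -1.0 + 1e-12:
        raise GeometryError("antipodal start/target: chain not unique")
    for eps in (0.0, 1e-9, 1e-7, 1e-5):
        tgt = target
        if eps > 0.0:
            # nudge the arc sideways: rotate the target about the axis
            # through the start (deterministic direction)
            axis = start
            tgt = _rotate_about(target, axis, eps)
            tgt /= np.linalg.norm(tgt)
        chain = _trace_chain(start, tgt, atlas, start, target)
        try:
            chain.validate(atlas)
            return chain
        except GeometryError:
            continue
    raise GeometryError("could not trace an edge-adjacent face chain")


def _contains(atlas: IcosahedralAtlas, face: int, p: np.ndarray,
              tol: float = 1e-9) -> bool:
    return bool(np.all(_cached_normals(atlas)[face] @ p >= -tol))


def _trace_chain(start, target, atlas, true_start=None, true_target=None) -> FaceChain:
    true_start = start if true_start is None else true_start
    true_target = target if true_target is None else true_target
    arc_deg = geodesic_distance(start, target, SPHERE)
    n = max(64, int(arc_deg / 0.02) + 2)
    P = _slerp_arc(start, target, n)
    fids = list(_locate_faces(P, atlas))
    seq = [int(fids[0])]
    for f in fids[1:]:
        if int(f) != seq[-1]:
            seq.append(int(f))
    # collapse immediate backtracks a-b-a caused by samples grazing an edge
    i = 0
    while i + 2 < len(seq):
        if seq[i] == seq[i + 2]:
            del seq[i + 1 : i + 3]
            i = max(i - 1, 0)
        else:
            i += 1
    # endpoints on an edge/vertex: the tie-broken face may differ from the
    # traced one; keep the traced face when it also contains the endpoint
    f_start = locate_face(true_start, atlas)
    if seq[0] != f_start and not _contains(atlas, seq[0], true_start):
        seq.insert(0, f_start)
    f_target = locate_face(true_target, atlas)
    if seq[-1] != f_target and not _contains(atlas, seq[-1], true_target):
        seq.append(f_target)
    # arc passing (numerically) through a vertex: bridge the two fan faces
    # with their lowest-id common neighbour
    out = [seq[0]]
    for f in seq[1:]:
        prev = out[-1]
        if f != prev and f not in atlas.face_neighbors[prev]:
            common = sorted(
                set(atlas.face_neighbors[prev]) & set(atlas.face_neighbors[f])
            )
            if common:
                out.append(common[0])
        if f != out[-1]:
            out.append(f)
    return FaceChain(tuple(out))


def _vertex_fan(atlas: IcosahedralAtlas, v: int) -> list[int]:
    """Faces incident to vertex v in cyclic order around it."""
    vv = atlas.vertices[v]
    nb = min(atlas.adjacent_vertices(v))
    e1 = np.cross(vv, atlas.vertices[nb])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(vv, e1)
    items = []
    for f in atlas.vertex_faces(v):
        c = atlas.face_centroid(f)
        t = c - float(vv @ c) * vv
        items.append((math.atan2(float(t @ e2), float(t @ e1)), f))
    return [f for _, f in sorted(items)]


def optimal_waypoints(
    start: np.ndarray, target: np.ndarray, atlas: IcosahedralAtlas
) -> list[int]:
    """Minimal landmark sequence along the optimal route.

    At each face-to-face crossing of the great-circle arc, the landmark
    the route hugs is the crossed edge's vertex nearer the arc's plane;
    deduplicated in order, excluding any vertex the target sits on.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    chain = geodesic_face_chain(start, target, atlas)
    nrm = np.cross(start, target)
    nrm /= np.linalg.norm(nrm)
    seq: list[int] = []
    for fa, fb in zip(chain.faces, chain.faces[1:]):
        i, j = sorted(atlas.shared_edge(fa, fb))
        di = abs(float(nrm @ atlas.vertices[i]))
        dj = abs(float(nrm @ atlas.vertices[j]))
        v = i if di < dj else j
        if geodesic_distance(atlas.vertices[v], target, SPHERE) < 1e-6:
            continue
        if v not in seq:
            seq.append(v)
    return seq


def default_detour_vertex(
    atlas: IcosahedralAtlas,
    start: np.ndarray,
    target: np.ndarray,
) -> int:
    """Deterministic detour landmark for the suboptimal arrangement.

    The detour plays the role of a wrongly recalled *first* landmark: it
    must be off the optimal landmark sequence (all vertices of the faces
    the optimal chain crosses), not among the start's or target's own
    face landmarks, and adjacent to the first optimal waypoint; ties are
    broken by lowest vertex id.  Fallbacks relax adjacency step by step.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    chain = geodesic_face_chain(start, target, atlas)
    on_route: set[int] = set()
    for f in chain.faces:
        on_route |= set(atlas.faces[f])
    start_face = set(atlas.faces[locate_face(start, atlas)])
    target_face = set(atlas.faces[locate_face(target, atlas)])
    excluded = on_route | start_face | target_face

    def legs_ok(v: int) -> bool:
        # both legs of the detour route must have well-defined bearings
        for p in (start, target):
            d = geodesic_distance(atlas.vertices[v], p, SPHERE)
            if d < 1.0 or d > 179.0:
                return False
        return True

    wps = optimal_waypoints(start, target, atlas)
    base = [v for v in range(12) if v not in excluded and legs_ok(v)]
    # "first recalled" landmark: in the start's neighbourhood (adjacent to
    # one of the start face's landmarks)
    local: set[int] = set()
    for v in start_face:
        local |= atlas.adjacent_vertices(v)
    tiers: list[list[int]] = []
    if wps:
        tiers.append(
            [v for v in base
             if v in local and v in atlas.adjacent_vertices(wps[0])]
        )
    tiers.append(
        [v for v in base if v in local and atlas.adjacent_vertices(v) & on_route]
    )
    tiers.append([v for v in base if v in local])
    tiers.append([v for v in base if atlas.adjacent_vertices(v) & on_route])
    tiers.append(base)
    tiers.append([v for v in range(12) if v not in on_route and legs_ok(v)])
    for candidates in tiers:
        if candidates:
            return min(candidates)
    raise GeometryError("no admissible detour vertex for this pair")


def _route_face_chain(
    points: list[np.ndarray],
    vertex_ids: list[int | None],
    atlas: IcosahedralAtlas,
) -> FaceChain:
    """Face chain along a geodesic polyline whose interior waypoints are
    atlas vertices; consecutive legs are stitched through the shorter
    side of each waypoint's face fan."""
    eps = 1e-4  # degrees: stop legs just short of waypoint vertices
    legs: list[list[int]] = []
    for (a, va), (b, vb) in zip(
        zip(points, vertex_ids), zip(points[1:], vertex_ids[1:])
    ):
        d = geodesic_distance(a, b, SPHERE)
        p0, p1 = a, b
        if va is not None:
            p0 = advance(
                Pose(a, initial_bearing(a, b, SPHERE), SPHERE), min(eps, d / 2)
            ).position
        if vb is not None:
            p1 = advance(
                Pose(b, initial_bearing(b, a, SPHERE), SPHERE), min(eps, d / 2)
            ).position
        legs.append(list(geodesic_face_chain(p0, p1, atlas).faces))

    seq = list(legs[0])
    for k, leg in enumerate(legs[1:]):
        v = vertex_ids[k + 1]
        fan = _vertex_fan(atlas, v)
        if seq[-1] not in fan:
            seq.append(_nearest_fan_face(atlas, fan, seq[-1]))
        if leg[0] not in fan:
            leg.insert(0, _nearest_fan_face(atlas, fan, leg[0]))
        ia, ib = fan.index(seq[-1]), fan.index(leg[0])
        m = len(fan)
        fwd = [(ia + s) % m for s in range(1, (ib - ia) % m)]
        bwd = [(ia - s) % m for s in range(1, (ia - ib) % m)]
        middle = [fan[i] for i in (fwd if len(fwd) <= len(bwd) else bwd)]
        seq += middle + leg

    out = [seq[0]]
    for f in seq[1:]:
        if f != out[-1]:
            out.append(f)
    i = 0
    while i + 2 < len(out):
        if out[i] == out[i + 2]:
            del out[i + 1 : i + 3]
            i = max(i - 1, 0)
        else:
            i += 1
    chain = FaceChain(tuple(out))
    chain.validate(atlas)
    return chain


def detour_face_chain(
    start: np.ndarray,
    target: np.ndarray,
    atlas: IcosahedralAtlas,
    detour: int,
) -> FaceChain:
    """Face chain of the suboptimally aligned map: the recalled route
    visits the detour landmark first and then the optimal landmark
    sequence on the way to the target (mirroring a wrongly recalled
    first landmark), and the map strip is developed along that polyline.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    chain_opt = geodesic_face_chain(start, target, atlas)
    on_route: set[int] = set()
    for f in chain_opt.faces:
        on_route |= set(atlas.faces[f])
    if detour in on_route:
        raise GeometryError("detour vertex lies on the optimal landmark route")
    for p in (start, target):
        d = geodesic_distance(atlas.vertices[detour], p, SPHERE)
        if d < 1.0 or d > 179.0:
            raise GeometryError("detour vertex too close/antipodal to endpoints")

    wps = optimal_waypoints(start, target, atlas)
    points = [start, atlas.vertices[detour]]
    vids: list[int | None] = [None, detour]
    for w in wps:
        points.append(atlas.vertices[w])
        vids.append(w)
    points.append(target)
    vids.append(None)
    # drop interior waypoints that make a leg degenerate (coincident or
    # antipodal with a neighbour, e.g. the polar waypoint of a polar target)
    changed = True
    while changed:
        changed = False
        for i in range(len(points) - 1):
            d = geodesic_distance(points[i], points[i + 1], SPHERE)
            if d < 1e-6 or d > 179.0:
                drop = i + 1 if vids[i + 1] is not None else i
                if vids[drop] is None:
                    raise GeometryError("degenerate detour route endpoints")
                del points[drop], vids[drop]
                changed = True
                break
    return _route_face_chain(points, vids, atlas)


def _nearest_fan_face(atlas, fan, f):
    for g in atlas.face_neighbors[f]:
        if g in fan:
            return g
    raise GeometryError("face chain does not reach the detour fan")


# ------------------------------------------------------------- unfolding

class _FaceMap:
    """Flattening map of one spherical face to its planar placement.

    Composition of the azimuthal-equidistant projection about the face
    centroid (radial arc lengths preserved) with the exact similarity
    that sends the three projected vertices onto the placed planar
    triangle.  Invertible; differentiable numerically.
    """

    def __init__(self, atlas: IcosahedralAtlas, face: int, placed_xy: dict):
        self.face = face
        c = atlas.face_centroid(face)
        self.centroid = c
        a = atlas.vertices[atlas.faces[face][0]]
        e1 = a - float(c @ a) * c
        e1 /= np.linalg.norm(e1)
        self.e1, self.e2 = e1, np.cross(c, e1)
        src = np.array([self._aep(atlas.vertices[v]) for v in atlas.faces[face]])
        dst = np.array([placed_xy[v] for v in atlas.faces[face]])
        zs = src[:, 0] + 1j * src[:, 1]
        zd = dst[:, 0] + 1j * dst[:, 1]
        zs_c, zd_c = zs - zs.mean(), zd - zd.mean()
        self._a = complex((zd_c @ zs_c.conj()) / (zs_c @ zs_c.conj()))
        self._b = complex(zd.mean() - self._a * zs.mean())
        resid = np.abs(self._a * zs + self._b - zd).max()
        if resid > 1e-9:
            raise GeometryError(f"similarity fit residual {resid:.2e}")

    def _aep(self, p: np.ndarray) -> np.ndarray:
        c = self.centroid
        theta = math.degrees(
            math.atan2(np.linalg.norm(np.cross(c, p)), float(c @ p))
        )
        if theta < 1e-15:
            return np.zeros(2)
        t = p - float(c @ p) * c
        t /= np.linalg.norm(t)
        return theta * np.array([float(t @ self.e1), float(t @ self.e2)])

    def _aep_inv(self, xy: np.ndarray) -> np.ndarray:
        theta = math.radians(float(np.hypot(xy[0], xy[1])))
        if theta < 1e-15:
            return self.centroid.copy()
        u = xy / np.linalg.norm(xy)
        t = u[0] * self.e1 + u[1] * self.e2
        return self.centroid * math.cos(theta) + t * math.sin(theta)

    def to_plane(self, p: np.ndarray) -> np.ndarray:
        xy = self._aep(p)
        z = self._a * complex(xy[0], xy[1]) + self._b
        return np.array([z.real, z.imag])

    def to_sphere(self, xy: np.ndarray) -> np.ndarray:
        z = (complex(xy[0], xy[1]) - self._b) / self._a
        return self._aep_inv(np.array([z.real, z.imag]))


def unfold_chain(
    chain: FaceChain,
    start: np.ndarray,
    target: np.ndarray,
    atlas: IcosahedralAtlas,
) -> UnfoldedChain:
    """Develop the face chain onto the plane by successive edge hinges.

    The first face is flattened about its centroid; each subsequent face
    is attached as the equilateral triangle across the already-placed
    shared edge.  Start and target are mapped through the flattening of
    their containing (first/last) faces.
    """
    side = EDGE_ARC_DEG
    f0 = chain.faces[0]
    c = atlas.face_centroid(f0)
    a0 = atlas.vertices[atlas.faces[f0][0]]
    e1 = a0 - float(c @ a0) * c
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)

    def aep0(p):
        th = math.degrees(math.atan2(np.linalg.norm(np.cross(c, p)), float(c @ p)))
        t = p - float(c @ p) * c
        n = np.linalg.norm(t)
        if n < 1e-15:
            return np.zeros(2)
        t /= n
        return th * np.array([float(t @ e1), float(t @ e2)])

    proj0 = {v: aep0(atlas.vertices[v]) for v in atlas.faces[f0]}
    # scale projected vertices to the ideal equilateral triangle
    circ_ideal = side / math.sqrt(3.0)
    r0 = float(np.linalg.norm(proj0[atlas.faces[f0][0]]))
    k = circ_ideal / r0
    placed: list[dict] = [{v: k * xy for v, xy in proj0.items()}]

    for prev, cur in zip(chain.faces, chain.faces[1:]):
        e = atlas.shared_edge(prev, cur)
        i, j = sorted(e)
        A, B = placed[-1][i], placed[-1][j]
        (third_prev,) = set(atlas.faces[prev]) - e
        (third_cur,) = set(atlas.faces[cur]) - e
        P = placed[-1][third_prev]
        M = (A + B) / 2.0
        d = B - A
        perp = np.array([-d[1], d[0]])
        perp /= np.linalg.norm(perp)
        h = side * math.sqrt(3.0) / 2.0
        sgn = -1.0 if float(perp @ (P - M)) > 0 else 1.0
        C = M + sgn * h * perp
        placed.append({i: A.copy(), j: B.copy(), third_cur: C})

    maps = [_FaceMap(atlas, f, placed[k]) for k, f in enumerate(chain.faces)]
    return UnfoldedChain(
        chain=chain,
        placed=placed,
        face_maps=maps,
        start_image=maps[0].to_plane(np.asarray(start, dtype=float)),
        target_image=maps[-1].to_plane(np.asarray(target, dtype=float)),
    )


# --------------------------------------------------------------- planner

def plan_and_execute(
    start: np.ndarray,
    target: np.ndarray,
    chain: FaceChain,
    atlas: IcosahedralAtlas,
    arrangement: str = "optimal",
) -> PlanErrorRecord:
    """Plan a straight route on the unfolded chain and execute on the sphere.

    The planar plan is the segment from the start's image to the
    target's image.  Its direction is lifted back to a spherical heading
    at the start through the first face's flattening map (numerical
    differential); the planar length is walked along that great circle.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    dist = geodesic_distance(start, target, SPHERE)
    unfolded = unfold_chain(chain, start, target, atlas)
    d = unfolded.target_image - unfolded.start_image
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        return PlanErrorRecord(start, target, dist, 0.0, 0.0, arrangement,
                               chain_length=len(chain))
    u = d / L
    eps = 1e-3  # degree units; lift error is O(eps^2/R^2), negligible
    fmap = unfolded.face_maps[0]
    p2 = fmap.to_sphere(unfolded.start_image + eps * u)
    heading = initial_bearing(start, p2, SPHERE)
    heading = heading - float(start @ heading) * start
    heading /= np.linalg.norm(heading)
    arrival = advance(Pose(start, heading, SPHERE), L).position
    true_bearing = initial_bearing(start, target, SPHERE)
    return PlanErrorRecord(
        start=start,
        target=target,
        start_target_distance=dist,
        direction_error=angular_separation(heading, true_bearing),
        position_error=geodesic_distance(arrival, target, SPHERE),
        arrangement=arrangement,
        chain_length=len(chain),
    )


def _sample_starts(
    rng: np.random.Generator,
    target: np.ndarray,
    n: int,
    min_distance: float,
    max_distance: float,
) -> np.ndarray:
    """Uniform points on the sphere, rejection-filtered by target distance."""
    out = []
    while len(out) < n:
        P = rng.normal(size=(4 * n, 3))
        P /= np.linalg.norm(P, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(P @ target, -1.0, 1.0)))
        keep = (ang > min_distance) & (ang < max_distance)
        out.extend(P[keep])
    return np.array(out[:n])


def simulate_route_planning(
    atlas: IcosahedralAtlas,
    n_starts: int,
    arrangement: str = "optimal",
    min_distance: float = 0.0,
    seed: int = 0,
    max_distance: float = 179.5,
    target_vertex: int | None = None,
) -> list[PlanErrorRecord]:
    """Multi-planar-map planning errors over random start locations.

    One fixed target sits at an atlas vertex (the rotational symmetry of
    the sphere makes a single target sufficient); starts are uniform on
    the admissible annulus.  ``arrangement="suboptimal"`` routes each
    start through a single detour landmark adjacent to the optimal
    landmark sequence and requires ``min_distance >= 120``.
    """
    if n_starts <= 0:
        raise ValueError("n_starts must be positive")
    if arrangement not in ("optimal", "suboptimal"):
        raise ValueError("arrangement must be 'optimal' or 'suboptimal'")
    if arrangement == "suboptimal" and min_distance < 120.0:
        raise ValueError("suboptimal arrangement requires min_distance >= 120")
    if target_vertex is None:
        # south pole: starts above 120 deg lie in the well-conditioned
        # northern cap of the vertex fan
        target_vertex = 11
    target = atlas.vertices[target_vertex]
    rng = np.random.default_rng(seed)
    starts = _sample_starts(rng, target, n_starts, min_distance, max_distance)
    records = []
    for s in starts:
        if arrangement == "optimal":
            chain = geodesic_face_chain(s, target, atlas)
        else:
            dv = default_detour_vertex(atlas, s, target)
            chain = detour_face_chain(s, target, atlas, dv)
        rec = plan_and_execute(s, target, chain, atlas, arrangement)
        rec.seed = seed
        records.append(rec)
    return records
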