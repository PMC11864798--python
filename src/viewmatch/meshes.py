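"""Polygon meshes: container, topology checks, Catmull-Clark subdivision, OBJ I/O.

Meshes are closed, oriented 2-manifolds of quads and/or triangles with sphere
topology (Euler characteristic 2).  The generator in :mod:`viewmatch.shapegen`
only performs operations that preserve these properties, and every public
routine here validates them where cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ObjectMesh",
    "MeshStructureError",
    "catmull_clark",
    "read_obj",
    "write_obj",
]


class MeshStructureError(ValueError):
    """Raised when a mesh violates the closed-2-manifold contract."""


@dataclass
class ObjectMesh:
    """A polygon mesh with identity metadata.

    Parameters
    ----------
    vertices : (V, 3) float array of vertex positions.
    faces : list of vertex-index polygons (counter-clockwise seen from
        outside).  Quads and triangles are both allowed.
    object_id, category : identity labels carried through rendering and
        trial construction.
    """

    vertices: np.ndarray
    faces: list[list[int]]
    object_id: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshStructureError("vertices must be an (V, 3) array")
        self.faces = [list(map(int, f)) for f in self.faces]
        nv = len(self.vertices)
        for f in self.faces:
            if len(f) < 3:
                raise MeshStructureError(f"face with fewer than 3 vertices: {f}")
            if len(set(f)) != len(f):
                raise MeshStructureError(f"degenerate face with repeated vertex: {f}")
            if any(i < 0 or i >= nv for i in f):
                raise MeshStructureError(f"face index out of range: {f}")

    # -- topology -----------------------------------------------------------

    def edges(self) -> dict[tuple[int, int], list[int]]:
        """Undirected edge -> incident face indices."""
        out: dict[tuple[int, int], list[int]] = {}
        for fi, f in enumerate(self.faces):
            for a, b in zip(f, f[1:] + f[:1]):
                key = (a, b) if a < b else (b, a)
                out.setdefault(key, []).append(fi)
        return out

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def validate_closed_manifold(self) -> None:
        """Check every edge is shared by exactly two faces and orientation is
        consistent (each directed edge used exactly once)."""
        for edge, facelist in self.edges().items():
            if len(facelist) != 2:
                raise MeshStructureError(
                    f"edge {edge} belongs to {len(facelist)} faces (expected 2)"
                )
        directed: set[tuple[int, int]] = set()
        for f in self.faces:
            for a, b in zip(f, f[1:] + f[:1]):
                if (a, b) in directed:
                    raise MeshStructureError(f"inconsistent orientation at edge {(a, b)}")
                directed.add((a, b))

    # -- geometry -----------------------------------------------------------

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bounding_radius(self) -> float:
        c = self.centroid()
        return float(np.linalg.norm(self.vertices - c, axis=1).max())

    def triangulated(self) -> np.ndarray:
        """Fan-triangulate polygons; returns (T, 3) int array of indices."""
        tris = []
        for f in self.faces:
            for i in range(1, len(f) - 1):
                tris.append((f[0], f[i], f[i + 1]))
        return np.asarray(tris, dtype=int)

    def copy(self) -> "ObjectMesh":
        return ObjectMesh(
            self.vertices.copy(), [list(f) for f in self.faces], self.object_id, self.category
        )


def catmull_clark(mesh: ObjectMesh, levels: int = 1) -> ObjectMesh:
    """Catmull-Clark subdivision applied ``levels`` times.

    One level of the classic scheme on a closed mesh:

    * face point ``F`` = centroid of each face,
    * edge point ``E`` = average of the edge's endpoints and the two adjacent
      face points,
    * moved vertex ``P' = (Q + 2R + (n - 3) P) / n`` with ``Q`` the average of
      adjacent face points, ``R`` the average of incident edge midpoints and
      ``n`` the vertex valence,
    * each k-gon is replaced by k quads, so ``V' = V + E + F`` and the Euler
      characteristic is preserved.

    ``levels = 0`` returns the input unchanged.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    out = mesh
    for _ in range(levels):
        out = _catmull_clark_once(out)
    return out


def _catmull_clark_once(mesh: ObjectMesh) -> ObjectMesh:
    mesh.validate_closed_manifold()
    verts = mesh.vertices
    faces = mesh.faces
    edge_to_faces = mesh.edges()

    face_points = np.array([verts[f].mean(axis=0) for f in faces])

    edge_keys = list(edge_to_faces.keys())
    edge_index = {e: i for i, e in enumerate(edge_keys)}
    edge_points = np.empty((len(edge_keys), 3))
    for e, i in edge_index.items():
        fa, fb = edge_to_faces[e]
        edge_points[i] = (verts[e[0]] + verts[e[1]] + face_points[fa] + face_points[fb]) / 4.0

    # accumulate per-vertex sums of adjacent face points and edge midpoints
    n = len(verts)
    q_sum = np.zeros((n, 3))
    face_count = np.zeros(n)
    for fi, f in enumerate(faces):
        for v in f:
            q_sum[v] += face_points[fi]
            face_count[v] += 1
    r_sum = np.zeros((n, 3))
    edge_count = np.zeros(n)
    for (a, b) in edge_keys:
        mid = (verts[a] + verts[b]) / 2.0
        r_sum[a] += mid
        r_sum[b] += mid
        edge_count[a] += 1
        edge_count[b] += 1

    # closed manifold: valence = #edges = #faces at each vertex
    val = edge_count
    q = q_sum / face_count[:, None]
    r = r_sum / edge_count[:, None]
    new_orig = (q + 2.0 * r + (val - 3.0)[:, None] * verts) / val[:, None]

    new_verts = np.vstack([new_orig, face_points, edge_points])
    fp_off = n
    ep_off = n + len(faces)

    new_faces: list[list[int]] = []
    for fi, f in enumerate(faces):
        k = len(f)
        for i in range(k):
            v = f[i]
            e_next = f[i], f[(i + 1) % k]
            e_prev = f[(i - 1) % k], f[i]
            ei_next = edge_index[tuple(sorted(e_next))]
            ei_prev = edge_index[tuple(sorted(e_prev))]
            new_faces.append([v, ep_off + ei_next, fp_off + fi, ep_off + ei_prev])

    return ObjectMesh(new_verts, new_faces, mesh.object_id, mesh.category)


# -- OBJ I/O ---------------------------------------------------------------


def write_obj(mesh: ObjectMesh, path: str | Path) -> None:
    """Write v/f records with 1-based indices."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"o {mesh.object_id or 'object'}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        for f in mesh.faces:
            fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")


def read_obj(path: str | Path, object_id: str = "", category: str = "") -> ObjectMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    oid = object_id
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "o" and not object_id:
            oid = parts[1] if len(parts) > 1 else oid
        elif parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            # tolerate v/vt/vn syntax
            faces.append([int(p.split("/")[0]) - 1 for p in parts[1:]])
    return ObjectMesh(np.asarray(verts), faces, oid, category)


def cube(extents: np.ndarray | tuple[float, float, float] = (1.0, 1.0, 1.0)) -> ObjectMesh:
    """Axis-aligned box centred at the origin, six outward-facing quads."""
    ex, ey, ez = np.asarray(extents, dtype=float) / 2.0
    verts = np.array(
        [
            [-ex, -ey, -ez],
            [+ex, -ey, -ez],
            [+ex, +ey, -ez],
            [-ex, +ey, -ez],
            [-ex, -ey, +ez],
            [+ex, -ey, +ez],
            [+ex, +ey, +ez],
            [-ex, +ey, +ez],
        ]
    )
    faces = [
        [0, 3, 2, 1],  # -z
        [4, 5, 6, 7],  # +z
        [0, 1, 5, 4],  # -y
        [2, 3, 7, 6],  # +y
        [1, 2, 6, 5],  # +x
        [3, 0, 4, 7],  # -x
    ]
    return ObjectMesh(verts, faces)
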