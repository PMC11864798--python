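"""Procedural abstract-object generator.

Objects start as a box whose edge lengths are drawn from a seeded random
stream, a random face is extruded 5-10 times (each extrusion at a random
angle off the face normal and with a random length), and the result is
smoothed with Catmull-Clark subdivision.  Every operation preserves closed
2-manifold sphere topology, so V - E + F = 2 holds for every output.

Candidate extrusion sequences that produce a self-intersecting cage are
rejected and resampled; the number of rejections is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .meshes import MeshStructureError, ObjectMesh, catmull_clark, cube

__all__ = ["ShapeGenParams", "generate_shape", "ShapeGenError"]

log = logging.getLogger(__name__)


class ShapeGenError(ValueError):
    """Invalid generator parameters."""


@dataclass
class ShapeGenParams:
    """Parameters of the procedural generator.

    ``extrude_min``/``extrude_max`` bound the number of face extrusions
    (default 5-10).  ``angle_range`` is the maximum tilt, in radians, of the
    extrusion direction away from the face normal.  ``length_range`` bounds
    the extrusion length in mesh units.  ``base_size_range`` bounds the box
    edge lengths (unstated upstream; exposed as configuration).
    """

    seed: int = 0
    extrude_min: int = 5
    extrude_max: int = 10
    angle_range: float = np.pi / 5
    length_range: tuple[float, float] = (0.3, 0.9)
    base_size_range: tuple[float, float] = (0.7, 1.4)
    subdivision_levels: int = 2
    max_resample: int = 50

    def validate(self) -> None:
        if self.extrude_min > self.extrude_max:
            raise ShapeGenError("extrude_min > extrude_max")
        if self.extrude_min < 0:
            raise ShapeGenError("extrude_min must be >= 0")
        if not (0 <= self.angle_range < np.pi / 2):
            raise ShapeGenError("angle_range must lie in [0, pi/2)")
        for name, (lo, hi) in (
            ("length_range", self.length_range),
            ("base_size_range", self.base_size_range),
        ):
            if lo > hi or lo <= 0:
                raise ShapeGenError(f"{name} must be a non-empty positive range")
        if self.subdivision_levels < 0:
            raise ShapeGenError("subdivision_levels must be >= 0")


def generate_shape(params: ShapeGenParams, object_id: str = "", category: str = "") -> ObjectMesh:
    """Generate one abstract object; identical seed => identical mesh."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    rejections = 0
    for _attempt in range(params.max_resample):
        cage = _build_cage(params, rng)
        if not _self_intersects(cage):
            mesh = catmull_clark(cage, params.subdivision_levels)
            mesh.object_id = object_id
            mesh.category = category
            mesh.validate_closed_manifold()
            # stash provenance for inspection
            mesh.n_rejected = rejections  # type: ignore[attr-defined]
            return mesh
        rejections += 1
        log.warning("self-intersecting cage rejected (attempt %d)", rejections)
    raise ShapeGenError(f"failed to generate a valid shape after {params.max_resample} attempts")


def _build_cage(params: ShapeGenParams, rng: np.random.Generator) -> ObjectMesh:
    lo, hi = params.base_size_range
    mesh = cube(rng.uniform(lo, hi, size=3))
    k = int(rng.integers(params.extrude_min, params.extrude_max + 1))
    for _ in range(k):
        face_idx = int(rng.integers(len(mesh.faces)))
        angle = rng.uniform(0.0, params.angle_range)
        azimuth = rng.uniform(0.0, 2 * np.pi)
        length = rng.uniform(*params.length_range)
        mesh = _extrude_face(mesh, face_idx, angle, azimuth, length)
    mesh.n_extrusions = k  # type: ignore[attr-defined]
    return mesh


def _face_normal(verts: np.ndarray, face: list[int]) -> np.ndarray:
    # Newell's method: robust for non-planar polygons
    n = np.zeros(3)
    for a, b in zip(face, face[1:] + face[:1]):
        va, vb = verts[a], verts[b]
        n[0] += (va[1] - vb[1]) * (va[2] + vb[2])
        n[1] += (va[2] - vb[2]) * (va[0] + vb[0])
        n[2] += (va[0] - vb[0]) * (va[1] + vb[1])
    norm = np.linalg.norm(n)
    if norm == 0:
        raise MeshStructureError("degenerate face with zero normal")
    return n / norm


def _extrude_face(
    mesh: ObjectMesh, face_idx: int, angle: float, azimuth: float, length: float
) -> ObjectMesh:
    """Extrude one face along its normal tilted by ``angle`` (azimuth picks
    the tilt plane).  Removes the face, adds a translated copy plus one side
    quad per edge; V += k, E += 2k, F += k so the Euler characteristic is
    unchanged."""
    verts = mesh.vertices
    face = mesh.faces[face_idx]
    normal = _face_normal(verts, face)

    # orthonormal frame around the normal for the tilt
    helper = np.array([0.0, 0.0, 1.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(normal, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    direction = (
        np.cos(angle) * normal + np.sin(angle) * (np.cos(azimuth) * t1 + np.sin(azimuth) * t2)
    )

    offset = len(verts)
    new_verts = verts[face] + length * direction
    all_verts = np.vstack([verts, new_verts])

    k = len(face)
    top = [offset + i for i in range(k)]
    faces = [f for i, f in enumerate(mesh.faces) if i != face_idx]
    faces.append(top)
    for i in range(k):
        a, b = face[i], face[(i + 1) % k]
        ta, tb = top[i], top[(i + 1) % k]
        faces.append([a, b, tb, ta])
    out = ObjectMesh(all_verts, faces, mesh.object_id, mesh.category)
    return out


# -- self-intersection test -------------------------------------------------


def _self_intersects(mesh: ObjectMesh, rel_tol: float = 1e-6) -> bool:
    """Triangle-pair intersection with an axis-aligned-box broad phase.

    Pairs that share a vertex are skipped (adjacent faces always touch).
    ``rel_tol`` scales with the bounding-box diagonal.
    """
    tris = mesh.triangulated()
    pts = mesh.vertices[tris]  # (T, 3, 3)
    lo = pts.min(axis=1)
    hi = pts.max(axis=1)
    diag = float(np.linalg.norm(mesh.vertices.max(0) - mesh.vertices.min(0)))
    eps = rel_tol * diag
    n = len(tris)
    for i in range(n):
        # broad phase against all later triangles at once
        overlap = np.all(lo[i + 1 :] <= hi[i] + eps, axis=1) & np.all(
            hi[i + 1 :] >= lo[i] - eps, axis=1
        )
        for j in np.nonzero(overlap)[0] + i + 1:
            if set(tris[i]) & set(tris[j]):
                continue
            if _tri_tri_intersect(pts[i], pts[j], eps):
                return True
    return False


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray, eps: float) -> bool:
    """Segment-against-triangle test in both directions (sufficient for
    detecting crossing cages; coplanar grazing contact below eps ignored)."""
    for a, b in ((t1, t2), (t2, t1)):
        for i in range(3):
            p, q = a[i], a[(i + 1) % 3]
            if _segment_hits_triangle(p, q, b, eps):
                return True
    return False


def _segment_hits_triangle(p: np.ndarray, q: np.ndarray, tri: np.ndarray, eps: float) -> bool:
    # Moller-Trumbore ray/triangle with segment-range clamp
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    d = q - p
    h = np.cross(d, e2)
    det = e1 @ h
    if abs(det) < 1e-14:
        return False
    inv = 1.0 / det
    s = p - tri[0]
    u = inv * (s @ h)
    if u < -1e-12 or u > 1 + 1e-12:
        return False
    qv = np.cross(s, e1)
    v = inv * (d @ qv)
    if v < -1e-12 or u + v > 1 + 1e-12:
        return False
    t = inv * (e2 @ qv)
    seg_len = np.linalg.norm(d)
    margin = eps / seg_len if seg_len > 0 else 0.0
    return margin < t < 1 - margin
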