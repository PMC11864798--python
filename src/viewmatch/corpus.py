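"""Synthetic stimulus corpora: procedural categories of abstract objects.

A *category* is defined by a prototype extrusion program: a base-box shape
and a fixed sequence of (face, tilt, azimuth, length) extrusion steps drawn
once per category.  Each object in the category re-runs the program with
its steps jittered by a small relative amount, so category members share
coarse 3D structure but differ in detail — the regime in which
within-category match-to-sample requires fine shape inferences rather than
category recognition.

Meshes are centred and scaled to unit bounding radius before rendering so
no size cue leaks object identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import sample_viewpoints
from .meshes import ObjectMesh, catmull_clark, cube
from .render import Stimulus, render_view
from .shapegen import ShapeGenError, ShapeGenParams, _extrude_face, _self_intersects

__all__ = ["CorpusSpec", "make_corpus", "make_object", "category_program"]


@dataclass
class CorpusSpec:
    """Conditions of the synthetic study corpus."""

    n_categories: int = 6
    objects_per_category: int = 8
    views_per_object: int = 6
    resolution: tuple[int, int] = (32, 32)
    radius: float = 3.0
    subdivision_levels: int = 1
    jitter: float = 0.35  # relative sd of per-object perturbations
    params: ShapeGenParams = field(default_factory=ShapeGenParams)
    seed: int = 0


@dataclass
class ExtrusionProgram:
    """A category prototype: base box extents plus extrusion steps.

    Each step is (face_rank, tilt, azimuth, length); ``face_rank`` in [0, 1)
    selects a face by index fraction so jittered programs mostly extrude the
    same faces in the same order.
    """

    extents: np.ndarray
    steps: list[tuple[float, float, float, float]]


def category_program(cat_index: int, spec: CorpusSpec) -> ExtrusionProgram:
    """Draw the prototype program for one category (deterministic).

    Each category first draws its own parameter regime — extrusion count,
    tilt ceiling, length scale and box aspect — from wide meta-ranges, so
    different categories occupy visibly different parts of shape space
    (stubby vs spiky, squat vs elongated), the way real object categories
    do.  The prototype program is then drawn inside that regime.
    Prototypes whose own cage self-intersects are rejected and redrawn, so
    every category centre is a valid shape."""
    p = spec.params
    rng = np.random.default_rng([spec.seed, 1000 + cat_index])
    # category regime
    k_lo = int(rng.integers(4, 9))
    k_hi = int(rng.integers(k_lo + 1, 13))
    angle_hi = float(rng.uniform(0.10, 0.65))
    length_scale = float(rng.uniform(0.25, 0.95))
    aspect = rng.uniform(0.6, 1.6, size=3)
    for _ in range(200):
        extents = aspect * rng.uniform(*p.base_size_range, size=3)
        k = int(rng.integers(k_lo, k_hi + 1))
        steps = [
            (
                float(rng.random()),
                float(rng.uniform(0.0, angle_hi)),
                float(rng.uniform(0.0, 2 * np.pi)),
                float(length_scale * rng.uniform(0.6, 1.4)),
            )
            for _ in range(k)
        ]
        program = ExtrusionProgram(extents, steps)
        if not _self_intersects(_run_program(program)):
            return program
    raise ShapeGenError(f"no valid prototype for category {cat_index}")


def _jittered(program: ExtrusionProgram, jitter: float,
              rng: np.random.Generator, params: ShapeGenParams) -> ExtrusionProgram:
    extents = program.extents * np.exp(rng.normal(0.0, jitter * 0.3, size=3))
    lo, hi = params.length_range
    steps = []
    for face_rank, tilt, azi, length in program.steps:
        steps.append(
            (
                float(np.clip(face_rank + rng.normal(0.0, jitter * 0.1), 0.0, 0.999)),
                float(np.clip(tilt + rng.normal(0.0, jitter * params.angle_range),
                              0.0, params.angle_range)),
                float(azi + rng.normal(0.0, jitter * np.pi / 2)),
                float(np.clip(length * np.exp(rng.normal(0.0, jitter * 0.5)), lo * 0.5, hi * 1.5)),
            )
        )
    return ExtrusionProgram(extents, steps)


def _run_program(program: ExtrusionProgram) -> ObjectMesh:
    mesh = cube(program.extents)
    for face_rank, tilt, azi, length in program.steps:
        face_idx = int(face_rank * len(mesh.faces))
        mesh = _extrude_face(mesh, face_idx, tilt, azi, length)
    return mesh


def make_object(
    program: ExtrusionProgram,
    jitter: float,
    seed: int,
    params: ShapeGenParams,
    subdivision_levels: int,
    object_id: str = "",
    category: str = "",
    max_resample: int = 50,
) -> ObjectMesh:
    """One jittered realisation of a category program.

    Self-intersecting candidates are rejected and re-jittered; after every
    ``max_resample`` rejections the jitter is halved, so the draw converges
    toward the (validated) prototype and always terminates."""
    rng = np.random.default_rng(seed)
    j = jitter
    for _round in range(8):
        for _ in range(max_resample):
            cage = _run_program(_jittered(program, j, rng, params))
            if not _self_intersects(cage):
                mesh = catmull_clark(cage, subdivision_levels)
                mesh.object_id = object_id
                mesh.category = category
                return mesh
        j *= 0.5
    raise ShapeGenError("no valid jittered object after annealing")


def make_corpus(spec: CorpusSpec) -> tuple[list[Stimulus], dict[str, str]]:
    """Generate and render the full corpus.

    Returns the rendered stimuli (object ids ``c{cat}_o{obj}``, viewpoint
    ids ``v{idx:02d}``) and the object-id -> category map.  Fully
    deterministic in ``spec.seed``.
    """
    stimuli: list[Stimulus] = []
    categories: dict[str, str] = {}
    for ci in range(spec.n_categories):
        cat = f"cat{ci}"
        program = category_program(ci, spec)
        for oi in range(spec.objects_per_category):
            seed = int(np.random.default_rng([spec.seed, ci, oi]).integers(2**31 - 1))
            oid = f"c{ci}_o{oi}"
            mesh = make_object(
                program,
                spec.jitter,
                seed,
                spec.params,
                spec.subdivision_levels,
                object_id=oid,
                category=cat,
            )
            mesh.vertices = (mesh.vertices - mesh.centroid()) / mesh.bounding_radius()
            categories[oid] = cat
            poses = sample_viewpoints(
                spec.views_per_object,
                spec.radius,
                seed=seed + 17,
                resolution=spec.resolution,
            )
            for vi, pose in enumerate(poses):
                stimuli.append(render_view(mesh, pose, viewpoint_id=f"v{vi:02d}"))
    return stimuli, categories
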