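"""Software rasterizer producing matte-grey stimuli.

Shading is Lambertian with a single directional light fixed in *camera*
coordinates plus an ambient term, so illumination never leaks viewpoint
information: every view is lit the same way relative to the camera.
Visibility is resolved with a z-buffer (perspective-correct depth).
Images are row-major, origin top-left, intensities in [0, 1]; the background
carries the constant value 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .camera import CameraPose
from .meshes import MeshStructureError, ObjectMesh

__all__ = ["Stimulus", "render_view", "save_stimulus", "load_stimulus"]

BACKGROUND = 0.0
ALBEDO = 0.85
AMBIENT = 0.25
# unit vector toward the light, in camera coordinates (x right, y up, z forward)
LIGHT_DIR = np.array([0.35, 0.55, -0.80])
LIGHT_DIR = LIGHT_DIR / np.linalg.norm(LIGHT_DIR)


@dataclass
class Stimulus:
    """A rendered view: grey-scale image plus identity and pose metadata."""

    image: np.ndarray  # (H, W) float in [0, 1]
    object_id: str
    viewpoint_id: str
    pose: CameraPose

    @property
    def resolution(self) -> tuple[int, int]:
        return self.image.shape[:2]


def render_view(mesh: ObjectMesh, pose: CameraPose, viewpoint_id: str = "") -> Stimulus:
    """Rasterize one view of ``mesh`` under ``pose``; fully deterministic."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise MeshStructureError("cannot render an empty mesh")
    h, w = pose.resolution
    right, up, forward = pose.basis()
    rot = np.stack([right, up, forward])  # world -> camera
    cam = (mesh.vertices - pose.position) @ rot.T

    tris = mesh.triangulated()
    v0, v1, v2 = cam[tris[:, 0]], cam[tris[:, 1]], cam[tris[:, 2]]

    # cull triangles behind the camera (object should be fully in front)
    in_front = (v0[:, 2] > 1e-9) & (v1[:, 2] > 1e-9) & (v2[:, 2] > 1e-9)

    # flat shading per triangle from the camera-space outward normal
    normals = np.cross(v1 - v0, v2 - v0)
    nrm = np.linalg.norm(normals, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    normals = normals / nrm
    shade = ALBEDO * (AMBIENT + (1.0 - AMBIENT) * np.maximum(0.0, normals @ LIGHT_DIR))

    # project to pixel coordinates
    def to_pix(v: np.ndarray) -> np.ndarray:
        scale = pose.plane_dist / v[:, 2]
        u = v[:, 0] * scale / pose.plane_halfwidth  # [-1, 1]
        s = v[:, 1] * scale / pose.plane_halfwidth
        col = (u + 1.0) / 2.0 * w - 0.5
        row = (1.0 - s) / 2.0 * h - 0.5
        return np.stack([row, col], axis=1)

    img = np.full((h, w), BACKGROUND, dtype=float)
    zbuf = np.full((h, w), np.inf)

    p0, p1, p2 = to_pix(v0), to_pix(v1), to_pix(v2)
    # backface culling: outward faces wind counter-clockwise in pixel space
    # (row axis points down, so the signed area flips sign)
    area2 = (p1[:, 1] - p0[:, 1]) * (p2[:, 0] - p0[:, 0]) - (p1[:, 0] - p0[:, 0]) * (
        p2[:, 1] - p0[:, 1]
    )
    visible = in_front & (np.abs(area2) > 1e-12) & (area2 < 0)

    iz0, iz1, iz2 = 1.0 / v0[:, 2], 1.0 / v1[:, 2], 1.0 / v2[:, 2]
    for t in np.nonzero(visible)[0]:
        a, b, c = p0[t], p1[t], p2[t]
        rmin = max(int(np.floor(min(a[0], b[0], c[0]))), 0)
        rmax = min(int(np.ceil(max(a[0], b[0], c[0]))), h - 1)
        cmin = max(int(np.floor(min(a[1], b[1], c[1]))), 0)
        cmax = min(int(np.ceil(max(a[1], b[1], c[1]))), w - 1)
        if rmin > rmax or cmin > cmax:
            continue
        rr, cc = np.meshgrid(
            np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
        )
        det = area2[t]
        # edge functions normalised by total signed area: lam_c = E(a,b,p),
        # lam_a = E(b,c,p), lam_b = remainder; inside when all >= 0
        lam_c = ((b[1] - a[1]) * (rr - a[0]) - (b[0] - a[0]) * (cc - a[1])) / det
        lam_a = ((c[1] - b[1]) * (rr - b[0]) - (c[0] - b[0]) * (cc - b[1])) / det
        lam_b = 1.0 - lam_c - lam_a
        inside = (lam_a >= 0) & (lam_b >= 0) & (lam_c >= 0)
        if not inside.any():
            continue
        # perspective-correct depth: 1/z is linear in screen space
        iz = lam_a * iz0[t] + lam_b * iz1[t] + lam_c * iz2[t]
        depth = np.where(iz > 0, 1.0 / np.maximum(iz, 1e-12), np.inf)
        rsel = rr[inside]
        csel = cc[inside]
        dsel = depth[inside]
        closer = dsel < zbuf[rsel, csel]
        rsel, csel, dsel = rsel[closer], csel[closer], dsel[closer]
        zbuf[rsel, csel] = dsel
        img[rsel, csel] = shade[t]

    return Stimulus(img, mesh.object_id, viewpoint_id, pose)


def silhouette(stim: Stimulus) -> np.ndarray:
    """Boolean foreground mask (background carries exactly BACKGROUND)."""
    return stim.image != BACKGROUND


# -- stimulus I/O ------------------------------------------------------------


def save_stimulus(stim: Stimulus, png_path: str | Path) -> None:
    """8-bit PNG plus a JSON sidecar carrying identity and the camera."""
    png_path = Path(png_path)
    arr = np.clip(np.round(stim.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(png_path)
    meta = {
        "object_id": stim.object_id,
        "viewpoint_id": stim.viewpoint_id,
        "camera": stim.pose.to_dict(),
    }
    png_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_stimulus(png_path: str | Path) -> Stimulus:
    png_path = Path(png_path)
    arr = np.asarray(Image.open(png_path), dtype=float) / 255.0
    meta = json.loads(png_path.with_suffix(".json").read_text())
    return Stimulus(
        arr, meta["object_id"], meta["viewpoint_id"], CameraPose.from_dict(meta["camera"])
    )
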