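"""Cameras on a viewing sphere and Plucker ray coordinates.

A pose is a perspective camera positioned on a sphere around the object
centroid, looking at the centroid.  The image plane sits at ``plane_dist``
in front of the camera; a square plane of half-extent ``plane_halfwidth``
maps onto the pixel grid (row-major, origin top-left).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CameraPose", "sample_viewpoints", "plucker_from_camera_pixel", "camera_basis"]


@dataclass
class CameraPose:
    position: np.ndarray
    look_at: np.ndarray
    up_hint: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    plane_dist: float = 1.0
    plane_halfwidth: float = 0.47
    resolution: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.look_at = np.asarray(self.look_at, dtype=float)
        self.up_hint = np.asarray(self.up_hint, dtype=float)
        if np.allclose(self.position, self.look_at):
            raise ValueError("camera position coincides with look_at point")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (right, up, forward); forward points at the target.

        ``right`` is screen-right, so (right, up, -forward) is the
        conventional right-handed camera frame (z toward the viewer)."""
        return camera_basis(self.position, self.look_at, self.up_hint)

    def extrinsic(self) -> np.ndarray:
        """3x4 world-to-camera matrix [R | t] with rows (right, up, forward)."""
        r, u, f = self.basis()
        rot = np.stack([r, u, f])
        return np.hstack([rot, (-rot @ self.position)[:, None]])

    def to_dict(self) -> dict:
        return {
            "position": self.position.tolist(),
            "look_at": self.look_at.tolist(),
            "up_hint": self.up_hint.tolist(),
            "plane_dist": self.plane_dist,
            "plane_halfwidth": self.plane_halfwidth,
            "resolution": list(self.resolution),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraPose":
        return cls(
            np.asarray(d["position"]),
            np.asarray(d["look_at"]),
            np.asarray(d["up_hint"]),
            float(d["plane_dist"]),
            float(d["plane_halfwidth"]),
            tuple(d["resolution"]),
        )


def camera_basis(
    position: np.ndarray, look_at: np.ndarray, up_hint: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    forward = look_at - position
    forward = forward / np.linalg.norm(forward)
    up = up_hint - (up_hint @ forward) * forward
    n = np.linalg.norm(up)
    if n < 1e-8:
        # looking straight along the hint (pole): fall back to world-x
        up = np.array([1.0, 0.0, 0.0])
        up = up - (up @ forward) * forward
        n = np.linalg.norm(up)
    up = up / n
    right = np.cross(forward, up)
    return right, up, forward


def sample_viewpoints(
    n: int,
    radius: float,
    seed: int,
    center: np.ndarray | None = None,
    plane_dist: float = 1.0,
    plane_halfwidth: float = 0.47,
    resolution: tuple[int, int] = (64, 64),
) -> list[CameraPose]:
    """``n`` poses area-uniform on the sphere of ``radius`` about ``center``,
    all looking at the center.  Positions are i.i.d. normalised Gaussian
    triples, which are exactly area-uniform on the sphere."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n):
        v = rng.normal(size=3)
        nv = np.linalg.norm(v)
        while nv < 1e-12:  # pragma: no cover - astronomically unlikely
            v = rng.normal(size=3)
            nv = np.linalg.norm(v)
        poses.append(
            CameraPose(
                center + radius * v / nv,
                center.copy(),
                plane_dist=plane_dist,
                plane_halfwidth=plane_halfwidth,
                resolution=resolution,
            )
        )
    return poses


def plucker_from_camera_pixel(pose: CameraPose, pixel: tuple[int, int]) -> np.ndarray:
    """Plucker coordinates (d, m) of the ray through one pixel.

    The ray starts at the camera position and passes through the pixel's
    point on the image plane; ``d`` is unit length and ``m = o x d`` is
    independent of which point ``o`` on the ray is used.
    Returns a 6-vector ``[dx, dy, dz, mx, my, mz]``.
    """
    row, col = pixel
    h, w = pose.resolution
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError(f"pixel {pixel} outside image bounds {pose.resolution}")
    d, m = _pixel_rays(pose, np.array([[row, col]], dtype=float))
    return np.concatenate([d[0], m[0]])


def _pixel_rays(pose: CameraPose, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ray construction for an (N, 2) array of (row, col)."""
    h, w = pose.resolution
    right, up, forward = pose.basis()
    # pixel centres mapped to the image plane; square plane, origin top-left
    u = (pixels[:, 1] + 0.5) / w * 2.0 - 1.0
    v = 1.0 - (pixels[:, 0] + 0.5) / h * 2.0
    plane_pts = (
        pose.position
        + pose.plane_dist * forward
        + (u * pose.plane_halfwidth)[:, None] * right
        + (v * pose.plane_halfwidth)[:, None] * up
    )
    d = plane_pts - pose.position
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    m = np.cross(np.broadcast_to(pose.position, d.shape), d)
    return d, m


def all_pixel_rays(pose: CameraPose) -> np.ndarray:
    """(H*W, 6) Plucker rays for every pixel, row-major order."""
    h, w = pose.resolution
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    d, m = _pixel_rays(pose, pix)
    return np.hstack([d, m])
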