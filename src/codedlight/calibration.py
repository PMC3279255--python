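"""Pinhole calibration: 3x4 projection matrices and pixel back-projection.

Both cameras and the projector are modeled as pinhole devices described by
a homogeneous 3x4 projection matrix P mapping world points (mm, platform
frame: origin at the platform center, z up) to pixels.  The projector is
simply an inverse camera: its matrix maps world points to the projector
pixel that illuminates them.  Matrices are estimated from world<->pixel
correspondences with the normalized direct linear transform (DLT); no lens
distortion terms are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

DeviceTag = Literal["ref_cam", "projector", "fluor_cam"]

__all__ = [
    "ProjectionMatrix",
    "Ray",
    "CorrespondenceSet",
    "estimate_projection_matrix",
    "project",
    "back_project",
    "pixel_rays",
    "device_center",
    "optical_axis",
    "DegenerateConfigurationError",
]


class DegenerateConfigurationError(ValueError):
    """Raised when correspondences cannot determine a projection matrix."""


def _canonicalize(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape != (3, 4):
        raise ValueError("projection matrix must be 3x4")
    norm = np.linalg.norm(m)
    if norm == 0:
        raise ValueError("zero projection matrix")
    m = m / norm
    # Canonical sign: a physical P = K[R|t] with positive focal lengths has
    # det of the left 3x3 block > 0.
    det = np.linalg.det(m[:, :3])
    if det < 0:
        m = -m
    return m


@dataclass
class ProjectionMatrix:
    """3x4 pinhole projection, stored at unit Frobenius norm.

    ``reprojection_rms`` (px) is populated when the matrix comes from
    :func:`estimate_projection_matrix`.
    """

    matrix: np.ndarray
    device_tag: str = "ref_cam"
    reprojection_rms: float | None = None

    def __post_init__(self) -> None:
        self.matrix = _canonicalize(self.matrix)
        if abs(np.linalg.det(self.matrix[:, :3])) < 1e-12:
            raise ValueError("left 3x3 submatrix is singular (no finite center)")

    @property
    def center(self) -> np.ndarray:
        return device_center(self)


@dataclass(frozen=True)
class Ray:
    """Half-infinite line in world coordinates (mm), unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-9):
            object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * np.asarray(self.direction)


@dataclass
class CorrespondenceSet:
    """Paired world (mm) and pixel coordinates for one device."""

    world_points: np.ndarray  # (N, 3)
    image_points: np.ndarray  # (N, 2)
    device_tag: str = "ref_cam"

    def __post_init__(self) -> None:
        self.world_points = np.asarray(self.world_points, dtype=np.float64)
        self.image_points = np.asarray(self.image_points, dtype=np.float64)
        if self.world_points.shape[0] != self.image_points.shape[0]:
            raise ValueError("world and image point counts differ")

    def __len__(self) -> int:
        return self.world_points.shape[0]


def project(P: ProjectionMatrix | np.ndarray, points: np.ndarray) -> np.ndarray:
    """Project world points (N,3) or (3,) to pixels (N,2) or (2,)."""
    m = P.matrix if isinstance(P, ProjectionMatrix) else np.asarray(P, dtype=np.float64)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    hom = np.hstack([pts, np.ones((pts.shape[0], 1))])
    proj = hom @ m.T
    uv = proj[:, :2] / proj[:, 2:3]
    return uv[0] if np.asarray(points).ndim == 1 else uv


def _normalizing_similarity(pts: np.ndarray) -> np.ndarray:
    """Hartley normalization: centroid to origin, mean norm sqrt(dim)."""
    dim = pts.shape[1]
    centroid = pts.mean(axis=0)
    dists = np.linalg.norm(pts - centroid, axis=1)
    mean = dists.mean()
    scale = np.sqrt(dim) / mean if mean > 0 else 1.0
    T = np.eye(dim + 1)
    T[:dim, :dim] *= scale
    T[:dim, dim] = -scale * centroid
    return T


def estimate_projection_matrix(corr: CorrespondenceSet) -> ProjectionMatrix:
    """Normalized-DLT least-squares estimate of the projection matrix.

    Requires at least 6 correspondences in a non-degenerate (not all
    coplanar, not collinear) configuration.  The reprojection RMS over the
    input correspondences is stored on the result.
    """
    X = corr.world_points
    x = corr.image_points
    n = len(corr)
    if n < 6:
        raise DegenerateConfigurationError(
            f"need at least 6 correspondences, got {n}"
        )
    centered = X - X.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[0] == 0 or svals[2] / svals[0] < 1e-8:
        raise DegenerateConfigurationError(
            "world points are coplanar or collinear; the DLT is degenerate"
        )

    U = _normalizing_similarity(X)
    T = _normalizing_similarity(x)
    Xh = np.hstack([X, np.ones((n, 1))]) @ U.T
    xh = np.hstack([x, np.ones((n, 1))]) @ T.T

    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xh[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xh[:, 1:2] * Xh
    _, _, Vt = np.linalg.svd(A)
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T) @ Pn @ U

    result = ProjectionMatrix(P, device_tag=corr.device_tag)
    residuals = project(result, X) - x
    result.reprojection_rms = float(np.sqrt(np.mean(residuals**2)))
    return result


def device_center(P: ProjectionMatrix) -> np.ndarray:
    """The device center: the unique point with P @ (c, 1) = 0."""
    m = P.matrix
    M, p4 = m[:, :3], m[:, 3]
    return -np.linalg.solve(M, p4)


def optical_axis(P: ProjectionMatrix) -> np.ndarray:
    """Unit principal-axis direction, pointing from the device into the scene."""
    M = P.matrix[:, :3]
    axis = np.linalg.det(M) * M[2]
    return axis / np.linalg.norm(axis)


def pixel_rays(P: ProjectionMatrix, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Back-project many pixels at once.

    Returns the common origin (device center) and unit directions (N,3),
    oriented so points along the ray have positive depth.
    """
    m = P.matrix
    M = m[:, :3]
    center = device_center(P)
    uv = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
    hom = np.hstack([uv, np.ones((uv.shape[0], 1))])
    dirs = np.linalg.solve(M, hom.T).T
    # positive depth: w = M[2] . d must have the sign that makes the
    # canonical (det>0) matrix project the point with positive scale
    w = dirs @ M[2]
    dirs = dirs * np.sign(w)[:, np.newaxis]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return center, dirs


def back_project(P: ProjectionMatrix, pixel: np.ndarray) -> Ray:
    """The world ray imaged by one pixel: through the device center and the
    pixel's pre-image, oriented into the scene."""
    center, dirs = pixel_rays(P, np.asarray(pixel, dtype=np.float64))
    return Ray(origin=center, direction=dirs[0])
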