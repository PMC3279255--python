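"""From decoded captures to filtered point clouds and surface meshes.

Each valid camera pixel pairs the camera ray through that pixel with the
projector ray of its decoded code; the closest-approach midpoint of the two
rays is the reconstructed surface point and the closest-approach distance
(the "ray gap") its quality measure.  The cloud is denoised with a radius
neighbor-count filter, triangulated by a 2-D Delaunay in the camera image
plane lifted to 3-D, and opposite views are merged by the known platform
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse
from scipy.spatial import Delaunay, cKDTree

from .calibration import ProjectionMatrix, Ray, pixel_rays
from .patterns import PixelCodeMap

__all__ = [
    "PointCloud",
    "SurfaceMesh",
    "segment_green",
    "triangulate_rays",
    "build_point_cloud",
    "filter_isolated",
    "smooth_cloud",
    "mesh_points",
    "mesh_regions",
    "merge_views",
    "compute_vertex_normals",
    "rotation_about_z",
]


@dataclass
class PointCloud:
    """Reconstructed 3-D points with per-point provenance.

    ``view`` holds the capture angle (deg) each point came from and
    ``labels`` an optional region/leaf id (-1 = unknown), both per point so
    that provenance survives filtering and merging.
    """

    points: np.ndarray  # (N, 3) mm
    source_pixel: np.ndarray  # (N, 2) camera (u, v)
    ray_gap: np.ndarray  # (N,) mm
    view: np.ndarray  # (N,) float degrees
    labels: np.ndarray  # (N,) int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        n = self.points.shape[0]
        self.source_pixel = np.asarray(self.source_pixel, dtype=np.float64).reshape(n, 2)
        self.ray_gap = np.asarray(self.ray_gap, dtype=np.float64).reshape(n)
        self.view = np.asarray(self.view, dtype=np.float64).reshape(n)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(n)

    def __len__(self) -> int:
        return self.points.shape[0]

    @classmethod
    def empty(cls) -> "PointCloud":
        z = np.zeros((0,))
        return cls(np.zeros((0, 3)), np.zeros((0, 2)), z, z, z.astype(int))

    def take(self, index: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.points[index],
            self.source_pixel[index],
            self.ray_gap[index],
            self.view[index],
            self.labels[index],
        )


@dataclass
class SurfaceMesh:
    """Triangle mesh with optional per-vertex scalar attributes."""

    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (T, 3) int
    vertex_attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def triangle_areas(self) -> np.ndarray:
        """Triangle areas in mm^2."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return cross / norm


def segment_green(rgb: np.ndarray, threshold: float = 20.0) -> np.ndarray:
    """Excess-green plant segmentation: true where 2G - R - B > threshold.

    ``threshold`` is on the 8-bit scale; float images in [0, 1] are scaled
    accordingly.
    """
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("segment_green expects an (H, W, 3) color image")
    chan = img.astype(np.float64)
    if np.issubdtype(img.dtype, np.floating):
        chan = chan * 255.0
    exg = 2.0 * chan[:, :, 1] - chan[:, :, 0] - chan[:, :, 2]
    return exg > threshold


def _closest_points_many(
    o1: np.ndarray,
    d1: np.ndarray,
    o2: np.ndarray,
    d2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closest-approach midpoints of ray pairs (unit directions assumed).

    Returns midpoints, gaps, the two line parameters, and the parallelism
    denominator 1 - (d1.d2)^2.
    """
    b = np.einsum("ij,ij->i", d1, d2)
    w = o1 - o2
    d = np.einsum("ij,ij->i", d1, w)
    e = np.einsum("ij,ij->i", d2, w)
    denom = 1.0 - b * b
    safe = np.where(denom < 1e-300, 1.0, denom)
    t1 = (b * e - d) / safe
    t2 = (e - b * d) / safe
    p1 = o1 + t1[:, None] * d1
    p2 = o2 + t2[:, None] * d2
    mid = 0.5 * (p1 + p2)
    gap = np.linalg.norm(p1 - p2, axis=1)
    return mid, gap, t1, t2, denom


def triangulate_rays(a: Ray, b: Ray, min_angle_deg: float = 0.01) -> tuple[np.ndarray, float]:
    """Midpoint of the shortest segment between two rays, plus its length.

    Symmetric in its arguments.  Raises for near-parallel rays (angle below
    ``min_angle_deg``), whose closest point is numerically meaningless.
    """
    d1 = np.asarray(a.direction, dtype=np.float64)
    d2 = np.asarray(b.direction, dtype=np.float64)
    sin2 = 1.0 - np.clip(np.dot(d1, d2), -1.0, 1.0) ** 2
    if sin2 < np.sin(np.radians(min_angle_deg)) ** 2:
        raise ValueError("rays are near-parallel; triangulation is unreliable")
    mid, gap, _, _, _ = _closest_points_many(
        a.origin[None], d1[None], b.origin[None], d2[None]
    )
    return mid[0], float(gap[0])


def build_point_cloud(
    codes: PixelCodeMap,
    cam: ProjectionMatrix,
    proj: ProjectionMatrix,
    max_gap: float = 3.0,
    view_deg: float = 0.0,
    labels: np.ndarray | None = None,
) -> PointCloud:
    """Triangulate every valid decoded pixel into a 3-D point.

    Points whose camera/projector rays pass farther than ``max_gap`` (mm)
    from each other, or that triangulate behind either device, are dropped.
    ``labels`` is an optional (H, W) region-id image sampled at each
    point's source pixel.
    """
    if cam.device_tag == proj.device_tag:
        raise ValueError("camera and projector calibrations share a device tag")
    vv, uu = np.nonzero(codes.valid_mask)
    if vv.size == 0:
        return PointCloud.empty()
    cam_px = np.stack([uu, vv], axis=1).astype(np.float64)
    proj_px = np.stack([codes.u[vv, uu], codes.v[vv, uu]], axis=1).astype(np.float64)

    cam_o, cam_d = pixel_rays(cam, cam_px)
    proj_o, proj_d = pixel_rays(proj, proj_px)
    o1 = np.broadcast_to(cam_o, cam_d.shape)
    o2 = np.broadcast_to(proj_o, proj_d.shape)
    mid, gap, t1, t2, denom = _closest_points_many(o1, cam_d, o2, proj_d)

    keep = (gap <= max_gap) & (t1 > 0) & (t2 > 0) & (denom > 1e-12)
    lab = np.full(vv.size, -1, dtype=np.int64)
    if labels is not None:
        lab = np.asarray(labels)[vv, uu].astype(np.int64)
    return PointCloud(
        points=mid[keep],
        source_pixel=cam_px[keep],
        ray_gap=gap[keep],
        view=np.full(keep.sum(), float(view_deg)),
        labels=lab[keep],
    )


def filter_isolated(
    cloud: PointCloud,
    radius: float = 2.5,
    min_neighbors: int = 10,
) -> PointCloud:
    """Drop points with fewer than ``min_neighbors`` others within ``radius``.

    Neighbor counts are taken on the original cloud in a single pass, so
    removal of one outlier never triggers removal of its neighbors.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(cloud) == 0 or min_neighbors <= 0:
        return cloud.take(np.arange(len(cloud)))
    tree = cKDTree(cloud.points)
    counts = tree.query_ball_point(cloud.points, r=radius, return_length=True) - 1
    return cloud.take(counts >= min_neighbors)


def smooth_cloud(
    cloud: PointCloud,
    radius: float = 1.5,
    min_neighbors: int = 5,
) -> PointCloud:
    """Moving-least-squares denoising: project each point onto the
    total-least-squares plane of its ``radius``-neighborhood.

    Coded-light range data is quantized to whole projector pixels, so raw
    triangulated points carry sub-millimeter jitter along their camera
    rays; meshing that jitter directly inflates surface area.  Local plane
    projection removes the jitter without bias wherever the surface is
    locally planar at the neighborhood scale.  Points with fewer than
    ``min_neighbors`` neighbors are left untouched.  Set ``radius`` to 0
    to disable.
    """
    if radius <= 0 or len(cloud) == 0:
        return cloud.take(np.arange(len(cloud)))
    pts = cloud.points
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(cloud)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n)])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n)])
    adj = scipy.sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    counts = np.asarray(adj.sum(axis=1)).ravel()
    means = adj @ pts / counts[:, None]
    # per-point covariance via neighbor sums of coordinate products
    prods = np.stack(
        [pts[:, i] * pts[:, j] for i in range(3) for j in range(3)], axis=1
    )
    second = (adj @ prods / counts[:, None]).reshape(n, 3, 3)
    cov = second - means[:, :, None] * means[:, None, :]
    eligible = counts >= min_neighbors + 1  # counts include the point itself
    normals = np.zeros_like(pts)
    if np.any(eligible):
        _, vecs = np.linalg.eigh(cov[eligible])
        normals[eligible] = vecs[:, :, 0]  # smallest-eigenvalue direction
    offsets = np.einsum("ij,ij->i", pts - means, normals)
    smoothed = pts - offsets[:, None] * normals
    out = cloud.take(np.arange(n))
    out.points = np.where(eligible[:, None], smoothed, pts)
    return out


def _drop_long_and_degenerate(
    vertices: np.ndarray, faces: np.ndarray, max_edge: float
) -> np.ndarray:
    tri = vertices[faces]
    edges = np.stack(
        [
            np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1),
        ],
        axis=1,
    )
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    keep = (edges.max(axis=1) <= max_edge) & (areas > 1e-9)
    return faces[keep]


def mesh_points(cloud: PointCloud, max_edge: float = 5.0) -> SurfaceMesh:
    """Single-view meshing: Delaunay on the source pixels, lifted to 3-D.

    For range data from one camera the image plane is a natural
    parameterization of the visible surface, so the 2-D Delaunay
    triangulation of the source pixels, lifted to the 3-D points, tiles it
    without self-folding.  Triangles with any 3-D edge longer than
    ``max_edge`` (mm) — bridges across empty space between leaves — are
    removed, as are degenerate (zero-area) triangles.
    """
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to mesh")
    tri = Delaunay(cloud.source_pixel.astype(np.float64))
    faces = _drop_long_and_degenerate(cloud.points, tri.simplices, max_edge)
    return SurfaceMesh(
        vertices=cloud.points,
        faces=faces,
        vertex_attrs={
            "label": cloud.labels.astype(np.float64),
            "view": cloud.view,
            "ray_gap": cloud.ray_gap,
        },
    )


def mesh_regions(cloud: PointCloud, max_edge: float = 5.0) -> SurfaceMesh:
    """Mesh a labeled (possibly multi-view) cloud region by region.

    Each labeled region (e.g., one leaf) is projected onto its own
    total-least-squares plane, Delaunay-triangulated there, and lifted
    back.  Because points of the same surface from both views land in one
    common parameterization, surfaces seen twice are meshed once — this is
    how merged clouds are meshed without double-counting area.  Points with
    label -1 are ignored.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    all_faces: list[np.ndarray] = []
    for label in np.unique(cloud.labels):
        if label < 0:
            continue
        idx = np.nonzero(cloud.labels == label)[0]
        if idx.size < 3:
            continue
        pts = cloud.points[idx]
        centroid = pts.mean(axis=0)
        _, svals, Vt = np.linalg.svd(pts - centroid, full_matrices=False)
        if svals[1] / max(svals[0], 1e-300) < 1e-10:
            continue  # collinear region
        plane2d = (pts - centroid) @ Vt[:2].T
        try:
            tri = Delaunay(plane2d)
        except Exception:
            continue
        faces = _drop_long_and_degenerate(cloud.points, idx[tri.simplices], max_edge)
        all_faces.append(faces)
    faces = np.vstack(all_faces) if all_faces else np.zeros((0, 3), dtype=np.int64)
    return SurfaceMesh(
        vertices=cloud.points,
        faces=faces,
        vertex_attrs={
            "label": cloud.labels.astype(np.float64),
            "view": cloud.view,
            "ray_gap": cloud.ray_gap,
        },
    )


def rotation_about_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def merge_views(a: PointCloud, b: PointCloud, rotation_deg: float = 180.0) -> PointCloud:
    """Rotate cloud ``b`` about the platform's vertical axis and append it
    to ``a``.  Per-point provenance (view, labels, gaps) is preserved."""
    rotated = b.points @ rotation_about_z(rotation_deg).T
    return PointCloud(
        points=np.vstack([a.points, rotated]),
        source_pixel=np.vstack([a.source_pixel, b.source_pixel]),
        ray_gap=np.concatenate([a.ray_gap, b.ray_gap]),
        view=np.concatenate([a.view, b.view]),
        labels=np.concatenate([a.labels, b.labels]),
    )


def compute_vertex_normals(
    mesh: SurfaceMesh, orient_toward: np.ndarray | None = None
) -> np.ndarray:
    """Area-weighted per-vertex normals; optionally flipped to face a point
    (e.g., the camera center) so orientation is consistent."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(normals, mesh.faces[:, k], cross)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    normals = normals / norm
    if orient_toward is not None:
        to_target = np.asarray(orient_toward, dtype=np.float64) - mesh.vertices
        flip = np.einsum("ij,ij->i", normals, to_target) < 0
        normals[flip] *= -1
    return normals
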