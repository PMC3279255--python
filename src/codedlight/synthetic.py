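"""Virtual capture rig: parametric plants with exact ground truth, rendered
through the coded-light pipeline's own camera model.

The module replaces the physical goniometric rig — DLP projector 1.33 m
from the platform center at 30 deg from vertical (1.15 m up), reference
camera 0.45 m out and 0.6 m up, fluorescence camera on the arch, plant on
a rotating platform imaged from two azimuths 180 deg apart — with a
ray-cast simulator.  Plants are stems carrying planar elliptical leaves
whose areas, normals, inclinations and height are known exactly, so every
downstream stage (decoding, triangulation, meshing, traits, fluorescence
correction) can be validated against analytic truth.

Rendering is per-pixel nearest-triangle ray casting: exact per-pixel
provenance (hit point, leaf id, illuminating projector pixel, shadowing)
falls out of the intersection test.  No shading model is applied to the
coded frames — a lit surface renders at the lit level regardless of
incidence angle — because binarization against per-pixel references is
insensitive to albedo and shading; the fluorescence render carries the
1/cos(phi) geometric amplification instead, which is the effect under
study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import raycast
from .calibration import (
    CorrespondenceSet,
    ProjectionMatrix,
    device_center,
    optical_axis,
    pixel_rays,
    project,
)
from .fluorescence import FluorescenceFrames
from .patterns import CodedCaptureSet, PatternSequence, PatternSpec, full_sequence
from .reconstruction import SurfaceMesh, rotation_about_z

__all__ = [
    "LeafTruth",
    "SceneGroundTruth",
    "ChessboardSpec",
    "DevicePose",
    "RigGeometry",
    "RenderTruth",
    "default_rig",
    "make_plant",
    "make_single_leaf_scene",
    "render_capture_set",
    "render_fluorescence",
    "make_chessboard_points",
    "default_camera_correspondences",
    "projector_correspondences",
    "build_device_matrix",
]

# Albedo / intensity constants of the virtual rig (fractions of full scale)
LIT_LEVEL = 0.85
AMBIENT_LEVEL = 0.06
BACKGROUND_LEVEL = 0.02
LEAF_RGB = np.array([38, 140, 31], dtype=np.uint8)  # excess green 211
STEM_RGB = np.array([110, 80, 50], dtype=np.uint8)  # excess green 0
BACKGROUND_RGB = np.array([13, 13, 15], dtype=np.uint8)


# ---------------------------------------------------------------------------
# Rig geometry


@dataclass
class DevicePose:
    eye: np.ndarray  # mm
    target: np.ndarray  # mm, aim point
    image_shape: tuple[int, int]  # (height, width) px
    focal_px: float
    device_tag: str = "ref_cam"


@dataclass
class RigGeometry:
    ref_cam: DevicePose
    projector: DevicePose
    fluor_cam: DevicePose

    def matrices(self) -> dict[str, ProjectionMatrix]:
        return {
            pose.device_tag: build_device_matrix(pose)
            for pose in (self.ref_cam, self.projector, self.fluor_cam)
        }


def _look_at_rotation(eye: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->device rotation: z forward, x right, y down (image rows)."""
    forward = np.asarray(target, float) - np.asarray(eye, float)
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(forward, up)) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    right = np.cross(forward, up)
    right = right / np.linalg.norm(right)
    down = np.cross(forward, right)
    return np.stack([right, down, forward])


def build_device_matrix(pose: DevicePose) -> ProjectionMatrix:
    h, w = pose.image_shape
    K = np.array(
        [
            [pose.focal_px, 0.0, (w - 1) / 2.0],
            [0.0, pose.focal_px, (h - 1) / 2.0],
            [0.0, 0.0, 1.0],
        ]
    )
    R = _look_at_rotation(pose.eye, pose.target)
    t = -R @ np.asarray(pose.eye, dtype=np.float64)
    P = K @ np.hstack([R, t[:, None]])
    return ProjectionMatrix(P, device_tag=pose.device_tag)


def default_rig(
    cam_shape: tuple[int, int] = (768, 1024),
    proj_shape: tuple[int, int] = (768, 1024),
    fluor_shape: tuple[int, int] = (512, 512),
) -> RigGeometry:
    """The hardware geometry of the physical system.

    Projector: 1.33 m from the platform center, inclined 30 deg from
    vertical (hence 1.15 m above the platform), native 1024x768.
    Reference camera: 0.45 m from the rotation axis, 0.6 m up (the native
    4416x3312 sensor is replaced by a configurable stand-in; the method is
    resolution-agnostic).  Fluorescence camera: 512x512, arch-mounted.
    All devices aim at the center of the plant volume, (0, 0, 80) mm.

    Focal lengths (unobservable from the published geometry) model a
    zoomed consumer camera (2.8x image width), a throw-ratio-2 DLP
    projector, and a 3.0x fluorescence camera.  The camera stand sits at
    90 deg azimuth from the projector: coded-light triangulation needs a
    wide camera-projector baseline (the perpendicular placement gives a
    ~52 deg ray intersection angle at the plant; a camera under the
    projector would leave the rays near-parallel and the depth
    ill-conditioned).
    """
    aim = np.array([0.0, 0.0, 80.0])
    proj_eye = np.array([1330.0 * np.sin(np.radians(30.0)), 0.0, 1330.0 * np.cos(np.radians(30.0))])
    return RigGeometry(
        ref_cam=DevicePose(
            eye=np.array([0.0, 450.0, 600.0]),
            target=aim,
            image_shape=cam_shape,
            focal_px=2.8 * cam_shape[1],
            device_tag="ref_cam",
        ),
        projector=DevicePose(
            eye=proj_eye,
            target=aim,
            image_shape=proj_shape,
            focal_px=2.0 * proj_shape[1],
            device_tag="projector",
        ),
        fluor_cam=DevicePose(
            eye=np.array([-400.0, 0.0, 900.0]),
            target=aim,
            image_shape=fluor_shape,
            focal_px=3.0 * fluor_shape[1],
            device_tag="fluor_cam",
        ),
    )


# ---------------------------------------------------------------------------
# Parametric plants


@dataclass
class LeafTruth:
    vertices: np.ndarray  # (m+1, 3) fan: center first, then rim
    faces: np.ndarray  # (m, 3) into its own vertices
    area_cm2: float  # exact polygon area
    normal: np.ndarray  # unit, positive z
    inclination_deg: float  # angle between leaf plane and the vertical axis
    tilt_deg: float  # tilt from horizontal (= 90 - inclination)
    azimuth_deg: float
    fp_yield: float
    fs_yield: float


@dataclass
class SceneGroundTruth:
    leaves: list[LeafTruth]
    stem_vertices: np.ndarray
    stem_faces: np.ndarray
    height_mm: float
    pot_height_mm: float
    seed: int

    @property
    def total_area_cm2(self) -> float:
        return float(sum(leaf.area_cm2 for leaf in self.leaves))

    def mesh_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Combined (vertices, faces, face_leaf_id); stem faces get id -1."""
        verts = [self.stem_vertices]
        faces = [self.stem_faces]
        ids = [np.full(self.stem_faces.shape[0], -1, dtype=np.int64)]
        offset = self.stem_vertices.shape[0]
        for i, leaf in enumerate(self.leaves):
            verts.append(leaf.vertices)
            faces.append(leaf.faces + offset)
            ids.append(np.full(leaf.faces.shape[0], i, dtype=np.int64))
            offset += leaf.vertices.shape[0]
        return np.vstack(verts), np.vstack(faces), np.concatenate(ids)

    def leaf_surface_mesh(self) -> SurfaceMesh:
        """Leaves only, with per-vertex leaf labels (stem excluded)."""
        verts, faces, labels = [], [], []
        offset = 0
        for i, leaf in enumerate(self.leaves):
            verts.append(leaf.vertices)
            faces.append(leaf.faces + offset)
            labels.append(np.full(leaf.vertices.shape[0], i, dtype=np.float64))
            offset += leaf.vertices.shape[0]
        return SurfaceMesh(
            vertices=np.vstack(verts),
            faces=np.vstack(faces),
            vertex_attrs={"label": np.concatenate(labels)},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "height_mm": self.height_mm,
            "pot_height_mm": self.pot_height_mm,
            "stem_vertices": self.stem_vertices.tolist(),
            "stem_faces": self.stem_faces.tolist(),
            "leaves": [
                {
                    "vertices": leaf.vertices.tolist(),
                    "faces": leaf.faces.tolist(),
                    "area_cm2": leaf.area_cm2,
                    "normal": leaf.normal.tolist(),
                    "inclination_deg": leaf.inclination_deg,
                    "tilt_deg": leaf.tilt_deg,
                    "azimuth_deg": leaf.azimuth_deg,
                    "fp_yield": leaf.fp_yield,
                    "fs_yield": leaf.fs_yield,
                }
                for leaf in self.leaves
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneGroundTruth":
        d = json.loads(Path(path).read_text())
        leaves = [
            LeafTruth(
                vertices=np.array(l["vertices"]),
                faces=np.array(l["faces"], dtype=np.int64),
                area_cm2=l["area_cm2"],
                normal=np.array(l["normal"]),
                inclination_deg=l["inclination_deg"],
                tilt_deg=l["tilt_deg"],
                azimuth_deg=l["azimuth_deg"],
                fp_yield=l["fp_yield"],
                fs_yield=l["fs_yield"],
            )
            for l in d["leaves"]
        ]
        return cls(
            leaves=leaves,
            stem_vertices=np.array(d["stem_vertices"]),
            stem_faces=np.array(d["stem_faces"], dtype=np.int64),
            height_mm=d["height_mm"],
            pot_height_mm=d["pot_height_mm"],
            seed=d["seed"],
        )


def _leaf_patch(
    attach: np.ndarray,
    azimuth_deg: float,
    tilt_deg: float,
    target_area_cm2: float,
    aspect: float,
    fp_yield: float,
    fs_yield: float,
    n_rim: int = 24,
    stem_clearance: float = 3.0,
) -> LeafTruth:
    """A planar elliptical leaf as a triangle fan with exact polygon area."""
    psi = np.radians(azimuth_deg)
    tau = np.radians(tilt_deg)
    e1 = np.array([np.cos(psi) * np.cos(tau), np.sin(psi) * np.cos(tau), np.sin(tau)])
    e2 = np.array([-np.sin(psi), np.cos(psi), 0.0])
    normal = np.cross(e1, e2)  # (-sin tau cos psi, -sin tau sin psi, cos tau)
    if normal[2] < 0:
        normal = -normal
    area_mm2 = target_area_cm2 * 100.0
    a = np.sqrt(area_mm2 / (np.pi * aspect))
    b = a * aspect
    center = attach + e1 * (a + stem_clearance)
    theta = 2.0 * np.pi * np.arange(n_rim) / n_rim
    rim = center + np.outer(a * np.cos(theta), e1) + np.outer(b * np.sin(theta), e2)
    vertices = np.vstack([center, rim])
    faces = np.array(
        [[0, 1 + k, 1 + (k + 1) % n_rim] for k in range(n_rim)], dtype=np.int64
    )
    polygon_area_mm2 = 0.5 * n_rim * a * b * np.sin(2.0 * np.pi / n_rim)
    return LeafTruth(
        vertices=vertices,
        faces=faces,
        area_cm2=polygon_area_mm2 / 100.0,
        normal=normal / np.linalg.norm(normal),
        inclination_deg=90.0 - tilt_deg,
        tilt_deg=tilt_deg,
        azimuth_deg=azimuth_deg,
        fp_yield=fp_yield,
        fs_yield=fs_yield,
    )


def _stem_mesh(top_z: float, pot_height: float, half_width: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Two crossed vertical ribbons so the stem is visible from any azimuth."""
    verts = []
    faces = []
    for axis in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        base = len(verts)
        lo, hi = pot_height, top_z
        verts.extend(
            [
                axis * half_width + [0, 0, lo],
                -axis * half_width + [0, 0, lo],
                -axis * half_width + [0, 0, hi],
                axis * half_width + [0, 0, hi],
            ]
        )
        faces.extend([[base, base + 1, base + 2], [base, base + 2, base + 3]])
    return np.array(verts, dtype=np.float64), np.array(faces, dtype=np.int64)


def _leaf_samples(leaf: LeafTruth) -> np.ndarray:
    """Surface sample points: fan center, rim, and interior rings."""
    center, rim = leaf.vertices[0], leaf.vertices[1:]
    rings = [center[None, :], rim]
    for frac in (0.35, 0.6, 0.85):
        rings.append(center + frac * (rim - center))
    return np.vstack(rings)


def _jointly_visible(
    leaves: list[LeafTruth],
    stem: tuple[np.ndarray, np.ndarray],
    rig: "RigGeometry",
    views_deg: tuple[float, ...],
    min_cos_cam: float = 0.2,
    min_cos_proj: float = 0.1,
) -> bool:
    """True if every leaf sample point is camera- AND projector-visible
    in at least one view.

    A view covers a sample only when the ray to the device is unblocked
    by other leaves or the stem AND the blade is not grazing to the
    device (cosine floors): an edge-on blade is geometrically visible but
    subtends too few pixels to reconstruct.
    """
    cam_eye = np.asarray(rig.ref_cam.eye, float)
    proj_eye = np.asarray(rig.projector.eye, float)
    for i, leaf in enumerate(leaves):
        samples = _leaf_samples(leaf)
        obst_v = [stem[0]] + [l.vertices for j, l in enumerate(leaves) if j != i]
        obst_f = [stem[1]]
        offset = stem[0].shape[0]
        for j, l in enumerate(leaves):
            if j == i:
                continue
            obst_f.append(l.faces + offset)
            offset += l.vertices.shape[0]
        vertices = np.vstack(obst_v)
        faces = np.vstack(obst_f)
        covered = np.zeros(samples.shape[0], dtype=bool)
        center = leaf.vertices[0]
        for view in views_deg:
            # plant rotates on the platform; equivalently rotate the eyes back
            R = rotation_about_z(-view)
            cam_v, proj_v = R @ cam_eye, R @ proj_eye
            cam_dir = cam_v - center
            proj_dir = proj_v - center
            cos_cam = abs(leaf.normal @ cam_dir) / np.linalg.norm(cam_dir)
            cos_proj = abs(leaf.normal @ proj_dir) / np.linalg.norm(proj_dir)
            if cos_cam < min_cos_cam or cos_proj < min_cos_proj:
                continue
            cam_blocked = raycast.any_hit_before(samples, cam_v, vertices, faces)
            proj_blocked = raycast.any_hit_before(samples, proj_v, vertices, faces)
            covered |= ~(cam_blocked | proj_blocked)
        if not covered.all():
            return False
    return True


def make_plant(
    n_leaves: int = 6,
    area_range_cm2: tuple[float, float] = (6.0, 11.5),
    inclination_range_deg: tuple[float, float] = (20.0, 50.0),
    height_mm: float = 120.0,
    pot_height_mm: float = 40.0,
    seed: int = 0,
    fp_yield: float = 0.55,
    fs_yield_range: tuple[float, float] = (0.23, 0.27),
    max_attempts: int = 250,
    rig: "RigGeometry | None" = None,
    views_deg: tuple[float, ...] = (0.0, 180.0),
) -> SceneGroundTruth:
    """Deterministic parametric plant with exact analytic ground truth.

    Leaves are planar elliptical patches spiraling up a vertical stem at
    near-even azimuths.  ``inclination_range_deg`` is the leaves' tilt
    from horizontal.  The whole plant is translated vertically so the
    highest leaf point sits exactly ``height_mm`` above the pot top.

    The generator emulates a healthy, turgid plant whose leaves do not
    overlap in imaging: a candidate packing is accepted only when the
    leaves keep a minimum mutual distance AND every leaf surface sample
    is jointly camera- and projector-visible in at least one of the
    capture views of ``rig`` (default: the standard rig, views 0/180 deg)
    — wilted, self-occluding plants are exactly the failure case excluded
    here.  Packing is retried with fresh jitter a bounded number of
    times; an infeasible request raises.
    """
    lo_a, hi_a = area_range_cm2
    if not (0 < lo_a <= hi_a):
        raise ValueError("invalid leaf-area range")
    check_rig = rig or default_rig()
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        # phyllotactic spiral: the ~137.5 deg golden divergence angle is
        # what real rosettes use to keep successive leaves out of each
        # other's light — and out of each other's camera/projector rays
        base_azimuth = rng.uniform(0.0, 360.0)
        azimuths = (
            base_azimuth
            + np.arange(n_leaves) * 137.5
            + rng.uniform(-10.0, 10.0, n_leaves)
        ) % 360.0
        areas = rng.uniform(lo_a, hi_a, n_leaves)
        tilts = rng.uniform(*inclination_range_deg, size=n_leaves)
        aspects = rng.uniform(0.5, 0.65, n_leaves)
        fs_yields = rng.uniform(*fs_yield_range, size=n_leaves)
        attach_z = (
            pot_height_mm
            + np.linspace(0.25, 0.95, n_leaves) * height_mm
            + rng.uniform(-6.0, 6.0, n_leaves)
        )
        petioles = rng.uniform(6.0, 18.0, n_leaves)  # blade offset from stem

        leaves = [
            _leaf_patch(
                attach=np.array([0.0, 0.0, attach_z[i]]),
                azimuth_deg=azimuths[i],
                tilt_deg=tilts[i],
                target_area_cm2=areas[i],
                aspect=aspects[i],
                fp_yield=fp_yield,
                fs_yield=fs_yields[i],
                stem_clearance=petioles[i],
            )
            for i in range(n_leaves)
        ]
        if _leaves_collide(leaves):
            continue
        # translate so the highest leaf point is exactly pot + height
        zmax = max(leaf.vertices[:, 2].max() for leaf in leaves)
        shift = pot_height_mm + height_mm - zmax
        top_attach = attach_z.max() + shift
        for leaf in leaves:
            leaf.vertices[:, 2] += shift
        if min(leaf.vertices[:, 2].min() for leaf in leaves) < pot_height_mm + 1.0:
            continue
        stem_v, stem_f = _stem_mesh(top_attach, pot_height_mm)
        if not _jointly_visible(leaves, (stem_v, stem_f), check_rig, views_deg):
            continue
        return SceneGroundTruth(
            leaves=leaves,
            stem_vertices=stem_v,
            stem_faces=stem_f,
            height_mm=height_mm,
            pot_height_mm=pot_height_mm,
            seed=seed,
        )
    raise ValueError("could not pack non-intersecting leaves; relax the ranges")


def _leaves_collide(leaves: list[LeafTruth], min_sep: float = 3.0) -> bool:
    from scipy.spatial.distance import cdist

    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            if cdist(leaves[i].vertices, leaves[j].vertices).min() < min_sep:
                return True
    return False


def make_single_leaf_scene(
    tilt_deg: float,
    azimuth_deg: float = 0.0,
    area_cm2: float = 10.0,
    center_z: float = 80.0,
    fp_yield: float = 0.55,
    fs_yield: float = 0.25,
    normal: np.ndarray | None = None,
) -> SceneGroundTruth:
    """One free-standing leaf, for angle and fluorescence closure tests.

    Either tilt+azimuth or an explicit unit ``normal`` fixes the leaf
    plane; the patch is centered on the vertical axis at ``center_z``.
    """
    if normal is not None:
        n = np.asarray(normal, dtype=np.float64)
        n = n / np.linalg.norm(n)
        if n[2] < 0:
            n = -n
        tilt_deg = float(np.degrees(np.arccos(np.clip(n[2], -1, 1))))
        azimuth_deg = float(np.degrees(np.arctan2(-n[1], -n[0]))) if tilt_deg > 1e-9 else 0.0
    leaf = _leaf_patch(
        attach=np.array([0.0, 0.0, center_z]),
        azimuth_deg=azimuth_deg,
        tilt_deg=tilt_deg,
        target_area_cm2=area_cm2,
        aspect=0.6,
        fp_yield=fp_yield,
        fs_yield=fs_yield,
        stem_clearance=0.0,
    )
    # center the patch on the axis so pose sweeps rotate it in place
    leaf.vertices -= leaf.vertices[0] - np.array([0.0, 0.0, center_z])
    stem_v, stem_f = _stem_mesh(center_z - 30.0, 0.0)
    height = float(max(leaf.vertices[:, 2].max(), 0.0))
    return SceneGroundTruth(
        leaves=[leaf],
        stem_vertices=stem_v,
        stem_faces=stem_f,
        height_mm=height,
        pot_height_mm=0.0,
        seed=0,
    )


def make_dihedral_scene(
    angle_deg: float,
    area_cm2: float = 9.0,
    z0: float = 80.0,
) -> SceneGroundTruth:
    """The leaf-angle validation setup: a horizontal reference leaf and a
    second leaf rotated by ``angle_deg`` about the x-axis.

    Mirrors the physical experiment of gluing two bean leaves to flat
    supports, one horizontal, one on an adjustable holder, and reading
    the dihedral angle between their fitted planes; positive and negative
    angles differ by the rotation direction about the (known) hinge, the
    x-axis here.  Leaf 0 is the reference, leaf 1 the rotated one.
    """
    ref = _leaf_patch(
        attach=np.array([0.0, -80.0, z0]),
        azimuth_deg=90.0,  # radial +y: blade spans y in [-80+c, ...]
        tilt_deg=0.0,
        target_area_cm2=area_cm2,
        aspect=0.6,
        fp_yield=0.55,
        fs_yield=0.25,
        stem_clearance=0.0,
    )
    rotated = _leaf_patch(
        attach=np.array([0.0, 25.0, z0]),
        azimuth_deg=90.0,
        tilt_deg=angle_deg,
        target_area_cm2=area_cm2,
        aspect=0.6,
        fp_yield=0.55,
        fs_yield=0.25,
        stem_clearance=0.0,
    )
    stem_v, stem_f = _stem_mesh(z0 - 40.0, 0.0)
    height = float(max(ref.vertices[:, 2].max(), rotated.vertices[:, 2].max()))
    return SceneGroundTruth(
        leaves=[ref, rotated],
        stem_vertices=stem_v,
        stem_faces=stem_f,
        height_mm=height,
        pot_height_mm=0.0,
        seed=0,
    )


# ---------------------------------------------------------------------------
# Rendering


@dataclass
class RenderTruth:
    """Exact per-camera-pixel provenance recorded during rendering."""

    hit_mask: np.ndarray  # (H, W) bool: camera ray hits the plant
    points: np.ndarray  # (H, W, 3) hit coordinates, nan where miss
    leaf_id: np.ndarray  # (H, W): leaf index, -1 stem, -2 background
    proj_pixel: np.ndarray  # (H, W, 2) illuminating (u, v), -1 where none
    proj_visible: np.ndarray  # (H, W) bool: hit sees the projector


def _render_geometry(
    P: ProjectionMatrix,
    image_shape: tuple[int, int],
    vertices: np.ndarray,
    faces: np.ndarray,
    margin_px: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel first hit of the device's rays against the scene mesh.

    Returns (hit_points (H,W,3) with nan, tri_id (H,W) with -1, hit_mask).
    Only pixels inside the projected bounding box of the mesh are cast.
    """
    h, w = image_shape
    tri_id = np.full((h, w), -1, dtype=np.int64)
    pts = np.full((h, w, 3), np.nan)
    uv = project(P, vertices)
    u0 = max(0, int(np.floor(uv[:, 0].min())) - margin_px)
    u1 = min(w - 1, int(np.ceil(uv[:, 0].max())) + margin_px)
    v0 = max(0, int(np.floor(uv[:, 1].min())) - margin_px)
    v1 = min(h - 1, int(np.ceil(uv[:, 1].max())) + margin_px)
    if u1 < u0 or v1 < v0:
        return pts, tri_id, tri_id >= 0
    uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
    pix = np.stack([uu.ravel(), vv.ravel()], axis=1).astype(np.float64)
    origin, dirs = pixel_rays(P, pix)
    t, tri = raycast.first_hit(origin, dirs, vertices, faces)
    hit = np.isfinite(t)
    hit_pts = origin + dirs * np.where(hit, t, 0.0)[:, None]
    block_tri = tri.reshape(uu.shape)
    block_pts = np.where(hit[:, None], hit_pts, np.nan).reshape(uu.shape + (3,))
    tri_id[v0 : v1 + 1, u0 : u1 + 1] = block_tri
    pts[v0 : v1 + 1, u0 : u1 + 1] = block_pts
    return pts, tri_id, tri_id >= 0


def render_capture_set(
    scene: SceneGroundTruth,
    rig: RigGeometry,
    patterns: PatternSequence | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    view_deg: float = 0.0,
) -> tuple[CodedCaptureSet, RenderTruth]:
    """Render the full coded capture stack for one platform angle.

    ``view_deg`` rotates the plant on the platform (the devices stay
    put, as in the physical rig).  For each camera pixel the nearest mesh
    intersection is found; if the hit sees the projector, each coded frame
    samples the pattern at the illuminating projector pixel.  Gaussian
    noise of ``noise_sd`` (fraction of full scale) is added to every
    grayscale image.  Returns the capture set plus exact per-pixel truth.
    """
    mats = rig.matrices()
    cam, proj = mats["ref_cam"], mats["projector"]
    if patterns is None:
        h_p, w_p = rig.projector.image_shape
        patterns = full_sequence(PatternSpec(width=w_p, height=h_p))
    spec = patterns.spec
    rng = np.random.default_rng(seed)

    vertices, faces, face_leaf = scene.mesh_arrays()
    vertices = vertices @ rotation_about_z(view_deg).T

    h, w = rig.ref_cam.image_shape
    pts, tri_id, hit = _render_geometry(cam, (h, w), vertices, faces)
    leaf_id = np.full((h, w), -2, dtype=np.int64)
    leaf_id[hit] = face_leaf[tri_id[hit]]

    # projector visibility and illuminating pixel
    proj_center = device_center(proj)
    hit_pts = pts[hit]
    shadowed = raycast.any_hit_before(hit_pts, proj_center, vertices, faces)
    uv = project(proj, hit_pts)
    proj_px_flat = np.rint(uv).astype(np.int64)
    h_p, w_p = rig.projector.image_shape
    inbounds = (
        (proj_px_flat[:, 0] >= 0)
        & (proj_px_flat[:, 0] < w_p)
        & (proj_px_flat[:, 1] >= 0)
        & (proj_px_flat[:, 1] < h_p)
    )
    lit_ok = ~shadowed & inbounds

    proj_pixel = np.full((h, w, 2), -1, dtype=np.int64)
    proj_visible = np.zeros((h, w), dtype=bool)
    rows, cols = np.nonzero(hit)
    proj_visible[rows, cols] = lit_ok
    proj_pixel[rows[lit_ok], cols[lit_ok]] = proj_px_flat[lit_ok]

    # grayscale base levels
    base = np.full((h, w), BACKGROUND_LEVEL)
    base[hit] = AMBIENT_LEVEL
    lit_rows, lit_cols = rows[lit_ok], cols[lit_ok]
    pu, pv = proj_px_flat[lit_ok, 0], proj_px_flat[lit_ok, 1]

    def grayscale(pattern_values: np.ndarray) -> np.ndarray:
        img = base.copy()
        img[lit_rows, lit_cols] = np.where(pattern_values > 0, LIT_LEVEL, AMBIENT_LEVEL)
        img += rng.normal(0.0, noise_sd, img.shape)
        return np.clip(img, 0.0, 1.0)

    lit_reference = grayscale(np.ones(pu.shape))
    dark_reference = grayscale(np.zeros(pu.shape))
    frames = np.empty((len(patterns), h, w), dtype=np.float32)
    for i, frame in enumerate(patterns.frames):
        frames[i] = grayscale(frame[pv, pu])

    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[:] = BACKGROUND_RGB
    rgb[leaf_id == -1] = STEM_RGB
    rgb[leaf_id >= 0] = LEAF_RGB

    captures = CodedCaptureSet(
        rgb=rgb,
        lit_reference=lit_reference,
        dark_reference=dark_reference,
        frames=frames,
        spec=spec,
        view_deg=view_deg,
    )
    truth = RenderTruth(
        hit_mask=hit,
        points=pts,
        leaf_id=leaf_id,
        proj_pixel=proj_pixel,
        proj_visible=proj_visible,
    )
    return captures, truth


def render_fluorescence(
    scene: SceneGroundTruth,
    rig: RigGeometry,
    amplification: bool = True,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[FluorescenceFrames, np.ndarray]:
    """Render Fp/Fs frames through the fluorescence camera.

    Each plant pixel reads its leaf's emission yield times the geometric
    amplification 1/cos(phi) (phi between the leaf normal and the camera
    optical axis) when ``amplification`` is on.  Distance effects cancel
    by construction: imaged surface per pixel and photon flux both scale
    with distance squared, in opposite directions.  The stem is dark.

    Returns the frames and the per-pixel leaf-id map (-1 stem, -2
    background).
    """
    mats = rig.matrices()
    fluor = mats["fluor_cam"]
    vertices, faces, face_leaf = scene.mesh_arrays()
    h, w = rig.fluor_cam.image_shape
    _, tri_id, hit = _render_geometry(fluor, (h, w), vertices, faces)
    leaf_id = np.full((h, w), -2, dtype=np.int64)
    leaf_id[hit] = face_leaf[tri_id[hit]]

    axis = optical_axis(fluor)
    rng = np.random.default_rng(seed)
    fp = np.zeros((h, w))
    fs = np.zeros((h, w))
    for i, leaf in enumerate(scene.leaves):
        factor = 1.0
        if amplification:
            cos_phi = abs(float(np.dot(leaf.normal, axis)))
            if cos_phi < 1e-6:
                continue  # edge-on leaf contributes no resolvable surface
            factor = 1.0 / cos_phi
        sel = leaf_id == i
        fp[sel] = leaf.fp_yield * factor
        fs[sel] = leaf.fs_yield * factor
    fp += rng.normal(0.0, noise_sd, fp.shape)
    fs += rng.normal(0.0, noise_sd, fs.shape)
    fp = np.clip(fp, 0.0, None)
    fs = np.clip(fs, 0.0, None)
    return FluorescenceFrames(fp=fp, fs=fs, actinic_level=100.0), leaf_id


# ---------------------------------------------------------------------------
# Calibration fixtures


@dataclass
class ChessboardSpec:
    """A physical chessboard: counts are squares, not corners."""

    rows: int = 8
    cols: int = 10
    square_size_m: float = 0.026
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    right: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("a chessboard needs at least 2x2 squares")
        if self.square_size_m <= 0:
            raise ValueError("square size must be positive")

    def interior_corners(self) -> np.ndarray:
        """(rows-1)*(cols-1) interior corner coordinates in mm, centered."""
        pitch = self.square_size_m * 1000.0
        i = np.arange(1, self.cols) - self.cols / 2.0
        j = np.arange(1, self.rows) - self.rows / 2.0
        ii, jj = np.meshgrid(i, j)
        return (
            np.asarray(self.origin, float)
            + np.outer(ii.ravel(), np.asarray(self.right, float)) * pitch
            + np.outer(jj.ravel(), np.asarray(self.up, float)) * pitch
        )


def make_chessboard_points(
    spec: ChessboardSpec,
    P: ProjectionMatrix,
    corner_noise_px: float = 0.0,
    seed: int = 0,
) -> CorrespondenceSet:
    """Project a board's interior corners to synthesize correspondences."""
    world = spec.interior_corners()
    pixels = project(P, world)
    if corner_noise_px > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, corner_noise_px, pixels.shape)
    return CorrespondenceSet(world, pixels, device_tag=P.device_tag)


def default_camera_correspondences(
    P: ProjectionMatrix,
    corner_noise_px: float = 0.0,
    seed: int = 0,
) -> CorrespondenceSet:
    """The two perpendicular calibration boards of the physical rig.

    A horizontal 8x10 board lying on the platform and a vertical 7x11
    board standing through the platform center, both with 26 mm squares;
    together their corners are non-coplanar, as the DLT requires.
    """
    horizontal = ChessboardSpec(rows=8, cols=10, origin=np.zeros(3))
    vertical = ChessboardSpec(
        rows=7,
        cols=11,
        origin=np.array([0.0, 0.0, 26.0 * 3.5]),
        right=np.array([0.0, 1.0, 0.0]),
        up=np.array([0.0, 0.0, 1.0]),
    )
    a = make_chessboard_points(horizontal, P, corner_noise_px, seed)
    b = make_chessboard_points(vertical, P, corner_noise_px, seed + 1)
    return CorrespondenceSet(
        np.vstack([a.world_points, b.world_points]),
        np.vstack([a.image_points, b.image_points]),
        device_tag=P.device_tag,
    )


def projector_correspondences(
    P_proj: ProjectionMatrix,
    image_shape: tuple[int, int] = (768, 1024),
    levels_mm: tuple[float, ...] = (0.0, 500.0, 1000.0),
    corner_noise_px: float = 0.0,
    seed: int = 0,
) -> CorrespondenceSet:
    """Projector calibration data: a projected chessboard on three planes.

    A chessboard image of 8x10 squares, 50x50 projector pixels each, is
    "projected" onto horizontal planes at the given heights; the world
    coordinates where each interior corner's light ray meets the plane are
    recorded against the corner's projector pixel.
    """
    h, w = image_shape
    # 7x9 interior corners at 50 px pitch, centered in the projector frame
    us = (np.arange(1, 10) - 5.0) * 50.0 + (w - 1) / 2.0
    vs = (np.arange(1, 8) - 4.0) * 50.0 + (h - 1) / 2.0
    uu, vv = np.meshgrid(us, vs)
    pixels = np.stack([uu.ravel(), vv.ravel()], axis=1)
    origin, dirs = pixel_rays(P_proj, pixels)
    world, pix_all = [], []
    for z in levels_mm:
        t = (z - origin[2]) / dirs[:, 2]
        world.append(origin + t[:, None] * dirs)
        pix_all.append(pixels)
    world = np.vstack(world)
    pix_all = np.vstack(pix_all)
    if corner_noise_px > 0:
        rng = np.random.default_rng(seed)
        pix_all = pix_all + rng.normal(0.0, corner_noise_px, pix_all.shape)
    return CorrespondenceSet(world, pix_all, device_tag=P_proj.device_tag)
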