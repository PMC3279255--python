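"""Chlorophyll-fluorescence vitality mapping onto the 3-D reconstruction.

The fluorescence decline ratio Rfd = (Fp - Fs)/Fs — peak minus steady-state
emission over steady state under actinic light — is a classical
non-destructive vitality index.  A 2-D fluorescence camera records a leaf
surface element S inclined by phi to its optical axis as S/cos(phi), so
the per-pixel signal of an inclined leaf is amplified by 1/cos(phi) under
(approximately) isotropic excitation.  Mapping the frames onto the plant
mesh gives per-vertex values, the per-vertex surface normal gives phi, and
multiplying by cos(phi) undoes the geometric amplification.  Note that Rfd
itself, being a ratio of two frames with the same geometry, is unaffected
by the amplification; the correction matters for Fp and Fs individually
and for any absolute-signal comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from . import raycast
from .calibration import ProjectionMatrix, device_center, optical_axis, project
from .reconstruction import SurfaceMesh, compute_vertex_normals

__all__ = [
    "FluorescenceFrames",
    "VertexFluorescence",
    "WholePlantSummary",
    "rfd",
    "angle_factor",
    "map_to_mesh",
    "cosine_correct",
    "attach_fluorescence",
    "whole_plant_summary",
]


@dataclass
class FluorescenceFrames:
    """Peak (Fp) and steady-state (Fs) emission frames, relative units."""

    fp: np.ndarray
    fs: np.ndarray
    actinic_level: float = 100.0  # umol photons m^-2 s^-1

    def __post_init__(self) -> None:
        self.fp = np.asarray(self.fp, dtype=np.float64)
        self.fs = np.asarray(self.fs, dtype=np.float64)
        if self.fp.shape != self.fs.shape:
            raise ValueError("Fp and Fs frames must have equal dimensions")


@dataclass
class VertexFluorescence:
    """Per-vertex fluorescence attributes on a plant mesh."""

    fp: np.ndarray
    fs: np.ndarray
    rfd: np.ndarray  # nan where Fs <= 0 or vertex invisible
    phi_deg: np.ndarray  # incidence angle to the camera axis
    fp_corrected: np.ndarray  # cos(phi)-renormalized, nan where phi >= 90
    fs_corrected: np.ndarray
    visible: np.ndarray  # bool


@dataclass
class WholePlantSummary:
    mean_rfd: float
    sd_rfd: float
    mean_fs_corrected: float
    band_edges_mm: np.ndarray  # (n_bands + 1,)
    band_mean_rfd: np.ndarray  # (n_bands,), nan where a band has no surface
    visible_area_cm2: float


def rfd(fp: np.ndarray | float, fs: np.ndarray | float) -> np.ndarray | float:
    """Fluorescence decline ratio (Fp - Fs)/Fs, elementwise.

    Undefined entries (Fs <= 0) are returned as nan rather than raising:
    background pixels of a fluorescence frame are legitimately zero.
    """
    fp_arr = np.asarray(fp, dtype=np.float64)
    fs_arr = np.asarray(fs, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(fs_arr > 0, (fp_arr - fs_arr) / fs_arr, np.nan)
    if np.isscalar(fp) and np.isscalar(fs):
        return float(out)
    return out


def angle_factor(phi_deg: float | np.ndarray) -> float | np.ndarray:
    """Geometric signal amplification 1/cos(phi) of an inclined surface.

    At 45 deg the factor is 1.41: the detected signal is 41% higher than
    for a perpendicular surface.  Angles >= 90 deg (surface edge-on or
    facing away) are rejected.
    """
    phi = np.asarray(phi_deg, dtype=np.float64)
    if np.any(phi < 0) or np.any(phi >= 90):
        raise ValueError("angle_factor requires 0 <= phi < 90 degrees")
    out = 1.0 / np.cos(np.radians(phi))
    return float(out) if np.isscalar(phi_deg) else out


def map_to_mesh(
    mesh: SurfaceMesh,
    frame: np.ndarray,
    fluor_cam: ProjectionMatrix,
    occlusion: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample an image at each mesh vertex through the fluorescence camera.

    Vertices are projected with ``fluor_cam`` and the frame is sampled by
    bilinear interpolation.  Vertices projecting outside the frame, behind
    the camera, or (with ``occlusion``) hidden behind other mesh surface
    get ``visible = False`` and value nan.

    Returns (values, visible).
    """
    img = np.asarray(frame, dtype=np.float64)
    uv = project(fluor_cam, mesh.vertices)
    h, w = img.shape
    visible = (
        (uv[:, 0] >= 0) & (uv[:, 0] <= w - 1) & (uv[:, 1] >= 0) & (uv[:, 1] <= h - 1)
    )
    # behind-camera check: positive depth along the optical axis
    center = device_center(fluor_cam)
    axis = optical_axis(fluor_cam)
    depth = (mesh.vertices - center) @ axis
    visible &= depth > 0

    if occlusion and mesh.faces.shape[0] > 0:
        blocked = raycast.any_hit_before(
            mesh.vertices, center, mesh.vertices, mesh.faces
        )
        visible &= ~blocked

    values = np.full(mesh.vertices.shape[0], np.nan)
    if np.any(visible):
        coords = np.stack([uv[visible, 1], uv[visible, 0]])  # (row, col)
        values[visible] = map_coordinates(img, coords, order=1, mode="nearest")
    return values, visible


def cosine_correct(
    values: np.ndarray,
    normals: np.ndarray,
    view_axis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Undo the 1/cos(phi) amplification: corrected = value * cos(phi).

    ``phi`` is the angle between each vertex normal and the camera's
    optical axis (orientation-insensitive).  Values at phi >= 90 deg are
    not correctable and come back nan.

    Returns (corrected, phi_deg).
    """
    normals = np.asarray(normals, dtype=np.float64)
    axis = np.asarray(view_axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    cos_phi = np.abs(normals @ axis)
    phi = np.degrees(np.arccos(np.clip(cos_phi, 0.0, 1.0)))
    corrected = np.where(phi < 90.0 - 1e-9, np.asarray(values) * cos_phi, np.nan)
    return corrected, phi


def attach_fluorescence(
    mesh: SurfaceMesh,
    frames: FluorescenceFrames,
    fluor_cam: ProjectionMatrix,
    occlusion: bool = True,
    correct: bool = True,
) -> VertexFluorescence:
    """Full per-vertex pipeline: sample Fp/Fs, compute Rfd, cosine-correct.

    Vertex normals are oriented toward the fluorescence camera before the
    incidence angle is computed.  With ``correct=False`` the corrected
    fields simply repeat the uncorrected values (the anisotropic
    camera-side-illumination regime where the cosine terms cancel).
    """
    center = device_center(fluor_cam)
    normals = compute_vertex_normals(mesh, orient_toward=center)
    fp_vals, vis_p = map_to_mesh(mesh, frames.fp, fluor_cam, occlusion=occlusion)
    fs_vals, vis_s = map_to_mesh(mesh, frames.fs, fluor_cam, occlusion=occlusion)
    visible = vis_p & vis_s
    axis = optical_axis(fluor_cam)
    if correct:
        fp_corr, phi = cosine_correct(fp_vals, normals, axis)
        fs_corr, _ = cosine_correct(fs_vals, normals, axis)
    else:
        _, phi = cosine_correct(np.zeros(len(normals)), normals, axis)
        fp_corr, fs_corr = fp_vals.copy(), fs_vals.copy()
    return VertexFluorescence(
        fp=fp_vals,
        fs=fs_vals,
        rfd=rfd(fp_vals, fs_vals),
        phi_deg=phi,
        fp_corrected=fp_corr,
        fs_corrected=fs_corr,
        visible=visible,
    )


def whole_plant_summary(
    vf: VertexFluorescence,
    mesh: SurfaceMesh,
    n_bands: int = 6,
) -> WholePlantSummary:
    """Area-weighted whole-plant statistics and a vertical Rfd profile.

    A triangle contributes when all three vertices are visible with finite
    Rfd; its value is the vertex mean and its weight its area.  The height
    profile averages Rfd in ``n_bands`` equal z-bands, exposing vertical
    gradients (e.g., water stress showing first in the top leaves).
    """
    tri_vis = np.all(vf.visible[mesh.faces], axis=1)
    tri_rfd = np.nanmean(vf.rfd[mesh.faces], axis=1)
    tri_fs_corr = np.nanmean(vf.fs_corrected[mesh.faces], axis=1)
    good = tri_vis & np.isfinite(tri_rfd)
    if not np.any(good):
        raise ValueError("no visible plant surface to summarize")
    areas = mesh.triangle_areas()
    w = areas[good]
    r = tri_rfd[good]
    mean = float(np.average(r, weights=w))
    sd = float(np.sqrt(np.average((r - mean) ** 2, weights=w)))
    goodc = good & np.isfinite(tri_fs_corr)
    mean_fs_corr = float(np.average(tri_fs_corr[goodc], weights=areas[goodc]))

    tri_z = mesh.vertices[mesh.faces, 2].mean(axis=1)
    lo, hi = float(tri_z[good].min()), float(tri_z[good].max())
    edges = np.linspace(lo, hi, n_bands + 1)
    band_means = np.full(n_bands, np.nan)
    which = np.clip(np.searchsorted(edges, tri_z, side="right") - 1, 0, n_bands - 1)
    for b in range(n_bands):
        sel = good & (which == b)
        if np.any(sel):
            band_means[b] = np.average(tri_rfd[sel], weights=areas[sel])
    return WholePlantSummary(
        mean_rfd=mean,
        sd_rfd=sd,
        mean_fs_corrected=mean_fs_corr,
        band_edges_mm=edges,
        band_mean_rfd=band_means,
        visible_area_cm2=float(w.sum()) / 100.0,
    )
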