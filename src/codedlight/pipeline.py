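"""End-to-end glue: capture set -> cloud -> merged mesh -> traits.

These functions chain the module stages exactly as the hardware protocol
does — segment the plant in the full-light photograph, binarize and decode
the 48 coded frames, triangulate camera and projector rays, denoise, mesh
and merge the two opposite views — and are what the CLI, the tests and the
validation studies call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ProjectionMatrix
from .config import PipelineConfig
from .patterns import (
    CodedCaptureSet,
    PatternSequence,
    binarize_captures,
    decode_projector_coords,
    full_sequence,
)
from .reconstruction import (
    PointCloud,
    SurfaceMesh,
    build_point_cloud,
    filter_isolated,
    merge_views,
    mesh_points,
    mesh_regions,
    segment_green,
    smooth_cloud,
)
from .synthetic import (
    RigGeometry,
    SceneGroundTruth,
    default_rig,
    render_capture_set,
)
from .traits import TraitReport, plant_height, surface_area

__all__ = [
    "reconstruct_view",
    "reconstruct_two_views",
    "TwoViewReconstruction",
    "simulate_and_reconstruct",
    "measure_traits",
]


def reconstruct_view(
    captures: CodedCaptureSet,
    cam: ProjectionMatrix,
    proj: ProjectionMatrix,
    config: PipelineConfig | None = None,
    labels: np.ndarray | None = None,
) -> PointCloud:
    """One viewpoint: segmentation, decoding, triangulation, denoising."""
    cfg = config or PipelineConfig()
    mask = segment_green(captures.rgb, cfg.green_threshold)
    bits, reliable = binarize_captures(
        captures.frames,
        captures.lit_reference,
        captures.dark_reference,
        contrast_floor=cfg.contrast_floor,
    )
    codes = decode_projector_coords(bits, captures.spec, mask & reliable)
    cloud = build_point_cloud(
        codes,
        cam,
        proj,
        max_gap=cfg.max_gap_mm,
        view_deg=captures.view_deg,
        labels=labels,
    )
    cloud = filter_isolated(cloud, cfg.filter_radius_mm, cfg.min_neighbors)
    return smooth_cloud(cloud, cfg.smooth_radius_mm)


@dataclass
class TwoViewReconstruction:
    clouds: list[PointCloud]  # per-view, in rig coordinates
    merged: PointCloud  # view B rotated back by the platform angle
    meshes: list[SurfaceMesh]  # per-view image-plane Delaunay meshes
    merged_mesh: SurfaceMesh | None  # per-region mesh of the merged cloud


def reconstruct_two_views(
    capture_sets: list[CodedCaptureSet],
    cam: ProjectionMatrix,
    proj: ProjectionMatrix,
    config: PipelineConfig | None = None,
    labels: list[np.ndarray] | None = None,
) -> TwoViewReconstruction:
    """Reconstruct opposite views and merge them by the platform rotation.

    The second view's points are rotated back by the capture angle so the
    merged cloud lives in the plant frame of the first view.  When
    per-point region labels are available the merged cloud is also meshed
    region-by-region (the de-duplicating parameterization for two-view
    clouds); otherwise only the per-view meshes are built.
    """
    cfg = config or PipelineConfig()
    clouds = []
    for i, captures in enumerate(capture_sets):
        lab = labels[i] if labels is not None else None
        clouds.append(reconstruct_view(captures, cam, proj, cfg, labels=lab))
    merged = clouds[0]
    for cloud in clouds[1:]:
        merged = merge_views(merged, cloud, rotation_deg=-float(cloud.view[0]) if len(cloud) else 0.0)
    meshes = [mesh_points(c, cfg.max_edge_mm) for c in clouds if len(c) >= 3]
    merged_mesh = None
    if len(merged) >= 3 and np.any(merged.labels >= 0):
        # re-smooth: the two views interleave as independent samplings of
        # the same surfaces, which would otherwise re-introduce jitter
        merged_smooth = smooth_cloud(merged, cfg.smooth_radius_mm)
        merged_mesh = mesh_regions(merged_smooth, cfg.max_edge_mm)
    return TwoViewReconstruction(
        clouds=clouds, merged=merged, meshes=meshes, merged_mesh=merged_mesh
    )


def simulate_and_reconstruct(
    scene: SceneGroundTruth,
    rig: RigGeometry | None = None,
    config: PipelineConfig | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    views_deg: tuple[float, ...] = (0.0, 180.0),
    patterns: PatternSequence | None = None,
    use_truth_labels: bool = True,
) -> TwoViewReconstruction:
    """Render a synthetic plant from each view and run the full pipeline.

    With ``use_truth_labels`` the renderer's per-pixel leaf ids ride along
    as point labels, standing in for the per-leaf annotation a user would
    supply for real captures.
    """
    cfg = config or PipelineConfig()
    rig = rig or default_rig()
    h_p, w_p = rig.projector.image_shape
    if patterns is None:
        spec = cfg.pattern_spec()
        if (spec.width, spec.height) != (w_p, h_p):
            from .patterns import PatternSpec

            spec = PatternSpec(
                width=w_p,
                height=h_p,
                gray_levels=cfg.gray_levels,
                shift_period=cfg.shift_period,
                line_width=cfg.line_width,
            )
        patterns = full_sequence(spec)
    mats = rig.matrices()
    capture_sets, label_maps = [], []
    rng = np.random.default_rng(seed)
    for view in views_deg:
        captures, truth = render_capture_set(
            scene,
            rig,
            patterns=patterns,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            view_deg=view,
        )
        capture_sets.append(captures)
        label_maps.append(truth.leaf_id if use_truth_labels else None)
    labels = label_maps if use_truth_labels else None
    return reconstruct_two_views(
        capture_sets, mats["ref_cam"], mats["projector"], cfg, labels=labels
    )


def measure_traits(
    mesh: SurfaceMesh,
    pot_height_mm: float = 40.0,
    label: str = "plant",
) -> TraitReport:
    """Area and height of a reconstructed mesh, as a report row."""
    return TraitReport(
        label=label,
        total_area_cm2=surface_area(mesh),
        height_mm=plant_height(mesh, pot_height_mm),
    )
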