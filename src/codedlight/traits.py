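"""Morphological traits from reconstructed meshes: area, height, angles.

Leaf area is the summed triangle area of the surface mesh; plant height is
the highest vertex minus the pot height; leaf orientation comes from
total-least-squares plane fits to labeled vertex regions.  Conventions:
leaf inclination is the angle between the leaf plane and a reference axis
(a horizontal leaf is at 90 degrees to the vertical axis, a vertical leaf
at 0); the dihedral angle between two leaves is signed by the rotation
direction about the hinge axis and reported in [-90, 90] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .calibration import ProjectionMatrix, optical_axis
from .reconstruction import SurfaceMesh

__all__ = [
    "LeafPlane",
    "TraitReport",
    "surface_area",
    "plant_height",
    "fit_leaf_plane",
    "leaf_inclination",
    "dihedral_angle",
    "growth_rates",
]


@dataclass
class LeafPlane:
    point: np.ndarray  # a point on the plane (mm)
    normal: np.ndarray  # unit normal, oriented with positive z (tie: +x)
    rms_residual: float  # mm
    region: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


@dataclass
class TraitReport:
    label: str
    total_area_cm2: float
    height_mm: float
    leaf_inclinations_deg: dict[int, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "label": self.label,
            "total_area_cm2": self.total_area_cm2,
            "height_mm": self.height_mm,
        }
        for leaf, angle in sorted(self.leaf_inclinations_deg.items()):
            row[f"leaf_{leaf}_inclination_deg"] = angle
        return row


def surface_area(mesh: SurfaceMesh) -> float:
    """Total mesh area in cm^2 (triangle areas summed, mm^2 -> cm^2)."""
    return float(mesh.triangle_areas().sum()) / 100.0


def plant_height(mesh: SurfaceMesh, pot_height: float = 0.0) -> float:
    """Highest vertex z minus the pot height, floored at zero (mm)."""
    if pot_height < 0:
        raise ValueError("pot_height must be >= 0")
    if mesh.vertices.shape[0] == 0:
        raise ValueError("cannot measure the height of an empty mesh")
    return max(0.0, float(mesh.vertices[:, 2].max()) - pot_height)


def fit_leaf_plane(points: np.ndarray, region: np.ndarray | None = None) -> LeafPlane:
    """Total-least-squares plane through a point set.

    The normal is the smallest principal component, oriented to have a
    positive vertical component (tie broken toward positive x).
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] == 0 or svals[1] / svals[0] < 1e-10:
        raise ValueError("points are collinear; plane is undetermined")
    normal = Vt[2]
    if normal[2] < 0 or (normal[2] == 0 and normal[0] < 0):
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return LeafPlane(
        point=centroid,
        normal=normal,
        rms_residual=rms,
        region=np.asarray(region if region is not None else [], dtype=np.int64),
    )


def leaf_inclination(
    plane: LeafPlane,
    reference: Literal["vertical_axis", "camera_axis"] = "vertical_axis",
    cam: ProjectionMatrix | None = None,
) -> float:
    """Angle between the leaf plane and a reference axis, in [0, 90] deg.

    With the vertical-axis reference a horizontal leaf reads 90 deg and a
    vertical leaf 0 deg.  The camera-axis reference uses the optical axis
    of ``cam`` instead of the world vertical.
    """
    if reference == "vertical_axis":
        axis = np.array([0.0, 0.0, 1.0])
    elif reference == "camera_axis":
        if cam is None:
            raise ValueError("camera_axis reference requires a camera matrix")
        axis = optical_axis(cam)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    # angle(plane, axis) = 90 deg - angle(normal, axis)
    cos_na = abs(float(np.dot(plane.normal, axis)))
    return 90.0 - np.degrees(np.arccos(np.clip(cos_na, 0.0, 1.0)))


def _default_hinge(na: np.ndarray, nb: np.ndarray) -> np.ndarray:
    hinge = np.cross(na, nb)
    norm = np.linalg.norm(hinge)
    if norm < 1e-12:  # parallel planes: any in-plane axis works, angle is 0
        hinge = np.cross(na, [0.0, 0.0, 1.0])
        if np.linalg.norm(hinge) < 1e-12:
            hinge = np.array([0.0, 1.0, 0.0])
        return hinge / np.linalg.norm(hinge)
    hinge = hinge / norm
    # deterministic sign: positive x component, ties toward +y then +z
    for k in (0, 1, 2):
        if abs(hinge[k]) > 1e-12:
            return hinge if hinge[k] > 0 else -hinge
    return hinge


def dihedral_angle(
    a: LeafPlane, b: LeafPlane, hinge: np.ndarray | None = None
) -> float:
    """Signed angle from plane ``a`` to plane ``b`` in [-90, 90] degrees.

    The sign is the rotation direction (right-hand rule) about the hinge
    axis — the planes' intersection line.  Pass ``hinge`` explicitly when
    the physical rotation axis is known (e.g., the leaf holder axis);
    otherwise a deterministic sign convention is applied to the
    intersection direction.  Translation of either plane has no effect.
    """
    na, nb = np.asarray(a.normal, float), np.asarray(b.normal, float)
    if hinge is None:
        axis = _default_hinge(na, nb)
    else:
        axis = np.asarray(hinge, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
    angle = np.degrees(
        np.arctan2(float(np.dot(np.cross(na, nb), axis)), float(np.dot(na, nb)))
    )
    # fitted normals are sign-ambiguous: fold into [-90, 90]
    if angle > 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return float(angle)


def growth_rates(areas_cm2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-day growth from a daily series of total leaf areas.

    Returns absolute change (cm^2/day) and relative change (fraction/day);
    both are reported since the normalization convention varies between
    studies.
    """
    areas = np.asarray(areas_cm2, dtype=np.float64)
    absolute = np.diff(areas)
    relative = absolute / areas[:-1]
    return absolute, relative
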