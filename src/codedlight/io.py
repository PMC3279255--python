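"""File formats: ASCII PLY clouds/meshes, correspondence CSV, calibration
JSON, pattern stacks and capture-set manifests.

Everything round-trips losslessly through plain text (or PNG/TIFF for
images) so that captures, calibrations and reconstructions can move
between the CLI stages and external tools (Meshlab reads the PLY output
directly).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import CorrespondenceSet, ProjectionMatrix
from .fluorescence import FluorescenceFrames
from .patterns import CodedCaptureSet, FrameMeta, PatternSequence, PatternSpec
from .reconstruction import PointCloud, SurfaceMesh

__all__ = [
    "write_ply_cloud",
    "read_ply_cloud",
    "write_ply_mesh",
    "read_ply_mesh",
    "write_obj_mesh",
    "write_correspondences_csv",
    "read_correspondences_csv",
    "save_calibration",
    "load_calibration",
    "save_patterns",
    "load_patterns",
    "save_capture_set",
    "load_capture_set",
    "save_fluorescence_frames",
    "load_fluorescence_frames",
]


# ---------------------------------------------------------------------------
# ASCII PLY


def _write_ply(
    path: str | Path,
    vertices: np.ndarray,
    scalars: dict[str, np.ndarray],
    faces: np.ndarray | None,
) -> None:
    lines = ["ply", "format ascii 1.0", f"element vertex {vertices.shape[0]}"]
    lines += [f"property double {ax}" for ax in "xyz"]
    names = list(scalars)
    lines += [f"property double {name}" for name in names]
    if faces is not None:
        lines.append(f"element face {faces.shape[0]}")
        lines.append("property list uchar int vertex_indices")
    lines.append("end_header")
    cols = [vertices] + [np.asarray(scalars[n], float).reshape(-1, 1) for n in names]
    data = np.hstack(cols)
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in data)
    text = "\n".join(lines) + "\n" + body + "\n"
    if faces is not None and faces.shape[0] > 0:
        text += "\n".join("3 " + " ".join(str(i) for i in f) for f in faces) + "\n"
    Path(path).write_text(text)


def _read_ply(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    tokens = Path(path).read_text().splitlines()
    if tokens[0].strip() != "ply":
        raise ValueError(f"{path} is not a PLY file")
    n_vert = n_face = 0
    names: list[str] = []
    current = None
    i = 1
    while i < len(tokens):
        parts = tokens[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "element":
            current = parts[1]
            if current == "vertex":
                n_vert = int(parts[2])
            elif current == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and current == "vertex" and parts[1] != "list":
            names.append(parts[2])
        elif parts[0] == "end_header":
            break
    rows = [tokens[i + k].split() for k in range(n_vert)]
    data = np.array(rows, dtype=np.float64) if n_vert else np.zeros((0, len(names)))
    i += n_vert
    faces = []
    for k in range(n_face):
        parts = tokens[i + k].split()
        faces.append([int(x) for x in parts[1 : 1 + int(parts[0])]])
    faces_arr = np.array(faces, dtype=np.int64) if faces else np.zeros((0, 3), dtype=np.int64)
    vertices = data[:, :3]
    scalars = {name: data[:, 3 + j] for j, name in enumerate(names[3:])}
    return vertices, scalars, faces_arr


def write_ply_cloud(path: str | Path, cloud: PointCloud) -> None:
    scalars = {
        "source_u": cloud.source_pixel[:, 0],
        "source_v": cloud.source_pixel[:, 1],
        "ray_gap": cloud.ray_gap,
        "view": cloud.view,
        "label": cloud.labels.astype(np.float64),
    }
    _write_ply(path, cloud.points, scalars, faces=None)


def read_ply_cloud(path: str | Path) -> PointCloud:
    vertices, scalars, _ = _read_ply(path)
    n = vertices.shape[0]
    return PointCloud(
        points=vertices,
        source_pixel=np.stack(
            [scalars.get("source_u", np.zeros(n)), scalars.get("source_v", np.zeros(n))],
            axis=1,
        ),
        ray_gap=scalars.get("ray_gap", np.zeros(n)),
        view=scalars.get("view", np.zeros(n)),
        labels=scalars.get("label", -np.ones(n)).astype(np.int64),
    )


def write_ply_mesh(path: str | Path, mesh: SurfaceMesh) -> None:
    _write_ply(path, mesh.vertices, mesh.vertex_attrs, mesh.faces)


def read_ply_mesh(path: str | Path) -> SurfaceMesh:
    vertices, scalars, faces = _read_ply(path)
    return SurfaceMesh(vertices=vertices, faces=faces, vertex_attrs=scalars)


def write_obj_mesh(path: str | Path, mesh: SurfaceMesh) -> None:
    import trimesh

    trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False).export(
        str(path)
    )


# ---------------------------------------------------------------------------
# Correspondences and calibration


def write_correspondences_csv(path: str | Path, corr: CorrespondenceSet) -> None:
    df = pd.DataFrame(
        {
            "x_mm": corr.world_points[:, 0],
            "y_mm": corr.world_points[:, 1],
            "z_mm": corr.world_points[:, 2],
            "u_px": corr.image_points[:, 0],
            "v_px": corr.image_points[:, 1],
            "device": corr.device_tag,
        }
    )
    df.to_csv(path, index=False)


def read_correspondences_csv(path: str | Path, device: str | None = None) -> CorrespondenceSet:
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "z_mm", "u_px", "v_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"correspondence CSV missing columns: {sorted(missing)}")
    if device is not None and "device" in df.columns:
        df = df[df["device"] == device]
        if df.empty:
            raise ValueError(f"no rows for device {device!r} in {path}")
    tag = device or (df["device"].iloc[0] if "device" in df.columns else "ref_cam")
    return CorrespondenceSet(
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        df[["u_px", "v_px"]].to_numpy(),
        device_tag=str(tag),
    )


def save_calibration(path: str | Path, P: ProjectionMatrix) -> None:
    payload = {
        "matrix": P.matrix.ravel().tolist(),
        "device": P.device_tag,
        "reprojection_rms_px": P.reprojection_rms,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path: str | Path) -> ProjectionMatrix:
    d = json.loads(Path(path).read_text())
    P = ProjectionMatrix(
        np.array(d["matrix"], dtype=np.float64).reshape(3, 4),
        device_tag=d.get("device", "ref_cam"),
    )
    P.reprojection_rms = d.get("reprojection_rms_px")
    return P


# ---------------------------------------------------------------------------
# Pattern stacks and capture sets


def save_patterns(directory: str | Path, seq: PatternSequence) -> None:
    """Write frames as 8-bit PNGs plus a JSON sidecar with the frame order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (frame, meta) in enumerate(zip(seq.frames, seq.meta)):
        name = f"pattern_{i:03d}_{meta.kind}_{meta.axis}_{meta.index:02d}.png"
        iio.imwrite(directory / name, (frame * 255).astype(np.uint8))
        entries.append(
            {"file": name, "kind": meta.kind, "axis": meta.axis, "index": meta.index}
        )
    sidecar = {
        "spec": {
            "width": seq.spec.width,
            "height": seq.spec.height,
            "gray_levels": seq.spec.gray_levels,
            "shift_period": seq.spec.shift_period,
            "line_width": seq.spec.line_width,
        },
        "frames": entries,
    }
    (directory / "patterns.json").write_text(json.dumps(sidecar, indent=2))


def load_patterns(directory: str | Path) -> PatternSequence:
    directory = Path(directory)
    sidecar = json.loads((directory / "patterns.json").read_text())
    spec = PatternSpec(**sidecar["spec"])
    frames, meta = [], []
    for entry in sidecar["frames"]:
        img = iio.imread(directory / entry["file"])
        frames.append((img > 127).astype(np.uint8))
        meta.append(FrameMeta(entry["kind"], entry["axis"], entry["index"]))
    return PatternSequence(spec, frames, meta)


def save_capture_set(directory: str | Path, captures: CodedCaptureSet) -> None:
    """One viewpoint's stack as PNGs plus a manifest naming every frame."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "full_light.png", captures.rgb)
    to8 = lambda img: np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    iio.imwrite(directory / "lit_reference.png", to8(captures.lit_reference))
    iio.imwrite(directory / "dark_reference.png", to8(captures.dark_reference))
    frame_names = []
    for i in range(captures.frames.shape[0]):
        name = f"coded_{i:03d}.png"
        iio.imwrite(directory / name, to8(captures.frames[i]))
        frame_names.append(name)
    manifest = {
        "full_light": "full_light.png",
        "lit_reference": "lit_reference.png",
        "dark_reference": "dark_reference.png",
        "frames": frame_names,
        "view_deg": captures.view_deg,
        "spec": {
            "width": captures.spec.width,
            "height": captures.spec.height,
            "gray_levels": captures.spec.gray_levels,
            "shift_period": captures.spec.shift_period,
            "line_width": captures.spec.line_width,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_capture_set(directory: str | Path) -> CodedCaptureSet:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    spec = PatternSpec(**manifest["spec"])

    def read_gray(name: str) -> np.ndarray:
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"capture set incomplete: missing frame {name}")
        return iio.imread(path).astype(np.float64) / 255.0

    frame_names = manifest["frames"]
    if len(frame_names) != spec.frame_count:
        raise ValueError(
            f"manifest lists {len(frame_names)} coded frames, spec needs "
            f"{spec.frame_count}"
        )
    rgb_path = directory / manifest["full_light"]
    if not rgb_path.exists():
        raise FileNotFoundError(
            f"capture set incomplete: missing frame {manifest['full_light']}"
        )
    return CodedCaptureSet(
        rgb=iio.imread(rgb_path),
        lit_reference=read_gray(manifest["lit_reference"]),
        dark_reference=read_gray(manifest["dark_reference"]),
        frames=np.stack([read_gray(n) for n in frame_names]),
        spec=spec,
        view_deg=float(manifest.get("view_deg", 0.0)),
    )


def save_fluorescence_frames(directory: str | Path, frames: FluorescenceFrames) -> None:
    """Fp/Fs as 16-bit TIFF, scaled to a recorded full-scale value."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = max(float(frames.fp.max()), float(frames.fs.max()), 1e-12)
    for name, img in (("Fp.tif", frames.fp), ("Fs.tif", frames.fs)):
        iio.imwrite(
            directory / name,
            np.clip(np.rint(img / scale * 65535), 0, 65535).astype(np.uint16),
        )
    (directory / "fluorescence.json").write_text(
        json.dumps({"scale": scale, "actinic_level": frames.actinic_level})
    )


def load_fluorescence_frames(directory: str | Path) -> FluorescenceFrames:
    directory = Path(directory)
    meta = json.loads((directory / "fluorescence.json").read_text())
    fp = iio.imread(directory / "Fp.tif").astype(np.float64) / 65535 * meta["scale"]
    fs = iio.imread(directory / "Fs.tif").astype(np.float64) / 65535 * meta["scale"]
    return FluorescenceFrames(fp=fp, fs=fs, actinic_level=meta["actinic_level"])
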