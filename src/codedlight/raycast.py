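"""Vectorized Moller-Trumbore ray casting against triangle soups.

Used by the virtual-scene renderer (per-pixel ground truth needs the hit
triangle id, not just the hit point) and by the fluorescence mapper's
occlusion test.  Triangles are treated as double-sided; intersections are
found in chunks of rays against all triangles at once, which is fast enough
for the few hundred triangles of a parametric plant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["first_hit", "any_hit_before"]

_EPS = 1e-9


def _intersect_chunk(
    origins: np.ndarray,
    dirs: np.ndarray,
    v0: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
) -> np.ndarray:
    """Ray/triangle distances for a chunk: (n_rays, n_tris), inf = miss."""
    # pvec: (R, T, 3)
    pvec = np.cross(dirs[:, None, :], e2[None, :, :])
    det = np.einsum("rtk,tk->rt", pvec, e1)
    valid = np.abs(det) > _EPS
    inv_det = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rtk,rtk->rt", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rtk,rk->rt", qvec, dirs) * inv_det
    t = np.einsum("rtk,tk->rt", qvec, e2) * inv_det
    hit = valid & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > _EPS)
    return np.where(hit, t, np.inf)


def first_hit(
    origin: np.ndarray,
    dirs: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    chunk: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest intersection of rays from a common origin with a mesh.

    Returns
    -------
    t : (N,) float distances, inf where the ray misses.
    tri : (N,) int triangle indices, -1 where the ray misses.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=np.float64))
    origin = np.asarray(origin, dtype=np.float64)
    tri_pts = np.asarray(vertices, dtype=np.float64)[np.asarray(faces)]
    v0 = tri_pts[:, 0]
    e1 = tri_pts[:, 1] - v0
    e2 = tri_pts[:, 2] - v0
    n_rays, n_tris = dirs.shape[0], v0.shape[0]
    if chunk is None:
        chunk = max(1, int(4_000_000 / max(n_tris, 1)))

    t_out = np.full(n_rays, np.inf)
    tri_out = np.full(n_rays, -1, dtype=np.int64)
    origins = np.broadcast_to(origin, dirs.shape)
    for start in range(0, n_rays, chunk):
        sl = slice(start, min(start + chunk, n_rays))
        tmat = _intersect_chunk(origins[sl], dirs[sl], v0, e1, e2)
        idx = np.argmin(tmat, axis=1)
        tmin = tmat[np.arange(tmat.shape[0]), idx]
        hit = np.isfinite(tmin)
        t_out[sl] = tmin
        tri_out[sl][hit] = idx[hit]
        tri_out[sl][~hit] = -1
    return t_out, tri_out


def any_hit_before(
    origins: np.ndarray,
    targets: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    offset: float = 0.1,
    margin: float = 0.2,
) -> np.ndarray:
    """True where the segment origin->target is blocked by the mesh.

    ``offset`` (mm) nudges the start point along the segment so a surface
    point does not immediately intersect its own triangle; ``margin`` (mm)
    is subtracted from the far end.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    targets = np.broadcast_to(np.asarray(targets, dtype=np.float64), origins.shape)
    seg = targets - origins
    dist = np.linalg.norm(seg, axis=1)
    dist = np.where(dist == 0, 1.0, dist)
    dirs = seg / dist[:, None]
    starts = origins + dirs * offset

    tri_pts = np.asarray(vertices, dtype=np.float64)[np.asarray(faces)]
    v0 = tri_pts[:, 0]
    e1 = tri_pts[:, 1] - v0
    e2 = tri_pts[:, 2] - v0
    n_rays, n_tris = dirs.shape[0], v0.shape[0]
    chunk = max(1, int(4_000_000 / max(n_tris, 1)))
    blocked = np.zeros(n_rays, dtype=bool)
    for start in range(0, n_rays, chunk):
        sl = slice(start, min(start + chunk, n_rays))
        tmat = _intersect_chunk(starts[sl], dirs[sl], v0, e1, e2)
        limit = (dist[sl] - offset - margin)[:, None]
        blocked[sl] = np.any(tmat < limit, axis=1)
    return blocked
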