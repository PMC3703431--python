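"""Time-resolved concordance of the evolving lesion with the final T2 outcome lesion.

For every step of an estimated evolution scenario, the deformed surface is compared
with the static final-outcome T2 surface through two complementary measures:

* dice(t) = 2 |V(S(t)) ∩ V(S_T2)| / (|V(S(t))| + |V(S_T2)|): volumetric overlap of
  the enclosed volumes on a common voxel grid, in [0, 1];
* d_sym(t): the symmetric surface distance, averaging closest point-to-surface
  Euclidean distances in both directions (mm).

The best-match times are the grid times of max dice and min d_sym; ties break
toward the earliest time. The dice curve need not ever reach 1: a lesion front can
merely cross the final boundary as it progresses or regresses.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from strokeflow.regression import EvolutionScenario
from strokeflow.surface_io import BinaryMask, TriangleSurface

__all__ = [
    "ConcordanceCurves",
    "voxelize",
    "dice_index",
    "point_surface_distance",
    "symmetric_distance",
    "concordance_curves",
]


@dataclasses.dataclass
class ConcordanceCurves:
    """Dice and symmetric-distance curves over the scenario grid, with best-match times."""

    times_hours: np.ndarray
    dice_t: np.ndarray
    dsym_t: np.ndarray
    t_dice: float
    t_dsym: float

    def summary(self) -> dict:
        return {
            "t_dice": float(self.t_dice),
            "t_dsym": float(self.t_dsym),
            "max_dice": float(self.dice_t.max()),
            "min_dsym": float(self.dsym_t.min()),
            "mean_dice": float(self.dice_t.mean()),
            "mean_dsym": float(self.dsym_t.mean()),
        }


def _is_closed(surface: TriangleSurface) -> bool:
    edges = surface.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    _, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def voxelize(
    surface: TriangleSurface,
    spacing: float = 1.0,
    *,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> BinaryMask:
    """Rasterize the volume enclosed by a closed surface onto a regular grid.

    A voxel center is foreground when an upward vertical ray from it crosses the
    surface an odd number of times (ray parity). `origin`/`shape` pin the grid so
    several surfaces can be compared voxel-to-voxel; by default the grid covers the
    surface bounds plus a one-voxel pad. Raises on non-watertight input.
    """
    if not _is_closed(surface):
        raise ValueError("surface is not closed (open edges); enclosed volume undefined")
    spacing = float(spacing)
    lo = surface.vertices.min(axis=0)
    hi = surface.vertices.max(axis=0)
    if origin is None:
        origin = lo - spacing  # voxel (0,0,0) center one voxel outside the bounds
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        shape = tuple(int(np.ceil((hi[k] - origin[k]) / spacing)) + 2 for k in range(3))

    nx, ny, nz = shape
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    # tiny deterministic ray offset avoids rays through vertices/edges
    eps = spacing * np.array([1.07e-5, 2.13e-5])

    tri = surface.vertices[surface.faces]  # (M, 3, 3)
    n3 = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    ok = np.abs(n3[:, 2]) > 1e-12 * np.linalg.norm(n3, axis=1).max()
    tri = tri[ok]
    n3 = n3[ok]

    gx, gy = np.meshgrid(xs + eps[0], ys + eps[1], indexing="ij")
    cols = np.column_stack([gx.ravel(), gy.ravel()])  # (Q, 2)
    voxels = np.zeros((nx, ny, nz), dtype=np.uint8)

    p0, p1, p2 = tri[:, 0], tri[:, 1], tri[:, 2]
    chunk = max(1, int(4e6 // max(tri.shape[0], 1)))
    for start in range(0, cols.shape[0], chunk):
        q = cols[start : start + chunk]  # (C, 2)
        # 2D cross-product sign tests, broadcast (C, M)
        d0 = (p1[None, :, 0] - p0[None, :, 0]) * (q[:, None, 1] - p0[None, :, 1]) - (
            p1[None, :, 1] - p0[None, :, 1]
        ) * (q[:, None, 0] - p0[None, :, 0])
        d1 = (p2[None, :, 0] - p1[None, :, 0]) * (q[:, None, 1] - p1[None, :, 1]) - (
            p2[None, :, 1] - p1[None, :, 1]
        ) * (q[:, None, 0] - p1[None, :, 0])
        d2 = (p0[None, :, 0] - p2[None, :, 0]) * (q[:, None, 1] - p2[None, :, 1]) - (
            p0[None, :, 1] - p2[None, :, 1]
        ) * (q[:, None, 0] - p2[None, :, 0])
        inside = ((d0 > 0) & (d1 > 0) & (d2 > 0)) | ((d0 < 0) & (d1 < 0) & (d2 < 0))
        ci, mi = np.nonzero(inside)
        if ci.size == 0:
            continue
        # plane intersection z for each (column, triangle) hit
        zc = (
            p0[mi, 2]
            - (n3[mi, 0] * (q[ci, 0] - p0[mi, 0]) + n3[mi, 1] * (q[ci, 1] - p0[mi, 1])) / n3[mi, 2]
        )
        for local_c in range(q.shape[0]):
            z_cross = np.sort(zc[ci == local_c])
            if z_cross.size == 0:
                continue
            flat = start + local_c
            ix, iy = divmod(flat, ny)
            # crossings strictly above the voxel center, odd => inside
            above = z_cross.size - np.searchsorted(z_cross, zs, side="right")
            voxels[ix, iy, :] = (above % 2).astype(np.uint8)
    return BinaryMask(voxels=voxels, spacing=(spacing, spacing, spacing), origin=tuple(origin))


def dice_index(a: BinaryMask, b: BinaryMask) -> float:
    """Dice volumetric overlap 2|A ∩ B| / (|A| + |B|) on a shared grid."""
    if a.voxels.shape != b.voxels.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(
        a.origin, b.origin
    ):
        raise ValueError("masks are not on the same grid")
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        warnings.warn("both masks empty; dice defined as 0", stacklevel=2)
        return 0.0
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def point_surface_distance(points: np.ndarray, surface: TriangleSurface) -> np.ndarray:
    """Exact Euclidean distance from each point to the closest triangle of a surface.

    All-pairs vectorized closest-point-on-triangle (Voronoi-region case analysis),
    minimized over triangles; chunked over points to bound memory.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.vertices[surface.faces]  # (M, 3, 3)
    m = tri.shape[0]
    out = np.empty(points.shape[0])
    chunk = max(1, int(2e6 // max(m, 1)))
    for start in range(0, points.shape[0], chunk):
        p = points[start : start + chunk][:, None, :]  # (C, 1, 3)
        a, b, c = tri[None, :, 0], tri[None, :, 1], tri[None, :, 2]
        ab, ac = b - a, c - a
        ap = p - a
        d1 = np.einsum("cmk,cmk->cm", np.broadcast_arrays(ab, ap)[0], ap)
        d2 = np.einsum("cmk,cmk->cm", np.broadcast_arrays(ac, ap)[0], ap)
        bp = p - b
        d3 = np.einsum("cmk,cmk->cm", np.broadcast_arrays(ab, bp)[0], bp)
        d4 = np.einsum("cmk,cmk->cm", np.broadcast_arrays(ac, bp)[0], bp)
        cp = p - c
        d5 = np.einsum("cmk,cmk->cm", np.broadcast_arrays(ab, cp)[0], cp)
        d6 = np.einsum("cmk,cmk->cm", np.broadcast_arrays(ac, cp)[0], cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        with np.errstate(divide="ignore", invalid="ignore"):
            v_ab = d1 / (d1 - d3)
            w_ac = d2 / (d2 - d6)
            w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
            denom = va + vb + vc
            v_in = vb / denom
            w_in = vc / denom
        # closest point per Voronoi region, selected in priority order
        close = a + ab * v_in[..., None] + ac * w_in[..., None]  # interior (default)
        reg_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        close = np.where(reg_bc[..., None], b + (c - b) * w_bc[..., None], close)
        reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        close = np.where(reg_ac[..., None], a + ac * w_ac[..., None], close)
        reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        close = np.where(reg_ab[..., None], a + ab * v_ab[..., None], close)
        reg_c = (d6 >= 0) & (d5 <= d6)
        close = np.where(reg_c[..., None], np.broadcast_arrays(c, close)[0], close)
        reg_b = (d3 >= 0) & (d4 <= d3)
        close = np.where(reg_b[..., None], np.broadcast_arrays(b, close)[0], close)
        reg_a = (d1 <= 0) & (d2 <= 0)
        close = np.where(reg_a[..., None], np.broadcast_arrays(a, close)[0], close)
        out[start : start + chunk] = np.sqrt(((p - close) ** 2).sum(axis=2)).min(axis=1)
    return out


def symmetric_distance(a: TriangleSurface, b: TriangleSurface) -> float:
    """Symmetric surface distance (mm): closest point-to-triangle distances from the
    vertices of each surface to the other, averaged over all sampled points."""
    if a.n_vertices == 0 or b.n_vertices == 0:
        raise ValueError("empty surface")
    d_ab = point_surface_distance(a.vertices, b)
    d_ba = point_surface_distance(b.vertices, a)
    return float((d_ab.sum() + d_ba.sum()) / (a.n_vertices + b.n_vertices))


def concordance_curves(
    scn: EvolutionScenario, t2: TriangleSurface, spacing: float = 1.0
) -> ConcordanceCurves:
    """Evaluate dice(t) and d_sym(t) against the final T2 surface at every dt step.

    All volumes are rasterized on one common grid covering the whole scenario and
    the T2 surface. Best-match times take the earliest grid time on ties.
    """
    all_pts = np.vstack([s.vertices for s in scn.surfaces_t] + [t2.vertices])
    origin = all_pts.min(axis=0) - spacing
    shape = tuple(int(np.ceil((all_pts.max(axis=0)[k] - origin[k]) / spacing)) + 2 for k in range(3))
    t2_mask = voxelize(t2, spacing, origin=origin, shape=shape)

    times = scn.times_hours
    dice_t = np.empty(len(times))
    dsym_t = np.empty(len(times))
    for i, surf in enumerate(scn.surfaces_t):
        mask = voxelize(surf, spacing, origin=origin, shape=shape)
        dice_t[i] = dice_index(mask, t2_mask)
        dsym_t[i] = symmetric_distance(surf, t2)
    i_dice = int(np.argmax(dice_t))  # argmax/argmin return the earliest tie
    i_dsym = int(np.argmin(dsym_t))
    return ConcordanceCurves(
        times_hours=times,
        dice_t=dice_t,
        dsym_t=dsym_t,
        t_dice=float(times[i_dice]),
        t_dsym=float(times[i_dsym]),
    )
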