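"""Unfolding of the 3D surface-voxel contour into a 2D dose map.

Each CT slice contributes an ordered chain of surface points. The 2D
coordinates preserve 3D distances the way a developable surface unrolls:
the in-slice coordinate ``u`` of a point is its cumulative 3D arc length
from the slice anchor, and the across-slice coordinate ``v`` is the
cumulative 3D distance along the anchor path. For developable surfaces
(plane, cylinder sector, the tilted cradle) consecutive-point distances are
preserved exactly; non-developable inputs distort only between slices, and
the distortion can be queried, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError, cKDTree

from .core import DoseGrid, FilmDoseMap, GeometryError, StructureMask

FILM_SPACING = 2.54 / 72.0  # 72 DPI film lattice, cm


@dataclass
class SurfaceSample:
    """Ordered per-slice surface points with dose in percent of prescription.

    ``points[i]`` is an (n_i, 3) array of world coordinates ordered along the
    slice contour, starting at the slice anchor; ``doses[i]`` the matching
    dose values. ``step_tolerance`` is the largest 3D step allowed between
    consecutive points before the contour counts as non-contiguous.
    """

    points: List[np.ndarray]
    doses: List[np.ndarray]
    slice_index: List[int] = field(default_factory=list)
    step_tolerance: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.points) != len(self.doses):
            raise ValueError("points and doses must have equal slice counts")
        if not self.slice_index:
            self.slice_index = list(range(len(self.points)))

    @property
    def n_points(self) -> int:
        return int(sum(len(p) for p in self.points))

    def all_doses(self) -> np.ndarray:
        return np.concatenate(self.doses) if self.doses else np.empty(0)


@dataclass
class UnfoldedSurface:
    """Scattered 2D layout of the unfolded surface dose.

    ``points2d`` columns are (u, v) cm; ``source_points`` holds each point's
    3D origin so every raster pixel stays traceable to a surface voxel.
    """

    points2d: np.ndarray
    doses: np.ndarray
    source_points: np.ndarray
    slice_id: np.ndarray


def _circle_center(pts_xy: np.ndarray) -> np.ndarray:
    """Algebraic (Kasa) least-squares circle centre of 2D points.

    Falls back to the centroid when the fit is degenerate (e.g. a single
    point or numerically singular system).
    """
    x, y = pts_xy[:, 0], pts_xy[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        center = np.array([sol[0] / 2.0, sol[1] / 2.0])
    except np.linalg.LinAlgError:
        return pts_xy.mean(axis=0)
    if not np.all(np.isfinite(center)):
        return pts_xy.mean(axis=0)
    return center


def _order_slice_points(pts_xy: np.ndarray, lateral_first: bool = True):
    """Order a slice's surface voxels along the contact arc.

    Points are sorted by polar angle about the least-squares circle centre
    of the slice contour (angle is monotone along a circular arc, and for
    straight contours the fitted centre recedes so the ordering follows the
    line); the branch cut is placed in the largest angular gap so arcs
    crossing +/-pi stay contiguous. Where the contour is locally two voxels
    thick (near-equal angles) the point closer to the centre is dropped,
    leaving a single chain. The traversal starts at the +x (lateral) end
    unless ``lateral_first`` is False.
    """
    if len(pts_xy) == 1:
        return np.array([0]), np.array([], dtype=int)
    center = _circle_center(pts_xy)
    rel = pts_xy - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(ang, kind="stable")
    sorted_ang = ang[order]
    gaps = np.diff(np.concatenate([sorted_ang, [sorted_ang[0] + 2 * np.pi]]))
    cut = int(np.argmax(gaps)) + 1
    order = np.concatenate([order[cut:], order[:cut]])
    # collapse the locally multi-voxel-thick contour to a single chain:
    # one point per angular step, keeping the outermost (true surface) voxel
    rho = np.hypot(rel[:, 0], rel[:, 1])
    a = np.unwrap(ang[order])
    rel_sorted = pts_xy[order]
    dist = np.linalg.norm(rel_sorted[1:] - rel_sorted[:-1], axis=1)
    h_est = np.median(dist) if dist.size else 0.0
    rho_med = np.median(rho)
    dropped = []
    if h_est > 0 and rho_med > 0 and len(order) > 2:
        bin_width = 0.9 * h_est / rho_med
        bins = np.floor((a - a[0]) / bin_width).astype(int)
        keep_idx = []
        for b in np.unique(bins):
            members = np.nonzero(bins == b)[0]
            best = members[np.argmax(rho[order[members]])]
            keep_idx.append(best)
            dropped.extend(order[m] for m in members if m != best)
        order = order[np.sort(np.array(keep_idx))]
    if lateral_first and pts_xy[order[0], 0] < pts_xy[order[-1], 0]:
        order = order[::-1]
    return order, np.array(dropped, dtype=int)


def _smooth_chain(pts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along an open chain (edge-padded)."""
    if window <= 1 or len(pts) <= window:
        return pts
    k = window // 2
    padded = np.concatenate([np.repeat(pts[:1], k, axis=0), pts,
                             np.repeat(pts[-1:], k, axis=0)])
    kernel = np.ones(window) / window
    out = np.column_stack([
        np.convolve(padded[:, j], kernel, mode="valid")
        for j in range(pts.shape[1])
    ])
    return out


def extract_surface_dose(
    dose: DoseGrid,
    surface: StructureMask,
    lateral_first: bool = True,
    smooth_window: int = 5,
) -> SurfaceSample:
    """Sample the dose grid at surface voxel centres, ordered per slice.

    Dose is sampled trilinearly at each contour point and expressed as
    percent of prescription. Each z-slice's voxels are ordered along the
    contact arc; the slice anchor is the traversal start (the lateral end by
    default). ``smooth_window`` applies a moving average to the in-slice
    chain coordinates, suppressing the voxel staircase that would otherwise
    inflate unfolded arc lengths (1 disables).
    """
    if not surface.mask.any():
        raise GeometryError("empty surface contour")
    spacing = surface.spacing
    grid = surface.grid()
    tol = np.sqrt(3.0) * float(np.hypot(spacing[0], spacing[1]))
    points, doses, slices = [], [], []
    for iz in range(surface.shape[2]):
        idx = np.argwhere(surface.mask[:, :, iz])
        if idx.size == 0:
            continue
        idx3 = np.column_stack([idx, np.full(len(idx), iz)])
        pts = grid.index_to_world(idx3)
        order, _ = _order_slice_points(pts[:, :2], lateral_first)
        pts = pts[order]
        if smooth_window > 1:
            pts = np.column_stack([
                _smooth_chain(pts[:, :2], smooth_window), pts[:, 2]
            ])
        vals = dose.sample_percent(pts)
        points.append(pts)
        doses.append(np.asarray(vals))
        slices.append(iz)
    return SurfaceSample(points, doses, slices, step_tolerance=tol)


def unfold_surface(sample: SurfaceSample) -> UnfoldedSurface:
    """Flatten ordered surface samples into the (u, v) plane.

    ``u`` = cumulative 3D arc length from the slice anchor along the contour,
    ``v`` = cumulative 3D anchor-to-anchor distance across slices. Dose
    values are carried unchanged. Raises :class:`GeometryError` on contour
    gaps larger than the sample's step tolerance.
    """
    if not sample.points:
        raise GeometryError("empty surface sample")
    anchors = np.array([p[0] for p in sample.points])
    v = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(anchors, axis=0), axis=1))])
    uv, dd, src, sid = [], [], [], []
    for i, (pts, dv) in enumerate(zip(sample.points, sample.doses)):
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if sample.step_tolerance is not None and steps.size:
            if steps.max() > sample.step_tolerance:
                raise GeometryError(
                    f"non-contiguous contour in slice {sample.slice_index[i]}: "
                    f"gap {steps.max():.3f} cm exceeds "
                    f"{sample.step_tolerance:.3f} cm"
                )
        u = np.concatenate([[0.0], np.cumsum(steps)])
        uv.append(np.column_stack([u, np.full_like(u, v[i])]))
        dd.append(dv)
        src.append(pts)
        sid.append(np.full(len(pts), sample.slice_index[i]))
    return UnfoldedSurface(
        points2d=np.concatenate(uv),
        doses=np.concatenate(dd),
        source_points=np.concatenate(src),
        slice_id=np.concatenate(sid),
    )


def isometry_error(sample: SurfaceSample, unfolded: UnfoldedSurface) -> float:
    """Largest |2D - 3D| distance mismatch over consecutive point pairs.

    Covers within-slice consecutive pairs and the anchor path; this is the
    distortion report for non-developable inputs.
    """
    err = 0.0
    start = 0
    anchors3d, anchors2d = [], []
    for pts in sample.points:
        n = len(pts)
        p2 = unfolded.points2d[start:start + n]
        d3 = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        d2 = np.linalg.norm(np.diff(p2, axis=0), axis=1)
        if d3.size:
            err = max(err, float(np.abs(d2 - d3).max()))
        anchors3d.append(pts[0])
        anchors2d.append(p2[0])
        start += n
    a3 = np.linalg.norm(np.diff(np.array(anchors3d), axis=0), axis=1)
    a2 = np.linalg.norm(np.diff(np.array(anchors2d), axis=0), axis=1)
    if a3.size:
        err = max(err, float(np.abs(a2 - a3).max()))
    return err


def rasterize_to_film_grid(
    unfolded: UnfoldedSurface,
    target_spacing: float = FILM_SPACING,
    provenance: str = "unfolded_tps",
) -> FilmDoseMap:
    """Linearly interpolate scattered unfolded points onto the film lattice.

    Triangulation-based linear interpolation; pixels outside the convex
    region of support are invalid. Each valid pixel records the index of its
    nearest source point for provenance.
    """
    pts = unfolded.points2d
    if len(pts) < 3:
        raise GeometryError("too few points to rasterise")
    try:
        interp = LinearNDInterpolator(pts, unfolded.doses)
    except (QhullError, ValueError) as exc:
        raise GeometryError(f"degenerate unfolded point set: {exc}") from exc
    u0, v0 = pts[:, 0].min(), pts[:, 1].min()
    u1, v1 = pts[:, 0].max(), pts[:, 1].max()
    nu = int(np.floor((u1 - u0) / target_spacing)) + 1
    nv = int(np.floor((v1 - v0) / target_spacing)) + 1
    if nu < 2 or nv < 2:
        raise GeometryError("unfolded points span a degenerate area")
    uu = u0 + target_spacing * np.arange(nu)
    vv = v0 + target_spacing * np.arange(nv)
    gu, gv = np.meshgrid(uu, vv)  # rows follow v, cols follow u
    dose = interp(gu, gv)
    valid = np.isfinite(dose)
    tree = cKDTree(pts)
    _, nearest = tree.query(np.column_stack([gu.ravel(), gv.ravel()]))
    source_index = np.where(valid, nearest.reshape(valid.shape), -1)
    return FilmDoseMap(
        np.where(valid, dose, np.nan),
        target_spacing,
        valid,
        provenance=provenance,
        source_index=source_index,
        source_points=unfolded.source_points,
    )


def segment_lat_inf(
    film: FilmDoseMap,
    lateral_extent: float = 11.0,
    inferior_extent: float = 14.0,
) -> Dict[str, np.ndarray]:
    """Partition the valid region into lateral (upper) and inferior (lower).

    Rows whose across-slice coordinate lies within the upper
    ``lateral_extent`` cm are lateral (the boundary row inclusive); the rest
    are inferior. Returns boolean masks for ``full``, ``lateral`` and
    ``inferior``.
    """
    if lateral_extent < 0 or inferior_extent < 0:
        raise ValueError("extents must be non-negative")
    if film.height_cm < lateral_extent:
        raise GeometryError(
            f"map height {film.height_cm:.1f} cm shorter than the lateral "
            f"extent {lateral_extent:.1f} cm"
        )
    v = np.arange(film.shape[0]) * film.pixel_spacing
    lateral_rows = v <= lateral_extent
    lateral = film.valid_mask & lateral_rows[:, None]
    inferior = film.valid_mask & ~lateral_rows[:, None]
    return {"full": film.valid_mask.copy(), "lateral": lateral,
            "inferior": inferior}
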