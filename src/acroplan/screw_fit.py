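"""Safe-zone extraction and maximal two-screw fitting.

The corridor map yields an oval "translucent" zone; fixation uses two
parallel screws, one per half of the zone. The zone is split evenly across
its long axis, the largest circle is inscribed in each half (the maximal
screw diameter that stays inside the corridor), and each screw's length is
the in-bone chord at its axis: the screw enters the anterior cortex and ends
just penetrating the posterior cortex (bicortical, flush exit, no protrusion
allowance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import trimesh
from scipy import ndimage, optimize
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import split as shapely_split
from skimage import measure as _skmeasure

from .corridor import ProjectionFrame, SafeMap, _cast_points, unitize
from .errors import DegenerateInputError, FitError, NoCorridorError, PreconditionError

log = logging.getLogger(__name__)

__all__ = [
    "SafeZone",
    "ScrewPlan",
    "extract_safe_zone",
    "split_zone",
    "max_inscribed_circle",
    "fit_screw",
    "plan_two_screws",
]


def _ring_moments(coords: np.ndarray):
    """Area, centroid and central second moments of one closed ring (Green)."""
    x, y = coords[:-1, 0], coords[:-1, 1]
    x1, y1 = coords[1:, 0], coords[1:, 1]
    cr = x * y1 - x1 * y
    a = cr.sum() / 2.0
    cx = ((x + x1) * cr).sum() / (6.0 * a) if a != 0 else 0.0
    cy = ((y + y1) * cr).sum() / (6.0 * a) if a != 0 else 0.0
    sxx = ((x * x + x * x1 + x1 * x1) * cr).sum() / 12.0
    syy = ((y * y + y * y1 + y1 * y1) * cr).sum() / 12.0
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cr).sum() / 24.0
    return a, cx, cy, sxx, syy, sxy


def polygon_principal_axes(poly: Polygon):
    """(centroid, major_axis, minor_axis) unit vectors from area moments."""
    rings = [np.asarray(poly.exterior.coords)]
    rings += [np.asarray(r.coords) for r in poly.interiors]
    A = Cx = Cy = Sxx = Syy = Sxy = 0.0
    for ring in rings:
        a, cx, cy, sxx, syy, sxy = _ring_moments(ring)
        A += a
        Cx += cx * a
        Cy += cy * a
        Sxx += sxx
        Syy += syy
        Sxy += sxy
    if abs(A) < 1e-12:
        raise DegenerateInputError("polygon has zero area")
    Cx, Cy = Cx / A, Cy / A
    # central second moments
    cov = np.array([[Sxx - A * Cx * Cx, Sxy - A * Cx * Cy],
                    [Sxy - A * Cx * Cy, Syy - A * Cy * Cy]]) / A
    w, vecs = np.linalg.eigh(cov)
    major, minor = vecs[:, 1], vecs[:, 0]  # eigh: ascending eigenvalues
    return np.array([Cx, Cy]), major, minor


@dataclass
class SafeZone:
    """Largest connected safe region, traced to a sub-pixel polygon (frame mm)."""

    polygon: Polygon
    frame: ProjectionFrame

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    @property
    def principal_axes(self):
        _, major, minor = polygon_principal_axes(self.polygon)
        return major, minor

    def as_json(self) -> dict:
        return {
            "exterior": np.asarray(self.polygon.exterior.coords).tolist(),
            "holes": [np.asarray(r.coords).tolist() for r in self.polygon.interiors],
            "area_mm2": self.area,
        }


@dataclass
class ScrewPlan:
    """One planned screw: geometry in mm, direction shared with the corridor."""

    side: str  # 'medial' | 'lateral'
    entry: np.ndarray  # 3D point on the anterior cortex
    direction: np.ndarray  # unit vector, anterior -> posterior
    diameter: float
    length: float
    center_uv: np.ndarray  # axis position in frame coordinates

    @property
    def exit_point(self) -> np.ndarray:
        return self.entry + self.length * self.direction

    def as_json(self) -> dict:
        return {
            "side": self.side,
            "entry_mm": self.entry.tolist(),
            "direction": self.direction.tolist(),
            "diameter_mm": round(float(self.diameter), 4),
            "length_mm": round(float(self.length), 4),
            "center_uv_mm": self.center_uv.tolist(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_json(), indent=2))

    def to_cylinder(self) -> trimesh.Trimesh:
        """Cylinder mesh of the screw for visual QC."""
        cyl = trimesh.creation.cylinder(radius=self.diameter / 2.0, height=self.length,
                                        sections=48)
        cyl.apply_translation([0, 0, self.length / 2.0])
        target = unitize(self.direction)
        rot = trimesh.geometry.align_vectors([0, 0, 1], target)
        cyl.apply_transform(rot)
        cyl.apply_translation(self.entry)
        return cyl


def extract_safe_zone(smap: SafeMap, entry_tol: float | None = None) -> SafeZone:
    """Trace the largest 8-connected safe component to a sub-pixel polygon.

    ``entry_tol`` (mm) additionally requires each ray's near-cortex crossing
    to lie on the common entry face: the screws enter through the anterior
    face of the distal acromion, so rays that only reach their chord by
    slipping in through the sloping inferior cortex further back are not
    part of the corridor. The face is identified by an iteratively
    reweighted plane fit of the entry depth t_in over the pixel grid; pixels
    whose entry deviates by more than ``entry_tol`` are dropped. An oblique
    planar face passes unclipped (the fit absorbs its slope); extruded
    shapes are unaffected.
    """
    safe = smap.safe
    if not safe.any():
        raise NoCorridorError("safe map has no safe pixels")
    if entry_tol is not None and safe.sum() >= 8:
        uu, vv = smap.frame.pixel_uv()
        x, y, tin = uu[safe], vv[safe], smap.t_in[safe]
        design = np.column_stack([np.ones_like(x), x, y])
        keep = np.ones(len(tin), dtype=bool)
        for _ in range(3):
            coef, *_ = np.linalg.lstsq(design[keep], tin[keep], rcond=None)
            resid = tin - design @ coef
            new_keep = np.abs(resid) <= entry_tol
            if new_keep.sum() < 8 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
        mask = np.zeros_like(safe)
        mask[safe] = keep
        safe = safe & mask
        if not safe.any():
            raise NoCorridorError("no safe pixels enter through the anterior face")
    labels, n = ndimage.label(safe, structure=np.ones((3, 3), dtype=int))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == int(np.argmax(counts))
    padded = np.pad(comp.astype(float), 1)
    contours = _skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise NoCorridorError("safe region too small to trace")
    ring = max(contours, key=lambda c: Polygon(c).area if len(c) >= 4 else 0.0)
    if len(ring) < 4:
        raise NoCorridorError("degenerate safe region")
    h = smap.frame.spacing
    xy = np.empty_like(ring)
    xy[:, 0] = smap.frame.u0 + (ring[:, 0] - 1.0) * h
    xy[:, 1] = smap.frame.v0 + (ring[:, 1] - 1.0) * h
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda p: p.area)
    if poly.area < 2.0 * h * h:
        raise NoCorridorError("safe region smaller than two pixels; no usable corridor")
    return SafeZone(polygon=poly, frame=smap.frame)


def split_zone(zone: SafeZone, medial_hint=None) -> tuple[Polygon, Polygon]:
    """Divide the zone evenly into a medial and a lateral half.

    The split line is perpendicular to the zone's major principal axis; its
    offset along that axis is solved so the two areas match (for symmetric
    zones this is the centroid line). Halves are labelled medial/lateral by
    projecting their centroids on ``medial_hint`` (an in-plane unit vector
    pointing medially; default +v axis).
    """
    poly = zone.polygon
    centroid, major, minor = polygon_principal_axes(poly)
    span = np.asarray(poly.exterior.coords) @ major
    lo, hi = float(span.min()), float(span.max())
    total = poly.area

    def left_area(offset: float) -> float:
        line = _split_line(centroid, major, minor, offset, poly)
        pieces = _split_pieces(poly, line)
        return sum(p.area for p in pieces
                   if (np.array(p.representative_point().coords[0]) @ major) < offset)

    offset = optimize.brentq(lambda off: left_area(off) - total / 2.0,
                             lo + 1e-9, hi - 1e-9, xtol=1e-6)

    line = _split_line(centroid, major, minor, offset, poly)
    pieces = _split_pieces(poly, line)
    sides = [(np.array(p.representative_point().coords[0]) @ major) < offset for p in pieces]
    neg = [p for p, s in zip(pieces, sides) if s]
    pos = [p for p, s in zip(pieces, sides) if not s]
    if len(pieces) > 2:
        log.warning("zone split produced %d pieces; keeping the largest per side", len(pieces))
    half_neg = max(neg, key=lambda p: p.area)
    half_pos = max(pos, key=lambda p: p.area)

    hint = np.asarray(medial_hint, dtype=float) if medial_hint is not None else np.array([0.0, 1.0])
    hint = hint / np.linalg.norm(hint)
    s_neg = float((np.array([half_neg.centroid.x, half_neg.centroid.y]) - centroid) @ hint)
    s_pos = float((np.array([half_pos.centroid.x, half_pos.centroid.y]) - centroid) @ hint)
    if s_neg >= s_pos:
        return half_neg, half_pos
    return half_pos, half_neg


def _split_line(centroid, major, minor, offset, poly) -> LineString:
    big = 4.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1]) + 10.0
    anchor = centroid + (offset - centroid @ major) * major
    return LineString([anchor - big * minor, anchor + big * minor])


def _split_pieces(poly: Polygon, line: LineString) -> list[Polygon]:
    pieces = [g for g in shapely_split(poly, line).geoms if g.geom_type == "Polygon"]
    return [p for p in pieces if p.area > 1e-12]


def max_inscribed_circle(region: Polygon, resolution: float = 0.1) -> tuple[np.ndarray, float]:
    """Largest circle inside ``region``: (center, radius) to ~0.05 mm.

    A Euclidean distance transform on a raster of the region locates the
    candidate center (first maximum in scan order, i.e. smallest (u, v) on
    ties); a Nelder-Mead polish against the exact polygon boundary refines
    it.
    """
    if region.is_empty or region.area <= 0:
        raise DegenerateInputError("cannot inscribe a circle in an empty region")
    x0, y0, x1, y1 = region.bounds
    h = min(resolution, max(x1 - x0, y1 - y0) / 40.0)
    xs = np.arange(x0 + h / 2, x1, h)
    ys = np.arange(y0 + h / 2, y1, h)
    if len(xs) == 0 or len(ys) == 0:
        raise DegenerateInputError("region too small to rasterize")
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = shapely.contains_xy(region, X.ravel(), Y.ravel()).reshape(X.shape)
    if not inside.any():
        raise DegenerateInputError("region has no interior at raster resolution")
    dist = ndimage.distance_transform_edt(np.pad(inside, 1)) * h
    dist = dist[1:-1, 1:-1]
    i, j = np.unravel_index(int(np.argmax(dist)), dist.shape)
    start = np.array([xs[i], ys[j]])

    boundary = region.boundary

    def neg_clearance(p):
        pt = Point(p)
        dd = boundary.distance(pt)
        return dd if not region.contains(pt) else -dd

    res = optimize.minimize(neg_clearance, start, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
    center = np.asarray(res.x)
    radius = -float(res.fun)
    if radius <= 0:
        raise DegenerateInputError("region degenerate: inscribed radius is zero")
    return center, radius


def fit_screw(
    mesh: trimesh.Trimesh,
    frame: ProjectionFrame,
    center_uv,
    direction,
    radius: float,
    side: str = "medial",
    tol: float = 0.05,
    n_ring: int = 96,
    max_shrink_steps: int = 10,
) -> ScrewPlan:
    """Fit one screw of the requested radius on the axis ray at ``center_uv``.

    The entry point is the near (anterior) cortex crossing of the axis ray
    and the length is the full in-bone chord, so the tip just penetrates the
    posterior cortex. Shaft containment is verified with ``n_ring`` rays on
    the cylinder surface, each of which must hold a single in-bone interval
    covering the axis chord; near the two cortical crossings an allowance of
    two screw radii absorbs cortex obliquity (up to ~63 degrees — an oblique
    entry cortex always leaves part of the screw circumference proud of the
    surface). If containment fails the radius is reduced in 0.05 mm steps
    (at most ``max_shrink_steps``) before raising :class:`FitError`.
    """
    direction = unitize(direction)
    if not np.allclose(direction, frame.d, atol=1e-9):
        raise PreconditionError("screw direction must match the corridor frame direction")
    center_uv = np.asarray(center_uv, dtype=float)
    axis = _cast_points(mesh, frame, center_uv[None, :], jitter_scale=1e-3)[0]
    if axis is None or len(axis) != 1:
        raise PreconditionError("axis ray is not a single-interval (safe) ray")
    t_in, t_out = axis[0]

    r = float(radius)
    psi = 2 * np.pi * np.arange(n_ring) / n_ring
    for _ in range(max_shrink_steps + 1):
        ring = center_uv[None, :] + r * np.stack([np.cos(psi), np.sin(psi)], axis=1)
        cap_allow = max(tol, 2.0 * r)
        res = _cast_points(mesh, frame, ring, jitter_scale=1e-3)
        lo, hi = t_in + cap_allow, t_out - cap_allow
        ok = True
        for ivals in res:
            if ivals is None or not any(a <= lo + tol and b >= hi - tol for a, b in ivals):
                ok = False
                break
        if ok:
            entry = frame.to_world(center_uv[0], center_uv[1], t_in)
            return ScrewPlan(side=side, entry=np.asarray(entry, dtype=float).reshape(3),
                             direction=direction, diameter=2.0 * r,
                             length=float(t_out - t_in), center_uv=center_uv)
        r -= 0.05
        if r <= 0:
            break
    raise FitError(f"no contained screw at {side} center {center_uv} (start radius {radius})")


def plan_two_screws(
    mesh: trimesh.Trimesh,
    frame: ProjectionFrame,
    zone: SafeZone,
    medial_hint=None,
    clearance: float = 0.0,
    min_diameter: float = 2.0,
) -> tuple[ScrewPlan, ScrewPlan]:
    """Maximal medial and lateral screws, one per half of the safe zone.

    Each half receives its maximum inscribed circle and a screw fitted at its
    center. The parallel axes must be separated by at least the sum of radii
    plus ``clearance`` mm; if not, both radii shrink proportionally. The
    default clearance is zero — the two maximal screws may touch, as the two
    half-zone inscribed circles both touch the split line — and a positive
    clearance is available for hardware that must not contact. Raises
    :class:`NoCorridorError` when either half cannot hold a screw of
    ``min_diameter``.
    """
    half_med, half_lat = split_zone(zone, medial_hint=medial_hint)
    planned = []
    for side, half in (("medial", half_med), ("lateral", half_lat)):
        try:
            center, radius = max_inscribed_circle(half)
        except DegenerateInputError as exc:
            raise NoCorridorError(f"{side} half-zone degenerate: {exc}") from exc
        if 2.0 * radius < min_diameter:
            raise NoCorridorError(
                f"{side} half-zone too small for a {min_diameter:.1f} mm screw")
        planned.append((side, center, radius))

    gap = float(np.linalg.norm(planned[0][1] - planned[1][1]))
    r_sum = planned[0][2] + planned[1][2]
    if gap < r_sum + clearance:
        scale = (gap - clearance) / r_sum
        if scale <= 0:
            raise NoCorridorError("screw centers too close for any clearance")
        log.warning("shrinking screw radii by %.3f to honour %.1f mm clearance", scale, clearance)
        planned = [(side, c, r * scale) for side, c, r in planned]
        if any(2 * r < min_diameter for _, _, r in planned):
            raise NoCorridorError("clearance rule leaves a screw under the minimum diameter")

    halves = {"medial": half_med, "lateral": half_lat}
    screws = []
    for side, c, r in planned:
        try:
            screws.append(fit_screw(mesh, frame, c, frame.d, r, side=side))
        except FitError:
            # the inscribed center can sit against a slanted-cortex edge of
            # the zone where no shrink of the radius alone helps; retry from
            # the inscribed circle of the eroded half, which recenters inward
            screws.append(_fit_recentred(mesh, frame, halves[side], side))
    return screws[0], screws[1]


def _fit_recentred(mesh, frame, half: Polygon, side: str) -> ScrewPlan:
    for erosion in (0.3, 0.6, 1.0):
        shrunk = half.buffer(-erosion)
        if shrunk.is_empty:
            break
        if shrunk.geom_type == "MultiPolygon":
            shrunk = max(shrunk.geoms, key=lambda g: g.area)
        try:
            c, r = max_inscribed_circle(shrunk)
            return fit_screw(mesh, frame, c, frame.d, r + erosion, side=side)
        except (DegenerateInputError, FitError):
            continue
    raise FitError(f"no contained {side} screw even after zone erosion")
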