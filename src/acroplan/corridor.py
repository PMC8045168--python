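"""Safe screw-corridor computation by parallel-ray classification.

A viewing direction ``d`` plays the role of the axial perspective: the view
down the long axis of the distal acromion. For a pixel grid on the plane
orthogonal to ``d`` we cast one ray per pixel through the solid bone and
record the in-bone intervals. A pixel is *safe* when its ray crosses the
solid exactly once (a single continuous in-bone segment) and that chord is at
least ``min_chord`` long: a screw on such a ray stays inside bone for its
whole course, while multi-interval rays imply a cortical breach and re-entry.
The safe pixels form the corridor ("translucent area") whose area the
direction optimizer maximizes.

Ray casting is done by rasterization: with all rays parallel, every triangle
is projected to the pixel grid once and its plane is solved for the ray
parameter ``t`` at each covered pixel, which is orders of magnitude faster
than independent ray/mesh queries and exact for watertight meshes. Grazing
hits (rays through triangle edges/vertices or edge-on triangles) are detected
by parity/orientation checks and resolved by deterministic sub-pixel
re-casts; pixels still ambiguous after four attempts are conservatively
marked unsafe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh

from .errors import AcroplanError, NoCorridorError
from .io_mesh import require_solid

__all__ = [
    "ProjectionFrame",
    "SafeMap",
    "build_frame",
    "solid_intervals",
    "safe_map",
    "safe_area",
    "optimize_direction",
    "full_length_floor",
    "unitize",
]

# deterministic sub-pixel jitter offsets (fractions of spacing/100)
_JITTERS = np.array([(0.37, 0.61), (-0.53, 0.29), (0.11, -0.73), (-0.67, -0.41)])
_BARY_EPS = 1e-8


def unitize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise AcroplanError("cannot normalize a zero vector")
    return v / n


def _orthonormal_basis(d: np.ndarray, up_hint: np.ndarray | None = None):
    """In-plane basis (u, v) with (u, v, d) right-handed.

    ``u`` is the component of ``up_hint`` (superior direction) orthogonal to
    ``d``; ``v = d x u`` then points along the remaining in-plane
    (mediolateral) axis.
    """
    d = unitize(d)
    if up_hint is None:
        up_hint = np.array([0.0, 0.0, 1.0])
    u = np.asarray(up_hint, dtype=float) - np.dot(up_hint, d) * d
    if np.linalg.norm(u) < 1e-6:
        # hint parallel to d: fall back to the most orthogonal world axis
        k = int(np.argmin(np.abs(d)))
        e = np.zeros(3)
        e[k] = 1.0
        u = e - np.dot(e, d) * d
    u = unitize(u)
    v = np.cross(d, u)
    return u, v


@dataclass(frozen=True)
class ProjectionFrame:
    """Pixel grid on the plane orthogonal to the viewing direction.

    Pixel (i, j) has in-plane coordinates ``(u0 + i*spacing, v0 + j*spacing)``
    and its ray is ``center + x*u + y*v + t*d`` for t in R.
    """

    center: np.ndarray  # 3D anchor point (mm)
    u: np.ndarray  # in-plane axis 1 (superior-ish)
    v: np.ndarray  # in-plane axis 2 (mediolateral)
    d: np.ndarray  # viewing direction
    spacing: float  # mm per pixel
    u0: float
    v0: float
    nu: int
    nv: int

    def __post_init__(self):
        for a, b in ((self.u, self.v), (self.u, self.d), (self.v, self.d)):
            if abs(float(np.dot(a, b))) > 1e-9:
                raise AcroplanError("projection frame basis is not orthogonal")
        if self.spacing <= 0:
            raise AcroplanError("pixel spacing must be positive")

    def pixel_uv(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (nu, nv) of in-plane pixel-center coordinates."""
        x = self.u0 + self.spacing * np.arange(self.nu)
        y = self.v0 + self.spacing * np.arange(self.nv)
        return np.meshgrid(x, y, indexing="ij")

    def to_world(self, x, y, t=0.0) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        t = np.asarray(t, dtype=float)[..., None]
        return self.center + x * self.u + y * self.v + t * self.d

    def project(self, points: np.ndarray) -> np.ndarray:
        """World points -> (x, y, t) frame coordinates."""
        rel = np.asarray(points, dtype=float) - self.center
        return np.stack([rel @ self.u, rel @ self.v, rel @ self.d], axis=-1)

    def as_json(self) -> dict:
        return {
            "center": self.center.tolist(),
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "d": self.d.tolist(),
            "spacing": self.spacing,
            "u0": self.u0,
            "v0": self.v0,
            "nu": self.nu,
            "nv": self.nv,
        }


def build_frame(
    mesh: trimesh.Trimesh,
    direction: np.ndarray,
    spacing: float = 0.25,
    up_hint: np.ndarray | None = None,
) -> ProjectionFrame:
    """Frame covering the mesh silhouette along ``direction`` with a margin.

    The grid is anchored with an irrational sub-pixel offset so pixel centers
    do not coincide with mesh edges of axis-aligned synthetic solids.
    """
    d = unitize(direction)
    u, v = _orthonormal_basis(d, up_hint)
    center = np.asarray(mesh.vertices.mean(axis=0), dtype=float)
    rel = mesh.vertices - center
    px, py = rel @ u, rel @ v
    margin = 2.0 * spacing
    frac = spacing * 0.31830988618  # 1/pi: keeps pixel centers off lattice edges
    u0 = float(px.min() - margin + frac)
    v0 = float(py.min() - margin + frac)
    nu = int(np.ceil((px.max() + margin - u0) / spacing)) + 1
    nv = int(np.ceil((py.max() + margin - v0) / spacing)) + 1
    return ProjectionFrame(center=center, u=u, v=v, d=d, spacing=spacing,
                           u0=u0, v0=v0, nu=nu, nv=nv)


@dataclass
class SafeMap:
    """Per-pixel ray classification over a projection frame.

    ``count`` is the number of disjoint in-bone intervals along the pixel's
    ray (-1 where grazing could not be resolved); ``t_in``/``t_out`` bound the
    single interval where ``count == 1`` (NaN elsewhere); ``chord`` is its
    length. ``safe`` marks pixels with exactly one interval of chord >=
    ``min_chord``.
    """

    frame: ProjectionFrame
    count: np.ndarray  # (nu, nv) int
    t_in: np.ndarray  # (nu, nv) float, NaN unless count == 1
    t_out: np.ndarray
    min_chord: float

    @property
    def chord(self) -> np.ndarray:
        return self.t_out - self.t_in

    @property
    def safe(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.count == 1) & (self.chord >= self.min_chord)

    @property
    def area(self) -> float:
        return float(self.safe.sum()) * self.frame.spacing**2

    @property
    def silhouette_area(self) -> float:
        return float((self.count >= 1).sum()) * self.frame.spacing**2

    def with_min_chord(self, min_chord: float) -> "SafeMap":
        return replace(self, min_chord=float(min_chord))

    def save_image(self, path: str | Path) -> None:
        """Export the classification as an 8-bit image + JSON frame sidecar.

        Grey levels: 0 = miss, 80 = multi-interval (breach), 160 = single
        interval below min_chord, 255 = safe.
        """
        from PIL import Image

        img = np.zeros(self.count.shape, dtype=np.uint8)
        img[self.count > 1] = 80
        img[self.count == 1] = 160
        img[self.safe] = 255
        Image.fromarray(img.T[::-1]).save(str(path))
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(json.dumps(
            {"frame": self.frame.as_json(), "min_chord": self.min_chord,
             "safe_area_mm2": self.area}, indent=2))


# ---------------------------------------------------------------------------
# ray casting internals
# ---------------------------------------------------------------------------

def _frame_coords(mesh: trimesh.Trimesh, frame: ProjectionFrame):
    """Triangle vertex coordinates in the frame: (M,3,2) in-plane + (M,3) t."""
    pts = frame.project(mesh.vertices)
    tri = pts[mesh.faces]  # (M, 3, 3)
    return tri[:, :, :2], tri[:, :, 2]


def _point_hits(tri2: np.ndarray, tri_t: np.ndarray, pts: np.ndarray):
    """Intersections of parallel rays at in-plane points with all triangles.

    Returns (point_idx, t, sign, suspect) arrays; ``sign`` is +1 where the
    ray exits the solid (outward normal along d) and -1 where it enters.
    ``suspect`` flags hits within a tolerance of a triangle boundary.
    """
    a, b, c = tri2[:, 0], tri2[:, 1], tri2[:, 2]
    e1, e2 = b - a, c - a
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]  # 2*signed area along d
    ok = np.abs(det) > 1e-14
    idx_tri = np.nonzero(ok)[0]
    a, e1, e2, det = a[ok], e1[ok], e2[ok], det[ok]
    t3 = tri_t[ok]
    # barycentric coordinates of every point in every triangle (broadcast)
    rel = pts[:, None, :] - a[None, :, :]  # (N, M, 2)
    l1 = (rel[..., 0] * e2[None, :, 1] - rel[..., 1] * e2[None, :, 0]) / det
    l2 = (e1[None, :, 0] * rel[..., 1] - e1[None, :, 1] * rel[..., 0]) / det
    l0 = 1.0 - l1 - l2
    inside = (l0 > -_BARY_EPS) & (l1 > -_BARY_EPS) & (l2 > -_BARY_EPS)
    pi, mi = np.nonzero(inside)
    lam = np.stack([l0[pi, mi], l1[pi, mi], l2[pi, mi]], axis=-1)
    t = np.einsum("ij,ij->i", lam, t3[mi])
    sign = np.where(det[mi] > 0, 1, -1)
    suspect = (np.abs(lam) < 1e-6).any(axis=1)
    return pi, t, sign, suspect, idx_tri[mi]


def _raster_hits(tri2: np.ndarray, tri_t: np.ndarray, frame: ProjectionFrame):
    """Grid version of :func:`_point_hits`: all triangles rasterized at once.

    Enumerates every (triangle, bbox-pixel) pair in flat arrays and solves the
    barycentric system vectorized. Returns flat pixel indices plus (t, sign,
    suspect) per hit and a boolean mask of pixels touched by edge-on
    (degenerate-projection) triangles.
    """
    h, u0, v0, nu, nv = frame.spacing, frame.u0, frame.v0, frame.nu, frame.nv
    degen_mask = np.zeros(nu * nv, dtype=bool)

    a, b, c = tri2[:, 0], tri2[:, 1], tri2[:, 2]
    e1, e2 = b - a, c - a
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    xmin = np.minimum(np.minimum(a[:, 0], b[:, 0]), c[:, 0])
    xmax = np.maximum(np.maximum(a[:, 0], b[:, 0]), c[:, 0])
    ymin = np.minimum(np.minimum(a[:, 1], b[:, 1]), c[:, 1])
    ymax = np.maximum(np.maximum(a[:, 1], b[:, 1]), c[:, 1])
    i0 = np.maximum(np.ceil((xmin - u0) / h).astype(np.int64), 0)
    i1 = np.minimum(np.floor((xmax - u0) / h).astype(np.int64), nu - 1)
    j0 = np.maximum(np.ceil((ymin - v0) / h).astype(np.int64), 0)
    j1 = np.minimum(np.floor((ymax - v0) / h).astype(np.int64), nv - 1)
    wi = np.maximum(i1 - i0 + 1, 0)
    hj = np.maximum(j1 - j0 + 1, 0)
    npix = wi * hj

    def _expand(sel: np.ndarray):
        """(tri_id, i, j) flat enumeration of bbox pixels for selected triangles."""
        cnt = npix[sel]
        tri_ids = np.nonzero(sel)[0]
        offs = np.concatenate([[0], np.cumsum(cnt)])
        total = int(offs[-1])
        if total == 0:
            return (np.empty(0, np.int64),) * 3
        rep = np.repeat(np.arange(len(tri_ids)), cnt)
        k = np.arange(total) - offs[rep]
        tid = tri_ids[rep]
        return tid, i0[tid] + k // hj[tid], j0[tid] + k % hj[tid]

    # edge-on triangles only poison the pixels they touch
    dg = (np.abs(det) <= 1e-14) & (npix > 0)
    if dg.any():
        _, di, dj = _expand(dg)
        degen_mask[di * nv + dj] = True

    tid, ii, jj = _expand((np.abs(det) > 1e-14) & (npix > 0))
    if len(tid) == 0:
        empty = np.empty(0)
        return empty.astype(int), empty, empty.astype(np.int8), empty.astype(bool), degen_mask
    rx = (u0 + h * ii) - a[tid, 0]
    ry = (v0 + h * jj) - a[tid, 1]
    l1 = (rx * e2[tid, 1] - ry * e2[tid, 0]) / det[tid]
    l2 = (e1[tid, 0] * ry - e1[tid, 1] * rx) / det[tid]
    l0 = 1.0 - l1 - l2
    inside = (l0 > -_BARY_EPS) & (l1 > -_BARY_EPS) & (l2 > -_BARY_EPS)
    tid, ii, jj = tid[inside], ii[inside], jj[inside]
    l0, l1, l2 = l0[inside], l1[inside], l2[inside]
    t = l0 * tri_t[tid, 0] + l1 * tri_t[tid, 1] + l2 * tri_t[tid, 2]
    sign = np.where(det[tid] > 0, 1, -1).astype(np.int8)
    suspect = (np.abs(l0) < 1e-6) | (np.abs(l1) < 1e-6) | (np.abs(l2) < 1e-6)
    return ii * nv + jj, t, sign, suspect, degen_mask


def _pair_intervals(ts: np.ndarray, signs: np.ndarray):
    """Sorted hit list -> disjoint (t_in, t_out) pairs, or None if invalid.

    Valid watertight crossings alternate enter (-1) / exit (+1) starting with
    an entry; coincident hits signal grazing.
    """
    n = len(ts)
    if n == 0:
        return []
    if n % 2:
        return None
    order = np.argsort(ts, kind="stable")
    ts, signs = ts[order], signs[order]
    if np.any(np.diff(ts) < 1e-9):
        return None
    if np.any(signs[0::2] != -1) or np.any(signs[1::2] != 1):
        return None
    return [(float(ts[k]), float(ts[k + 1])) for k in range(0, n, 2)]


def _cast_points(mesh, frame, pts_uv, jitter_scale):
    """Intervals for arbitrary in-plane points, with grazing jitter fallback.

    Returns a list (one entry per point) of interval lists; None marks points
    unresolved after all jitter attempts.
    """
    tri2, tri_t = _frame_coords(mesh, frame)
    pts_uv = np.atleast_2d(np.asarray(pts_uv, dtype=float))
    n = len(pts_uv)
    out: list = [None] * n
    pending = np.arange(n)
    pts = pts_uv.copy()
    for attempt in range(1 + len(_JITTERS)):
        pi, t, sign, suspect, _ = _point_hits(tri2, tri_t, pts[pending])
        still = []
        for k, orig in enumerate(pending):
            sel = pi == k
            ivals = _pair_intervals(t[sel], sign[sel])
            if ivals is None or suspect[sel].any():
                still.append(orig)
            else:
                out[orig] = ivals
        if not still:
            break
        pending = np.asarray(still)
        if attempt < len(_JITTERS):
            pts = pts_uv.copy()
            pts[pending] += _JITTERS[attempt] * jitter_scale
    return out


def solid_intervals(mesh: trimesh.Trimesh, origin, direction) -> list[tuple[float, float]]:
    """In-bone intervals (t_in, t_out) along the ray origin + t*direction.

    The mesh must be a watertight, outward-oriented solid. Intervals are
    strictly increasing and disjoint; grazing hits are resolved by
    deterministic sub-ray jitter.
    """
    require_solid(mesh)
    d = unitize(direction)
    u, v = _orthonormal_basis(d)
    frame = ProjectionFrame(center=np.asarray(origin, dtype=float), u=u, v=v, d=d,
                            spacing=1.0, u0=0.0, v0=0.0, nu=1, nv=1)
    res = _cast_points(mesh, frame, np.array([[0.0, 0.0]]), jitter_scale=1e-3)
    if res[0] is None:
        raise AcroplanError("grazing ray could not be resolved by jitter")
    return res[0]


def safe_map(
    mesh: trimesh.Trimesh,
    direction,
    spacing: float = 0.25,
    min_chord: float = 10.0,
    up_hint=None,
    frame: ProjectionFrame | None = None,
) -> SafeMap:
    """Classify one ray per pixel over the silhouette of ``mesh`` along ``direction``."""
    require_solid(mesh)
    if frame is None:
        if spacing > 1.0:
            raise AcroplanError("pixel spacing must be <= 1.0 mm")
        frame = build_frame(mesh, direction, spacing=spacing, up_hint=up_hint)
    tri2, tri_t = _frame_coords(mesh, frame)
    idx, t, sign, suspect, degen = _raster_hits(tri2, tri_t, frame)

    npix = frame.nu * frame.nv
    count = np.zeros(npix, dtype=np.int16)
    t_in = np.full(npix, np.nan)
    t_out = np.full(npix, np.nan)
    bad: set[int] = set(np.nonzero(degen)[0].tolist())

    if len(idx):
        order = np.lexsort((t, idx))
        idx, t, sign, suspect = idx[order], t[order], sign[order], suspect[order]
        starts = np.nonzero(np.r_[True, np.diff(idx) != 0])[0]
        ends = np.r_[starts[1:], len(idx)]
        nhits = ends - starts

        # fast path: the common 2-hit (single interval) pixels, vectorized
        two = nhits == 2
        s2 = starts[two]
        p2 = idx[s2]
        good2 = ((sign[s2] == -1) & (sign[s2 + 1] == 1)
                 & (t[s2 + 1] - t[s2] >= 1e-9)
                 & ~suspect[s2] & ~suspect[s2 + 1])
        ok2 = p2[good2]
        count[ok2] = 1
        t_in[ok2], t_out[ok2] = t[s2[good2]], t[s2[good2] + 1]
        bad.update(p2[~good2].tolist())

        for s, e in zip(starts[~two], ends[~two]):
            p = int(idx[s])
            if p in bad:
                continue
            ivals = _pair_intervals(t[s:e], sign[s:e])
            if ivals is None or suspect[s:e].any():
                bad.add(p)
                continue
            count[p] = len(ivals)
            if len(ivals) == 1:
                t_in[p], t_out[p] = ivals[0]

    if bad:
        bad_list = sorted(bad)
        xy = np.array([(frame.u0 + frame.spacing * (p // frame.nv),
                        frame.v0 + frame.spacing * (p % frame.nv)) for p in bad_list])
        res = _cast_points(mesh, frame, xy, jitter_scale=frame.spacing / 100.0)
        for p, ivals in zip(bad_list, res):
            if ivals is None:
                count[p] = -1  # conservatively unsafe
            else:
                count[p] = len(ivals)
                if len(ivals) == 1:
                    t_in[p], t_out[p] = ivals[0]

    shape = (frame.nu, frame.nv)
    return SafeMap(frame=frame, count=count.reshape(shape),
                   t_in=t_in.reshape(shape), t_out=t_out.reshape(shape),
                   min_chord=float(min_chord))


def safe_area(smap: SafeMap) -> float:
    """Corridor area in mm^2: number of safe pixels times pixel area."""
    return smap.area


def _cone_directions(init: np.ndarray, half_angle_deg: float, step_deg: float):
    """Deterministic quasi-uniform grid of unit vectors inside a cone."""
    init = unitize(init)
    e1, e2 = _orthonormal_basis(init)
    dirs = [init]
    n_rings = int(np.floor(half_angle_deg / step_deg))
    for k in range(1, n_rings + 1):
        theta = np.deg2rad(k * step_deg)
        n_az = max(6, int(round(360.0 * np.sin(theta) / step_deg)))
        psi = 2 * np.pi * np.arange(n_az) / n_az
        ring = (np.cos(theta) * init[None, :]
                + np.sin(theta) * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2))
        dirs.extend(ring)
    return np.asarray(dirs)


def optimize_direction(
    mesh: trimesh.Trimesh,
    init,
    cone_half_angle: float = 30.0,
    coarse_step: float = 3.0,
    refine_tol: float = 0.5,
    spacing: float = 0.25,
    search_spacing: float | None = None,
    min_chord: float = 10.0,
    rel_chord: float = 0.9,
    up_hint=None,
) -> tuple[np.ndarray, SafeMap]:
    """Find the viewing direction maximizing the safe-corridor area.

    Coarse spherical grid search inside a cone of ``cone_half_angle`` around
    the anatomical initialization, followed by a shrinking 3x3 local search
    down to ``refine_tol``. The search runs at ``search_spacing`` (default:
    the coarser of ``spacing`` and 0.5 mm); the returned map is recomputed at
    ``spacing``. Deterministic for fixed inputs; ties go to the first grid
    candidate.

    Candidate directions are scored by the area of pixels whose chord
    reaches ``rel_chord`` times the longest corridor achievable in the cone
    (the maximum 95th-percentile chord over the coarse candidates, never
    below ``min_chord``). The raw safe area alone would reward oblique views
    — tilting a rod inflates its silhouette while many chords stay above a
    small absolute floor — whereas the screw corridor must run the full
    length of the bone; scoring against the cone-wide full-length reference
    makes the extrusion axis the optimum for straight rods. The returned map
    uses the absolute ``min_chord`` only.
    """
    init = unitize(init)
    if search_spacing is None:
        search_spacing = max(spacing, 0.5)

    def chords_of(d) -> np.ndarray:
        m = safe_map(mesh, d, spacing=search_spacing, min_chord=min_chord,
                     up_hint=up_hint)
        return (m.t_out - m.t_in)[m.count == 1]

    cand = _cone_directions(init, cone_half_angle, coarse_step)
    cand_chords = [chords_of(d) for d in cand]
    p95 = [float(np.percentile(c, 95)) if c.size else 0.0 for c in cand_chords]
    floor = max(min_chord, rel_chord * max(p95, default=0.0))
    px_area = search_spacing**2

    def score_chords(c: np.ndarray) -> float:
        return float(np.count_nonzero(c >= floor)) * px_area

    def area_of(d) -> float:
        return score_chords(chords_of(d))

    areas = np.array([score_chords(c) for c in cand_chords])
    best = cand[int(np.argmax(areas))]
    best_area = float(areas.max())

    e1, e2 = _orthonormal_basis(init)
    step = coarse_step / 2.0
    while step >= refine_tol / 2.0:
        th = np.deg2rad(step)
        moved = True
        while moved:
            moved = False
            for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)):
                cand_d = unitize(best + np.tan(th) * (da * e1 + db * e2))
                if np.degrees(np.arccos(np.clip(np.dot(cand_d, init), -1, 1))) > cone_half_angle + 1e-9:
                    continue
                a = area_of(cand_d)
                if a > best_area + 1e-12:
                    best, best_area = cand_d, a
                    moved = True
        step /= 2.0

    if best_area <= 0.0:
        raise NoCorridorError(
            f"no safe corridor (min_chord={min_chord} mm) in a {cone_half_angle} deg cone")
    final = safe_map(mesh, best, spacing=spacing, min_chord=min_chord, up_hint=up_hint)
    return best, full_length_floor(final, min_chord=min_chord, rel_chord=rel_chord)


def full_length_floor(smap: SafeMap, min_chord: float = 10.0,
                      rel_chord: float = 0.9) -> SafeMap:
    """Raise a map's chord floor to ``rel_chord`` x its 95th-percentile chord.

    The screw corridor must traverse the whole distal fragment; with only a
    small absolute floor the safe region would also admit short paths through
    the thick proximal bone that never cross the fracture. The floor never
    drops below ``min_chord``.
    """
    chords = (smap.t_out - smap.t_in)[smap.count == 1]
    if chords.size == 0:
        return smap.with_min_chord(min_chord)
    return smap.with_min_chord(max(min_chord, rel_chord * float(np.percentile(chords, 95))))
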