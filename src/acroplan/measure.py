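"""Per-subject morphometry: entry-point distances and screw angles.

Conventions:

* ``L1``/``L2`` — 3D Euclidean distances from the medial screw entry point to
  the acromioclavicular (AC) facet landmark and to the distal anterior edge
  of the acromion; ``L3``/``L4`` are the same distances for the lateral
  screw. Distances are straight-line caliper measurements to single
  representative landmark points (the AC facet is represented by its
  centroid); a point-to-patch minimum distance is available via
  ``facet_mode='surface'``.
* ``alpha`` — downdip angle between the screw axis and plane A, the
  total-least-squares plane of the superior surface of the distal acromion.
* ``beta`` — inclination of the screw axis relative to plane B, a plane
  perpendicular to plane A through the corridor. Plane B's free rotation is
  fixed by a reference axis: by default the corridor direction itself (in
  which case parallel screws give beta = 0); the pipeline passes the
  anatomical axial-view axis instead so beta measures the mediolateral tilt
  of the planned screws against the anatomical axial plane.

Both screws are parallel by construction, so each subject has a single
(alpha, beta) pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .corridor import ProjectionFrame, unitize
from .errors import AcroplanError, DegenerateInputError, FormatError
from .screw_fit import SafeZone, ScrewPlan

__all__ = [
    "LandmarkSet",
    "ReferencePlane",
    "SubjectMeasurement",
    "fit_plane_A",
    "define_plane_B",
    "screw_plane_angle",
    "landmark_distances",
    "measure_subject",
]


def _point_surface_distance(mesh: trimesh.Trimesh, point: np.ndarray) -> float:
    """Exact min distance from one point to the triangulated surface."""
    tris = mesh.triangles
    closest = trimesh.triangles.closest_point(tris, np.tile(point, (len(tris), 1)))
    return float(np.linalg.norm(closest - point, axis=1).min())


@dataclass
class LandmarkSet:
    """Anatomical landmarks: AC facet point, distal anterior edge, superior patch."""

    ac_facet: np.ndarray  # representative point of the AC articular surface
    anterior_edge: np.ndarray  # distal anterior edge of the acromion
    superior_patch: np.ndarray  # mesh vertex indices on the upper distal surface

    def __post_init__(self):
        self.ac_facet = np.asarray(self.ac_facet, dtype=float).reshape(3)
        self.anterior_edge = np.asarray(self.anterior_edge, dtype=float).reshape(3)
        self.superior_patch = np.asarray(self.superior_patch, dtype=int).reshape(-1)

    def validate(self, mesh: trimesh.Trimesh, surface_tol: float = 1.0) -> None:
        if len(self.superior_patch) < 30:
            raise DegenerateInputError("superior patch needs at least 30 vertices")
        if self.superior_patch.max() >= len(mesh.vertices) or self.superior_patch.min() < 0:
            raise DegenerateInputError("superior patch indices out of range")
        pts = np.vstack([self.ac_facet, self.anterior_edge])
        dist = [_point_surface_distance(mesh, p) for p in pts]
        if np.any(np.asarray(dist) > surface_tol):
            raise DegenerateInputError(
                f"landmark further than {surface_tol} mm from the surface (d={dist})")

    @classmethod
    def load_json(cls, path: str | Path) -> "LandmarkSet":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"landmark file not found: {path}")
        try:
            obj = json.loads(path.read_text())
            return cls(ac_facet=obj["ac_facet"], anterior_edge=obj["anterior_edge"],
                       superior_patch=obj["superior_patch"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"invalid landmark file {path}: {exc}") from exc

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "ac_facet": self.ac_facet.tolist(),
            "anterior_edge": self.anterior_edge.tolist(),
            "superior_patch": self.superior_patch.tolist(),
        }))


@dataclass(frozen=True)
class ReferencePlane:
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        object.__setattr__(self, "normal", unitize(self.normal))


@dataclass
class SubjectMeasurement:
    """One subject's row of the measurement table (mm and degrees)."""

    subject_id: str
    sex: str
    ms_length: float
    ms_diameter: float
    ls_length: float
    ls_diameter: float
    L1: float
    L2: float
    L3: float
    L4: float
    alpha: float
    beta: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = [self.ms_length, self.ms_diameter, self.ls_length, self.ls_diameter,
                self.L1, self.L2, self.L3, self.L4]
        if any(v < 0 or not np.isfinite(v) for v in vals):
            raise AcroplanError("measurements must be finite and non-negative")
        for name in ("alpha", "beta"):
            a = getattr(self, name)
            if not (0.0 <= a <= 90.0):
                raise AcroplanError(f"{name} must lie in [0, 90] degrees, got {a}")

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "subject_id", "sex", "ms_length", "ms_diameter", "ls_length",
            "ls_diameter", "L1", "L2", "L3", "L4", "alpha", "beta")}
        return d


def fit_plane_A(mesh: trimesh.Trimesh, landmarks: LandmarkSet) -> ReferencePlane:
    """Total-least-squares plane of the superior patch, normal pointing outward.

    The normal is the smallest right singular vector of the centred patch
    vertices, oriented along the mean outward vertex normal of the patch
    (superiorly).
    """
    idx = landmarks.superior_patch
    if len(idx) < 3:
        raise DegenerateInputError("plane A needs at least 3 patch vertices")
    pts = mesh.vertices[idx]
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9:
        raise DegenerateInputError("superior patch is collinear; plane A undefined")
    normal = vt[2]
    outward = np.asarray(mesh.vertex_normals[idx]).mean(axis=0)
    if np.dot(normal, outward) < 0:
        normal = -normal
    return ReferencePlane(point=centroid, normal=normal)


def define_plane_B(
    plane_a: ReferencePlane,
    zone: SafeZone,
    frame: ProjectionFrame,
    reference_dir=None,
) -> ReferencePlane:
    """Plane through the zone centroid, perpendicular to plane A.

    Its free rotation is fixed so the plane contains the projection of
    ``reference_dir`` (default: the corridor direction ``frame.d``) onto
    plane A; the normal is the in-plane-A direction orthogonal to that
    projection. Raises when the reference axis is parallel to plane A's
    normal (the projection vanishes and the plane is undefined).
    """
    ref = unitize(reference_dir if reference_dir is not None else frame.d)
    n_a = plane_a.normal
    proj = ref - np.dot(ref, n_a) * n_a
    if np.linalg.norm(proj) < 1e-9:
        raise DegenerateInputError(
            "reference axis parallel to plane A normal; plane B undefined")
    normal = unitize(np.cross(n_a, proj))
    cuv = zone.centroid
    point = np.asarray(frame.to_world(cuv[0], cuv[1], 0.0), dtype=float).reshape(3)
    return ReferencePlane(point=point, normal=normal)


def screw_plane_angle(screw: ScrewPlan | np.ndarray, plane: ReferencePlane) -> float:
    """Angle in degrees between a screw axis and a plane, in [0, 90]."""
    direction = screw.direction if isinstance(screw, ScrewPlan) else np.asarray(screw, float)
    s = abs(float(np.dot(unitize(direction), plane.normal)))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


def landmark_distances(
    screws: tuple[ScrewPlan, ScrewPlan],
    landmarks: LandmarkSet,
    facet_mode: str = "point",
    mesh: trimesh.Trimesh | None = None,
) -> tuple[float, float, float, float]:
    """(L1, L2, L3, L4): entry-point distances to the AC facet and anterior edge.

    ``facet_mode='surface'`` replaces the facet-point distance with the
    minimum distance from the entry to the mesh vertices of the superior
    patch neighbourhood of the facet (requires ``mesh``).
    """
    medial, lateral = screws
    if facet_mode == "point":
        L1 = float(np.linalg.norm(medial.entry - landmarks.ac_facet))
        L3 = float(np.linalg.norm(lateral.entry - landmarks.ac_facet))
    elif facet_mode == "surface":
        # distance to the facet neighbourhood (vertices within 4 mm of the point)
        if mesh is None:
            raise AcroplanError("facet_mode='surface' requires the mesh")
        near = np.linalg.norm(mesh.vertices - landmarks.ac_facet, axis=1) < 4.0
        patch = mesh.vertices[near] if near.any() else landmarks.ac_facet[None, :]
        L1 = float(np.linalg.norm(patch - medial.entry, axis=1).min())
        L3 = float(np.linalg.norm(patch - lateral.entry, axis=1).min())
    else:
        raise AcroplanError(f"unknown facet_mode {facet_mode!r}")
    L2 = float(np.linalg.norm(medial.entry - landmarks.anterior_edge))
    L4 = float(np.linalg.norm(lateral.entry - landmarks.anterior_edge))
    return L1, L2, L3, L4


def measure_subject(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    screws: tuple[ScrewPlan, ScrewPlan],
    plane_a: ReferencePlane,
    plane_b: ReferencePlane,
    subject_id: str = "subject",
    sex: str = "U",
) -> SubjectMeasurement:
    """Assemble one complete measurement row for a planned subject.

    alpha and beta are averaged over the two screws; they are identical by
    construction because the screws share the corridor direction.
    """
    medial, lateral = screws
    L1, L2, L3, L4 = landmark_distances(screws, landmarks)
    alpha = float(np.mean([screw_plane_angle(s, plane_a) for s in screws]))
    beta = float(np.mean([screw_plane_angle(s, plane_b) for s in screws]))
    return SubjectMeasurement(
        subject_id=subject_id, sex=sex,
        ms_length=float(medial.length), ms_diameter=float(medial.diameter),
        ls_length=float(lateral.length), ls_diameter=float(lateral.diameter),
        L1=L1, L2=L2, L3=L3, L4=L4, alpha=alpha, beta=beta)
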