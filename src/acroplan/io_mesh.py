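"""Bone geometry input: surface meshes and binary segmentation volumes.

All geometry is handled in millimetres in a right-handed frame. The planning
pipeline was designed for right scapulae; left-side inputs must be mirrored by
the user before loading.

Surfaces are represented with :class:`trimesh.Trimesh`; this module adds
validation, unit handling and marching-cubes extraction from binary volumes
(e.g. a thresholded CT segmentation exported as NIfTI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure as _skmeasure

from .errors import DegenerateInputError, FormatError, PreconditionError

log = logging.getLogger(__name__)

__all__ = [
    "BinaryVolume",
    "ValidationReport",
    "load_mesh",
    "save_mesh",
    "load_volume",
    "mesh_from_volume",
    "validate_mesh",
    "require_solid",
]


@dataclass
class BinaryVolume:
    """Binary segmentation on a regular voxel grid.

    Parameters
    ----------
    data : ndarray of bool, shape (ni, nj, nk)
        Foreground = bone.
    spacing : (3,) float
        Voxel edge lengths in mm per axis.
    affine : (4, 4) float, optional
        Voxel-index -> mm map. Defaults to a diagonal scaling by ``spacing``.
    """

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise DegenerateInputError("voxel spacing must be strictly positive")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise DegenerateInputError("volume affine is singular")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class ValidationReport:
    watertight: bool
    oriented: bool
    n_components: int
    n_vertices: int
    n_faces: int
    volume_mm3: float

    @property
    def solid_ok(self) -> bool:
        return self.watertight and self.oriented and self.n_components == 1


def load_mesh(path: str | Path, units: str = "mm") -> trimesh.Trimesh:
    """Load an STL/PLY surface, returning a mesh in millimetres.

    ``units='m'`` rescales coordinates by 1000. Multi-component meshes are
    reduced to the largest component by volume (segmentation debris is
    common); a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), process=True)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"could not read mesh {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise DegenerateInputError(f"no geometry in {path}")
        mesh = trimesh.util.concatenate(geoms)
    if mesh.vertices.shape[0] == 0 or mesh.faces.shape[0] == 0:
        raise DegenerateInputError(f"empty mesh: {path}")
    if not np.isfinite(mesh.vertices).all():
        raise FormatError(f"non-finite vertex coordinates in {path}")
    if units == "m":
        mesh = mesh.copy()
        mesh.apply_scale(1000.0)
    elif units != "mm":
        raise FormatError(f"unknown units flag {units!r}; expected 'mm' or 'm'")
    mesh = _largest_component(mesh)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    mesh.metadata["provenance"] = {"path": str(path), "units": units}
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh to STL or PLY (format from the suffix)."""
    mesh.export(str(path))


def _largest_component(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    parts = mesh.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    log.warning("mesh has %d components; keeping the largest", len(parts))
    sizes = [abs(p.volume) if p.is_watertight else p.area for p in parts]
    return parts[int(np.argmax(sizes))]


def load_volume(path: str | Path) -> BinaryVolume:
    """Read a binary segmentation from NIfTI (.nii / .nii.gz)."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return BinaryVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def mesh_from_volume(vol: BinaryVolume, iso_smoothing: bool = False) -> trimesh.Trimesh:
    """Extract a watertight surface from a binary volume.

    Runs marching cubes at the 0.5 level on the (zero-padded) binary grid, in
    voxel index space, then maps vertices through the affine. If the
    foreground has several 6-connected components the largest is used with a
    warning. ``iso_smoothing`` applies one pass of Laplacian smoothing; off by
    default so outputs are deterministic and volumes are conserved.
    """
    from scipy import ndimage

    data = vol.data
    if not data.any():
        raise DegenerateInputError("volume has no foreground voxels")
    labels, n = ndimage.label(data, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        log.warning("volume has %d components; keeping the largest", n)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        data = labels == int(np.argmax(counts))
    padded = np.pad(data.astype(np.float32), 1)
    verts, faces, _, _ = _skmeasure.marching_cubes(padded, level=0.5)
    verts -= 1.0  # undo pad
    hom = np.c_[verts, np.ones(len(verts))]
    verts_mm = (vol.affine @ hom.T).T[:, :3]
    mesh = trimesh.Trimesh(vertices=verts_mm, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if iso_smoothing:
        trimesh.smoothing.filter_laplacian(mesh, iterations=1)
    if not mesh.is_watertight:  # pragma: no cover - marching cubes on padded grids closes
        raise DegenerateInputError("isosurface extraction produced a non-watertight mesh")
    return mesh


def validate_mesh(mesh: trimesh.Trimesh) -> ValidationReport:
    """Report watertightness, orientation and component count; never raises."""
    watertight = bool(mesh.is_watertight)
    oriented = bool(watertight and mesh.is_winding_consistent and mesh.volume > 0)
    n_components = int(mesh.body_count)
    return ValidationReport(
        watertight=watertight,
        oriented=oriented,
        n_components=n_components,
        n_vertices=int(len(mesh.vertices)),
        n_faces=int(len(mesh.faces)),
        volume_mm3=float(mesh.volume) if watertight else float("nan"),
    )


def require_solid(mesh: trimesh.Trimesh) -> None:
    """Raise :class:`PreconditionError` unless the mesh is a usable solid."""
    rep = validate_mesh(mesh)
    if not rep.watertight:
        raise PreconditionError("mesh is not watertight; solid ray queries are undefined")
    if not rep.oriented:
        raise PreconditionError("mesh is not consistently outward-oriented")
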