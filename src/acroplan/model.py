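"""Model/Results interface over the planning pipeline.

:class:`ScrewPlanner` is built from one subject's geometry (mesh +
landmarks); ``fit()`` runs the corridor optimization, fits the two maximal
screws and measures the subject, returning a :class:`ScrewPlanResults` that
carries the plans, the measurement row and a ``summary()`` table.
:class:`SexComparison` is built from a cohort measurement table and its
``fit()`` reproduces the sex-stratified comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import cohort_stats, corridor, io_mesh, measure, screw_fit
from .errors import AcroplanError
from .measure import LandmarkSet

__all__ = ["PlannerConfig", "ScrewPlanner", "ScrewPlanResults",
           "SexComparison", "SexComparisonResults"]


@dataclass(frozen=True)
class PlannerConfig:
    """Tunable geometry parameters of the planning pipeline (mm / degrees)."""

    spacing: float = 0.25  # safe-map pixel size
    search_spacing: float | None = None  # coarser grid for direction search
    min_chord: float = 10.0  # minimum bicortical chord for a safe ray
    cone_half_angle: float = 30.0  # direction search cone around the init axis
    coarse_step: float = 3.0
    refine_tol: float = 0.5
    clearance: float = 0.0  # minimum gap between screw surfaces (0: may touch)
    min_diameter: float = 2.0
    entry_tol: float | None = 2.0  # entry-face coherence window for the zone
    optimize: bool = True  # False: use the init direction as-is

    def validate(self) -> None:
        if not (0 < self.spacing <= 1.0):
            raise AcroplanError("spacing must lie in (0, 1] mm")
        if self.min_chord < 0 or self.clearance < 0:
            raise AcroplanError("min_chord and clearance must be non-negative")
        if not (0 < self.cone_half_angle <= 90):
            raise AcroplanError("cone_half_angle must lie in (0, 90] degrees")


class ScrewPlanner:
    """Two-screw corridor planner for one subject.

    Parameters
    ----------
    mesh : trimesh.Trimesh
        Watertight solid bone surface in mm (right side).
    landmarks : LandmarkSet
        AC facet, anterior edge, superior patch.
    init_direction : (3,) array, optional
        Anatomical axial-view axis (roughly the distal acromion long axis).
        Defaults to the mesh's longest principal axis, oriented away from the
        anterior edge landmark.
    config : PlannerConfig
    """

    def __init__(self, mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                 init_direction=None, config: PlannerConfig = PlannerConfig(),
                 subject_id: str = "subject", sex: str = "U"):
        config.validate()
        io_mesh.require_solid(mesh)
        self.mesh = mesh
        self.landmarks = landmarks
        self.config = config
        self.subject_id = subject_id
        self.sex = sex
        if init_direction is None:
            init_direction = self._default_axis()
        self.init_direction = corridor.unitize(init_direction)

    @classmethod
    def from_files(cls, mesh_path, landmarks_path, units: str = "mm", **kwargs):
        mesh = io_mesh.load_mesh(mesh_path, units=units)
        lm = LandmarkSet.load_json(landmarks_path)
        return cls(mesh, lm, **kwargs)

    def _default_axis(self) -> np.ndarray:
        # longest principal axis of the vertex cloud, pointing away from the
        # anterior edge (screws run anterior -> posterior)
        verts = self.mesh.vertices - self.mesh.vertices.mean(axis=0)
        _, _, vt = np.linalg.svd(verts, full_matrices=False)
        axis = vt[0]
        toward = self.mesh.vertices.mean(axis=0) - self.landmarks.anterior_edge
        if np.dot(axis, toward) < 0:
            axis = -axis
        return axis

    def fit(self) -> "ScrewPlanResults":
        cfg = self.config
        plane_a = measure.fit_plane_A(self.mesh, self.landmarks)
        up_hint = plane_a.normal

        if cfg.optimize:
            direction, smap = corridor.optimize_direction(
                self.mesh, self.init_direction,
                cone_half_angle=cfg.cone_half_angle, coarse_step=cfg.coarse_step,
                refine_tol=cfg.refine_tol, spacing=cfg.spacing,
                search_spacing=cfg.search_spacing, min_chord=cfg.min_chord,
                up_hint=up_hint)
        else:
            direction = self.init_direction
            smap = corridor.safe_map(self.mesh, direction, spacing=cfg.spacing,
                                     min_chord=cfg.min_chord, up_hint=up_hint)
            smap = corridor.full_length_floor(smap, min_chord=cfg.min_chord)

        zone = screw_fit.extract_safe_zone(smap, entry_tol=cfg.entry_tol)
        facet_uv = smap.frame.project(self.landmarks.ac_facet[None, :])[0, :2]
        hint = facet_uv - zone.centroid
        medial_hint = hint / np.linalg.norm(hint) if np.linalg.norm(hint) > 1e-9 else None
        medial, lateral = screw_fit.plan_two_screws(
            self.mesh, smap.frame, zone, medial_hint=medial_hint,
            clearance=cfg.clearance, min_diameter=cfg.min_diameter)

        plane_b = measure.define_plane_B(plane_a, zone, smap.frame,
                                         reference_dir=self.init_direction)
        row = measure.measure_subject(self.mesh, self.landmarks, (medial, lateral),
                                      plane_a, plane_b, subject_id=self.subject_id,
                                      sex=self.sex)
        return ScrewPlanResults(model=self, direction=direction, safe_map=smap,
                                zone=zone, medial=medial, lateral=lateral,
                                plane_a=plane_a, plane_b=plane_b, measurement=row)


@dataclass
class ScrewPlanResults:
    """Fitted plan: corridor direction, safe zone, two screws, measurements."""

    model: ScrewPlanner
    direction: np.ndarray
    safe_map: corridor.SafeMap
    zone: screw_fit.SafeZone
    medial: screw_fit.ScrewPlan
    lateral: screw_fit.ScrewPlan
    plane_a: measure.ReferencePlane
    plane_b: measure.ReferencePlane
    measurement: measure.SubjectMeasurement
    extra: dict = field(default_factory=dict)

    @property
    def screws(self) -> tuple[screw_fit.ScrewPlan, screw_fit.ScrewPlan]:
        return self.medial, self.lateral

    def summary(self) -> str:
        m = self.measurement
        lines = [
            f"Screw corridor plan — subject {m.subject_id} (sex {m.sex})",
            f"  corridor direction    : [{self.direction[0]:+.4f} {self.direction[1]:+.4f} "
            f"{self.direction[2]:+.4f}]",
            f"  safe-zone area        : {self.zone.area:8.2f} mm^2",
            f"  medial screw          : Ø {m.ms_diameter:5.2f} mm × {m.ms_length:6.2f} mm",
            f"  lateral screw         : Ø {m.ls_diameter:5.2f} mm × {m.ls_length:6.2f} mm",
            f"  entry distances       : L1 {m.L1:5.2f}  L2 {m.L2:5.2f}  "
            f"L3 {m.L3:5.2f}  L4 {m.L4:5.2f} mm",
            f"  angles                : alpha {m.alpha:5.2f}°  beta {m.beta:5.2f}°",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.measurement.as_dict()])

    def save(self, outdir) -> dict:
        """Write screw JSONs, safe-map image and the measurement row; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for s in self.screws:
            p = outdir / f"screw_{s.side}.json"
            s.save_json(p)
            paths[f"screw_{s.side}"] = str(p)
        img = outdir / "safe_map.png"
        self.safe_map.save_image(img)
        paths["safe_map"] = str(img)
        csv = outdir / "measurement.csv"
        self.to_frame().to_csv(csv, index=False, float_format="%.6f")
        paths["measurement"] = str(csv)
        return paths

    def plot_map(self, ax=None):
        """Safe map with zone outline and screw circles (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.safe_map.frame
        extent = [f.v0, f.v0 + f.nv * f.spacing, f.u0, f.u0 + f.nu * f.spacing]
        img = np.where(self.safe_map.safe, 2.0, np.where(self.safe_map.count >= 1, 1.0, 0.0))
        ax.imshow(img, origin="lower", extent=extent, cmap="bone")
        ext = np.asarray(self.zone.polygon.exterior.coords)
        ax.plot(ext[:, 1], ext[:, 0], "y-", lw=1)
        for s, c in ((self.medial, "tab:red"), (self.lateral, "tab:blue")):
            th = np.linspace(0, 2 * np.pi, 100)
            ax.plot(s.center_uv[1] + s.diameter / 2 * np.sin(th),
                    s.center_uv[0] + s.diameter / 2 * np.cos(th), color=c,
                    label=f"{s.side} Ø{s.diameter:.1f}")
        ax.set_xlabel("v (mediolateral, mm)")
        ax.set_ylabel("u (superior, mm)")
        ax.legend(loc="upper right", fontsize=7)
        return ax


class SexComparison:
    """Male/female comparison model over a cohort measurement table."""

    def __init__(self, data: pd.DataFrame, method: str = "pooled"):
        self.data = pd.DataFrame(data)
        self.method = method

    @classmethod
    def from_measurements(cls, rows, **kwargs) -> "SexComparison":
        return cls(pd.DataFrame([r.as_dict() for r in rows]), **kwargs)

    def fit(self) -> "SexComparisonResults":
        tables = cohort_stats.build_tables(self.data, method=self.method)
        return SexComparisonResults(model=self, tables=tables)


_TABLE_TITLES = {
    "medial_screw": "Medial screw",
    "lateral_screw": "Lateral screw",
    "angles": "Screw angles",
}


@dataclass
class SexComparisonResults:
    model: SexComparison
    tables: dict

    def formatted(self) -> dict[str, pd.DataFrame]:
        return {k: cohort_stats.format_table(v) for k, v in self.tables.items() if v}

    def summary(self) -> str:
        parts = []
        for key, df in self.formatted().items():
            parts.append(f"{_TABLE_TITLES.get(key, key)} — males vs females "
                         f"({self.model.method} t test)")
            parts.append(df.to_string(index=False))
            parts.append("")
        return "\n".join(parts).rstrip()

    def save(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for key, df in self.formatted().items():
            p = outdir / f"table_{key}.csv"
            df.to_csv(p, index=False)
            paths[key] = str(p)
        return paths
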