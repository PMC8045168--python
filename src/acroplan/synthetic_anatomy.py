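"""Parametric acromion-like solids with known ground truth.

The study population (CT scans of real scapulae) is not redistributable, so
the pipeline is exercised on synthetic bones that reproduce the geometric
features the planning method depends on:

* a curved, rod-like distal acromion: a solid swept along a circular-arc
  centerline (plan view) with elliptical cross-sections, the medial side on
  the convex (longer) side of the arc;
* a flat superior strip (the "upper plane of the distal acromion" that
  defines plane A). The cross-section height grows proximally with the flat
  top held level, so the canal axis genuinely dips below plane A by a known
  angle (the downdip ground truth for alpha);
* the two landmark points (AC facet on the medial rim, distal anterior edge)
  and the superior vertex patch;
* smooth low-frequency surface noise (watertightness-safe, unlike white
  noise).

Every generator is deterministic given its seed, and each subject carries a
ground-truth record (canal axis chord, downdip angle, axial-view hint with
its built-in observer error, cross-section semi-axes) against which pipeline
recovery is tested.

Cohort defaults are constructed to land near the magnitudes of published
two-screw acromion morphometry (male medial screw length ~51 mm, diameter
~5.7 mm; female ~42 mm / ~3.7 mm); they are synthetic constructions, not
patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import AcroplanError, DegenerateInputError
from .measure import LandmarkSet

__all__ = [
    "AcromionParams",
    "CohortSpec",
    "Subject",
    "make_solid_cylinder",
    "make_elliptic_rod",
    "generate_acromion",
    "sample_cohort",
    "default_cohort_spec",
]


# ---------------------------------------------------------------------------
# swept-solid builder
# ---------------------------------------------------------------------------

def _sweep_solid(rings: np.ndarray) -> trimesh.Trimesh:
    """Watertight solid from (K, N, 3) section rings (consistent winding).

    Side walls join consecutive rings; the end caps are centroid fans, which
    is exact for star-shaped sections. Outward orientation is enforced by a
    signed-volume check.
    """
    K, N, _ = rings.shape
    verts = rings.reshape(-1, 3)
    faces = []
    for k in range(K - 1):
        base0, base1 = k * N, (k + 1) * N
        for i in range(N):
            j = (i + 1) % N
            faces.append([base0 + i, base1 + i, base0 + j])
            faces.append([base0 + j, base1 + i, base1 + j])
    c0 = len(verts)
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    for i in range(N):
        j = (i + 1) % N
        faces.append([c0, i, j])  # distal cap
        faces.append([c0 + 1, (K - 1) * N + j, (K - 1) * N + i])  # proximal cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise DegenerateInputError("swept solid is not watertight (section self-intersection?)")
    return mesh


def make_solid_cylinder(r: float, L: float, n_ring: int = 64, n_sections: int = 24):
    """Oracle shape: solid circular cylinder along +z, z in [0, L].

    Landmarks: anterior edge at (r, 0, 0), AC facet at (-r, 0, L/4), superior
    patch = vertices of the +y band.
    """
    if r <= 0 or L <= 0:
        raise AcroplanError("cylinder radius and length must be positive")
    psi = 2 * np.pi * np.arange(n_ring) / n_ring
    z = np.linspace(0.0, L, n_sections)
    rings = np.empty((n_sections, n_ring, 3))
    rings[:, :, 0] = r * np.cos(psi)[None, :]
    rings[:, :, 1] = r * np.sin(psi)[None, :]
    rings[:, :, 2] = z[:, None]
    mesh = _sweep_solid(rings)
    patch = np.nonzero(mesh.vertices[:, 1] > 0.85 * r)[0]
    lm = LandmarkSet(ac_facet=[-r, 0.0, L / 4.0], anterior_edge=[r, 0.0, 0.0],
                     superior_patch=patch)
    return mesh, lm


def make_elliptic_rod(a: float, b: float, L: float, n_ring: int = 64, n_sections: int = 24):
    """Oracle shape: elliptic cross-section (semi-axes a >= b) extruded along +z."""
    if not (a >= b > 0) or L <= 0:
        raise AcroplanError("elliptic rod needs a >= b > 0 and L > 0")
    psi = 2 * np.pi * np.arange(n_ring) / n_ring
    z = np.linspace(0.0, L, n_sections)
    rings = np.empty((n_sections, n_ring, 3))
    rings[:, :, 0] = a * np.cos(psi)[None, :]
    rings[:, :, 1] = b * np.sin(psi)[None, :]
    rings[:, :, 2] = z[:, None]
    mesh = _sweep_solid(rings)
    patch = np.nonzero(mesh.vertices[:, 1] > 0.85 * b)[0]
    lm = LandmarkSet(ac_facet=[-a, 0.0, L / 4.0], anterior_edge=[a, 0.0, 0.0],
                     superior_patch=patch)
    return mesh, lm


# ---------------------------------------------------------------------------
# acromion generator
# ---------------------------------------------------------------------------

@dataclass
class AcromionParams:
    """Shape parameters of one synthetic distal acromion (mm / degrees).

    The solid is swept along a plan-view circular arc of ``arc_angle_deg``
    (straight when 0) with total centerline length ``length``. Sections are
    ellipses with mediolateral semi-axis ``a(s)`` widening by ``taper``
    toward the proximal end and vertical semi-axis ``b(s)`` growing so the
    canal dips below the level superior strip by ``alpha_tilt_deg``. The top
    is flattened by ``flat_frac * b_distal`` to form the plane-A strip.
    """

    a_distal: float = 9.0  # mediolateral semi-axis at the distal tip
    b_distal: float = 2.9  # vertical (canal) semi-axis at the distal tip
    length: float = 50.0  # centerline arc length
    arc_angle_deg: float = 30.0
    taper: float = 0.35  # proximal widening fraction of a
    alpha_tilt_deg: float = 14.0  # downdip of the canal axis vs the superior strip
    flat_frac: float = 0.2
    facet_offset: float = 6.0  # AC facet arc-length from the distal tip
    noise_amp: float = 0.12  # mm, smooth surface bumps
    hint_downdip_err_deg: float = 0.0  # axial-view observer error, sagittal
    hint_medlat_err_deg: float = 0.0  # axial-view observer error, mediolateral
    seed: int = 0
    n_ring: int = 48
    n_sections: int = 30

    def validate(self) -> None:
        if not (0.0 <= self.arc_angle_deg <= 90.0):
            raise AcroplanError("arc angle must lie in [0, 90] degrees")
        if min(self.a_distal, self.b_distal) <= 1.0:
            raise AcroplanError("cross-section semi-axes must exceed 1 mm")
        if self.noise_amp >= min(self.a_distal, self.b_distal) / 5.0:
            raise AcroplanError("surface noise must stay below min semi-axis / 5")
        if self.length <= 0:
            raise AcroplanError("length must be positive")
        if self.arc_angle_deg > 1e-6:
            R = self.length / np.deg2rad(self.arc_angle_deg)
            if self.a_distal * (1 + self.taper) >= 0.8 * R:
                raise AcroplanError("arc too tight: sweep would self-intersect")


@dataclass
class Subject:
    subject_id: str
    sex: str
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    truth: dict
    params: AcromionParams


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def generate_acromion(params: AcromionParams) -> Subject:
    """Build one synthetic subject with ground truth.

    Frame: +x medial, +y anterior-to-posterior (sweep direction), +z
    superior. The distal (anterior) face is at s = 0; screws enter there.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = params
    L = p.length
    phi = np.deg2rad(p.arc_angle_deg)
    tan_tilt = np.tan(np.deg2rad(p.alpha_tilt_deg))
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)

    # ring stations, densified near the tip so the flat crest (which only
    # spans ~flat_depth/tan(tilt) of arc length) carries enough vertices;
    # the crest must cover at least three ring rows or the plane-A patch
    # would be collinear, hence the tilt-adaptive floor on its depth
    n_tip = max(p.n_sections // 3, 8)
    tip_len = 0.12 * L
    s = np.concatenate([
        np.linspace(0.0, tip_len, n_tip, endpoint=False),
        np.linspace(tip_len, L, p.n_sections - n_tip),
    ])
    flat_depth = max(p.flat_frac * p.b_distal, 5.0 * tan_tilt * tip_len / n_tip)
    a_s = p.a_distal * (1.0 + p.taper * s / L)
    # the canal (section centers) dips linearly below the level superior
    # crest, so the straight screw corridor makes the downdip angle with
    # plane A; sections inflate only mildly, keeping the bone a narrow
    # dipping tube (a deepening wedge would admit diagonal paths longer
    # than the canal itself)
    h_s = p.b_distal * (1.0 + 0.15 * s / L)  # vertical semi-axis
    z_c = -p.b_distal - tan_tilt * s  # canal center height
    if phi > 1e-6:
        R = L / phi
        th = s / R
        cx = R * np.cos(th) - R  # bends toward -x (lateral); medial +x is convex
        cy = R * np.sin(th)
        hx, hy = np.cos(th), np.sin(th)  # horizontal normal, +x-ish (medial)
    else:
        cx, cy = np.zeros_like(s), s
        hx, hy = np.ones_like(s), np.zeros_like(s)

    psi = 2 * np.pi * np.arange(p.n_ring) / p.n_ring
    noise = 1.0 + (p.noise_amp / max(p.b_distal, 1e-6)) * (
        np.sin(3 * psi + phase1)[None, :] * np.cos(4 * np.pi * s / L + phase2)[:, None])
    ex = a_s[:, None] * np.cos(psi)[None, :] * noise  # along H
    ez = h_s[:, None] * np.sin(psi)[None, :] * noise  # along z, centered at z_c(s)

    rings = np.empty((p.n_sections, p.n_ring, 3))
    rings[:, :, 0] = cx[:, None] + hx[:, None] * ex
    rings[:, :, 1] = cy[:, None] + hy[:, None] * ex
    rings[:, :, 2] = z_c[:, None] + ez
    rings[:, :, 2] = np.minimum(rings[:, :, 2], -flat_depth)  # superior flat crest

    # slant the two end faces about the canal center (square-cornered caps
    # would admit corner-to-corner diagonals longer than the canal); the
    # slant fades smoothly over the end segments so the surface cannot fold
    # back over the neighbouring rings
    shear_prof = (0.4 * np.clip(1.0 - s / (0.15 * L), 0.0, None)
                  + 0.6 * np.clip(1.0 - (L - s) / (0.15 * L), 0.0, None))
    for k in np.nonzero(shear_prof > 1e-9)[0]:
        tx, ty = (-hy[k], hx[k])  # plan tangent
        dz = rings[k, :, 2] - z_c[k]
        rings[k, :, 0] += shear_prof[k] * dz * tx
        rings[k, :, 1] += shear_prof[k] * dz * ty

    mesh = _sweep_solid(rings)

    # landmarks -------------------------------------------------------------
    k_f = int(np.argmin(np.abs(s - p.facet_offset)))
    facet = np.array([cx[k_f] + hx[k_f] * a_s[k_f] * noise[k_f, 0],
                      cy[k_f] + hy[k_f] * a_s[k_f] * noise[k_f, 0],
                      z_c[k_f]])
    # top edge of the (slanted) distal face, centre of the crest strip
    dz_edge = -flat_depth - z_c[0]
    anterior_edge = np.array([cx[0] - 0.4 * dz_edge * hy[0],
                              cy[0] + 0.4 * dz_edge * hx[0], -flat_depth])
    on_flat = np.abs(mesh.vertices[:, 2] + flat_depth) < 1e-6
    distal_half = mesh.vertices[:, 1] < cy[p.n_sections // 2]
    patch = np.nonzero(on_flat & distal_half)[0]
    if len(patch) < 30:
        patch = np.nonzero(on_flat)[0]
    landmarks = LandmarkSet(ac_facet=facet, anterior_edge=anterior_edge,
                            superior_patch=patch)

    # ground truth ----------------------------------------------------------
    start = np.array([cx[0], cy[0], z_c[0]])
    end = np.array([cx[-1], cy[-1], z_c[-1]])
    chord = end - start
    chord_len = float(np.linalg.norm(chord))
    chord_dir = chord / chord_len
    hint = _rot_z(p.hint_medlat_err_deg) @ (_rot_x(p.hint_downdip_err_deg) @ chord_dir)
    # realized downdip of the canal chord below the level superior strip
    alpha_true = float(np.degrees(np.arcsin(abs(chord_dir[2]))))
    truth = {
        "chord_dir": chord_dir.tolist(),
        "chord_length": chord_len,
        "alpha_true_deg": alpha_true,
        "hint_dir": hint.tolist(),
        "medlat_err_deg": float(p.hint_medlat_err_deg),
        "a_distal": p.a_distal,
        "b_distal": p.b_distal,
        "arc_angle_deg": p.arc_angle_deg,
        "length": p.length,
    }
    return Subject(subject_id=f"synth-{p.seed}", sex="U", mesh=mesh,
                   landmarks=landmarks, truth=truth, params=p)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Sex-stratified parameter distributions (normal, truncated at 3 SD)."""

    n_male: int = 50
    n_female: int = 50
    seed: int = 0
    male: dict = field(default_factory=dict)
    female: dict = field(default_factory=dict)
    hint_err_sd_deg: float = 4.0  # axial-view alignment scatter, both axes

    def __post_init__(self):
        if self.n_male < 1 or self.n_female < 1:
            raise AcroplanError("each sex group needs at least one subject")
        base_m = {"b_distal": (2.9, 0.4), "length": (51.0, 4.0),
                  "a_distal": (9.5, 0.9), "arc_angle_deg": (30.0, 8.0),
                  "alpha_tilt_deg": (14.0, 5.0)}
        base_f = {"b_distal": (2.0, 0.3), "length": (42.0, 4.0),
                  "a_distal": (8.0, 0.8), "arc_angle_deg": (30.0, 8.0),
                  "alpha_tilt_deg": (14.0, 5.0)}
        self.male = {**base_m, **self.male}
        self.female = {**base_f, **self.female}


def default_cohort_spec(n_male: int = 50, n_female: int = 50, seed: int = 0) -> CohortSpec:
    return CohortSpec(n_male=n_male, n_female=n_female, seed=seed)


_HARD_BOUNDS = {
    "b_distal": (1.2, 6.0),
    "a_distal": (4.0, 14.0),
    "length": (20.0, 75.0),
    "arc_angle_deg": (0.0, 60.0),
    "alpha_tilt_deg": (2.0, 28.0),
}


def _draw(rng: np.random.Generator, mean: float, sd: float, key: str) -> float:
    x = float(rng.normal(mean, sd))
    x = min(max(x, mean - 3 * sd), mean + 3 * sd)
    lo, hi = _HARD_BOUNDS[key]
    return min(max(x, lo), hi)


def sample_cohort(spec: CohortSpec) -> list[Subject]:
    """Reproducible synthetic cohort; each subject is a valid watertight solid."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for sex, n, dists in (("M", spec.n_male, spec.male), ("F", spec.n_female, spec.female)):
        for i in range(n):
            draws = {k: _draw(rng, *v, k) for k, v in dists.items()}
            params = AcromionParams(
                **draws,
                hint_downdip_err_deg=float(np.clip(rng.normal(0, spec.hint_err_sd_deg), -10, 10)),
                hint_medlat_err_deg=float(np.clip(rng.normal(0, spec.hint_err_sd_deg), -10, 10)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            subj = generate_acromion(params)
            subj = replace(subj, subject_id=f"{sex}{i:03d}", sex=sex)
            subjects.append(subj)
    return subjects
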