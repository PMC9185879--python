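"""Synthetic single-rooted premolar generator and scalar cohort simulator.

Coordinate convention (shared by every module): tooth axis = z with the apex
at ``z = -root_length`` and the CEJ plane at ``z = 0``; buccolingual = y,
mesiodistal = x; all lengths in mm.

The root is a surface of revolution with an elliptical cross-section whose
half-axes shrink with depth ``d`` below the CEJ as ``(1 - d/L)**p``:

* ``p = 0.5`` gives a convex, cervically parallel-walled profile used for the
  *normal* taper class;
* ``p = 1.0`` gives a straight-sided cone used for the *conical* class.

With equal cervical dimensions the conical profile is pointwise narrower at
every depth, so its lateral area and volume are strictly smaller — the same
qualitative contrast the two diagnostic classes exhibit.

Closed-form ground truth: the root volume is
``pi * a * b * L / (2 p + 1)``; the lateral area has no elementary closed
form for elliptical sections and is provided by adaptive quadrature of the
parametric surface integral (independent of the meshing path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .meshes import TriangleMesh
from .morphometry import Plane, ToothMesh

__all__ = [
    "ToothProfile",
    "PopulationSpec",
    "TABLE_PARAMS",
    "generate_tooth",
    "generate_cohort",
    "project_to_radiograph",
    "root_lateral_area_quadrature",
    "root_volume_exact",
]

#: Published group means and SDs (mm / mm² / mm³ as appropriate) used as the
#: default scalar-population parameters: {param: {group: (mean, sd)}}.
TABLE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "RL": {"NRT": (11.62, 1.19), "CRT": (11.65, 1.54)},
    "PRW": {"NRT": (0.48, 0.12), "CRT": (0.33, 0.16)},
    "RSA": {"NRT": (236.88, 27.93), "CRT": (207.98, 27.80)},
    "RV": {"NRT": (316.93, 49.89), "CRT": (253.40, 41.98)},
    "RSA_RL": {"NRT": (20.42, 1.86), "CRT": (17.88, 1.31)},
    "RV_RL": {"NRT": (27.34, 3.87), "CRT": (21.76, 2.43)},
}

PARAM_NAMES = tuple(TABLE_PARAMS.keys())

TAPER_EXPONENTS = {"normal": 0.5, "conical": 1.0}


@dataclass(frozen=True)
class ToothProfile:
    """Parametric description of one synthetic tooth."""

    root_length: float = 12.0
    cervical_halfwidth_md: float = 3.5  # mesiodistal (x) half-axis at the CEJ
    cervical_halfwidth_bl: float = 4.0  # buccolingual (y) half-axis at the CEJ
    taper_class: str = "normal"
    taper_exponent: float | None = None  # defaults by class
    crown_height: float = 7.0
    apex_rounding: float = 0.3  # spherical-cap-style tip blend, mm
    mesh_resolution: tuple[int, int] = (64, 64)  # (n_axial, n_circumferential)
    seed: int = 0

    def __post_init__(self):
        if self.root_length <= 0:
            raise ValueError("root_length must be positive")
        if self.cervical_halfwidth_md <= 0 or self.cervical_halfwidth_bl <= 0:
            raise ValueError("cervical halfwidths must be positive")
        if self.taper_class not in TAPER_EXPONENTS:
            raise ValueError(f"unknown taper_class {self.taper_class!r}")
        if self.mesh_resolution[0] < 8 or self.mesh_resolution[1] < 8:
            raise ValueError("mesh_resolution must be at least (8, 8)")
        if self.crown_height < 0:
            raise ValueError("crown_height must be non-negative")
        if not 0 <= self.apex_rounding < self.root_length:
            raise ValueError("apex_rounding must lie in [0, root_length)")

    @property
    def exponent(self) -> float:
        if self.taper_exponent is not None:
            return float(self.taper_exponent)
        return TAPER_EXPONENTS[self.taper_class]

    def radial_scale(self, depth) -> np.ndarray:
        """Cross-section scale factor at depth ``d`` below the CEJ, in [0, 1]."""
        d = np.asarray(depth, dtype=np.float64)
        return np.clip(1.0 - d / self.root_length, 0.0, 1.0) ** self.exponent


def root_volume_exact(profile: ToothProfile) -> float:
    """pi·a·b·L / (2p + 1): exact volume of the un-rounded root of revolution."""
    p = profile.exponent
    return (
        math.pi
        * profile.cervical_halfwidth_md
        * profile.cervical_halfwidth_bl
        * profile.root_length
        / (2.0 * p + 1.0)
    )


def root_lateral_area_quadrature(profile: ToothProfile) -> float:
    """Lateral area of the root surface by adaptive quadrature.

    Parametrise ``P(d, t) = (a s(d) cos t, b s(d) sin t, -d)`` and integrate
    ``|P_d x P_t|`` over ``d in [0, L], t in [0, 2 pi)``.  Serves as the
    mesh-independent oracle for generated meshes.
    """
    a = profile.cervical_halfwidth_md
    b = profile.cervical_halfwidth_bl
    L = profile.root_length
    p = profile.exponent

    def ring_integrand(d: float) -> float:
        s = (1.0 - d / L) ** p
        ds = -p / L * (1.0 - d / L) ** (p - 1.0) if d < L else 0.0

        def f(t: float) -> float:
            ct, st = math.cos(t), math.sin(t)
            # |P_d x P_t| for the elliptical surface of revolution
            gx = b * s * ct
            gy = a * s * st
            gz = a * b * s * ds
            return math.sqrt(gx * gx + gy * gy + gz * gz)

        val, _ = integrate.quad(f, 0.0, 2.0 * math.pi, limit=200)
        return val

    val, _ = integrate.quad(ring_integrand, 0.0, L, limit=400, points=[L])
    return float(val)


def _crown_scale(h: float, crown_height: float) -> float:
    """Mild cervical bulge, shrinking towards the crown tip; 1.0 at the CEJ."""
    u = float(h) / max(crown_height, 1e-12)
    u = min(max(u, 0.0), 1.0)
    return (1.0 + 0.25 * math.sin(math.pi * u**0.8)) * math.sqrt(max(1.0 - u**2, 0.0))


def generate_tooth(profile: ToothProfile) -> ToothMesh:
    """Build a watertight tooth mesh with landmarks and ground-truth metrics.

    The returned :class:`~rootmorph.morphometry.ToothMesh` carries the exact
    CEJ plane (z = 0), the six landmarks, and ``ground_truth`` entries for
    ``RL`` plus quadrature-based ``root_lateral_area`` and exact
    ``root_volume`` of the ideal (un-rounded) profile.
    """
    n_ax, n_circ = profile.mesh_resolution
    L = profile.root_length
    a = profile.cervical_halfwidth_md
    b = profile.cervical_halfwidth_bl

    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)

    rows: list[np.ndarray] = []  # each row: (n_circ, 3) ring of vertices

    # crown rings, top to CEJ (skip the degenerate tip ring; fan it later)
    crown_tip = None
    if profile.crown_height > 0:
        hs = np.linspace(profile.crown_height, 0.0, max(n_ax // 3, 4), endpoint=False)
        crown_tip = np.array([0.0, 0.0, profile.crown_height])
        for h in hs:
            s = max(_crown_scale(h, profile.crown_height), 1e-3)
            rows.append(np.column_stack([a * s * ct, b * s * st, np.full(n_circ, h)]))

    # root rings, CEJ down to the rounding start
    d_tip = L - profile.apex_rounding
    depths = np.linspace(0.0, d_tip, n_ax, endpoint=(profile.apex_rounding > 0))
    for d in depths:
        s = float(profile.radial_scale(d))
        rows.append(np.column_stack([a * s * ct, b * s * st, np.full(n_circ, -d)]))

    # blended tip rings: ellipsoidal cap shrinking onto the apex point
    if profile.apex_rounding > 0:
        s_base = float(profile.radial_scale(d_tip))
        n_cap = max(4, n_ax // 8)
        phi = np.linspace(0.0, np.pi / 2.0, n_cap + 1)[1:-1]
        for ph in phi:
            s = s_base * math.cos(ph)
            z = -(d_tip + profile.apex_rounding * math.sin(ph))
            rows.append(np.column_stack([a * s * ct, b * s * st, np.full(n_circ, z)]))
    apex = np.array([0.0, 0.0, -L])

    verts = [np.concatenate(rows, axis=0)]
    faces: list[list[int]] = []
    n_rows = len(rows)

    def vid(row: int, col: int) -> int:
        return row * n_circ + (col % n_circ)

    for r in range(n_rows - 1):
        for c in range(n_circ):
            # outward winding: x cross-section CCW seen from +z, rows descend in z
            faces.append([vid(r, c), vid(r, c + 1), vid(r + 1, c)])
            faces.append([vid(r + 1, c), vid(r, c + 1), vid(r + 1, c + 1)])

    next_idx = n_rows * n_circ
    apex_idx = next_idx
    verts.append(apex[None, :])
    next_idx += 1
    for c in range(n_circ):
        faces.append([vid(n_rows - 1, c), vid(n_rows - 1, c + 1), apex_idx])

    if crown_tip is not None:
        tip_idx = next_idx
        verts.append(crown_tip[None, :])
        for c in range(n_circ):
            faces.append([vid(0, c + 1), vid(0, c), tip_idx])
    else:
        # flat cap over the CEJ ring
        top_idx = next_idx
        verts.append(np.array([[0.0, 0.0, 0.0]]))
        for c in range(n_circ):
            faces.append([vid(0, c + 1), vid(0, c), top_idx])

    mesh = TriangleMesh(np.concatenate(verts, axis=0), np.asarray(faces))
    if not mesh.is_watertight():
        raise RuntimeError("internal failure: generated mesh is not watertight")
    if mesh.signed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])

    landmarks = {
        "apex": apex,
        "cej_buccal": np.array([0.0, b, 0.0]),
        "cej_lingual": np.array([0.0, -b, 0.0]),
        "cej_mesial": np.array([a, 0.0, 0.0]),
        "cej_distal": np.array([-a, 0.0, 0.0]),
    }
    if crown_tip is not None:
        landmarks["crown_tip"] = crown_tip

    ground_truth = {
        "RL": L,
        "root_lateral_area": root_lateral_area_quadrature(profile),
        "root_volume": root_volume_exact(profile),
    }
    return ToothMesh(
        mesh,
        landmarks,
        cej_plane=Plane([0.0, 0.0, 0.0], [0.0, 0.0, 1.0]),
        ground_truth=ground_truth,
    )


# -- scalar cohorts ------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Normal-distribution parameters per metric and group for cohort draws."""

    params: dict = field(
        default_factory=lambda: {
            p: {g: TABLE_PARAMS[p][g] for g in ("NRT", "CRT")} for p in PARAM_NAMES
        }
    )
    n_nrt: int = 54
    n_crt: int = 41
    seed: int = 0

    def __post_init__(self):
        if self.n_nrt <= 1 or self.n_crt <= 1:
            raise ValueError("group sizes must exceed 1")
        for p, groups in self.params.items():
            for g, (_, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {p}/{g}")


def generate_cohort(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a labelled cohort table; independent normals per parameter.

    Columns: ``tooth_id, group`` plus one column per metric. Deterministic
    for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    offset = 0
    for group, n in (("NRT", spec.n_nrt), ("CRT", spec.n_crt)):
        data = {"tooth_id": [f"T{offset + i + 1:04d}" for i in range(n)], "group": group}
        for p in spec.params:
            mean, sd = spec.params[p][group]
            data[p] = rng.normal(mean, sd, size=n)
        frames.append(pd.DataFrame(data))
        offset += n
    return pd.concat(frames, ignore_index=True)


# -- 2D projection -------------------------------------------------------------


def project_to_radiograph(
    tooth: ToothMesh, direction=(0.0, 1.0, 0.0)
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Orthographic silhouette of the tooth seen along ``direction``.

    Default direction is buccolingual (+y), emulating a periapical view: the
    image plane is spanned by the mesiodistal axis (x) and the tooth axis (z).
    Returns ``(polygon, landmarks_2d)`` where the polygon is a closed
    (first != last, implicitly closed) CCW vertex loop in mm and the 2D
    landmarks are ``G`` (apex), ``F`` (mesial CEJ) and ``E`` (distal CEJ).
    """
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    direction = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("projection direction must be non-zero")
    w = direction / norm

    # build image-plane basis (u, v): v is the tooth axis when possible
    v_axis = np.array([0.0, 0.0, 1.0])
    if abs(w @ v_axis) > 0.99:
        raise ValueError("projection direction may not be (anti)parallel to the tooth axis")
    u_axis = np.cross(v_axis, w)
    un = np.linalg.norm(u_axis)
    u_axis /= un
    v_axis = np.cross(w, u_axis)
    if abs(u_axis @ np.array([1.0, 0.0, 0.0])) < 1e-9:
        raise ValueError("direction is parallel to the mesiodistal axis; silhouette degenerate")

    def to2d(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.column_stack([pts @ u_axis, pts @ v_axis])

    tris2d = to2d(tooth.mesh.vertices)[tooth.mesh.faces]
    polys = []
    for t in tris2d:
        e1, e2 = t[1] - t[0], t[2] - t[0]
        if abs(e1[0] * e2[1] - e1[1] * e2[0]) < 1e-12:
            continue
        polys.append(Polygon(t))
    if not polys:
        raise ValueError("empty silhouette")
    union = unary_union(polys)
    if union.is_empty:
        raise ValueError("empty silhouette")
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    union = union.buffer(0)
    boundary = np.asarray(union.exterior.coords)[:-1]

    landmarks_2d = {
        "G": to2d(tooth.landmark("apex"))[0],
        "F": to2d(tooth.landmark("cej_mesial"))[0],
        "E": to2d(tooth.landmark("cej_distal"))[0],
    }
    return boundary, landmarks_2d
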