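"""3D root morphometry from landmark-annotated closed tooth meshes.

The measurement chain mirrors a crown/root segmentation workflow on a
reconstructed tooth surface:

* the cemento-enamel junction (CEJ) plane is fitted through four CEJ
  landmarks (buccal, lingual, mesial, distal);
* the closed tooth mesh is split by that plane into a capped crown object and
  a capped root object, tracking the shared truncation-cap area ``S_S1``;
* root length ``RL`` is the distance from the apex landmark to the midpoint
  of the buccal–lingual CEJ chord;
* root surface area is recovered from the three closed-object areas as
  ``RSA = (S_MT + S_MR - S_MC) / 2``, which algebraically removes the cap;
* root volume ``RV`` is the enclosed volume of the root object, and the
  scale-normalised indices are ``RSA/RL`` and ``RV/RL``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .meshes import MeshError, NotWatertightError, TriangleMesh, read_stl

__all__ = [
    "Plane",
    "ToothMesh",
    "RootMetrics",
    "surface_area",
    "enclosed_volume",
    "split_by_plane",
    "root_surface_area",
    "root_length",
    "fit_cej_plane",
    "compute_metrics",
    "load_tooth",
]

CEJ_LANDMARKS = ("cej_buccal", "cej_lingual", "cej_mesial", "cej_distal")

_ON_PLANE_TOL = 1e-9


@dataclass(frozen=True)
class Plane:
    """Plane given as a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64))
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class ToothMesh:
    """Closed tooth surface with named anatomical landmarks (units: mm).

    Required landmarks: ``apex``, ``cej_buccal``, ``cej_lingual``,
    ``cej_mesial``, ``cej_distal``; ``crown_tip`` is optional.
    """

    mesh: TriangleMesh
    landmarks: dict[str, np.ndarray]
    cej_plane: Plane | None = None
    ground_truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.landmarks = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.landmarks.items()
        }

    def landmark(self, name: str) -> np.ndarray:
        if name not in self.landmarks:
            raise KeyError(f"missing landmark: {name!r}")
        return self.landmarks[name]

    def transformed(self, rotation, translation) -> "ToothMesh":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        lm = {k: R @ v + t for k, v in self.landmarks.items()}
        plane = None
        if self.cej_plane is not None:
            plane = Plane(R @ self.cej_plane.point + t, R @ self.cej_plane.normal)
        return ToothMesh(self.mesh.transformed(R, t), lm, plane, dict(self.ground_truth))


@dataclass
class RootMetrics:
    """Per-tooth scalar morphometry record."""

    RL: float
    RSA: float
    RV: float
    RSA_over_RL: float
    RV_over_RL: float
    PRW: float | None = None
    label: str = "unknown"

    def as_dict(self) -> dict:
        d = {
            "RL": self.RL,
            "PRW": self.PRW,
            "RSA": self.RSA,
            "RV": self.RV,
            "RSA_RL": self.RSA_over_RL,
            "RV_RL": self.RV_over_RL,
            "label": self.label,
        }
        return d


def surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area in mm²; accepts open triangle soups."""
    return mesh.area()


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in mm³ (divergence theorem); requires a closed mesh."""
    return mesh.volume()


def root_surface_area(s_mt: float, s_mr: float, s_mc: float) -> float:
    """RSA = (S_MT + S_MR - S_MC) / 2 from the three closed-object areas."""
    if min(s_mt, s_mr, s_mc) < 0:
        raise ValueError("surface areas must be non-negative")
    rsa = (s_mt + s_mr - s_mc) / 2.0
    if rsa < -1e-9 * max(s_mt, 1.0):
        raise ValueError(
            f"inconsistent areas: RSA = ({s_mt} + {s_mr} - {s_mc})/2 < 0"
        )
    return rsa


def root_length(tooth: ToothMesh) -> float:
    """Distance from the apex to the midpoint of the buccal-lingual CEJ chord."""
    apex = tooth.landmark("apex")
    mid = 0.5 * (tooth.landmark("cej_buccal") + tooth.landmark("cej_lingual"))
    return float(np.linalg.norm(apex - mid))


def fit_cej_plane(tooth: ToothMesh) -> Plane:
    """Least-squares plane through the four CEJ landmarks, normal away from apex."""
    pts = np.stack([tooth.landmark(n) for n in CEJ_LANDMARKS])
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-12:
        raise ValueError("CEJ landmarks are collinear; plane is undetermined")
    normal = vt[2]
    plane = Plane(centroid, normal)
    if plane.signed_distance(tooth.landmark("apex"))[0] > 0:
        plane = Plane(centroid, -normal)
    return plane


# -- plane splitting -----------------------------------------------------------


def _safe_plane(mesh: TriangleMesh, plane: Plane) -> Plane:
    """Nudge the plane so no vertex sits exactly on it (robust classification)."""
    for _ in range(8):
        d = plane.signed_distance(mesh.vertices)
        near = np.abs(d) < _ON_PLANE_TOL
        if not near.any():
            return plane
        nonzero = np.abs(d[~near]) if (~near).any() else np.array([1.0])
        shift = min(float(nonzero.min()) / 2.0, 1e-7) + _ON_PLANE_TOL
        plane = Plane(plane.point + shift * plane.normal, plane.normal)
    raise MeshError("could not find a vertex-free cutting plane near the request")


def _chain_loops(segments: list[tuple]) -> list[list]:
    """Chain intersection segments (keyed by mesh edge) into closed loops."""
    adj: dict = {}
    for a, b in segments:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for key, nbrs in adj.items():
        if len(nbrs) != 2:
            raise MeshError(
                "plane intersection is not a set of simple closed curves"
            )
    loops = []
    visited = set()
    for start in adj:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxt = [n for n in adj[cur] if n != prev]
            if not nxt:
                raise MeshError("open intersection curve")
            prev, cur = cur, nxt[0]
            if cur == start:
                break
            if cur in visited:
                raise MeshError("self-intersecting cut curve")
            visited.add(cur)
            loop.append(cur)
        loops.append(loop)
    return loops


def split_by_plane(
    mesh: TriangleMesh, plane: Plane
) -> tuple[TriangleMesh, TriangleMesh, float]:
    """Split a closed mesh by a plane into two capped closed meshes.

    Returns ``(above, below, cap_area)`` where *above* collects the material on
    the positive-normal side. Each piece receives a planar cap (triangle fan
    from the cut-curve centroid) over every intersection loop; ``cap_area`` is
    the area of one copy of the caps (the truncation area ``S_S1``).

    The conservation identities
    ``area(above) + area(below) == area(mesh) + 2 * cap_area`` and
    ``volume(above) + volume(below) == volume(mesh)`` hold by construction.
    """
    n_open = mesh.count_open_edges()
    if n_open:
        raise NotWatertightError(n_open)
    plane = _safe_plane(mesh, plane)
    d = plane.signed_distance(mesh.vertices)
    side = d > 0

    face_side = side[mesh.faces]
    n_pos = face_side.sum(axis=1)
    if n_pos.max() == 0 or n_pos.min() == 3:
        raise MeshError("plane does not intersect the mesh")

    verts = list(mesh.vertices)
    cut_point_idx: dict[tuple[int, int], int] = {}

    def cut_index(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key not in cut_point_idx:
            t = d[i] / (d[i] - d[j])
            p = mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i])
            cut_point_idx[key] = len(verts)
            verts.append(p)
        return cut_point_idx[key]

    faces_above: list[list[int]] = []
    faces_below: list[list[int]] = []
    segments: list[tuple[int, int]] = []

    for f, np_pos in zip(mesh.faces, n_pos):
        if np_pos == 3:
            faces_above.append(list(f))
            continue
        if np_pos == 0:
            faces_below.append(list(f))
            continue
        # rotate so that the lone vertex (on the minority side) is first
        lone_positive = np_pos == 1
        for k in range(3):
            if side[f[k]] == lone_positive:
                a, b, c = f[k], f[(k + 1) % 3], f[(k + 2) % 3]
                break
        pab = cut_index(a, b)
        pca = cut_index(c, a)
        tri_lone = [a, pab, pca]
        quad = [[pab, b, c], [pab, c, pca]]
        if lone_positive:
            faces_above.append(tri_lone)
            faces_below.extend(quad)
            segments.append((pab, pca))  # oriented: above-side keeps (pab->pca)
        else:
            faces_below.append(tri_lone)
            faces_above.extend(quad)
            segments.append((pca, pab))

    loops = _chain_loops(segments)

    # in-plane basis for orienting loops counter-clockwise seen from +normal
    n = plane.normal
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    cap_area = 0.0
    for loop in loops:
        pts = np.asarray([verts[i] for i in loop])
        x, y = pts @ u, pts @ v
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        signed2 = float((x * yn - xn * y).sum())
        if signed2 < 0:
            loop = loop[::-1]
            pts = pts[::-1]
        centroid = pts.mean(axis=0)
        ci = len(verts)
        verts.append(centroid)
        for i in range(len(loop)):
            a_i, b_i = loop[i], loop[(i + 1) % len(loop)]
            pa, pb = verts[a_i], verts[b_i]
            cap_area += 0.5 * np.linalg.norm(np.cross(pa - centroid, pb - centroid))
            # CCW loop seen from +n: (ci, a, b) faces +n -> outward for below
            faces_below.append([ci, a_i, b_i])
            faces_above.append([ci, b_i, a_i])

    verts_arr = np.asarray(verts)
    above = TriangleMesh(verts_arr, np.asarray(faces_above)).merged(tol=1e-12)
    below = TriangleMesh(verts_arr, np.asarray(faces_below)).merged(tol=1e-12)
    return above, below, float(cap_area)


# -- full pipeline -------------------------------------------------------------


def compute_metrics(
    tooth: ToothMesh, prw: float | None = None, label: str = "unknown"
) -> RootMetrics:
    """Run the full split-and-measure pipeline on one annotated tooth."""
    plane = tooth.cej_plane if tooth.cej_plane is not None else fit_cej_plane(tooth)
    rl = root_length(tooth)
    if rl <= _ON_PLANE_TOL:
        raise ValueError("root length is zero: apex coincides with the CEJ midpoint")

    crown, root, s_s1 = split_by_plane(tooth.mesh, plane)
    if plane.signed_distance(tooth.landmark("apex"))[0] > 0:
        crown, root = root, crown

    s_mt = surface_area(tooth.mesh)
    s_mr = surface_area(root)
    s_mc = surface_area(crown)
    rsa = root_surface_area(s_mt, s_mr, s_mc)
    rv = enclosed_volume(root)

    return RootMetrics(
        RL=rl,
        RSA=rsa,
        RV=rv,
        RSA_over_RL=rsa / rl,
        RV_over_RL=rv / rl,
        PRW=prw,
        label=label,
    )


def load_tooth(stl_path, landmarks_json_path) -> ToothMesh:
    """Load an STL mesh plus its JSON landmark sidecar ({name: [x, y, z]})."""
    mesh = read_stl(stl_path)
    if not mesh.is_watertight():
        mesh = mesh.merged(tol=1e-6)
        n_open = mesh.count_open_edges()
        if n_open:
            raise NotWatertightError(n_open)
    with open(landmarks_json_path) as fh:
        raw = json.load(fh)
    landmarks = {k: np.asarray(v, dtype=np.float64) for k, v in raw.items()}
    missing = [n for n in ("apex", *CEJ_LANDMARKS) if n not in landmarks]
    if missing:
        raise KeyError(f"missing landmark(s) in sidecar: {missing}")
    return ToothMesh(mesh, landmarks)


def format_metrics(m: RootMetrics, decimals: int = 2) -> dict:
    """Rounded view for reports (internal values stay at full precision)."""
    out = {}
    for k, v in m.as_dict().items():
        out[k] = round(v, decimals) if isinstance(v, (int, float)) and v is not None else v
    return out
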