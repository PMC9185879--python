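"""Shape atlas: rigid landmark registration, mean models and signed
surface-distance colour maps.

Registration is landmark-based orthogonal Procrustes (no scaling, reflection
excluded); an optional dense ICP refinement, initialised by the landmark fit,
is available behind a flag.  Mean models average, per template vertex, the
closest surface points on every aligned mesh.  Distance maps are signed along
the reference's angle-weighted vertex pseudo-normals and rendered on a
blue-green-red ramp clamped at +-1.145 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshes import MeshError, TriangleMesh, closest_points
from .morphometry import ToothMesh

__all__ = [
    "RigidTransform",
    "ColourMap",
    "DEFAULT_BOUND_MM",
    "rigid_align",
    "icp_refine",
    "mean_model",
    "distance_colour_map",
]

DEFAULT_BOUND_MM = 1.145  # display clamp for the signed-distance colour scale


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not allowed")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def rigid_align(moving_landmarks, fixed_landmarks) -> RigidTransform:
    """Least-squares rigid transform taking moving landmarks onto fixed ones.

    Orthogonal Procrustes (Kabsch) without scaling; a reflection in the SVD
    solution is corrected by flipping the smallest singular direction.
    Requires at least three non-collinear correspondences.
    """
    P = np.atleast_2d(np.asarray(moving_landmarks, dtype=np.float64))
    Q = np.atleast_2d(np.asarray(fixed_landmarks, dtype=np.float64))
    if P.shape != Q.shape or P.shape[0] < 3 or P.shape[1] != 3:
        raise ValueError("need >= 3 corresponding 3D landmark pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("landmarks are collinear; rotation is undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t)


def icp_refine(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    init: RigidTransform | None = None,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
) -> RigidTransform:
    """Point-to-closest-point ICP initialised from ``init`` (usually the
    landmark fit); iterates until the RMS update falls below ``tolerance`` mm."""
    current = init if init is not None else RigidTransform.identity()
    pts = moving.vertices
    prev_rms = None
    for _ in range(max_iterations):
        moved = current.apply(pts)
        targets = closest_points(fixed, moved)
        step = rigid_align(moved, targets)
        current = step.compose(current)
        rms = float(np.sqrt(((step.apply(moved) - moved) ** 2).sum(axis=1).mean()))
        if prev_rms is not None and abs(prev_rms - rms) < tolerance:
            break
        if rms < tolerance:
            break
        prev_rms = rms
    return current


def mean_model(aligned: list[TriangleMesh], template_index: int = 0) -> TriangleMesh:
    """Average shape over already-aligned meshes.

    Each template vertex moves to the mean of its closest surface points on
    every input mesh (the template itself contributes its own vertex), so the
    result keeps the template's connectivity.  Permutation-invariant and
    idempotent on identical inputs.
    """
    if len(aligned) < 2:
        raise ValueError("mean model needs at least 2 meshes")
    template = aligned[template_index]
    acc = np.zeros_like(template.vertices)
    for mesh in aligned:
        if mesh is template:
            acc += template.vertices
        else:
            acc += closest_points(mesh, template.vertices)
    return TriangleMesh(acc / len(aligned), template.faces.copy())


@dataclass
class ColourMap:
    """Per-vertex signed distances (mm) and RGB colours on the reference mesh."""

    mesh: TriangleMesh  # reference geometry carrying the map
    signed_distance: np.ndarray  # (V,), mm
    colors: np.ndarray  # (V, 3) uint8
    bound: float = DEFAULT_BOUND_MM


def _ramp(signed: np.ndarray, bound: float) -> np.ndarray:
    """Piecewise-linear blue(-bound) -> green(0) -> red(+bound), clamped."""
    x = np.clip(signed / bound, -1.0, 1.0)
    rgb = np.zeros((len(x), 3))
    neg = x < 0
    rgb[neg, 2] = -x[neg]
    rgb[neg, 1] = 1.0 + x[neg]
    rgb[~neg, 0] = x[~neg]
    rgb[~neg, 1] = 1.0 - x[~neg]
    return np.round(rgb * 255).astype(np.uint8)


def distance_colour_map(
    model: TriangleMesh, reference: TriangleMesh, bound: float = DEFAULT_BOUND_MM
) -> ColourMap:
    """Signed distance from each reference vertex to the model surface.

    Positive where the model lies outside the reference along the reference's
    outward vertex normal; colours follow the clamped blue-green-red ramp.
    """
    if len(model.faces) == 0 or len(reference.faces) == 0:
        raise MeshError("empty mesh in distance map")
    ref_pts = reference.vertices
    nearest = closest_points(model, ref_pts)
    delta = nearest - ref_pts
    dist = np.linalg.norm(delta, axis=1)
    normals = reference.vertex_normals()
    sign = np.where(np.einsum("ij,ij->i", delta, normals) >= 0, 1.0, -1.0)
    signed = sign * dist
    colors = _ramp(signed, bound)
    carrier = TriangleMesh(ref_pts.copy(), reference.faces.copy(), colors)
    return ColourMap(mesh=carrier, signed_distance=signed, colors=colors, bound=bound)


def align_teeth(
    teeth: list[ToothMesh], reference_index: int = 0, use_icp: bool = False
) -> list[ToothMesh]:
    """Register every tooth onto the chosen reference via its landmarks."""
    ref = teeth[reference_index]
    names = sorted(set(ref.landmarks) & set.intersection(*(set(t.landmarks) for t in teeth)))
    if len(names) < 3:
        raise ValueError("need at least 3 shared landmarks to align")
    fixed = np.stack([ref.landmarks[n] for n in names])
    out = []
    for tooth in teeth:
        moving = np.stack([tooth.landmarks[n] for n in names])
        tf = rigid_align(moving, fixed)
        if use_icp:
            tf = icp_refine(tooth.mesh, ref.mesh, init=tf)
        out.append(tooth.transformed(tf.rotation, tf.translation))
    return out
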