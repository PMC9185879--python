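"""Triangle-mesh container, STL/PLY I/O and low-level geometry kernels.

Everything operates on plain ``float64`` numpy arrays: ``vertices`` of shape
``(V, 3)`` in millimetres and integer ``faces`` of shape ``(F, 3)``.  Meshes
are expected to be closed 2-manifolds with outward-facing, consistently wound
triangles whenever a volume is requested; pure surface-area queries accept any
triangle soup.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "MeshError",
    "NotWatertightError",
    "read_stl",
    "write_stl",
    "write_ply",
    "closest_points",
]


class MeshError(ValueError):
    """Invalid mesh input (empty, malformed indices, degenerate query)."""


class NotWatertightError(MeshError):
    """Raised when an operation requires a closed mesh but open edges exist."""

    def __init__(self, n_open_edges: int):
        self.n_open_edges = n_open_edges
        super().__init__(
            f"mesh is not closed: {n_open_edges} boundary edge(s) found"
        )


@dataclass
class TriangleMesh:
    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must have shape (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must have shape (F, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")

    # -- basic derived quantities -------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """Corner coordinates per face, shape (F, 3, 3)."""
        return self.vertices[self.faces]

    def face_cross(self) -> np.ndarray:
        t = self.triangles
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def face_normals(self) -> np.ndarray:
        c = self.face_cross()
        n = np.linalg.norm(c, axis=1)
        n[n == 0] = 1.0
        return c / n[:, None]

    def area(self) -> float:
        if len(self.faces) == 0:
            raise MeshError("empty mesh has no surface area")
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward orientation."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def volume(self) -> float:
        if len(self.faces) == 0:
            raise MeshError("empty mesh has no volume")
        n_open = self.count_open_edges()
        if n_open:
            raise NotWatertightError(n_open)
        return abs(self.signed_volume())

    # -- topology -----------------------------------------------------------------

    def _edges_sorted(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def count_open_edges(self) -> int:
        if len(self.faces) == 0:
            return 0
        _, counts = np.unique(self._edges_sorted(), axis=0, return_counts=True)
        return int((counts != 2).sum())

    def is_watertight(self) -> bool:
        return self.count_open_edges() == 0

    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted pseudo-normals (robust sign reference at creases)."""
        t = self.triangles
        normals = self.face_normals()
        out = np.zeros_like(self.vertices)
        for k in range(3):
            a = t[:, (k + 1) % 3] - t[:, k]
            b = t[:, (k + 2) % 3] - t[:, k]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            ok = (na > 0) & (nb > 0)
            cosang = np.zeros(len(t))
            cosang[ok] = np.clip(
                np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok]), -1.0, 1.0
            )
            ang = np.arccos(cosang)
            np.add.at(out, self.faces[:, k], normals * ang[:, None])
        norm = np.linalg.norm(out, axis=1)
        norm[norm == 0] = 1.0
        return out / norm[:, None]

    # -- transforms / cleanup -----------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        v = self.vertices @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return TriangleMesh(v, self.faces.copy(), self.vertex_colors)

    def merged(self, tol: float = 1e-6) -> "TriangleMesh":
        """Merge vertices closer than ``tol`` and drop degenerate/duplicate faces."""
        key = np.round(self.vertices / tol).astype(np.int64)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        faces = inverse[self.faces]
        keep = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 2] != faces[:, 0])
        )
        faces = faces[keep]
        canon = np.sort(faces, axis=1)
        _, uniq = np.unique(canon, axis=0, return_index=True)
        faces = faces[np.sort(uniq)]
        used = np.unique(faces)
        remap = np.full(len(first), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[first][used], remap[faces])

    def copy(self) -> "TriangleMesh":
        cols = None if self.vertex_colors is None else self.vertex_colors.copy()
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), cols)


# -- STL -----------------------------------------------------------------------


def write_stl(mesh: TriangleMesh, path, binary: bool = True, name: str = "rootmorph") -> None:
    tris = mesh.triangles
    normals = mesh.face_normals()
    if binary:
        with open(path, "wb") as fh:
            fh.write(name.encode("ascii", "replace")[:80].ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(tris)))
            rec = np.zeros(len(tris), dtype=np.dtype(
                [("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]))
            rec["n"] = normals
            rec["v"] = tris
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(f"solid {name}\n")
            for n, t in zip(normals, tris):
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {name}\n")


def _read_stl_ascii(text: str) -> TriangleMesh:
    coords = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("vertex"):
            parts = line.split()
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if not coords or len(coords) % 3:
        raise MeshError("malformed ASCII STL")
    v = np.asarray(coords, dtype=np.float64)
    f = np.arange(len(v), dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(v, f).merged(tol=1e-9)


def read_stl(path) -> TriangleMesh:
    """Read an STL file (binary or ASCII), welding duplicated corners."""
    with open(path, "rb") as fh:
        data = fh.read()
    looks_ascii = data.lstrip()[:5].lower() == b"solid" and b"facet" in data
    is_binary = False
    if len(data) >= 84:
        n_tri = struct.unpack_from("<I", data, 80)[0]
        is_binary = len(data) == 84 + 50 * n_tri
    if looks_ascii and not is_binary:
        return _read_stl_ascii(data.decode("ascii", "replace"))
    if not is_binary:
        raise MeshError("not a valid STL file")
    rec = np.frombuffer(data, offset=84, count=n_tri, dtype=np.dtype(
        [("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]))
    v = rec["v"].reshape(-1, 3).astype(np.float64)
    f = np.arange(len(v), dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(v, f).merged(tol=1e-9)


def write_ply(mesh: TriangleMesh, path) -> None:
    """ASCII PLY, with per-vertex uchar RGB when colours are attached."""
    has_col = mesh.vertex_colors is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if has_col:
            fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i, v in enumerate(mesh.vertices):
            row = f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}"
            if has_col:
                c = mesh.vertex_colors[i]
                row += f" {int(c[0])} {int(c[1])} {int(c[2])}"
            fh.write(row + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# -- closest-point queries -----------------------------------------------------


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to each ``points[i]`` (paired).

    Vectorised version of the standard barycentric-region walk
    (Ericson, *Real-Time Collision Detection*, §5.1.5).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(d1 - d3 != 0, d1 - d3, 1.0)
    t = (d1 / denom)[:, None]
    out[m] = (a + t * ab)[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(d2 - d6 != 0, d2 - d6, 1.0)
    t = (d2 / denom)[:, None]
    out[m] = (a + t * ac)[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom != 0, denom, 1.0)
    t = ((d4 - d3) / denom)[:, None]
    out[m] = (b + t * (c - b))[m]
    done |= m

    m = ~done
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = (vb / denom)[:, None]
    w = (vc / denom)[:, None]
    out[m] = (a + v * ab + w * ac)[m]
    return out


def closest_points(mesh: TriangleMesh, points: np.ndarray, k: int = 24) -> np.ndarray:
    """Closest point on ``mesh``'s surface for each query point.

    Candidate triangles are pre-selected with a KD-tree over triangle
    centroids (``k`` nearest, padded by the largest triangle radius), then the
    exact point–triangle distance decides among candidates.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tris = mesh.triangles
    if len(tris) == 0:
        raise MeshError("empty mesh in closest-point query")
    centroids = tris.mean(axis=1)
    k = min(k, len(tris))
    _, idx = cKDTree(centroids).query(points, k=k)
    idx = np.atleast_2d(idx.reshape(len(points), k))

    best_pts = np.zeros_like(points)
    best_d2 = np.full(len(points), np.inf)
    for j in range(k):
        cand = _closest_on_triangles(points, tris[idx[:, j]])
        d2 = np.einsum("ij,ij->i", cand - points, cand - points)
        better = d2 < best_d2
        best_pts[better] = cand[better]
        best_d2[better] = d2[better]
    return best_pts
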