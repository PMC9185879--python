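import numpy as np
import pytest

from rootmorph.meshes import TriangleMesh
from rootmorph.synthetic import ToothProfile, generate_tooth


def make_cube(side: float = 1.0) -> TriangleMesh:
    """Axis-aligned cube [0, side]^3 with outward-wound triangles."""
    s = side
    v = np.array(
        [
            [0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0],
            [0, 0, s], [s, 0, s], [s, s, s], [0, s, s],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z=0), normal -z
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # y=0
            [2, 3, 7], [2, 7, 6],  # y=s
            [1, 2, 6], [1, 6, 5],  # x=s
            [3, 0, 4], [3, 4, 7],  # x=0
        ]
    )
    return TriangleMesh(v, f)


def make_cone(radius: float, height: float, n: int = 256) -> TriangleMesh:
    """Closed cone: apex at (0, 0, height), base disc of ``radius`` at z=0."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])
    verts = np.vstack([ring, [[0, 0, height]], [[0, 0, 0]]])
    apex, center = n, n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([i, j, apex])     # lateral, outward
        faces.append([j, i, center])   # base, normal -z
    return TriangleMesh(verts, np.array(faces))


def make_uv_sphere(radius: float, n: int = 48) -> TriangleMesh:
    th = np.linspace(0, np.pi, n)[1:-1]
    m = 2 * n
    ph = np.linspace(0, 2 * np.pi, m, endpoint=False)
    verts = [[0.0, 0.0, radius]]
    row_start = []
    for t in th:
        row_start.append(len(verts))
        for p in ph:
            verts.append(
                [radius * np.sin(t) * np.cos(p), radius * np.sin(t) * np.sin(p), radius * np.cos(t)]
            )
    south = len(verts)
    verts.append([0.0, 0.0, -radius])
    faces = []
    for j in range(m):
        faces.append([0, row_start[0] + j, row_start[0] + (j + 1) % m])
    for i in range(len(row_start) - 1):
        a, b = row_start[i], row_start[i + 1]
        for j in range(m):
            faces.append([a + j, b + j, a + (j + 1) % m])
            faces.append([a + (j + 1) % m, b + j, b + (j + 1) % m])
    a = row_start[-1]
    for j in range(m):
        faces.append([a + j, south, a + (j + 1) % m])
    return TriangleMesh(np.array(verts), np.array(faces))


@pytest.fixture(scope="session")
def cube():
    return make_cube()


@pytest.fixture(scope="session")
def fine_cone():
    return make_cone(radius=3.0, height=4.0, n=512)


@pytest.fixture(scope="session")
def default_tooth():
    """Standard crowned 'normal' tooth at working resolution."""
    return generate_tooth(ToothProfile(mesh_resolution=(96, 96)))


@pytest.fixture(scope="session")
def cone_tooth_fine():
    """Crownless exact-cone tooth (p=1, circular, no tip rounding)."""
    profile = ToothProfile(
        root_length=12.0,
        cervical_halfwidth_md=4.0,
        cervical_halfwidth_bl=4.0,
        taper_class="conical",
        crown_height=0.0,
        apex_rounding=0.0,
        mesh_resolution=(200, 200),
    )
    return generate_tooth(profile)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
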