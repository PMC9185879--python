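"""Root-width parameter (PRW) from a 2D root silhouette.

Construction: with apex ``G`` and mesial/distal CEJ points ``F``/``E``, take
the chord midpoints ``B = mid(G, F)`` and ``C = mid(G, E)``, extend the line
through ``B`` and ``C`` until it meets the mesial and distal root margins at
``A`` and ``D``, and report ``PRW = (|AD| - |BC|) / 2``.  Straight (conical)
margins give PRW = 0; margins bulging outward from the chords give PRW > 0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = ["RadiographOutline", "PrwResult", "prw", "read_outline_csv", "write_outline_csv"]


@dataclass
class RadiographOutline:
    """Closed 2D silhouette polygon (mm) with apex and CEJ landmarks."""

    polygon: np.ndarray  # (N, 2), implicitly closed
    G: np.ndarray  # apex
    F: np.ndarray  # mesial CEJ
    E: np.ndarray  # distal CEJ

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be an (N>=3, 2) array")
        self.G = np.asarray(self.G, dtype=np.float64)
        self.F = np.asarray(self.F, dtype=np.float64)
        self.E = np.asarray(self.E, dtype=np.float64)
        if not Polygon(self.polygon).is_valid:
            raise ValueError("outline polygon is not simple")


@dataclass
class PrwResult:
    prw: float
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray


def prw(outline: RadiographOutline) -> PrwResult:
    """Compute the root-width parameter and the construction points A, B, C, D.

    The BC line is extended well beyond the silhouette on both sides; among
    its crossings with the outline, ``A`` is the one nearest ``B`` on the
    mesial side (beyond B) and ``D`` the one nearest ``C`` on the distal side.
    """
    B = 0.5 * (outline.G + outline.F)
    C = 0.5 * (outline.G + outline.E)
    bc = C - B
    bc_len = float(np.linalg.norm(bc))
    if bc_len < 1e-12:
        raise ValueError("degenerate construction: B and C coincide")
    u = bc / bc_len

    poly = Polygon(outline.polygon)
    diam = 4.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    line = LineString([B - diam * u, C + diam * u])
    inter = line.intersection(poly.exterior)
    if inter.is_empty:
        raise ValueError("line BC does not intersect the outline")

    pts = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.geom_type == "Point":
            pts.append([geom.x, geom.y])
        else:  # collinear overlap: keep segment endpoints
            pts.extend(np.asarray(geom.coords))
    pts = np.asarray(pts, dtype=np.float64)
    t = (pts - B) @ u  # param along the line: B at 0, C at bc_len

    mesial = t[t < 0.5 * bc_len]
    distal = t[t >= 0.5 * bc_len]
    if len(mesial) == 0 or len(distal) == 0:
        raise ValueError("line BC does not cross both root margins")
    tA = float(mesial[np.argmin(np.abs(mesial))])  # margin crossing nearest B
    tD = float(distal[np.argmin(np.abs(distal - bc_len))])  # nearest C

    A = B + tA * u
    D = B + tD * u
    ad_len = tD - tA
    return PrwResult(prw=(ad_len - bc_len) / 2.0, A=A, B=B, C=C, D=D)


def read_outline_csv(outline_path, landmarks_json_path) -> RadiographOutline:
    """Outline CSV has one ``x,y`` row per vertex (header optional); landmarks
    JSON maps ``G``/``F``/``E`` to ``[x, y]``."""
    rows = []
    with open(outline_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                rows.append([float(row[0]), float(row[1])])
            except ValueError:
                continue  # header
    with open(landmarks_json_path) as fh:
        lm = json.load(fh)
    return RadiographOutline(np.asarray(rows), lm["G"], lm["F"], lm["E"])


def write_outline_csv(outline: RadiographOutline, outline_path, landmarks_json_path) -> None:
    with open(outline_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y"])
        for p in outline.polygon:
            w.writerow([f"{p[0]:.6f}", f"{p[1]:.6f}"])
    with open(landmarks_json_path, "w") as fh:
        json.dump(
            {k: list(map(float, getattr(outline, k))) for k in ("G", "F", "E")},
            fh,
            indent=1,
        )
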