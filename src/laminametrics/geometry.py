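"""Surface-curvature proxy and the elliptical-leaf null model.

A flat lamina can be characterised entirely in the plane, but a cupped or
crinkly lamina carries non-zero Gaussian curvature and cannot be flattened
without cuts.  The scale-free statistic P/sqrt(A) — boundary perimeter over
the square root of surface area — is used as a global proxy for net surface
curvature: for planar shapes it is bounded below by the isoperimetric value
2*sqrt(pi) (attained by the disc), a dome/cup (positive Gaussian curvature)
pushes it below that floor, and marginal excess growth (saddle, negative
curvature) pushes it above.

The null model for a flat leaf is a planar ellipse with semi-axes a = L/2,
b = W/2, using the quadratic-mean perimeter approximation
P = 2*pi*sqrt((a^2 + b^2)/2) and A = pi*a*b.  The resulting predicted proxy
depends only on the aspect ratio L:W, so measured deviations from it reflect
surface curvature and non-elliptic planform, not size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FLAT_DISC_PROXY",
    "EllipseModel",
    "ShapeMetrics",
    "SurfaceMetrics",
    "LeafSurfaceMesh",
    "ellipse_predicted_perimeter",
    "ellipse_area",
    "ellipse_exact_perimeter",
    "curvature_proxy",
    "predicted_proxy_from_length_width",
    "mesh_metrics",
]

#: P/sqrt(A) of a flat disc, the isoperimetric floor for planar shapes.
FLAT_DISC_PROXY: float = 2.0 * math.sqrt(math.pi)

#: Relative half-width of the "flat" band around ``FLAT_DISC_PROXY`` used by
#: :func:`mesh_metrics` to classify curvature sign; chosen to exceed mesh
#: discretisation error at default resolutions.
FLAT_BAND_REL_TOL: float = 0.02


@dataclass(frozen=True)
class EllipseModel:
    """Planar ellipse with semi-major axis ``a`` and semi-minor ``b`` (mm)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"ellipse semi-axes must be positive, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class ShapeMetrics:
    """Planar shape descriptors of a flattened lamina (Table-1 style)."""

    length: float  # mm, maximal extent along the principal (proximo-distal) axis
    width: float  # mm, maximal orthogonal extent
    perimeter: float  # mm
    area: float  # mm^2
    length_width_ratio: float
    curvature_proxy: float  # P / sqrt(A), unitless


@dataclass(frozen=True)
class SurfaceMetrics:
    """Intrinsic descriptors of a 3-D lamina patch."""

    surface_area: float  # mm^2
    boundary_perimeter: float  # mm
    proxy: float  # P / sqrt(A)
    curvature_class: Literal["flat", "positive", "negative"]


@dataclass
class LeafSurfaceMesh:
    """Triangulated lamina patch with a single boundary loop.

    ``vertices`` is an (n, 3) float array in mm; ``faces`` an (m, 3) int
    array of vertex indices (counter-clockwise seen from the adaxial side).
    """

    vertices: np.ndarray
    faces: np.ndarray
    kind: str = "surface"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")


def ellipse_predicted_perimeter(model: EllipseModel) -> float:
    """Quadratic-mean perimeter approximation 2*pi*sqrt((a^2+b^2)/2).

    This is deliberately the simple root-mean-square approximation, not the
    exact elliptic integral: its error is < 1% for the aspect ratios of real
    leaves and it is what the null-model prediction is defined with.  Exact
    to machine precision for a circle (a == b).
    """
    return 2.0 * math.pi * math.sqrt((model.a**2 + model.b**2) / 2.0)


def ellipse_area(model: EllipseModel) -> float:
    """Exact ellipse area pi*a*b (mm^2)."""
    return math.pi * model.a * model.b


def ellipse_exact_perimeter(model: EllipseModel) -> float:
    """Near-exact ellipse perimeter via Ramanujan's second approximation.

    Used as an independent reference to document the error of the
    quadratic-mean approximation; relative error < 1e-9 for aspect
    ratios below ~5.
    """
    a, b = model.a, model.b
    h = (a - b) ** 2 / (a + b) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def curvature_proxy(perimeter: float, area: float) -> float:
    """P/sqrt(A) from a perimeter (mm) and area (mm^2).

    No rounding is applied here; round only at reporting time.
    """
    if perimeter <= 0:
        raise ValueError(f"perimeter must be positive, got {perimeter}")
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    return perimeter / math.sqrt(area)


def predicted_proxy_from_length_width(length: float, width: float) -> float:
    """Null-model P/sqrt(A) of a flat elliptic leaf of given length and width.

    Depends only on the length:width ratio (scale invariant), so it isolates
    the contribution of planform ellipticity to the measured proxy.
    """
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    model = EllipseModel(a=length / 2.0, b=width / 2.0)
    return curvature_proxy(ellipse_predicted_perimeter(model), ellipse_area(model))


# ---------------------------------------------------------------------------
# Intrinsic metrics on triangulated laminae
# ---------------------------------------------------------------------------


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - p0
    e2 = vertices[faces[:, 2]] - p0
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered vertex loops of boundary edges (edges used by one face only)."""
    edges: dict[tuple[int, int], int] = {}
    for tri in faces:
        for i in range(3):
            u, v = int(tri[i]), int(tri[(i + 1) % 3])
            key = (u, v) if u < v else (v, u)
            edges[key] = edges.get(key, 0) + 1
    boundary = [e for e, count in edges.items() if count == 1]
    if not boundary:
        return []
    # walk adjacency to order edges into loops
    adj: dict[int, list[int]] = {}
    for u, v in boundary:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    if any(len(nbrs) != 2 for nbrs in adj.values()):
        raise ValueError("boundary is not a union of simple closed loops")
    unvisited = set(adj)
    loops: list[list[int]] = []
    while unvisited:
        start = min(unvisited)
        loop = [start]
        prev, cur = None, start
        while True:
            nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
            if nxt == start:
                break
            loop.append(nxt)
            prev, cur = cur, nxt
        unvisited.difference_update(loop)
        loops.append(loop)
    return loops


def mesh_metrics(mesh: LeafSurfaceMesh) -> SurfaceMetrics:
    """Intrinsic P/sqrt(A) of a lamina patch, with a curvature-sign call.

    Surface area is the sum of triangle areas and the perimeter the summed
    length of boundary edges — both intrinsic quantities, so the proxy equals
    what the cut-and-flatten measurement convention yields when newly cut
    edges are excluded, with no flattening step required.

    The curvature class compares the proxy against the flat-disc reference
    2*sqrt(pi): below the band => net positive (cup/dome), above => net
    negative (saddle/crinkly), inside => flat.  The call is only meaningful
    for roughly isotropic planforms; a flat but elongated patch also raises
    the proxy (the planform effect the ellipse null model quantifies).

    Raises ``ValueError`` if the mesh has zero or multiple boundary loops
    (a cut mesh must be re-joined before measuring) or degenerate triangles.
    """
    areas = _triangle_areas(mesh.vertices, mesh.faces)
    if np.any(areas <= 0):
        raise ValueError("mesh contains degenerate (zero-area) triangles")
    loops = boundary_loops(mesh.faces)
    if len(loops) != 1:
        raise ValueError(f"mesh must have exactly one boundary loop, found {len(loops)}")
    loop = loops[0]
    pts = mesh.vertices[np.asarray(loop + [loop[0]])]
    perimeter = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    area = float(areas.sum())
    proxy = curvature_proxy(perimeter, area)
    band = FLAT_BAND_REL_TOL * FLAT_DISC_PROXY
    if proxy < FLAT_DISC_PROXY - band:
        cls: Literal["flat", "positive", "negative"] = "positive"
    elif proxy > FLAT_DISC_PROXY + band:
        cls = "negative"
    else:
        cls = "flat"
    return SurfaceMetrics(
        surface_area=area, boundary_perimeter=perimeter, proxy=proxy, curvature_class=cls
    )
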