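"""Iso-surface meshing, 3D convex hulls, and the two shape descriptors.

The descriptor conventions:

* object volume V and surface area A come from a triangulated iso-surface
  of the binary body at level 0.5 (not voxel-face counting, which is a
  biased area estimator);
* the convex hull is computed over the mesh vertices, so the meshed region
  is contained in the hull and solidity S = V/Vc <= 1 holds exactly;
* convexity C = Ac/A is *not* clamped: for flat bodies with in-plane
  concavities the hull area can exceed the object area (C > 1), although
  thin warped sheets give C < 1.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull as _SciPyHull
from scipy.spatial import QhullError
from skimage import measure as _sk_measure

from .exceptions import DegenerateGeometryError
from .volume_io import BinaryVolume

logger = logging.getLogger(__name__)

#: relative tolerance for hull containment / solidity checks
_REL_TOL = 1e-9


@dataclass
class SurfaceMesh:
    """Closed, outward-oriented triangle mesh (vertices in length units)."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int, counter-clockwise seen from outside

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of vertex triples")


@dataclass
class ConvexHull3D:
    """Triangulated convex hull; vertices are a subset of the input points."""

    vertices: np.ndarray   # (n, 3) hull vertex coordinates
    faces: np.ndarray      # (m, 3) indices into ``vertices``
    normals: np.ndarray    # (m, 3) outward unit facet normals
    offsets: np.ndarray    # (m,) plane offsets: normal . x <= offset inside

    def as_mesh(self) -> SurfaceMesh:
        return SurfaceMesh(vertices=self.vertices, faces=self.faces)

    def contains(self, points: np.ndarray, rtol: float = _REL_TOL) -> np.ndarray:
        """Per-point containment test against every facet plane.

        Evaluated in chunks so the (n_points x n_facets) distance matrix
        never materializes at once.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        diag = np.linalg.norm(self.vertices.max(0) - self.vertices.min(0))
        tol = rtol * max(diag, 1.0)
        out = np.empty(len(points), dtype=bool)
        chunk = max(1, int(5e6) // max(len(self.normals), 1))
        for start in range(0, len(points), chunk):
            block = points[start:start + chunk]
            d = block @ self.normals.T - self.offsets
            out[start:start + chunk] = (d <= tol).all(axis=1)
        return out


@dataclass
class MorphDescriptors:
    """Per-individual morphological record.

    V, A: object volume / surface area; Vc, Ac: convex-hull volume / area;
    C = Ac/A (convexity); S = V/Vc (solidity); ``label`` is an optional
    group tag used by the classification step.
    """

    name: str
    V: float
    Vc: float
    A: float
    Ac: float
    C: float
    S: float
    label: str | None = None


# ---------------------------------------------------------------------------
# Meshing


def mesh_surface(b: BinaryVolume, smoothing_sigma: float = 0.0) -> SurfaceMesh:
    """Triangulate the 0.5 iso-surface of a binary body, scaled by spacing.

    The volume is padded by background voxels when the mask touches the
    grid boundary (logged), so the mesh is always closed.  Faces are
    oriented outward (positive signed volume).

    ``smoothing_sigma`` (voxels) applies a Gaussian to the binary field
    before extracting the iso-surface.  The raw (sigma 0) surface of a
    voxelized smooth body overestimates its area by ~9% (staircase
    artifact); sigma ~1 removes the bias while preserving volume to <1%.
    If smoothing flattens the field below the iso-level (very small or
    one-voxel-thin masks), the raw surface is used instead (logged).
    """
    if b.count() == 0:
        raise DegenerateGeometryError("cannot mesh an empty mask")
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    data = b.data
    touches = (
        data[0].any() or data[-1].any()
        or data[:, 0].any() or data[:, -1].any()
        or data[:, :, 0].any() or data[:, :, -1].any()
    )
    if touches:
        logger.info("mask touches the grid boundary; padding before meshing")
    # padding never changes the surface away from the boundary; do it always
    pad = max(1, int(np.ceil(3 * smoothing_sigma)))
    field = np.pad(data, pad).astype(np.float32)
    if smoothing_sigma > 0:
        smoothed = ndi.gaussian_filter(field, smoothing_sigma)
        if smoothed.max() <= 0.5:
            logger.warning(
                "smoothing sigma %.3g erases the mask (max %.3g <= iso-level); "
                "falling back to the raw binary surface",
                smoothing_sigma, smoothed.max(),
            )
        else:
            field = smoothed
    s = b.spacing
    verts, faces, _, _ = _sk_measure.marching_cubes(field, level=0.5, spacing=(s, s, s))
    mesh = SurfaceMesh(vertices=verts, faces=faces)
    if mesh_volume(mesh) < 0:
        mesh = SurfaceMesh(vertices=verts, faces=faces[:, ::-1])
    return mesh


def _assert_closed(faces: np.ndarray) -> None:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if not (counts == 2).all():
        raise DegenerateGeometryError(
            "mesh is not closed: some edges are not shared by exactly 2 faces"
        )


def mesh_volume(m: SurfaceMesh) -> float:
    """Signed volume by summed tetrahedra against the origin.

    Exactly translation-invariant for closed meshes (up to rounding);
    positive for outward orientation.
    """
    _assert_closed(m.faces)
    v0 = m.vertices[m.faces[:, 0]]
    v1 = m.vertices[m.faces[:, 1]]
    v2 = m.vertices[m.faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def mesh_area(m: SurfaceMesh) -> float:
    """Total surface area: sum of triangle areas."""
    _assert_closed(m.faces)
    v0 = m.vertices[m.faces[:, 0]]
    v1 = m.vertices[m.faces[:, 1]]
    v2 = m.vertices[m.faces[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    return float(np.linalg.norm(cross, axis=1).sum() / 2.0)


# ---------------------------------------------------------------------------
# Convex hull


def convex_hull(points: np.ndarray) -> ConvexHull3D:
    """Convex hull of a 3D point set.

    Raises :class:`DegenerateGeometryError` for fewer than 4 points or
    coplanar/collinear input rather than silently returning a flat hull.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(points) < 4:
        raise DegenerateGeometryError(
            f"convex hull needs >= 4 points, got {len(points)}"
        )
    try:
        qh = _SciPyHull(points)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "degenerate point set (coplanar or collinear); no 3D hull exists"
        ) from exc
    vert_idx = qh.vertices
    remap = np.full(len(points), -1, dtype=np.intp)
    remap[vert_idx] = np.arange(len(vert_idx))
    vertices = points[vert_idx]
    faces = remap[qh.simplices]
    centroid = vertices.mean(axis=0)
    # orient every facet outward (normal away from the hull centroid)
    v0, v1, v2 = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    n = np.cross(v1 - v0, v2 - v0)
    flip = np.einsum("ij,ij->i", n, v0 - centroid) < 0
    faces[flip] = faces[flip][:, ::-1]
    n[flip] *= -1
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    normals = n / norms
    offsets = np.einsum("ij,ij->i", normals, points[qh.simplices[:, 0]])
    hull = ConvexHull3D(vertices=vertices, faces=faces, normals=normals, offsets=offsets)
    # containment safety net; for large inputs the full n x m check is
    # quadratic, so verify a deterministic subsample instead
    if len(points) * len(normals) > 2e7:
        step = max(1, len(points) * len(normals) // int(2e7))
        check = points[::step]
    else:
        check = points
    if not hull.contains(check).all():
        raise DegenerateGeometryError("hull containment check failed (numerical issue)")
    return hull


def hull_volume(h: ConvexHull3D) -> float:
    """Volume of the hull via its triangulation."""
    return mesh_volume(h.as_mesh())


def hull_area(h: ConvexHull3D) -> float:
    """Surface area of the hull via its triangulation."""
    return mesh_area(h.as_mesh())


# ---------------------------------------------------------------------------
# Descriptors


def convexity(Ac: float, A: float) -> float:
    """C = Ac / A: ratio of convex-hull surface area to object surface area."""
    if A <= 0 or Ac <= 0:
        raise ValueError(f"areas must be positive, got Ac={Ac}, A={A}")
    return Ac / A


def solidity(V: float, Vc: float) -> float:
    """S = V / Vc: ratio of object volume to convex-hull volume.

    V may exceed Vc only within mesh tolerance; beyond that the inputs are
    inconsistent (object volume cannot exceed its hull's) and we fail loudly.
    """
    if V <= 0 or Vc <= 0:
        raise ValueError(f"volumes must be positive, got V={V}, Vc={Vc}")
    if V > Vc * (1.0 + _REL_TOL):
        raise ValueError(
            f"V={V} exceeds hull volume Vc={Vc}: inconsistent mesh/hull conventions"
        )
    return min(V, Vc) / Vc


def measure(b: BinaryVolume, name: str | None = None,
            label: str | None = None,
            smoothing_sigma: float = 1.0) -> MorphDescriptors:
    """Compute the full descriptor record for a binary plant body.

    V and A come from the iso-surface mesh (anti-staircase smoothing at
    sigma 1 by default); the hull is taken over the mesh vertices, so
    S <= 1 by construction.  All quantities are in spacing**3 /
    spacing**2 units.
    """
    mesh = mesh_surface(b, smoothing_sigma=smoothing_sigma)
    V = mesh_volume(mesh)
    A = mesh_area(mesh)
    hull = convex_hull(mesh.vertices)
    Vc = hull_volume(hull)
    Ac = hull_area(hull)
    return MorphDescriptors(
        name=name if name is not None else b.name,
        V=V, Vc=Vc, A=A, Ac=Ac,
        C=convexity(Ac, A), S=solidity(V, Vc),
        label=label,
    )


# ---------------------------------------------------------------------------
# Mesh export


def write_ply(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    """Write a triangle mesh as ASCII PLY."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
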