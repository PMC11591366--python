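"""Triangle-mesh and point-cloud foundation: I/O, nearest-point queries, and
mesh-to-mesh deviation metrics.

All coordinates are millimetres.  File units are assumed to be millimetres
already; no unit metadata is trusted or rescaled.

The nearest-point query is point-to-*surface*: the minimum Euclidean distance
from a query point to any point of any triangle (interior, edge, or vertex),
not a vertex-to-vertex shortcut.  Candidate triangles are pruned with a
KD-tree over triangle centroids using an exact bound, so results match a
brute-force scan over every triangle to machine precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import ValidationError
from .rigid import RigidTransform

_SUPPORTED_FORMATS = {"ply", "stl", "obj"}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class PointCloud:
    """A bare set of 3D points in millimetres."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] == 0:
            raise ValidationError(f"points must be a non-empty (n, 3) array, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValidationError("non-finite point coordinates")
        self.points = p

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def transformed(self, transform: RigidTransform) -> "PointCloud":
        return PointCloud(transform.apply(self.points))


@dataclass(eq=False)
class TriangleMesh:
    """Vertices + triangular faces; optional integer per-vertex labels mark
    patch membership (anatomical regions)."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None
    _query: "_SurfaceQuery | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise ValidationError(f"vertices must be a non-empty (n, 3) array, got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] == 0:
            raise ValidationError(f"faces must be a non-empty (m, 3) array, got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise ValidationError("face index out of range")
        self.vertices = v
        self.faces = f

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))

    def transformed(self, transform: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(
            transform.apply(self.vertices),
            self.faces.copy(),
            None if self.vertex_labels is None else self.vertex_labels.copy(),
        )

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex outward normals (orientation follows the
        face winding)."""
        return np.asarray(self.to_trimesh().vertex_normals, dtype=float)

    def surface_query(self) -> "_SurfaceQuery":
        if self._query is None or self._query.n_faces != self.n_faces:
            self._query = _SurfaceQuery(self)
        return self._query


@dataclass(frozen=True)
class DeviationMetrics:
    """Point-to-surface deviation summary between two models.

    ``rmsd`` is the root-mean-square deviation, ``ad`` the average deviation
    (unsigned unless the computation was signed), over ``n_points`` query
    vertices.
    """

    rmsd: float
    ad: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValidationError("n_points must be >= 1")
        if self.rmsd < 0 or self.rmsd + 1e-12 < abs(self.ad):
            raise ValidationError("requires rmsd >= |ad| >= 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path, file_format: str | None = None) -> TriangleMesh:
    """Load a surface model from PLY/STL/OBJ.

    The loaded mesh is cleaned: exactly duplicated vertices are merged (STL is
    a vertex soup) and zero-area faces are dropped.  Units are taken to be
    millimetres as-is.
    """
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r} (use ply/stl/obj)")
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, force="mesh", process=True)
    except Exception as exc:  # trimesh raises assorted types on corrupt input
        raise IOError(f"could not read mesh {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValidationError(f"no triangle geometry in {path}")
    tm.merge_vertices()
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    if len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise ValidationError(f"mesh {path} is empty after cleaning")
    return TriangleMesh.from_trimesh(tm)


def write_mesh(mesh: TriangleMesh, path: str | Path, file_format: str | None = None) -> Path:
    """Write a mesh as PLY/STL/OBJ (format from extension when omitted)."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r} (use ply/stl/obj)")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(str(path), file_type=fmt)
    return path


def read_point_cloud(path: str | Path) -> PointCloud:
    """Load a point cloud from a PLY file (faces, if any, are ignored)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point-cloud file not found: {path}")
    loaded = trimesh.load(str(path), process=False)
    pts = np.asarray(loaded.vertices, dtype=float)
    return PointCloud(pts)


def write_point_cloud(cloud: PointCloud, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trimesh.PointCloud(cloud.points).export(str(path))
    return path


# ---------------------------------------------------------------------------
# Closest point on a triangle (exact, vectorized)
# ---------------------------------------------------------------------------


def closest_points_on_triangles(query: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point to ``query`` (3,) on each triangle of an
    (m, 3, 3) array.  Returns (distances (m,), footpoints (m, 3)).

    Region-based algorithm: classify the query against the triangle's Voronoi
    regions (vertices, edges, interior) from the barycentric gradient signs,
    then evaluate the clamped projection for the active region.
    """
    q = np.asarray(query, dtype=float).reshape(3)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0, :], tri[:, 1, :], tri[:, 2, :]
    ab = b - a
    ac = c - a
    ap = q - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = q - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = q - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    foot = np.empty_like(a)
    assigned = np.zeros(len(tri), dtype=bool)

    def _take(mask: np.ndarray, value: np.ndarray) -> None:
        m = mask & ~assigned
        if m.any():
            foot[m] = value[m] if value.shape == foot.shape else value
            assigned[m] = True

    _take((d1 <= 0) & (d2 <= 0), a)                              # vertex a
    _take((d3 >= 0) & (d4 <= d3), b)                             # vertex b
    _take((d6 >= 0) & (d5 <= d6), c)                             # vertex c

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        edge_ab = a + v_ab[:, None] * ab
        _take((vc <= 0) & (d1 >= 0) & (d3 <= 0), edge_ab)        # edge ab

        w_ac = d2 / (d2 - d6)
        edge_ac = a + w_ac[:, None] * ac
        _take((vb <= 0) & (d2 >= 0) & (d6 <= 0), edge_ac)        # edge ac

        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        edge_bc = b + w_bc[:, None] * (c - b)
        _take((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), edge_bc)  # edge bc

        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        interior = a + v[:, None] * ab + w[:, None] * ac
        _take(np.ones(len(tri), dtype=bool), interior)           # face interior

    dist = np.linalg.norm(foot - q, axis=1)
    return dist, foot


class _SurfaceQuery:
    """Cached acceleration structure for exact nearest-point-on-surface
    queries against one mesh."""

    def __init__(self, mesh: TriangleMesh):
        self.triangles = mesh.triangles
        self.n_faces = mesh.n_faces
        self._vertex_tree = cKDTree(mesh.vertices)
        centroids = self.triangles.mean(axis=1)
        self._centroid_tree = cKDTree(centroids)
        # max distance from any centroid to its own triangle corners: an
        # exact pruning pad (a triangle holding a closer point than d_up must
        # have its centroid within d_up + pad of the query)
        self._pad = float(np.linalg.norm(self.triangles - centroids[:, None, :], axis=2).max())

    def query_one(self, point: np.ndarray) -> tuple[float, np.ndarray]:
        d_up, _ = self._vertex_tree.query(point)
        radius = d_up + self._pad + 1e-12
        cand = self._centroid_tree.query_ball_point(point, radius)
        dists, feet = closest_points_on_triangles(point, self.triangles[cand])
        k = int(np.argmin(dists))
        return float(dists[k]), feet[k]

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out_d = np.empty(len(points))
        out_f = np.empty((len(points), 3))
        for i, p in enumerate(points):
            out_d[i], out_f[i] = self.query_one(p)
        return out_d, out_f


def nearest_point_distance(query: np.ndarray, mesh: TriangleMesh) -> tuple[float, np.ndarray]:
    """Minimum Euclidean distance from ``query`` to the surface of ``mesh``
    and the footpoint attaining it."""
    return mesh.surface_query().query_one(np.asarray(query, dtype=float).reshape(3))


# ---------------------------------------------------------------------------
# Deviation metrics
# ---------------------------------------------------------------------------


def _signed_distances(mesh_a: TriangleMesh, mesh_b: TriangleMesh, signed: bool) -> np.ndarray:
    sq = mesh_b.surface_query()
    dists, feet = sq.query(mesh_a.vertices)
    if not signed:
        return dists
    # positive when the query vertex lies on the outward-normal side of its
    # footpoint; outward sense taken from mesh_b's face winding
    tm_b = mesh_b.to_trimesh()
    face_normals = np.asarray(tm_b.face_normals)
    # re-associate each footpoint with the face that produced it by a nearest
    # re-query (cheap: signed mode is a reporting variant, not the hot path)
    signs = np.ones(len(dists))
    for i, (p, f) in enumerate(zip(mesh_a.vertices, feet)):
        d_up, _ = sq._vertex_tree.query(f)
        cand = sq._centroid_tree.query_ball_point(f, d_up + sq._pad + 1e-12)
        cd, _ = closest_points_on_triangles(f, sq.triangles[cand])
        face_idx = cand[int(np.argmin(cd))]
        if np.dot(p - f, face_normals[face_idx]) < 0:
            signs[i] = -1.0
    return signs * dists


def deviation_metrics(
    mesh_a: TriangleMesh,
    mesh_b: TriangleMesh,
    signed: bool = False,
    symmetric: bool = False,
) -> DeviationMetrics:
    """RMSD and AD of mesh_a's vertices against mesh_b's surface.

    The metric is asymmetric by convention (query vertices from ``mesh_a``);
    ``symmetric=True`` averages both directions, mimicking symmetric
    inspection reports.
    """
    d = _signed_distances(mesh_a, mesh_b, signed)
    if symmetric:
        d = np.concatenate([d, _signed_distances(mesh_b, mesh_a, signed)])
    return DeviationMetrics(
        rmsd=float(np.sqrt(np.mean(d**2))),
        ad=float(np.mean(d)),
        n_points=int(len(d)),
    )


def pairwise_repeatability(
    meshes: list[TriangleMesh], signed: bool = False
) -> tuple[list[tuple[tuple[int, int], DeviationMetrics]], float, float]:
    """All unordered pairwise deviations among repeated models of the same
    object, plus the mean RMSD and mean AD over the pairs.

    This reproduces the repeated-segmentation repeatability design: n models
    of one object give n(n-1)/2 comparisons (5 models -> 10 comparisons), and
    the pair-mean RMSD/AD is the repeatability floor against which apparent
    morphology change is judged.
    """
    if len(meshes) < 2:
        raise ValidationError("pairwise repeatability needs at least 2 meshes")
    results: list[tuple[tuple[int, int], DeviationMetrics]] = []
    for i in range(len(meshes)):
        for j in range(i + 1, len(meshes)):
            results.append(((i, j), deviation_metrics(meshes[i], meshes[j], signed=signed)))
    mean_rmsd = float(np.mean([m.rmsd for _, m in results]))
    mean_ad = float(np.mean([m.ad for _, m in results]))
    return results, mean_rmsd, mean_ad


def write_deviation_report(
    results: list[tuple[tuple[int, int], DeviationMetrics]],
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write pairwise deviation metrics as CSV and/or JSON."""
    rows = [
        {"pair_id": f"{i}-{j}", "rmsd_mm": m.rmsd, "ad_mm": m.ad, "n_points": m.n_points}
        for (i, j), m in results
    ]
    if csv_path is not None:
        p = Path(csv_path)
        p.parent.mkdir(parents=True, exist_ok=True)
        with open(p, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["pair_id", "rmsd_mm", "ad_mm", "n_points"])
            writer.writeheader()
            writer.writerows(rows)
    if json_path is not None:
        p = Path(json_path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(rows, indent=2))
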