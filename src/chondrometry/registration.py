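"""Fiducial-sphere registration between paired scans.

The measurement design scans the same bone twice — once with articular
cartilage, once after its removal — with rigid spherical fiducial markers
attached throughout.  Each marker's scanned surface is reduced to a fitted
sphere center; corresponding centers across the two scans then determine the
least-squares rigid transform (Kabsch/SVD), and that transform carries the
with-cartilage model into the without-cartilage frame (or vice versa) so
thickness can be measured by closest-point distance.

Sphere fitting is geometric least squares: an algebraic (Coope) linear fit
initializes an iterative Gauss-Newton refinement of sum((|p - c| - r)^2),
which stays unbiased on partial-coverage marker scans.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    AmbiguousMatchError,
    ConvergenceError,
    DegenerateGeometryError,
    ValidationError,
)
from .meshes import PointCloud, TriangleMesh
from .rigid import RigidTransform

#: FRE above this (mm) triggers a configuration-quality warning — about twice
#: the single-scan precision of a metrology-grade laser scanner.
FRE_WARN_MM = 0.2


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: center and radius in mm, RMS geometric residual
    over the ``n_points`` fitted surface points."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("fitted radius must be positive")
        if self.rms_residual < 0:
            raise ValidationError("rms_residual must be >= 0")


@dataclass
class MarkerSet:
    """Labelled fitted fiducial spheres from one scan."""

    markers: dict[str, SphereFit]
    scan_id: str = ""

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValidationError("marker set is empty")

    @property
    def labels(self) -> list[str]:
        return list(self.markers.keys())

    def centers(self, labels: list[str] | None = None) -> np.ndarray:
        labels = labels if labels is not None else self.labels
        return np.array([self.markers[lb].center for lb in labels])


@dataclass(frozen=True)
class RegistrationResult:
    """Estimated rigid transform plus its fiducial registration error (RMS
    residual distance between corresponding centers after alignment) and the
    label correspondence used."""

    transform: RigidTransform
    fre_rms: float
    correspondence: tuple[tuple[str, str], ...]

    @property
    def quality_warning(self) -> bool:
        return self.fre_rms > FRE_WARN_MM

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(
                {
                    "matrix_4x4_row_major": self.transform.as_matrix().tolist(),
                    "fre_rms_mm": self.fre_rms,
                    "correspondence": [list(pair) for pair in self.correspondence],
                    "quality_warning": self.quality_warning,
                },
                indent=2,
            )
        )
        return path


# ---------------------------------------------------------------------------
# Sphere fitting
# ---------------------------------------------------------------------------


def _algebraic_sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Coope's linear least-squares sphere fit (initialization)."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("points are coplanar or otherwise degenerate for a sphere fit")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit produced non-positive radius")
    return center, float(np.sqrt(r2))


def _fixed_radius_center_init(p: np.ndarray, radius: float) -> np.ndarray:
    """Initial center for a fixed-radius fit.

    The centroid is a stationary point of the objective for symmetric point
    sets, so it cannot seed Gauss-Newton.  Instead: lift the circumcenter of
    the first three points off their plane by sqrt(r^2 - R_circ^2) (the
    mirror solution is geometrically equivalent; the +normal side per vertex
    order is taken, deterministically).  With >= 4 non-coplanar points the
    algebraic fit is preferred.
    """
    if len(p) >= 4:
        try:
            center, _ = _algebraic_sphere_fit(p)
            return center
        except DegenerateGeometryError:
            pass
    a, b, c = p[0], p[1], p[2]
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = n @ n
    if nn < 1e-18:
        raise DegenerateGeometryError("first three points are collinear")
    # circumcenter via the standard cross-product formula
    circ = a + (np.cross(np.dot(ab, ab) * ac - np.dot(ac, ac) * ab, np.cross(ab, ac))) / (2 * nn)
    r_circ2 = float(np.dot(circ - a, circ - a))
    if radius**2 < r_circ2:
        raise DegenerateGeometryError(
            f"fixed radius {radius} smaller than the circumradius {np.sqrt(r_circ2):.4f}"
        )
    h = np.sqrt(radius**2 - r_circ2)
    return circ + h * n / np.sqrt(nn)


def fit_sphere(
    points: PointCloud | np.ndarray,
    fixed_radius: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> SphereFit:
    """Geometric least-squares sphere fit.

    Minimizes sum_i (|p_i - c| - r)^2 by Gauss-Newton from an algebraic
    initialization.  With ``fixed_radius`` only the center is free (3 points
    suffice); otherwise at least 4 non-coplanar points are required.
    """
    p = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
    p = np.atleast_2d(p)
    min_pts = 3 if fixed_radius is not None else 4
    if len(p) < min_pts:
        raise ValidationError(f"need at least {min_pts} points, got {len(p)}")

    if fixed_radius is not None:
        radius = float(fixed_radius)
        if radius <= 0:
            raise ValidationError("fixed_radius must be positive")
        center = _fixed_radius_center_init(p, radius)
    else:
        center, radius = _algebraic_sphere_fit(p)

    for _ in range(max_iter):
        diff = p - center
        dist = np.linalg.norm(diff, axis=1)
        if np.any(dist < 1e-12):
            raise DegenerateGeometryError("a point coincides with the sphere center")
        r = radius if fixed_radius is not None else float(dist.mean())
        resid = dist - r
        # Gauss-Newton: jacobian rows d(resid_i)/dc = -diff_i / dist_i
        J = -diff / dist[:, None]
        if fixed_radius is None:
            J = np.c_[J, -np.ones(len(p))]
        try:
            step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"sphere fit linear algebra failed: {exc}") from exc
        center = center + step[:3]
        if fixed_radius is None:
            radius = r + step[3]
        if np.linalg.norm(step) < tol:
            break
    else:
        if np.linalg.norm(step) > 1e-6:
            raise ConvergenceError(
                f"sphere fit did not converge: last step {np.linalg.norm(step):.3g} mm, "
                f"center {center}, radius {radius:.6f}"
            )

    dist = np.linalg.norm(p - center, axis=1)
    r = radius if fixed_radius is not None else float(dist.mean())
    if r <= 0:
        raise DegenerateGeometryError("converged to non-positive radius")
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return SphereFit(center=np.asarray(center, float), radius=float(r), rms_residual=rms, n_points=len(p))


def fit_marker_set(
    clouds: dict[str, PointCloud], scan_id: str = "", fixed_radius: float | None = None
) -> MarkerSet:
    """Fit a sphere to each labelled marker point cloud."""
    return MarkerSet(
        markers={lb: fit_sphere(cl, fixed_radius=fixed_radius) for lb, cl in clouds.items()},
        scan_id=scan_id,
    )


# ---------------------------------------------------------------------------
# Correspondence
# ---------------------------------------------------------------------------

#: two assignments closer than this (mm) in distance-matrix residual are a tie
AMBIGUITY_TOL_MM = 0.05


def match_markers(
    set_a: MarkerSet, set_b: MarkerSet
) -> tuple[tuple[tuple[str, str], ...], float]:
    """Pair markers across two scans.

    If the label sets share >= 3 labels, pairing is by label.  Otherwise the
    inter-center distance matrices are matched over all assignments
    (exhaustive; marker counts are 6-8 in practice), minimizing the RMS
    discrepancy of corresponding pairwise distances — a rigid-invariant
    criterion.  A near-tie between two assignments raises
    :class:`AmbiguousMatchError` (symmetric layouts cannot be disambiguated
    from geometry alone).
    """
    if len(set_a.markers) < 3 or len(set_b.markers) < 3:
        raise ValidationError("marker matching needs at least 3 markers per scan")
    common = [lb for lb in set_a.labels if lb in set_b.markers]
    if len(common) >= 3:
        return tuple((lb, lb) for lb in common), 0.0

    labels_a, labels_b = set_a.labels, set_b.labels
    if len(labels_a) > len(labels_b):
        swapped, resid = match_markers(set_b, set_a)
        return tuple((a, b) for b, a in swapped), resid
    if len(labels_b) > 8:
        raise ValidationError("exhaustive marker matching supports at most 8 markers")

    ca = set_a.centers()
    cb = set_b.centers()
    da = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    best: list[tuple[float, tuple[int, ...]]] = []
    n = len(labels_a)
    iu = np.triu_indices(n, k=1)
    for perm in itertools.permutations(range(len(labels_b)), n):
        sub = cb[list(perm)]
        db = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
        resid = float(np.sqrt(np.mean((da[iu] - db[iu]) ** 2)))
        best.append((resid, perm))
    best.sort(key=lambda x: x[0])
    top_resid, top_perm = best[0]
    if len(best) > 1 and best[1][0] - top_resid < AMBIGUITY_TOL_MM:
        raise AmbiguousMatchError(
            f"two marker assignments within {AMBIGUITY_TOL_MM} mm residual "
            f"({top_resid:.4f} vs {best[1][0]:.4f}); supply labels"
        )
    return tuple((labels_a[i], labels_b[j]) for i, j in enumerate(top_perm)), top_resid


# ---------------------------------------------------------------------------
# Rigid transform estimation (Kabsch)
# ---------------------------------------------------------------------------


def estimate_rigid_transform(source: np.ndarray, target: np.ndarray) -> RegistrationResult:
    """Least-squares rigid transform mapping ``source`` points onto
    ``target`` (Kabsch: SVD of the cross-covariance of centered points, with
    determinant correction so no reflection is ever returned)."""
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != tgt.shape or src.shape[1] != 3:
        raise ValidationError(f"source/target must be matching (n, 3) arrays, got {src.shape} vs {tgt.shape}")
    if len(src) < 3:
        raise ValidationError("need at least 3 corresponding points")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    A = src - mu_s
    B = tgt - mu_t
    # collinearity check: rank of the centered source configuration
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 2:
        raise DegenerateGeometryError("source points are collinear; rotation is unconstrained")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    transform = RigidTransform(R, t)
    resid = transform.apply(src) - tgt
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationResult(
        transform=transform,
        fre_rms=fre,
        correspondence=tuple((str(i), str(i)) for i in range(len(src))),
    )


def register_marker_sets(set_a: MarkerSet, set_b: MarkerSet) -> RegistrationResult:
    """Match markers across scans and estimate the A->B rigid transform."""
    pairs, _ = match_markers(set_a, set_b)
    src = np.array([set_a.markers[a].center for a, _ in pairs])
    tgt = np.array([set_b.markers[b].center for _, b in pairs])
    result = estimate_rigid_transform(src, tgt)
    return RegistrationResult(result.transform, result.fre_rms, pairs)


def propagate_to_cartilage_model(
    reg_without: RegistrationResult, mesh_with_cartilage: TriangleMesh
) -> TriangleMesh:
    """Apply the transform estimated from the without-cartilage scan's
    fiducials to the with-cartilage surface model.

    The markers are rigid with the bone, so the transform that aligns the
    bone-only scan also carries the cartilage-bearing scan of the same bone
    into the same frame — this is what lets the two surfaces be compared by
    closest-point distance without shape matching.
    """
    return mesh_with_cartilage.transformed(reg_without.transform)


# ---------------------------------------------------------------------------
# Marker-center I/O
# ---------------------------------------------------------------------------


def read_marker_centers_csv(path: str | Path, scan_id: str = "") -> MarkerSet:
    """Read pre-fit centers from CSV columns label, x_mm, y_mm, z_mm
    (optional radius_mm, rms_mm)."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"marker CSV not found: {path}")
    df = pd.read_csv(path)
    required = {"label", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"marker CSV must have columns {sorted(required)}")
    markers = {}
    for _, row in df.iterrows():
        markers[str(row["label"])] = SphereFit(
            center=np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float),
            radius=float(row.get("radius_mm", 1.0) if "radius_mm" in df.columns else 1.0),
            rms_residual=float(row["rms_mm"]) if "rms_mm" in df.columns else 0.0,
            n_points=4,
        )
    return MarkerSet(markers=markers, scan_id=scan_id or path.stem)


def write_marker_centers_csv(marker_set: MarkerSet, path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "label": lb,
            "x_mm": m.center[0],
            "y_mm": m.center[1],
            "z_mm": m.center[2],
            "radius_mm": m.radius,
            "rms_mm": m.rms_residual,
        }
        for lb, m in marker_set.markers.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
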