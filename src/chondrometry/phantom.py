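"""Synthetic paired-scan phantoms with machine-readable ground truth.

The phantoms stand in for laser scans of a real distal femur: a
cartilage-free "bone" surface and a cartilage-bearing surface offset from it
along the outward normal by a known thickness field, plus spherical fiducial
markers, anatomical landmark patches, and configurable per-scan sensor
noise.  Every quantity the pipeline later estimates (marker centers, the
inter-scan rigid transform, anatomical frame, cartilage extent, per-vertex
thickness) is recorded as truth, so each stage can be tested against known
values without specimens.

Geometry is generated in the anatomical frame itself: x = medial->lateral,
y = posterior->anterior, z = distal->proximal, origin midway between the
condylar sphere centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import trimesh

from .errors import ValidationError
from .frames import AnatomicalFrame
from .meshes import PointCloud, TriangleMesh
from .rigid import RigidTransform
from .subregions import CartilageExtent

#: default per-scan surface noise SD in mm (metrology-grade laser scanner)
DEFAULT_SIGMA_MM = 0.087


@dataclass(frozen=True)
class MarkerTruth:
    label: str
    center: np.ndarray
    radius: float


@dataclass(eq=False)
class PhantomTruth:
    """A synthetic specimen plus everything the pipeline should recover."""

    bone_mesh: TriangleMesh
    cartilage_mesh: TriangleMesh
    bone_normals: np.ndarray
    cartilage_normals: np.ndarray
    thickness_truth: np.ndarray  # per cartilage vertex, mm
    patches: dict[str, np.ndarray]  # name -> cartilage vertex indices
    plateau_points: PointCloud | None = None
    frame_truth: AnatomicalFrame | None = None
    extent_truth: CartilageExtent | None = None
    markers: dict[str, MarkerTruth] = dc_field(default_factory=dict)
    warnings: list[str] = dc_field(default_factory=list)
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.thickness_truth) < 0):
            raise ValidationError("thickness truth must be >= 0")
        if len(self.thickness_truth) != self.cartilage_mesh.n_vertices:
            raise ValidationError("thickness truth must align with cartilage vertices")

    def truth_json(self) -> dict:
        return {
            "params": self.params,
            "thickness_truth_mm": np.asarray(self.thickness_truth).tolist(),
            "patches": {k: np.asarray(v).tolist() for k, v in self.patches.items()},
            "frame": None
            if self.frame_truth is None
            else {
                "origin_mm": np.asarray(self.frame_truth.origin).tolist(),
                "axis_ml": np.asarray(self.frame_truth.axis_ml).tolist(),
                "axis_ap": np.asarray(self.frame_truth.axis_ap).tolist(),
                "axis_pd": np.asarray(self.frame_truth.axis_pd).tolist(),
                "side": self.frame_truth.side,
            },
            "extent": None
            if self.extent_truth is None
            else {
                "W_mm": self.extent_truth.W,
                "L_med_mm": self.extent_truth.L_med,
                "L_lat_mm": self.extent_truth.L_lat,
                "trochlear_lowest_point_mm": np.asarray(
                    self.extent_truth.trochlear_lowest_point
                ).tolist(),
                "most_posterior_point_medial_mm": np.asarray(
                    self.extent_truth.most_posterior_point_medial
                ).tolist(),
                "most_posterior_point_lateral_mm": np.asarray(
                    self.extent_truth.most_posterior_point_lateral
                ).tolist(),
                "condyle_split_ml_mm": self.extent_truth.condyle_split_ml,
            },
            "markers": {
                lb: {"center_mm": np.asarray(m.center).tolist(), "radius_mm": m.radius}
                for lb, m in self.markers.items()
            },
            "warnings": list(self.warnings),
        }

    def write(self, out_dir: str | Path) -> None:
        from .meshes import write_mesh

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mesh(self.bone_mesh, out / "bone.ply")
        write_mesh(self.cartilage_mesh, out / "cartilage.ply")
        (out / "truth.json").write_text(json.dumps(self.truth_json(), indent=2))
        if self.plateau_points is not None:
            from .meshes import write_point_cloud

            write_point_cloud(self.plateau_points, out / "plateau.ply")


# ---------------------------------------------------------------------------
# Mesh-building helpers
# ---------------------------------------------------------------------------


def _grid_faces(ni: int, nj: int, offset: int = 0) -> np.ndarray:
    """Triangulate an ni x nj vertex grid (row-major) into 2*(ni-1)*(nj-1)
    faces."""
    faces = []
    for i in range(ni - 1):
        for j in range(nj - 1):
            v00 = offset + i * nj + j
            v01 = v00 + 1
            v10 = v00 + nj
            v11 = v10 + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return np.asarray(faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# Concentric-sphere phantom
# ---------------------------------------------------------------------------


def make_concentric_sphere_phantom(
    r_bone: float = 50.0, thickness: float = 2.0, n_subdiv: int = 3
) -> PhantomTruth:
    """Icosphere pair with a constant analytic thickness everywhere."""
    if r_bone <= 0:
        raise ValidationError("r_bone must be positive")
    if thickness < 0:
        raise ValidationError("thickness must be >= 0")
    unit = trimesh.creation.icosphere(subdivisions=n_subdiv, radius=1.0)
    dirs = np.asarray(unit.vertices, dtype=float)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(unit.faces, dtype=np.int64)
    bone = TriangleMesh(r_bone * dirs, faces.copy())
    cart = TriangleMesh((r_bone + thickness) * dirs, faces.copy())
    return PhantomTruth(
        bone_mesh=bone,
        cartilage_mesh=cart,
        bone_normals=dirs.copy(),
        cartilage_normals=dirs.copy(),
        thickness_truth=np.full(len(dirs), float(thickness)),
        patches={},
        params={"kind": "concentric_spheres", "r_bone": r_bone, "thickness": thickness,
                "n_subdiv": n_subdiv},
    )


# ---------------------------------------------------------------------------
# Bicondylar phantom
# ---------------------------------------------------------------------------


def make_bicondylar_phantom(
    condyle_radius: float = 22.0,
    condyle_separation: float = 44.0,
    thickness_base: float = 2.0,
    thickness_amplitude: float = 0.0,
    angular_step_deg: float = 2.0,
    theta_range_deg: tuple[float, float] = (-60.0, 110.0),
    psi_half_deg: float = 40.0,
    groove_radius: float = 8.0,
    groove_center: tuple[float, float] = (12.0, -10.0),
    groove_half_width: float = 14.0,
    groove_edge_lift: float = 1.5,
) -> PhantomTruth:
    """Two sphere-patch condyles plus a connecting trochlear groove surface,
    with a smooth thickness field t(theta) = t0 + a*cos(theta).

    Each condyle is a spherical patch of radius ``condyle_radius`` centered
    at (+-separation/2, 0, 0), parameterized by the sagittal angle theta
    (0 = distal pole, 90 deg = most posterior) and the ML tilt psi.  The
    trochlear groove is a partial cylinder (axis along ML) anterior and
    proximal to the condylar distal surfaces, with its edges lifted
    proximally so the lowest trochlear point is unique and central.  The
    cartilage surface is the bone surface offset along the outward normal by
    the thickness field; truth records per-vertex thickness, anatomical
    patches, the frame, and the cartilage extent landmarks.
    """
    R = float(condyle_radius)
    half_sep = float(condyle_separation) / 2.0
    t0, a = float(thickness_base), float(thickness_amplitude)
    if R <= 0 or half_sep <= 0 or groove_radius <= 0:
        raise ValidationError("radii and separation must be positive")
    if t0 - abs(a) < 0:
        raise ValidationError("thickness field must stay non-negative (t0 >= |a|)")
    if t0 + abs(a) > 4.0:
        raise ValidationError("peak thickness above 4 mm is outside the physiological range")
    if t0 + abs(a) >= min(R, groove_radius):
        raise ValidationError("offset exceeds surface curvature radius; cartilage would self-intersect")

    step = np.radians(angular_step_deg)
    theta = np.arange(np.radians(theta_range_deg[0]), np.radians(theta_range_deg[1]) + step / 2, step)
    psi = np.arange(-np.radians(psi_half_deg), np.radians(psi_half_deg) + step / 2, step)

    bone_v, cart_v, normals, thick, faces = [], [], [], [], []
    patches: dict[str, list] = {
        "trochlea": [],
        "condyle_medial": [],
        "condyle_lateral": [],
        "posterior_condyle_medial": [],
        "posterior_condyle_lateral": [],
    }
    offset = 0

    for condyle, cx in (("medial", -half_sep), ("lateral", +half_sep)):
        tt, pp = np.meshgrid(theta, psi, indexing="ij")
        # outward direction: distal at theta=0, posterior at theta=90deg,
        # tilting toward +-ML with psi
        u = np.stack(
            [np.sin(pp), -np.cos(pp) * np.sin(tt), -np.cos(pp) * np.cos(tt)], axis=-1
        )
        center = np.array([cx, 0.0, 0.0])
        t_field = t0 + a * np.cos(tt)
        bv = center + R * u
        cv = center + (R + t_field[..., None]) * u
        n_pts = bv.shape[0] * bv.shape[1]
        idx = offset + np.arange(n_pts)
        bone_v.append(bv.reshape(-1, 3))
        cart_v.append(cv.reshape(-1, 3))
        normals.append(u.reshape(-1, 3))
        thick.append(t_field.reshape(-1))
        faces.append(_grid_faces(len(theta), len(psi), offset))
        patches[f"condyle_{condyle}"].extend(idx.tolist())
        posterior = tt.reshape(-1) >= np.radians(60.0)
        patches[f"posterior_condyle_{condyle}"].extend(idx[posterior].tolist())
        offset += n_pts

    # trochlear groove: partial cylinder, axis along ML through
    # (y, z) = groove_center, spanning alpha in [-30, 60] deg from distal
    y_g, z_g = groove_center
    alpha = np.arange(np.radians(-30.0), np.radians(60.0) + step / 2, step)
    xs = np.arange(-groove_half_width, groove_half_width + 0.5, 1.0)
    aa, xx = np.meshgrid(alpha, xs, indexing="ij")
    lift = groove_edge_lift * (xx / groove_half_width) ** 2
    gb = np.stack(
        [xx, y_g + groove_radius * np.sin(aa), z_g - groove_radius * np.cos(aa) + lift],
        axis=-1,
    )
    gn = np.stack([np.zeros_like(aa), np.sin(aa), -np.cos(aa)], axis=-1)
    t_groove = t0 + a * np.cos(aa)
    gc = gb + t_groove[..., None] * gn
    n_pts = gb.shape[0] * gb.shape[1]
    idx = offset + np.arange(n_pts)
    bone_v.append(gb.reshape(-1, 3))
    cart_v.append(gc.reshape(-1, 3))
    normals.append(gn.reshape(-1, 3))
    thick.append(t_groove.reshape(-1))
    faces.append(_grid_faces(len(alpha), len(xs), offset))
    patches["trochlea"] = idx.tolist()
    offset += n_pts

    bone_vertices = np.vstack(bone_v)
    cart_vertices = np.vstack(cart_v)
    all_faces = np.vstack(faces)
    all_normals = np.vstack(normals)
    all_thick = np.concatenate(thick)

    bone_mesh = TriangleMesh(bone_vertices, all_faces.copy())
    cart_mesh = TriangleMesh(cart_vertices, all_faces.copy())
    patch_arrays = {k: np.asarray(v, dtype=np.int64) for k, v in patches.items()}

    # ---- truth: extent landmarks, measured directly off the vertex arrays
    tro_idx = patch_arrays["trochlea"]
    tro_pts = cart_vertices[tro_idx]
    lowest = tro_pts[int(np.argmin(tro_pts[:, 2]))]
    split = float(lowest[0])
    post_pts = {}
    for condyle in ("medial", "lateral"):
        mask = cart_vertices[:, 0] <= split if condyle == "medial" else cart_vertices[:, 0] > split
        side = cart_vertices[mask]
        post_pts[condyle] = side[int(np.argmin(side[:, 1]))]
    W = float(cart_vertices[:, 0].max() - cart_vertices[:, 0].min())
    y_t = float(lowest[1])
    extent = CartilageExtent(
        trochlear_lowest_point=lowest,
        most_posterior_point_medial=post_pts["medial"],
        most_posterior_point_lateral=post_pts["lateral"],
        W=W,
        L_med=0.6 * (y_t - float(post_pts["medial"][1])),
        L_lat=0.6 * (y_t - float(post_pts["lateral"][1])),
        condyle_split_ml=split,
    )

    frame = AnatomicalFrame(
        origin=np.zeros(3),
        axis_ml=np.array([1.0, 0.0, 0.0]),
        axis_ap=np.array([0.0, 1.0, 0.0]),
        axis_pd=np.array([0.0, 0.0, 1.0]),
        side="right",
    )

    # medial tibial plateau stand-in: a planar patch distal to the condyles
    gx, gy = np.meshgrid(np.linspace(-25.0, -5.0, 9), np.linspace(-20.0, 20.0, 17))
    plateau = PointCloud(
        np.c_[gx.ravel(), gy.ravel(), np.full(gx.size, -(R + 18.0))]
    )

    return PhantomTruth(
        bone_mesh=bone_mesh,
        cartilage_mesh=cart_mesh,
        bone_normals=all_normals,
        cartilage_normals=all_normals.copy(),
        thickness_truth=all_thick,
        patches=patch_arrays,
        plateau_points=plateau,
        frame_truth=frame,
        extent_truth=extent,
        params={
            "kind": "bicondylar",
            "condyle_radius": R,
            "condyle_separation": condyle_separation,
            "thickness_base": t0,
            "thickness_amplitude": a,
            "angular_step_deg": angular_step_deg,
        },
    )


# ---------------------------------------------------------------------------
# Fiducial markers
# ---------------------------------------------------------------------------

# irregular default layout (cylindrical coords: angle deg, radial mm, height mm)
_DEFAULT_MARKER_LAYOUT = [
    (0.0, 60.0, 30.0),
    (50.0, 70.0, 45.0),
    (95.0, 65.0, 25.0),
    (160.0, 75.0, 50.0),
    (205.0, 62.0, 35.0),
    (265.0, 72.0, 55.0),
    (310.0, 68.0, 20.0),
    (340.0, 58.0, 42.0),
]


def add_markers(
    phantom: PhantomTruth,
    n_markers: int = 7,
    radius: float = 12.0,
    layout: str = "default",
) -> PhantomTruth:
    """Attach labelled spherical fiducial markers (truth centers) to a
    phantom.

    The default layout is deliberately irregular so that distance-matrix
    marker matching has a unique solution; ``layout='ring'`` places markers
    on a regular ring (symmetric, hence ambiguous) and records a warning.
    """
    if not (3 <= n_markers <= 8):
        raise ValidationError("n_markers must be between 3 and 8")
    if radius <= 0:
        raise ValidationError("marker radius must be positive")
    markers: dict[str, MarkerTruth] = {}
    if layout == "default":
        coords = _DEFAULT_MARKER_LAYOUT[:n_markers]
    elif layout == "ring":
        coords = [(360.0 * k / n_markers, 65.0, 35.0) for k in range(n_markers)]
        phantom.warnings.append(
            "ring marker layout is rotationally symmetric: distance-matrix "
            "matching will be ambiguous"
        )
    else:
        raise ValidationError(f"unknown marker layout {layout!r}")
    for k, (ang, rad, height) in enumerate(coords):
        phi = np.radians(ang)
        center = np.array([rad * np.cos(phi), rad * np.sin(phi), height])
        markers[f"M{k + 1}"] = MarkerTruth(label=f"M{k + 1}", center=center, radius=float(radius))
    phantom.markers = markers
    return phantom


# ---------------------------------------------------------------------------
# Two-scan simulation
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ScanPair:
    """Simulated paired scans: with-cartilage surfaces in frame A,
    without-cartilage surfaces in frame B = transform(A)."""

    with_mesh: TriangleMesh
    without_mesh: TriangleMesh
    markers_with: dict[str, PointCloud]
    markers_without: dict[str, PointCloud]
    transform: RigidTransform
    sigma: float
    seed: int


def _sample_sphere_cloud(
    rng: np.random.Generator, center: np.ndarray, radius: float, n: int, sigma: float
) -> PointCloud:
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    r = np.full(n, radius) + (rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0)
    return PointCloud(center + r[:, None] * dirs)


def simulate_two_scans(
    phantom: PhantomTruth,
    sigma: float = DEFAULT_SIGMA_MM,
    inter_scan_transform: RigidTransform | None = None,
    seed: int = 0,
    points_per_marker: int = 400,
) -> ScanPair:
    """Simulate the two laser scans of one phantom.

    Scan A carries the cartilage-bearing surface and markers in the phantom
    frame; scan B carries the cartilage-free surface and markers, rigidly
    moved by ``inter_scan_transform`` (the specimen was repositioned between
    scans).  Sensor noise is iid Gaussian displacement of SD ``sigma`` along
    each vertex's outward normal, drawn independently per scan, so the
    per-vertex RMS deviation of each scan equals ``sigma``.  Fully seeded.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    T = inter_scan_transform if inter_scan_transform is not None else RigidTransform.identity()
    rng = np.random.default_rng(seed)

    cart_v = phantom.cartilage_mesh.vertices.copy()
    bone_v = phantom.bone_mesh.vertices.copy()
    if sigma > 0:
        cart_v = cart_v + rng.normal(0.0, sigma, len(cart_v))[:, None] * phantom.cartilage_normals
        bone_v = bone_v + rng.normal(0.0, sigma, len(bone_v))[:, None] * phantom.bone_normals
    with_mesh = TriangleMesh(cart_v, phantom.cartilage_mesh.faces.copy())
    without_mesh = TriangleMesh(T.apply(bone_v), phantom.bone_mesh.faces.copy())

    markers_with, markers_without = {}, {}
    for lb, m in phantom.markers.items():
        markers_with[lb] = _sample_sphere_cloud(rng, m.center, m.radius, points_per_marker, sigma)
        cloud_b = _sample_sphere_cloud(rng, m.center, m.radius, points_per_marker, sigma)
        markers_without[lb] = cloud_b.transformed(T)

    return ScanPair(
        with_mesh=with_mesh,
        without_mesh=without_mesh,
        markers_with=markers_with,
        markers_without=markers_without,
        transform=T,
        sigma=float(sigma),
        seed=int(seed),
    )
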