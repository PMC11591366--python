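"""Anatomical standard planes of the knee and the coordinate frame they span.

The standard sagittal plane is normal to the medial-lateral (ML) axis, which
is operationalized as the line joining the centers of spheres least-squares
fit to the two posterior femoral condylar surfaces (the posterior-condylar
flexion-facet convention).  The standard axial plane is normal to the
sagittal plane and parallel to the medial tibial plateau surface; the
standard coronal plane is mutually perpendicular.  In the resulting frame
+x = medial->lateral (ML), +y = posterior->anterior (AP), +z =
distal->proximal (PD), origin at the midpoint of the condylar sphere centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError, FrameQualityError, ValidationError
from .meshes import PointCloud, TriangleMesh
from .registration import SphereFit, fit_sphere
from .rigid import RigidTransform

#: condylar sphere fits with RMS residual above this (mm) are rejected
CONDYLE_FIT_RMS_MAX = 1.0
#: minimum angle (degrees) between the ML axis and the plateau normal
MIN_AXIS_PLATEAU_ANGLE_DEG = 10.0


@dataclass(frozen=True)
class PlaneFit:
    """Total-least-squares plane: a point on it, the unit normal, and the RMS
    orthogonal residual of the fitted points."""

    point: np.ndarray
    normal: np.ndarray
    rms_residual: float


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame (axes as world vectors)."""

    origin: np.ndarray
    axis_ml: np.ndarray
    axis_ap: np.ndarray
    axis_pd: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        axes = np.vstack([self.axis_ml, self.axis_ap, self.axis_pd])
        if np.abs(axes @ axes.T - np.eye(3)).max() > 1e-9:
            raise ValidationError("frame axes are not orthonormal")
        if np.abs(np.cross(self.axis_ml, self.axis_ap) - self.axis_pd).max() > 1e-9:
            raise ValidationError("frame is not right-handed (ml x ap != pd)")
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")

    @property
    def world_to_frame(self) -> RigidTransform:
        """Transform taking world coordinates into frame coordinates
        (ML, AP, PD -> +x, +y, +z; origin -> 0)."""
        R = np.vstack([self.axis_ml, self.axis_ap, self.axis_pd])
        return RigidTransform(R, -R @ np.asarray(self.origin, float))

    def transformed(self, transform: RigidTransform) -> "AnatomicalFrame":
        return AnatomicalFrame(
            origin=transform.apply(self.origin),
            axis_ml=transform.apply_vectors(self.axis_ml),
            axis_ap=transform.apply_vectors(self.axis_ap),
            axis_pd=transform.apply_vectors(self.axis_pd),
            side=self.side,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(
                {
                    "origin_mm": np.asarray(self.origin).tolist(),
                    "axis_ml": np.asarray(self.axis_ml).tolist(),
                    "axis_ap": np.asarray(self.axis_ap).tolist(),
                    "axis_pd": np.asarray(self.axis_pd).tolist(),
                    "side": self.side,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AnatomicalFrame":
        data = json.loads(Path(path).read_text())
        return cls(
            origin=np.asarray(data["origin_mm"], float),
            axis_ml=np.asarray(data["axis_ml"], float),
            axis_ap=np.asarray(data["axis_ap"], float),
            axis_pd=np.asarray(data["axis_pd"], float),
            side=data.get("side", "right"),
        )


def fit_plane(points: PointCloud | np.ndarray, orient: np.ndarray | None = None) -> PlaneFit:
    """Total-least-squares plane through a point set.

    The normal is the smallest principal component of the centered points.
    ``orient`` (a reference direction) fixes the normal's sign; without it
    the sign is arbitrary.
    """
    p = points.points if isinstance(points, PointCloud) else np.atleast_2d(np.asarray(points, float))
    if len(p) < 3:
        raise ValidationError("plane fit needs at least 3 points")
    centroid = p.mean(axis=0)
    centered = p - centroid
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(1.0, float(np.abs(centered).max()))
    if s[1] <= 1e-9 * scale:
        raise DegenerateGeometryError("points are collinear; plane is underdetermined")
    normal = Vt[2]
    if orient is not None and np.dot(normal, np.asarray(orient, float)) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(point=centroid, normal=normal, rms_residual=rms)


def build_standard_frame(
    posterior_condyle_medial: PointCloud,
    posterior_condyle_lateral: PointCloud,
    medial_plateau: PointCloud,
    anterior_hint: PointCloud,
    side: str = "right",
) -> tuple[AnatomicalFrame, dict[str, SphereFit | PlaneFit]]:
    """Construct the standard-plane anatomical frame from landmark patches.

    Inputs are surface patches (sub-clouds) supplied by the user or the
    phantom generator: the two posterior condylar surfaces, the medial tibial
    plateau surface, and an anterior (trochlea-side) patch whose centroid
    fixes the AP sign.  Returns the frame plus the intermediate fits for
    quality inspection.

    Construction: ML = line through the condylar sphere centers; PD = medial
    plateau normal orthogonalized against ML and oriented proximally (toward
    the condyles); AP = PD x ML.  If AP points away from the anterior hint,
    ML and AP are jointly negated (left-knee mirroring), keeping the frame
    right-handed with AP anterior and PD proximal.
    """
    fit_med = fit_sphere(posterior_condyle_medial)
    fit_lat = fit_sphere(posterior_condyle_lateral)
    for name, f in (("medial", fit_med), ("lateral", fit_lat)):
        if f.rms_residual > CONDYLE_FIT_RMS_MAX:
            raise FrameQualityError(
                f"{name} posterior-condyle sphere fit residual {f.rms_residual:.3f} mm "
                f"exceeds {CONDYLE_FIT_RMS_MAX} mm"
            )
    origin = 0.5 * (fit_med.center + fit_lat.center)
    ml = fit_lat.center - fit_med.center
    norm = np.linalg.norm(ml)
    if norm < 1e-9:
        raise DegenerateGeometryError("condylar sphere centers coincide")
    ml = ml / norm

    plateau = fit_plane(medial_plateau, orient=origin - np.asarray(medial_plateau.centroid))
    # angle between the plateau normal and the ML axis; near 0 the axial
    # plane is unconstrained
    angle = np.degrees(np.arccos(np.clip(abs(np.dot(plateau.normal, ml)), -1.0, 1.0)))
    if angle < MIN_AXIS_PLATEAU_ANGLE_DEG:
        raise DegenerateGeometryError(
            f"plateau normal within {MIN_AXIS_PLATEAU_ANGLE_DEG} deg of the ML axis"
        )
    pd = plateau.normal - np.dot(plateau.normal, ml) * ml
    pd = pd / np.linalg.norm(pd)
    ap = np.cross(pd, ml)

    if np.dot(ap, np.asarray(anterior_hint.centroid) - origin) < 0:
        ml, ap = -ml, -ap

    frame = AnatomicalFrame(origin=origin, axis_ml=ml, axis_ap=ap, axis_pd=pd, side=side)
    fits = {"condyle_medial": fit_med, "condyle_lateral": fit_lat, "plateau": plateau}
    return frame, fits


def to_frame(mesh: TriangleMesh, frame: AnatomicalFrame) -> TriangleMesh:
    """Express a mesh in the anatomical frame (ML, AP, PD -> x, y, z)."""
    return mesh.transformed(frame.world_to_frame)


def cloud_to_frame(cloud: PointCloud, frame: AnatomicalFrame) -> PointCloud:
    return cloud.transformed(frame.world_to_frame)
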