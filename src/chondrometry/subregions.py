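"""Condylar subregion extraction on the cartilage surface.

Operates on a cartilage mesh expressed in the anatomical frame (x = ML,
y = AP anterior-positive, z = PD proximal-positive).  Two subregions are
defined per femoral condyle:

* 0-degree flexion (distal, weight-bearing): the weight-bearing region is
  bounded anteriorly by the medio-lateral line through the lowest (most
  distal) trochlear cartilage point and extends posteriorly 60% of the AP
  distance from that line to the condyle's most posterior cartilage point
  (length L per condyle).  The central third of that strip in AP is kept,
  then the ML width is reduced to 15% of the total ML cartilage width W,
  centered at the retained vertices' ML centroid.
* 90-degree flexion (posterior): a proximal-distal band of the posterior
  condylar cartilage centered at the most posterior point, with the same
  length as the 0-degree subregion (L/3), followed by the same 15%-of-W ML
  reduction about the band's ML centroid.

All selections are closed-interval coordinate predicates over the mesh
vertices; ties at extrema resolve to the lowest vertex index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptySubregionError, ValidationError
from .meshes import TriangleMesh


@dataclass(frozen=True)
class SubregionSpec:
    """The three dimensionless constants of the subregion construction:
    the 60% weight-bearing extent, the central-1/3 AP band, and the
    15%-of-W ML width."""

    wb_fraction: float = 0.60
    ap_band_fraction: float = 1.0 / 3.0
    ml_width_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("wb_fraction", "ap_band_fraction", "ml_width_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class CartilageExtent:
    """Landmark points and lengths of the articular cartilage in the
    anatomical frame: the lowest trochlear point, per-condyle most posterior
    points, total ML width W, and the weight-bearing lengths L_med/L_lat
    (already scaled by the weight-bearing fraction)."""

    trochlear_lowest_point: np.ndarray
    most_posterior_point_medial: np.ndarray
    most_posterior_point_lateral: np.ndarray
    W: float
    L_med: float
    L_lat: float
    condyle_split_ml: float

    def __post_init__(self) -> None:
        if self.W <= 0 or self.L_med <= 0 or self.L_lat <= 0:
            raise ValidationError("W, L_med, L_lat must all be positive")

    def L(self, condyle: str) -> float:
        return self.L_med if condyle == "medial" else self.L_lat

    def most_posterior_point(self, condyle: str) -> np.ndarray:
        return (
            self.most_posterior_point_medial
            if condyle == "medial"
            else self.most_posterior_point_lateral
        )


@dataclass(frozen=True)
class Subregion:
    """A vertex-index set on the cartilage mesh with the coordinate bounds
    that produced it."""

    vertex_indices: np.ndarray
    condyle: str
    flexion_deg: int
    centroid: np.ndarray
    ap_bounds: tuple[float, float] | None = None
    pd_bounds: tuple[float, float] | None = None
    ml_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.vertex_indices, dtype=np.int64)
        if idx.size == 0:
            raise EmptySubregionError("subregion has no vertices")
        if self.condyle not in ("medial", "lateral"):
            raise ValidationError("condyle must be 'medial' or 'lateral'")
        if self.flexion_deg not in (0, 90):
            raise ValidationError("flexion_deg must be 0 or 90")
        object.__setattr__(self, "vertex_indices", idx)

    def __len__(self) -> int:
        return int(self.vertex_indices.size)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(
                {
                    "condyle": self.condyle,
                    "flexion_deg": self.flexion_deg,
                    "vertex_indices": self.vertex_indices.tolist(),
                    "centroid_mm": np.asarray(self.centroid).tolist(),
                    "ap_bounds_mm": self.ap_bounds,
                    "pd_bounds_mm": self.pd_bounds,
                    "ml_bounds_mm": self.ml_bounds,
                },
                indent=2,
            )
        )
        return path


def _argmin_lowest_index(values: np.ndarray) -> int:
    """First index attaining the minimum (deterministic tie-break)."""
    return int(np.argmin(values))


def _condyle_mask(x: np.ndarray, split: float, condyle: str) -> np.ndarray:
    # medial->lateral maps to +x, so the medial condyle is the low-x side
    return x <= split if condyle == "medial" else x > split


def measure_cartilage_extent(
    cartilage_mesh: TriangleMesh,
    trochlea_indices: np.ndarray,
    wb_fraction: float = 0.60,
    condyle_split_ml: float | None = None,
) -> CartilageExtent:
    """Locate the extremal cartilage landmarks and lengths in the anatomical
    frame.

    ``trochlea_indices`` restricts the search for the lowest (most distal)
    trochlear point; the medial/lateral split defaults to that point's ML
    coordinate.  W is the full ML extent of the cartilage; L per condyle is
    ``wb_fraction`` times the AP distance from the trochlear line to that
    condyle's most posterior cartilage point.
    """
    v = cartilage_mesh.vertices
    trochlea_indices = np.asarray(trochlea_indices, dtype=np.int64)
    if trochlea_indices.size == 0:
        raise ValidationError("trochlea_indices is empty")
    if trochlea_indices.min() < 0 or trochlea_indices.max() >= len(v):
        raise ValidationError("trochlea index out of range")

    tro = v[trochlea_indices]
    lowest = tro[_argmin_lowest_index(tro[:, 2])]
    split = float(lowest[0]) if condyle_split_ml is None else float(condyle_split_ml)

    condyle_points = {}
    for condyle in ("medial", "lateral"):
        mask = _condyle_mask(v[:, 0], split, condyle)
        if not mask.any():
            raise ValidationError(f"no cartilage vertices on the {condyle} side of the split")
        side = v[mask]
        condyle_points[condyle] = side[_argmin_lowest_index(side[:, 1])]

    W = float(v[:, 0].max() - v[:, 0].min())
    y_t = float(lowest[1])
    L = {}
    for condyle in ("medial", "lateral"):
        d = y_t - float(condyle_points[condyle][1])
        if d <= 0:
            raise ValidationError(
                f"{condyle} most posterior point is anterior to the trochlear line"
            )
        L[condyle] = wb_fraction * d
    return CartilageExtent(
        trochlear_lowest_point=lowest,
        most_posterior_point_medial=condyle_points["medial"],
        most_posterior_point_lateral=condyle_points["lateral"],
        W=W,
        L_med=L["medial"],
        L_lat=L["lateral"],
        condyle_split_ml=split,
    )


def _ml_trim(
    v: np.ndarray, idx: np.ndarray, spec: SubregionSpec, extent: CartilageExtent, stage: str
) -> tuple[np.ndarray, tuple[float, float], np.ndarray]:
    """Reduce a vertex set's ML width to ml_width_fraction * W about the
    set's ML centroid; returns (indices, ml bounds, centroid of input set)."""
    centroid = v[idx].mean(axis=0)
    half = spec.ml_width_fraction * extent.W / 2.0
    lo, hi = float(centroid[0] - half), float(centroid[0] + half)
    keep = idx[(v[idx, 0] >= lo) & (v[idx, 0] <= hi)]
    if keep.size == 0:
        raise EmptySubregionError(f"ML-width reduction emptied the subregion at stage {stage!r}")
    return keep, (lo, hi), centroid


def subregion_0deg(
    cartilage_mesh: TriangleMesh,
    extent: CartilageExtent,
    spec: SubregionSpec = SubregionSpec(),
    condyle: str = "medial",
) -> Subregion:
    """Distal (weight-bearing, 0-degree flexion) subregion of one condyle."""
    v = cartilage_mesh.vertices
    y_t = float(extent.trochlear_lowest_point[1])
    L = extent.L(condyle)
    side = np.flatnonzero(_condyle_mask(v[:, 0], extent.condyle_split_ml, condyle))
    if side.size == 0:
        raise EmptySubregionError(f"no vertices on the {condyle} condyle")

    strip = side[(v[side, 1] >= y_t - L) & (v[side, 1] <= y_t)]
    if strip.size == 0:
        raise EmptySubregionError("weight-bearing strip is empty")

    # central AP band of the strip (length ap_band_fraction * L, centered)
    band_half = spec.ap_band_fraction * L / 2.0
    center = y_t - L / 2.0
    lo, hi = center - band_half, center + band_half
    band = strip[(v[strip, 1] >= lo) & (v[strip, 1] <= hi)]
    if band.size == 0:
        raise EmptySubregionError("central AP band is empty")

    keep, ml_bounds, centroid = _ml_trim(v, band, spec, extent, "0deg ML trim")
    return Subregion(
        vertex_indices=np.sort(keep),
        condyle=condyle,
        flexion_deg=0,
        centroid=centroid,
        ap_bounds=(float(lo), float(hi)),
        ml_bounds=ml_bounds,
    )


def subregion_90deg(
    cartilage_mesh: TriangleMesh,
    extent: CartilageExtent,
    spec: SubregionSpec = SubregionSpec(),
    condyle: str = "medial",
    length_from_0deg: float | None = None,
    anterior_cutoff_ap: float = 0.0,
) -> Subregion:
    """Posterior (90-degree flexion) subregion of one condyle.

    The proximal-distal band is centered at the condyle's most posterior
    cartilage point with length equal to the 0-degree subregion's AP length
    (``ap_band_fraction * L`` by default), restricted to the posterior aspect
    (AP below ``anterior_cutoff_ap``; the default 0 is the frame origin's AP
    coordinate, i.e. the condylar sphere centers).
    """
    v = cartilage_mesh.vertices
    L = extent.L(condyle)
    length = spec.ap_band_fraction * L if length_from_0deg is None else float(length_from_0deg)
    if length <= 0:
        raise ValidationError("length_from_0deg must be positive")
    posterior_pt = extent.most_posterior_point(condyle)
    z_p = float(posterior_pt[2])
    lo, hi = z_p - length / 2.0, z_p + length / 2.0

    side = np.flatnonzero(_condyle_mask(v[:, 0], extent.condyle_split_ml, condyle))
    band = side[
        (v[side, 2] >= lo) & (v[side, 2] <= hi) & (v[side, 1] <= anterior_cutoff_ap)
    ]
    if band.size == 0:
        raise EmptySubregionError("posterior PD band is empty")

    keep, ml_bounds, centroid = _ml_trim(v, band, spec, extent, "90deg ML trim")
    return Subregion(
        vertex_indices=np.sort(keep),
        condyle=condyle,
        flexion_deg=90,
        centroid=centroid,
        pd_bounds=(float(lo), float(hi)),
        ml_bounds=ml_bounds,
    )


def extract_all_subregions(
    cartilage_mesh: TriangleMesh,
    trochlea_indices: np.ndarray,
    spec: SubregionSpec = SubregionSpec(),
    condyle_split_ml: float | None = None,
    anterior_cutoff_ap: float = 0.0,
) -> tuple[CartilageExtent, dict[tuple[str, int], Subregion]]:
    """Convenience: measure the extent and extract all four subregions
    (medial/lateral x 0/90 degrees)."""
    extent = measure_cartilage_extent(
        cartilage_mesh, trochlea_indices, spec.wb_fraction, condyle_split_ml
    )
    out: dict[tuple[str, int], Subregion] = {}
    for condyle in ("medial", "lateral"):
        out[(condyle, 0)] = subregion_0deg(cartilage_mesh, extent, spec, condyle)
        out[(condyle, 90)] = subregion_90deg(
            cartilage_mesh, extent, spec, condyle, anterior_cutoff_ap=anterior_cutoff_ap
        )
    return extent, out
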