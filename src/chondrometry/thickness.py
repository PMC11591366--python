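"""Cartilage thickness mapping, study-level summaries, and precision
propagation.

Thickness at a cartilage-surface point is the minimum Euclidean distance
from that point to the registered bone (cartilage-free) surface — the
closest-point definition.  Per-subregion statistics are the arithmetic mean
and sample standard deviation over valid points; reported values are
additionally rounded to 0.1 mm as in the study-table convention.

Because thickness is the difference of two independently scanned surfaces,
a single-scan precision sigma propagates to a thickness precision
sigma_t = sqrt(sigma^2 + sigma^2) = sqrt(2) * sigma.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientCoverageError, ValidationError
from .meshes import TriangleMesh
from .subregions import Subregion

#: default ceiling (mm) above which a closest-point distance is considered a
#: geometry mismatch (e.g. a point over cartilage-free bone), not cartilage
DEFAULT_MAX_VALID_MM = 10.0

#: study tables report thickness to this precision (mm)
REPORT_DECIMALS = 1

CONDYLE_COLUMNS = [("medial", 0), ("lateral", 0), ("medial", 90), ("lateral", 90)]


def _round_report(x: float) -> float:
    """Round half away from zero at 0.1 mm, the table-report convention."""
    q = 10.0**REPORT_DECIMALS
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


@dataclass(eq=False)
class ThicknessMap:
    """Per-point thickness over one subregion.

    ``thickness_mm`` aligns with ``subregion.vertex_indices``; ``valid``
    flags points whose closest-point distance is at most the validity
    ceiling.  ``mean``/``sd`` are recomputed from the valid per-point values
    (sample SD, n-1).
    """

    subregion: Subregion
    thickness_mm: np.ndarray
    valid: np.ndarray
    max_valid_mm: float

    def __post_init__(self) -> None:
        t = np.asarray(self.thickness_mm, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("thickness and valid must be matching 1-D arrays")
        if t.shape[0] != len(self.subregion):
            raise ValidationError("thickness map length must match the subregion")
        if np.any(t[v] < 0):
            raise ValidationError("valid thickness values must be >= 0")
        self.thickness_mm = t
        self.valid = v

    @property
    def valid_values(self) -> np.ndarray:
        return self.thickness_mm[self.valid]

    @property
    def mean(self) -> float:
        return float(np.mean(self.valid_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.valid_values, ddof=1))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class PrecisionModel:
    """Two-scan precision propagation: sigma_thickness = sqrt(2) * sigma_scan."""

    sigma_scan: float
    sigma_thickness: float

    def __post_init__(self) -> None:
        if self.sigma_scan < 0:
            raise ValidationError("sigma_scan must be >= 0")
        if abs(self.sigma_thickness - math.sqrt(2.0) * self.sigma_scan) > 1e-12:
            raise ValidationError("sigma_thickness must equal sqrt(2) * sigma_scan")

    def relative_error(self, reference_thickness_mm: float) -> float:
        """sigma_t as a fraction of a reference thickness."""
        if reference_thickness_mm <= 0:
            raise ValidationError("reference thickness must be positive")
        return self.sigma_thickness / reference_thickness_mm


def propagate_precision(sigma_scan: float) -> PrecisionModel:
    """Propagate single-scan precision to thickness precision.

    Thickness is the difference of two independent scans of the same
    specimen, so the random errors add in quadrature:
    sigma_t = sqrt(sigma^2 + sigma^2) = sqrt(2) * sigma.
    """
    if sigma_scan < 0:
        raise ValidationError("sigma_scan must be >= 0")
    return PrecisionModel(sigma_scan=float(sigma_scan), sigma_thickness=math.sqrt(2.0) * float(sigma_scan))


def compute_thickness_map(
    cartilage_mesh: TriangleMesh,
    bone_mesh: TriangleMesh,
    subregion: Subregion,
    max_valid: float = DEFAULT_MAX_VALID_MM,
) -> ThicknessMap:
    """Closest-point thickness at every subregion vertex.

    Both meshes must already be registered into a common frame (the fiducial
    chain).  Distances above ``max_valid`` are flagged invalid and excluded
    from statistics; fewer than 10 valid points raises
    :class:`InsufficientCoverageError`.
    """
    if max_valid <= 0:
        raise ValidationError("max_valid must be positive")
    points = cartilage_mesh.vertices[subregion.vertex_indices]
    dists, _ = bone_mesh.surface_query().query(points)
    valid = dists <= max_valid
    if valid.sum() < 10:
        raise InsufficientCoverageError(
            f"only {int(valid.sum())} of {len(dists)} subregion points have a bone "
            f"surface within {max_valid} mm"
        )
    return ThicknessMap(subregion=subregion, thickness_mm=dists, valid=valid, max_valid_mm=max_valid)


def subregion_stats(thickness_map: ThicknessMap) -> tuple[float, float]:
    """Arithmetic mean and sample SD (mm) of the valid per-point
    thicknesses, rounded to the 0.1 mm report convention."""
    if thickness_map.n_valid < 2:
        raise ValidationError("need at least 2 valid points for mean/SD")
    return _round_report(thickness_map.mean), _round_report(thickness_map.sd)


# ---------------------------------------------------------------------------
# Study summary
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class StudySummary:
    """Summary of per-specimen subregion means: the wide table, the four
    column means, their overall mean (mean of column means), and the extreme
    cells with their labels.  All report values rounded to 0.1 mm."""

    table: pd.DataFrame
    column_means: dict[tuple[str, int], float]
    overall_mean: float
    min_cell: tuple[str, str, int, float]
    max_cell: tuple[str, str, int, float]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(
                {
                    "column_means_mm": {
                        f"{c}_{f}deg": m for (c, f), m in self.column_means.items()
                    },
                    "overall_mean_mm": self.overall_mean,
                    "min_cell": {
                        "specimen": self.min_cell[0],
                        "condyle": self.min_cell[1],
                        "flexion_deg": self.min_cell[2],
                        "mean_mm": self.min_cell[3],
                    },
                    "max_cell": {
                        "specimen": self.max_cell[0],
                        "condyle": self.max_cell[1],
                        "flexion_deg": self.max_cell[2],
                        "mean_mm": self.max_cell[3],
                    },
                },
                indent=2,
            )
        )
        return path


def summarize_study(per_specimen_stats: pd.DataFrame) -> StudySummary:
    """Summarize a long-form table of per-specimen subregion statistics.

    Expects columns ``specimen``, ``condyle`` (medial/lateral),
    ``flexion_deg`` (0/90), ``mean_mm`` (``sd_mm`` optional).  Every specimen
    must have all four subregion cells.  Column means are taken over
    specimens per (condyle, flexion) column; the overall mean is the
    arithmetic mean of the four column means; extremes are over cell means.
    """
    df = per_specimen_stats.copy()
    required = {"specimen", "condyle", "flexion_deg", "mean_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"summary table needs columns {sorted(required)}")
    if df.empty:
        raise ValidationError("summary table is empty")
    df["flexion_deg"] = df["flexion_deg"].astype(int)

    specimens = df["specimen"].unique()
    for spec_id in specimens:
        sub = df[df["specimen"] == spec_id]
        cells = set(zip(sub["condyle"], sub["flexion_deg"]))
        missing = [c for c in CONDYLE_COLUMNS if c not in cells]
        if missing:
            raise ValidationError(f"specimen {spec_id!r} is missing cells {missing}")

    wide = df.pivot_table(
        index="specimen", columns=["condyle", "flexion_deg"], values="mean_mm"
    )
    column_means = {
        (c, f): _round_report(float(wide[(c, f)].mean())) for c, f in CONDYLE_COLUMNS
    }
    overall = _round_report(
        float(np.mean([float(wide[(c, f)].mean()) for c, f in CONDYLE_COLUMNS]))
    )

    imin = df["mean_mm"].idxmin()
    imax = df["mean_mm"].idxmax()
    min_row, max_row = df.loc[imin], df.loc[imax]
    return StudySummary(
        table=wide,
        column_means=column_means,
        overall_mean=overall,
        min_cell=(
            str(min_row["specimen"]), str(min_row["condyle"]),
            int(min_row["flexion_deg"]), _round_report(float(min_row["mean_mm"])),
        ),
        max_cell=(
            str(max_row["specimen"]), str(max_row["condyle"]),
            int(max_row["flexion_deg"]), _round_report(float(max_row["mean_mm"])),
        ),
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_thickness_csv(
    thickness_map: ThicknessMap, cartilage_mesh: TriangleMesh, path: str | Path
) -> Path:
    """Per-point CSV: vertex_index, x/y/z (mm), thickness_mm, valid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    idx = thickness_map.subregion.vertex_indices
    pts = cartilage_mesh.vertices[idx]
    pd.DataFrame(
        {
            "vertex_index": idx,
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "z_mm": pts[:, 2],
            "thickness_mm": thickness_map.thickness_mm,
            "valid": thickness_map.valid.astype(int),
        }
    ).to_csv(path, index=False)
    return path
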