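"""Independent brute-force oracles used to validate the package's geometry.

These deliberately use different algorithmic decompositions from the
implementations they check (feature enumeration instead of Voronoi-region
classification, Kasa normal equations instead of Coope lstsq, Horn's
quaternion method instead of Kabsch SVD) so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def point_triangle_distance_features(q: np.ndarray, a, b, c) -> float:
    """Exact point-to-triangle distance by enumerating candidate closest
    features: the 3 vertices, the 3 edges (clamped projections), and the
    plane projection when it falls inside the triangle."""
    q, a, b, c = (np.asarray(x, float) for x in (q, a, b, c))
    candidates = [a, b, c]
    for p0, p1 in ((a, b), (b, c), (c, a)):
        e = p1 - p0
        t = np.clip(np.dot(q - p0, e) / np.dot(e, e), 0.0, 1.0)
        candidates.append(p0 + t * e)
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    if nn > 0:
        proj = q - (np.dot(q - a, n) / nn) * n
        # barycentric inside test
        v0, v1, v2 = b - a, c - a, proj - a
        d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
        d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
        denom = d00 * d11 - d01 * d01
        if denom > 0:
            v = (d11 * d20 - d01 * d21) / denom
            w = (d00 * d21 - d01 * d20) / denom
            if v >= 0 and w >= 0 and v + w <= 1:
                candidates.append(proj)
    return min(np.linalg.norm(q - cand) for cand in candidates)


def brute_force_mesh_distance(q: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> float:
    """Minimum distance from q to any triangle of the mesh, one triangle at
    a time."""
    tris = vertices[faces]
    return min(point_triangle_distance_features(q, *tri) for tri in tris)


def kasa_sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Kasa algebraic sphere fit via the normal equations of
    |p|^2 = 2 c.p + (r^2 - |c|^2)."""
    p = np.asarray(points, float)
    A = np.c_[2.0 * p, np.ones(len(p))]
    b = (p**2).sum(axis=1)
    sol = np.linalg.solve(A.T @ A, A.T @ b)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def horn_rigid_transform(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horn's closed-form absolute orientation (unit quaternion method).
    Returns (R, t) with target ~= R @ source + t."""
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    A = src - mu_s
    B = tgt - mu_t
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(N)
    q = v[:, np.argmax(w)]
    q0, qx, qy, qz = q
    R = np.array(
        [
            [q0**2 + qx**2 - qy**2 - qz**2, 2 * (qx * qy - q0 * qz), 2 * (qx * qz + q0 * qy)],
            [2 * (qy * qx + q0 * qz), q0**2 - qx**2 + qy**2 - qz**2, 2 * (qy * qz - q0 * qx)],
            [2 * (qz * qx - q0 * qy), 2 * (qz * qy + q0 * qx), q0**2 - qx**2 - qy**2 + qz**2],
        ]
    )
    t = mu_t - R @ mu_s
    return R, t


def subregion_0deg_filter(
    vertices: np.ndarray,
    split: float,
    condyle: str,
    y_trochlea: float,
    L: float,
    ap_band_fraction: float,
    ml_width_fraction: float,
    W: float,
) -> np.ndarray:
    """Brute-force predicate filter reproducing the 0-degree subregion rules
    vertex by vertex."""
    x, y = vertices[:, 0], vertices[:, 1]
    side = x <= split if condyle == "medial" else x > split
    strip = side & (y >= y_trochlea - L) & (y <= y_trochlea)
    center = y_trochlea - L / 2.0
    half = ap_band_fraction * L / 2.0
    band = strip & (y >= center - half) & (y <= center + half)
    idx = np.flatnonzero(band)
    cx = vertices[idx].mean(axis=0)[0]
    hw = ml_width_fraction * W / 2.0
    keep = idx[(x[idx] >= cx - hw) & (x[idx] <= cx + hw)]
    return np.sort(keep)


def subregion_90deg_filter(
    vertices: np.ndarray,
    split: float,
    condyle: str,
    z_posterior: float,
    length: float,
    anterior_cutoff: float,
    ml_width_fraction: float,
    W: float,
) -> np.ndarray:
    """Brute-force predicate filter for the 90-degree subregion rules."""
    x, y, z = vertices[:, 0], vertices[:, 1], vertices[:, 2]
    side = x <= split if condyle == "medial" else x > split
    band = side & (z >= z_posterior - length / 2) & (z <= z_posterior + length / 2) & (y <= anterior_cutoff)
    idx = np.flatnonzero(band)
    cx = vertices[idx].mean(axis=0)[0]
    hw = ml_width_fraction * W / 2.0
    keep = idx[(x[idx] >= cx - hw) & (x[idx] <= cx + hw)]
    return np.sort(keep)
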