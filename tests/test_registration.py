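"""Fiducial-sphere fitting, marker correspondence, and rigid registration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chondrometry as cm
from chondrometry.registration import AMBIGUITY_TOL_MM

from conftest import random_rotation
from helpers_oracles import horn_rigid_transform, kasa_sphere_fit


def sphere_points(rng, center, radius, n, hemisphere=False, sigma=0.0):
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if hemisphere:
        dirs[:, 2] = np.abs(dirs[:, 2])
    r = np.full(n, float(radius)) + (rng.normal(0, sigma, n) if sigma > 0 else 0.0)
    return np.asarray(center, float) + r[:, None] * dirs


class TestFitSphere:
    def test_exact_octahedral_points(self):
        pts = np.array(
            [[14, 0, 0], [-14, 0, 0], [0, 14, 0], [0, -14, 0], [0, 0, 14], [0, 0, -14]],
            float,
        ) + [10, -5, 3]
        fit = cm.fit_sphere(pts)
        np.testing.assert_allclose(fit.center, [10, -5, 3], atol=1e-9)
        assert fit.radius == pytest.approx(14.0, abs=1e-9)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_on_noiseless_hemisphere(self, rng):
        """Partial marker visibility: the geometric fit stays exact with
        points on only one hemisphere."""
        pts = sphere_points(rng, [1.5, -2.0, 7.0], 12.0, 200, hemisphere=True)
        fit = cm.fit_sphere(pts)
        assert np.abs(fit.center - [1.5, -2.0, 7.0]).max() < 1e-6
        assert abs(fit.radius - 12.0) < 1e-6

    def test_noisy_fit_center_accuracy_vs_algebraic_oracle(self, rng):
        """With 500 points and 0.05 mm surface noise the geometric center is
        within 0.02 mm of truth and close to the independent algebraic fit."""
        truth = np.array([3.0, -1.0, 2.0])
        pts = sphere_points(rng, truth, 14.0, 500, sigma=0.05)
        fit = cm.fit_sphere(pts)
        assert np.linalg.norm(fit.center - truth) < 0.02
        c_alg, r_alg = kasa_sphere_fit(pts)
        assert np.linalg.norm(fit.center - c_alg) < 0.01
        assert abs(fit.radius - r_alg) < 0.01
        assert fit.rms_residual == pytest.approx(0.05, rel=0.2)

    def test_center_bias_bound_on_full_sphere(self, rng):
        """Zero-mean noise on symmetric full-sphere sampling leaves the
        center nearly unbiased: |bias| < 3 * sigma / sqrt(n)."""
        truth = np.zeros(3)
        n, sigma = 400, 0.05
        centers = np.array(
            [cm.fit_sphere(sphere_points(rng, truth, 14.0, n, sigma=sigma)).center for _ in range(40)]
        )
        bias = np.linalg.norm(centers.mean(axis=0))
        assert bias < 3 * sigma / np.sqrt(n)

    def test_fixed_radius_allows_three_points(self):
        """Three points constrain a fixed-radius sphere up to a mirror pair;
        either solution must have zero residual."""
        pts = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 10]], float)
        fit = cm.fit_sphere(pts, fixed_radius=10.0)
        assert fit.radius == 10.0
        assert fit.rms_residual < 1e-9
        np.testing.assert_allclose(
            np.linalg.norm(pts - fit.center, axis=1), 10.0, atol=1e-9
        )

    def test_degenerate_inputs_rejected(self, rng):
        coplanar = np.c_[rng.normal(size=(20, 2)), np.zeros(20)]
        with pytest.raises(cm.DegenerateGeometryError):
            cm.fit_sphere(coplanar)
        with pytest.raises(cm.ValidationError):
            cm.fit_sphere(np.zeros((3, 3)) + np.eye(3))  # < 4 points, free radius


class TestMatchMarkers:
    def _marker_set(self, centers, labels, scan_id="s"):
        markers = {
            lb: cm.SphereFit(center=np.asarray(c, float), radius=12.0, rms_residual=0.0, n_points=10)
            for lb, c in zip(labels, centers)
        }
        return cm.MarkerSet(markers=markers, scan_id=scan_id)

    def test_shared_labels_pair_identically(self):
        centers = [[0, 0, 0], [50, 0, 0], [0, 60, 0], [20, 20, 40]]
        s = self._marker_set(centers, ["A", "B", "C", "D"])
        pairs, resid = cm.match_markers(s, s)
        assert pairs == tuple((lb, lb) for lb in "ABCD")
        assert resid == 0.0

    def test_geometric_matching_recovers_shuffled_labels(self, rng):
        """Renamed + permuted + rigidly moved markers are re-paired by
        distance-matrix matching."""
        centers = np.array(
            [[0, 0, 0], [55, 5, -3], [10, 62, 8], [25, 18, 45], [-30, 40, 12]], float
        )
        T = cm.RigidTransform(random_rotation(rng), [4.0, -7.0, 2.0])
        perm = [3, 0, 4, 1, 2]
        set_a = self._marker_set(centers, [f"A{i}" for i in range(5)])
        set_b = self._marker_set(T.apply(centers[perm]), [f"B{i}" for i in range(5)])
        pairs, resid = cm.match_markers(set_a, set_b)
        assert resid < 1e-9
        recovered = {a: b for a, b in pairs}
        for bi, ai in enumerate(perm):
            assert recovered[f"A{ai}"] == f"B{bi}"

    def test_symmetric_configuration_is_ambiguous(self):
        """An isosceles marker triangle admits two equally good assignments."""
        centers = np.array([[0, 0, 0], [40, 0, 0], [20, 30, 0]], float)
        set_a = self._marker_set(centers, ["A1", "A2", "A3"])
        set_b = self._marker_set(centers, ["B1", "B2", "B3"])
        with pytest.raises(cm.AmbiguousMatchError):
            cm.match_markers(set_a, set_b)
        assert AMBIGUITY_TOL_MM == pytest.approx(0.05)

    def test_too_few_markers_rejected(self):
        s2 = self._marker_set([[0, 0, 0], [10, 0, 0]], ["A", "B"])
        s4 = self._marker_set([[0, 0, 0], [50, 0, 0], [0, 60, 0], [20, 20, 40]], list("ABCD"))
        with pytest.raises(cm.ValidationError):
            cm.match_markers(s2, s4)


class TestEstimateRigidTransform:
    def test_identity_on_equal_sets(self, rng):
        pts = rng.normal(size=(6, 3)) * 30
        res = cm.estimate_rigid_transform(pts, pts)
        assert res.transform.almost_equal(cm.RigidTransform.identity(), tol=1e-12)
        assert res.fre_rms < 1e-12

    def test_recovers_known_motion(self, rng):
        pts = rng.normal(size=(6, 3)) * 30
        T = cm.RigidTransform.from_axis_angle([0, 0, 1], np.radians(30), [1, 2, 3])
        res = cm.estimate_rigid_transform(pts, T.apply(pts))
        assert res.transform.almost_equal(T, tol=1e-9)
        assert res.fre_rms < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_exact_for_any_proper_rigid_motion(self, seed):
        """Machine-precision recovery of arbitrary proper rigid motions on
        noiseless correspondences, cross-checked against Horn's quaternion
        method."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(5, 3)) * 40
        T = cm.RigidTransform(random_rotation(rng), rng.normal(size=3) * 20)
        res = cm.estimate_rigid_transform(pts, T.apply(pts))
        assert np.abs(res.transform.rotation - T.rotation).max() < 1e-9
        assert np.abs(res.transform.translation - T.translation).max() < 1e-9
        R_h, t_h = horn_rigid_transform(pts, T.apply(pts))
        assert np.abs(res.transform.rotation - R_h).max() < 1e-7
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_centers_fre_and_accuracy(self, rng):
        """Six centers with 0.05 mm Gaussian perturbation: FRE in a plausible
        band and the recovered motion close to truth (also vs Horn oracle)."""
        pts = rng.normal(size=(6, 3)) * 40
        T = cm.RigidTransform(random_rotation(rng), rng.normal(size=3) * 10)
        noisy_target = T.apply(pts) + rng.normal(0, 0.05, size=(6, 3))
        res = cm.estimate_rigid_transform(pts, noisy_target)
        assert 0.02 <= res.fre_rms <= 0.10
        delta = res.transform.compose(T.inverse())
        assert np.degrees(delta.rotation_angle_rad()) < 0.5
        R_h, t_h = horn_rigid_transform(pts, noisy_target)
        assert np.abs(res.transform.rotation - R_h).max() < 1e-7
        assert np.abs(res.transform.translation - t_h).max() < 1e-7

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(cm.DegenerateGeometryError):
            cm.estimate_rigid_transform(src, src + [0, 1, 0])

    def test_never_returns_reflection(self, rng):
        """Near-planar configurations tempt the SVD toward a reflection; the
        determinant correction must always yield det +1."""
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * np.array([30, 30, 0.01])
            T = cm.RigidTransform(random_rotation(rng), rng.normal(size=3))
            res = cm.estimate_rigid_transform(pts, T.apply(pts) + rng.normal(0, 0.5, size=(4, 3)))
            assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_chain_consistency(self, rng):
        """A->B then B->C composes to exactly A->C on noiseless data."""
        pts = rng.normal(size=(7, 3)) * 25
        T1 = cm.RigidTransform(random_rotation(rng), rng.normal(size=3) * 5)
        T2 = cm.RigidTransform(random_rotation(rng), rng.normal(size=3) * 5)
        ab = cm.estimate_rigid_transform(pts, T1.apply(pts)).transform
        bc = cm.estimate_rigid_transform(T1.apply(pts), T2.apply(T1.apply(pts))).transform
        ac = cm.estimate_rigid_transform(pts, T2.apply(T1.apply(pts))).transform
        assert bc.compose(ab).almost_equal(ac, tol=1e-9)


class TestTransformPropagation:
    def test_identity_registration_leaves_mesh(self, unit_square_patch):
        reg = cm.estimate_rigid_transform(np.eye(3) * 10, np.eye(3) * 10)
        out = cm.propagate_to_cartilage_model(reg, unit_square_patch)
        np.testing.assert_allclose(out.vertices, unit_square_patch.vertices, atol=1e-12)

    def test_pure_translation(self, unit_square_patch):
        src = np.eye(3) * 10
        reg = cm.estimate_rigid_transform(src, src + [0, 0, 5])
        out = cm.propagate_to_cartilage_model(reg, unit_square_patch)
        np.testing.assert_allclose(out.vertices, unit_square_patch.vertices + [0, 0, 5], atol=1e-9)

    def test_round_trip_restores_vertices(self, rng, unit_square_patch):
        T = cm.RigidTransform(random_rotation(rng), rng.normal(size=3) * 8)
        back = unit_square_patch.transformed(T).transformed(T.inverse())
        np.testing.assert_allclose(back.vertices, unit_square_patch.vertices, atol=1e-9)


class TestMarkerCsvRoundTrip:
    def test_write_read(self, tmp_path, rng):
        centers = rng.normal(size=(4, 3)) * 40
        markers = {
            f"M{i}": cm.SphereFit(center=c, radius=12.0, rms_residual=0.01, n_points=50)
            for i, c in enumerate(centers)
        }
        ms = cm.MarkerSet(markers=markers, scan_id="t")
        from chondrometry.registration import read_marker_centers_csv, write_marker_centers_csv

        p = write_marker_centers_csv(ms, tmp_path / "markers.csv")
        back = read_marker_centers_csv(p)
        assert set(back.labels) == set(ms.labels)
        for lb in ms.labels:
            np.testing.assert_allclose(back.markers[lb].center, ms.markers[lb].center, atol=1e-9)
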