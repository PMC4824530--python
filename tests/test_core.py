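"""Triangulation, patch validation, splitting and the iterative loop."""

import numpy as np
import pytest

from hpft import HpftConfig, fixtures
from hpft.core import (
    AffineHomography,
    TriPatch,
    barycentric_point,
    epipolar_segment,
    estimate_affine_homography,
    hpft_register,
    incircle_center,
    match_point_on_segment,
    patch_ncc,
    select_segment_candidate,
    triangulate_matches,
)
from hpft.features import DegenerateGeometryError, FundamentalMatrix, MatchPair


def _cross2(a, b):
    return float(a[0] * b[1] - a[1] * b[0])


def _mp(r, t):
    return MatchPair(ref=np.array(r, dtype=float), tgt=np.array(t, dtype=float), distance=0.0)


def _patch(ref, tgt=None):
    ref = np.asarray(ref, dtype=float)
    tgt = ref if tgt is None else np.asarray(tgt, dtype=float)
    return TriPatch(vertex_ids=np.arange(3), ref_triangle=ref, tgt_triangle=tgt)


class TestTriangulate:
    def test_three_matches_one_patch(self):
        ms = [_mp([0, 0], [0, 0]), _mp([10, 0], [10, 0]), _mp([0, 10], [0, 10])]
        assert len(triangulate_matches(ms)) == 1

    def test_square_gives_two_patches(self):
        ms = [_mp(p, p) for p in [[0, 0], [10, 0], [10, 10], [0, 10]]]
        assert len(triangulate_matches(ms)) == 2

    def test_reflected_correspondence_marked_unmatchable(self):
        ms = [
            _mp([0, 0], [10, 0]),  # swapped with the next point: flips orientation
            _mp([10, 0], [0, 0]),
            _mp([0, 10], [0, 10]),
        ]
        patches = triangulate_matches(ms)
        assert len(patches) == 1 and not patches[0].matchable

    def test_collinear_errors(self):
        ms = [_mp([i, 0], [i, 0]) for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            triangulate_matches(ms)


class TestAffineHomography:
    def test_identity(self):
        tri = np.array([[0, 0], [7, 1], [2, 9]], dtype=float)
        H = estimate_affine_homography(_patch(tri)).H
        assert np.allclose(H, np.eye(3), atol=1e-12)

    def test_pure_translation(self):
        src = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        dst = np.array([[2, 3], [3, 3], [2, 4]], dtype=float)
        H = estimate_affine_homography(_patch(src, dst)).H
        assert np.allclose(H[:2, :2], np.eye(2), atol=1e-12)
        assert np.allclose(H[:2, 2], [2, 3], atol=1e-12)

    def test_agrees_with_six_by_six_solve(self):
        """Exact 3-point fit equals the generic 6-unknown linear system."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            src = rng.uniform(0, 100, (3, 2))
            dst = rng.uniform(0, 100, (3, 2))
            if abs(_cross2(src[1] - src[0], src[2] - src[0])) < 1.0:
                continue
            H = estimate_affine_homography(_patch(src, dst)).H
            A = np.zeros((6, 6))
            b = np.zeros(6)
            for i, (s, d) in enumerate(zip(src, dst)):
                A[2 * i, :3] = [s[0], s[1], 1]
                A[2 * i + 1, 3:] = [s[0], s[1], 1]
                b[2 * i], b[2 * i + 1] = d
            x = np.linalg.solve(A, b)
            assert np.allclose(H[0], [x[0], x[1], x[2]], atol=1e-9)
            assert np.allclose(H[1], [x[3], x[4], x[5]], atol=1e-9)
            assert np.allclose(H[2], [0, 0, 1])
            resid = np.abs(src @ H[:2, :2].T + H[:2, 2] - dst)
            assert resid.max() < 1e-9

    def test_degenerate_reference_errors(self):
        tri = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            estimate_affine_homography(_patch(tri))


class TestBarycentric:
    def test_vertex_limits(self):
        tri = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        p = _patch(tri)
        assert np.allclose(barycentric_point(p, 1 - 1e-9, 1e-10), tri[0], atol=1e-6)
        assert np.allclose(barycentric_point(p, 1e-10, 1e-10), tri[2], atol=1e-6)

    def test_centroid(self):
        tri = np.array([[0, 0], [9, 0], [0, 9]], dtype=float)
        assert np.allclose(barycentric_point(_patch(tri), 1 / 3, 1 / 3), tri.mean(axis=0))

    def test_interior_by_half_plane_oracle(self):
        rng = np.random.default_rng(4)
        tri = np.array([[3, 2], [40, 10], [15, 35]], dtype=float)
        p = _patch(tri)
        for _ in range(100):
            s = rng.uniform(0.01, 0.8)
            t = rng.uniform(0.01, 0.98 - s)
            q = barycentric_point(p, s, t)
            for i in range(3):
                a, b = tri[i], tri[(i + 1) % 3]
                c = tri[(i + 2) % 3]
                side = _cross2(b - a, q - a) * _cross2(b - a, c - a)
                assert side > 0  # strictly same side as the opposite vertex

    def test_out_of_range_rejected(self):
        p = _patch(np.array([[0, 0], [1, 0], [0, 1]], dtype=float))
        with pytest.raises(ValueError):
            barycentric_point(p, 0.7, 0.7)


class TestPatchNcc:
    def test_identical_patch_scores_one(self, small_texture):
        tri = np.array([[20, 20], [100, 30], [50, 90]], dtype=float)
        d = patch_ncc(small_texture, small_texture, _patch(tri), AffineHomography(np.eye(3)))
        assert abs(d - 1.0) < 1e-9

    def test_inverted_patch_scores_minus_one(self, small_texture):
        tri = np.array([[20, 20], [100, 30], [50, 90]], dtype=float)
        inv = (255 - small_texture.astype(int)).astype(np.uint8)
        d = patch_ncc(small_texture, inv, _patch(tri), AffineHomography(np.eye(3)))
        assert abs(d + 1.0) < 1e-9

    def test_independent_textures_decorrelated(self):
        """|NCC| < 0.3 for nearly all independent texture pairs."""
        tri = np.array([[10, 10], [80, 20], [40, 70]], dtype=float)
        low = 0
        n = 100
        for s in range(n):
            a = fixtures.generate_textured_plane(96, 96, seed=1000 + s)
            b = fixtures.generate_textured_plane(96, 96, seed=2000 + s)
            d = patch_ncc(a, b, _patch(tri), AffineHomography(np.eye(3)))
            low += abs(d) < 0.3
        assert low >= 97

    def test_flat_patch_unvalidatable(self):
        img = np.full((64, 64), 90, dtype=np.uint8)
        tri = np.array([[5, 5], [50, 10], [20, 50]], dtype=float)
        assert patch_ncc(img, img, _patch(tri), AffineHomography(np.eye(3))) is None

    def test_tiny_patch_unvalidatable(self, small_texture):
        tri = np.array([[5, 5], [8, 5], [5, 8]], dtype=float)
        assert (
            patch_ncc(small_texture, small_texture, _patch(tri), AffineHomography(np.eye(3)))
            is None
        )


class TestIncircle:
    def test_equilateral_centroid(self):
        tri = np.array([[0, 0], [2, 0], [1, np.sqrt(3)]])
        assert np.allclose(incircle_center(tri), tri.mean(axis=0), atol=1e-12)

    def test_right_triangle_closed_form(self):
        tri = np.array([[0, 0], [4, 0], [0, 3]], dtype=float)
        assert np.allclose(incircle_center(tri), [1.0, 1.0], atol=1e-12)

    def test_strictly_interior(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tri = rng.uniform(0, 100, (3, 2))
            if abs(_cross2(tri[1] - tri[0], tri[2] - tri[0])) < 1.0:
                continue
            c = incircle_center(tri)
            for i in range(3):
                a, b = tri[i], tri[(i + 1) % 3]
                v = tri[(i + 2) % 3]
                assert _cross2(b - a, c - a) * _cross2(b - a, v - a) > 0


class TestEpipolarSegment:
    F_HORIZ = FundamentalMatrix(F=np.array([[0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]]))

    def test_endpoints_on_triangle_boundary(self):
        tri = np.array([[0, 0], [40, 0], [20, 40]], dtype=float)
        seg = epipolar_segment(self.F_HORIZ, np.array([5.0, 10.0]), tri)
        assert seg is not None
        for end in seg:
            d = []
            for i in range(3):
                a, b = tri[i], tri[(i + 1) % 3]
                t = np.clip(np.dot(end - a, b - a) / np.dot(b - a, b - a), 0, 1)
                d.append(np.linalg.norm(a + t * (b - a) - end))
            assert min(d) < 1e-9

    def test_line_missing_triangle(self):
        tri = np.array([[0, 0], [40, 0], [20, 40]], dtype=float)
        assert epipolar_segment(self.F_HORIZ, np.array([5.0, 90.0]), tri) is None

    def test_against_dense_sampling_oracle(self):
        rng = np.random.default_rng(6)
        from hpft.features import epipolar_line

        for _ in range(50):
            tri = rng.uniform(0, 100, (3, 2))
            if abs(_cross2(tri[1] - tri[0], tri[2] - tri[0])) < 50:
                continue
            F = FundamentalMatrix(F=rng.normal(size=(3, 3)))
            p = rng.uniform(0, 100, 2)
            seg = epipolar_segment(F, p, tri)
            a, b, c = epipolar_line(F, p)
            d = np.array([-b, a])
            P0 = np.array([-a * c, -b * c])
            ts = np.linspace(-300, 300, 1000)
            pts = P0[None] + ts[:, None] * d[None]
            inside = np.array(
                [
                    all(
                        _cross2(tri[(i + 1) % 3] - tri[i], q - tri[i])
                        * _cross2(tri[(i + 1) % 3] - tri[i], tri[(i + 2) % 3] - tri[i])
                        >= 0
                        for i in range(3)
                    )
                    for q in pts
                ]
            )
            if seg is None:
                # no sampled point may be clearly interior
                assert inside.sum() <= 2
            else:
                lo = np.dot(seg[0] - P0, d) / np.dot(d, d)
                hi = np.dot(seg[1] - P0, d) / np.dot(d, d)
                lo, hi = sorted([lo, hi])
                for t, flag in zip(ts, inside):
                    if flag:
                        assert lo - 0.5 <= t <= hi + 0.5


class TestSegmentCandidateRule:
    def test_clear_winner_accepted(self):
        assert select_segment_candidate(np.array([0.05, 0.90, 0.85]), epsilon=0.5) == 0

    def test_ambiguous_ratio_rejected(self):
        assert select_segment_candidate(np.array([0.45, 0.50]), epsilon=0.5) is None

    def test_weak_minimum_rejected(self):
        assert select_segment_candidate(np.array([0.70, 4.0]), epsilon=0.5) is None

    def test_single_candidate_only_epsilon_applies(self):
        assert select_segment_candidate(np.array([0.1]), epsilon=0.35) == 0
        assert select_segment_candidate(np.array([0.5]), epsilon=0.35) is None


class TestMatchPointOnSegment:
    def test_recovers_known_correspondence(self, plane_scene, affine_truth):
        cfg = HpftConfig()
        p = np.array([280.0, 240.0])
        truth = affine_truth[:2, :2] @ p + affine_truth[:2, 2]
        # horizontal segment through the true position
        seg = np.array([truth - [25, 0], truth + [25, 0]])
        m = match_point_on_segment(
            plane_scene.reference_image, plane_scene.target_image, p, seg, cfg
        )
        assert m is not None
        assert np.hypot(*(m.tgt - truth)) <= 2.0


class TestRegister:
    def test_identical_images_fixpoint(self, small_texture):
        res = hpft_register(small_texture, small_texture, None, HpftConfig(seed=5))
        assert res.iterations == 1
        assert all(m.distance < 1e-9 for m in res.matches)
        assert len(res.patches) > 0
        assert all(abs(pm.dif_h - 1.0) < 1e-9 for pm in res.patches)

    def test_plane_recovery_within_two_px(self, plane_registration, affine_truth):
        A = affine_truth
        ref = np.stack([m.ref for m in plane_registration.matches])
        tgt = np.stack([m.tgt for m in plane_registration.matches])
        err = np.hypot(*(ref @ A[:2, :2].T + A[:2, 2] - tgt).T)
        assert (err <= 2.0).mean() >= 0.9

    def test_accepted_patch_homographies_near_truth(self, plane_registration, affine_truth):
        A = affine_truth
        for pm in plane_registration.patches:
            v = pm.patch.ref_triangle
            pred = pm.H.apply(v)
            truth = v @ A[:2, :2].T + A[:2, 2]
            assert np.hypot(*(pred - truth).T).max() < 2.0

    def test_piecewise_fold_is_refined(self, piecewise_registration):
        res = piecewise_registration
        # some straddling patch failed validation and was split via centers
        assert any(m.source.startswith("center") for m in res.matches)
        assert len(res.matches) > res.n_initial_inliers

    def test_monotone_growth_and_termination(self, plane_registration, piecewise_registration):
        for res in (plane_registration, piecewise_registration):
            assert 1 <= res.iterations <= HpftConfig().max_iterations
            pts = [t["total_points"] for t in res.trace]
            pat = [t["total_patches"] for t in res.trace]
            assert all(b >= a for a, b in zip(pts, pts[1:]))
            assert all(b >= a for a, b in zip(pat, pat[1:]))

    def test_seeded_determinism(self, small_texture):
        H = np.array([[1, 0, 4.0], [0, 1, -2.0], [0, 0, 1]])
        scene = fixtures.warp_scene(small_texture, H, noise_sigma=3.0, seed=8)
        a = hpft_register(scene.reference_image, scene.target_image, None, HpftConfig(seed=9))
        b = hpft_register(scene.reference_image, scene.target_image, None, HpftConfig(seed=9))
        assert len(a.matches) == len(b.matches)
        assert all(
            np.array_equal(x.ref, y.ref) and np.array_equal(x.tgt, y.tgt)
            for x, y in zip(a.matches, b.matches)
        )
        assert a.trace == b.trace

    def test_exact_truth_from_exact_correspondences(self, small_texture):
        """Noise-free affine scene: patches built on exact correspondences
        reproduce the truth matrix to 1e-6."""
        H = np.array([[0.99, -0.02, 5.0], [0.03, 1.01, -3.0], [0, 0, 1]])
        rng = np.random.default_rng(10)
        pts = np.column_stack([rng.uniform(10, 180, 30), rng.uniform(10, 150, 30)])
        ms = [_mp(p, H[:2, :2] @ p + H[:2, 2]) for p in pts]
        for patch in triangulate_matches(ms):
            if not patch.matchable:
                continue
            Hest = estimate_affine_homography(patch).H
            assert np.allclose(Hest, H, atol=1e-6)

    def test_mismatched_shapes_rejected(self, small_texture):
        with pytest.raises(ValueError):
            hpft_register(small_texture, small_texture[:-10], None, HpftConfig())
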