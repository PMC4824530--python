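"""The iterative homographic-patch registration algorithm.

The working hypothesis is that a smooth internal organ surface is composed
of many small planar patches, so that within each patch the two views are
related by a homography — and because patches are small, by its 6-parameter
affine form.  The algorithm:

1. detects features and initial matches, keeps epipolar inliers;
2. clusters the matched reference points into Delaunay triangles; each
   triangle's affine map is fixed exactly by its three vertex
   correspondences, and the planar hypothesis is validated by normalized
   cross-correlation (NCC) between the reference patch interior and its
   warped counterpart;
3. patches that fail validation (typically triangles straddling a fold)
   are refined: the triangle's incircle center is matched along the
   intersection of its epipolar line with the corresponding target
   triangle, the symmetric operation runs from the target side, and every
   accepted center point joins the match set;
4. the triangulation is rebuilt from the grown match set and the loop
   repeats until no new point and no new patch appears.

Growing the match set only ever subdivides failed area, so the iteration
terminates; match and patch sets grow monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from . import preprocess
from .features import (
    DegenerateGeometryError,
    DescriptorExtractor,
    FundamentalMatrix,
    MatchPair,
    detect_features,
    epipolar_line,
    estimate_fundamental,
    initial_match,
)

__all__ = [
    "TriPatch",
    "AffineHomography",
    "PatchMatch",
    "RegistrationResult",
    "HpftConfig",
    "triangulate_matches",
    "estimate_affine_homography",
    "barycentric_point",
    "patch_ncc",
    "incircle_center",
    "epipolar_segment",
    "match_point_on_segment",
    "select_segment_candidate",
    "hpft_register",
    "propagate_points",
]


@dataclass
class HpftConfig:
    """Tunables of the iterative registration.

    epsilon : absolute descriptor-distance gate for center matches, in
        squared-normalized-descriptor units (range [0, 4]).
    ratio : nearest/second-nearest rejection threshold.
    ncc_accept : minimum patch NCC for the planar hypothesis to be accepted.
    min_patch_area : reference-triangle area (px^2) below which a failed
        patch is abandoned instead of split.
    fb_threshold : forward-backward error (px) below which a tracked
        feature counts as reliable.
    budget : initial feature budget per frame.
    """

    epsilon: float = 0.35
    ratio: float = 0.8
    ncc_accept: float = 0.9
    min_patch_area: float = 25.0
    max_iterations: int = 50
    fb_threshold: float = 4.0
    budget: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must be in (0, 1)")
        if not 0 < self.ncc_accept <= 1:
            raise ValueError("ncc_accept must be in (0, 1]")
        if self.min_patch_area <= 0:
            raise ValueError("min_patch_area must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.budget < 4:
            raise ValueError("budget must be >= 4")


@dataclass
class TriPatch:
    vertex_ids: np.ndarray  # 3 indices into the match set
    ref_triangle: np.ndarray  # (3, 2)
    tgt_triangle: np.ndarray  # (3, 2)
    matchable: bool = True  # False if target triangle degenerate/flipped


@dataclass
class AffineHomography:
    H: np.ndarray  # 3x3, last row exactly (0, 0, 1)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.H[:2, :2].T + self.H[:2, 2]


@dataclass
class PatchMatch:
    patch: TriPatch
    H: AffineHomography
    dif_h: float


@dataclass
class RegistrationResult:
    matches: list[MatchPair]
    patches: list[PatchMatch]
    iterations: int
    trace: list[dict] = field(default_factory=list)
    fundamental: FundamentalMatrix | None = None
    n_initial_inliers: int = 0


def _signed_area(tri: np.ndarray) -> float:
    a, b, c = tri
    return 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


def triangulate_matches(matches: list[MatchPair]) -> list[TriPatch]:
    """Delaunay triangulation of the reference points.

    Target triangles are formed by vertex correspondence.  Patches whose
    target triangle is degenerate (area < 1 px^2) or orientation-flipped
    relative to the reference are marked unmatchable.
    """
    if len(matches) < 3:
        raise DegenerateGeometryError("need >= 3 matches to triangulate")
    ref = np.stack([m.ref for m in matches])
    tgt = np.stack([m.tgt for m in matches])
    try:
        tri = Delaunay(ref)
    except QhullError as exc:
        raise DegenerateGeometryError("reference points are collinear") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("reference points are collinear")
    patches = []
    for simplex in tri.simplices:
        r = ref[simplex]
        t = tgt[simplex]
        ra = _signed_area(r)
        ta = _signed_area(t)
        matchable = abs(ta) >= 1.0 and abs(ra) >= 1.0 and np.sign(ta) == np.sign(ra)
        patches.append(
            TriPatch(vertex_ids=simplex.copy(), ref_triangle=r, tgt_triangle=t, matchable=matchable)
        )
    return patches


def estimate_affine_homography(patch: TriPatch) -> AffineHomography:
    """The unique affine map sending the 3 reference vertices to the target."""
    src, dst = patch.ref_triangle, patch.tgt_triangle
    if abs(_signed_area(src)) < 1e-9:
        raise DegenerateGeometryError("degenerate reference triangle")
    A = np.hstack([src, np.ones((3, 1))])
    coef = np.linalg.solve(A, dst)  # (3, 2)
    H = np.eye(3)
    H[0] = [coef[0, 0], coef[1, 0], coef[2, 0]]
    H[1] = [coef[0, 1], coef[1, 1], coef[2, 1]]
    return AffineHomography(H=H)


def barycentric_point(patch: TriPatch, s: float, t: float) -> np.ndarray:
    """p(s, t) = s v1 + t v2 + (1 - s - t) v3 inside the reference triangle."""
    if not (0 < s < 1 and 0 < t < 1 and s + t < 1):
        raise ValueError("(s, t) must satisfy 0 < s < 1, 0 < t < 1, s + t < 1")
    v1, v2, v3 = patch.ref_triangle
    return s * v1 + t * v2 + (1 - s - t) * v3


def _interior_pixels(tri: np.ndarray) -> np.ndarray:
    """Integer pixels strictly inside a triangle, as an (n, 2) xy array."""
    x0 = int(np.floor(tri[:, 0].min()))
    x1 = int(np.ceil(tri[:, 0].max()))
    y0 = int(np.floor(tri[:, 1].min()))
    y1 = int(np.ceil(tri[:, 1].max()))
    if x1 < x0 or y1 < y0:
        return np.empty((0, 2))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    a, b, c = tri
    d = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
    s = ((pts[:, 0] - a[0]) * (c[1] - a[1]) - (pts[:, 1] - a[1]) * (c[0] - a[0])) / d
    t = ((pts[:, 1] - a[1]) * (b[0] - a[0]) - (pts[:, 0] - a[0]) * (b[1] - a[1])) / d
    inside = (s > 1e-9) & (t > 1e-9) & (s + t < 1 - 1e-9)
    return pts[inside]


def _bilinear(img: np.ndarray, pts: np.ndarray) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    return map_coordinates(np.asarray(img, dtype=float), [pts[:, 1], pts[:, 0]], order=1, mode="constant", cval=np.nan)


def patch_ncc(
    img_ref: np.ndarray,
    img_tgt: np.ndarray,
    patch: TriPatch,
    H: AffineHomography,
    mask_ref: np.ndarray | None = None,
    mask_tgt: np.ndarray | None = None,
) -> float | None:
    """Zero-mean, unit-variance NCC between a patch and its warp.

    All integer pixels strictly inside the reference triangle are compared
    against bilinear samples of the target at their H-mapped positions.
    Specular-masked pixels and pixels warping outside the target are
    excluded.  Returns ``None`` ("unvalidatable") when fewer than 16 usable
    pixels remain or either intensity vector is flat.
    """
    pts = _interior_pixels(patch.ref_triangle)
    if len(pts) < 16:
        return None
    h, w = np.asarray(img_tgt).shape[:2]
    warped = H.apply(pts)
    ok = (
        (warped[:, 0] >= 0)
        & (warped[:, 0] <= w - 1)
        & (warped[:, 1] >= 0)
        & (warped[:, 1] <= h - 1)
    )
    if mask_ref is not None:
        mr = np.asarray(mask_ref, dtype=bool)
        ok &= ~mr[pts[:, 1].astype(int), pts[:, 0].astype(int)]
    if mask_tgt is not None:
        mt = np.asarray(mask_tgt, dtype=bool)
        wi = np.clip(np.round(warped[:, 1]).astype(int), 0, h - 1)
        wj = np.clip(np.round(warped[:, 0]).astype(int), 0, w - 1)
        ok &= ~mt[wi, wj]
    pts, warped = pts[ok], warped[ok]
    if len(pts) < 16:
        return None
    a = _bilinear(img_ref, pts)
    b = _bilinear(img_tgt, warped)
    a = a - a.mean()
    b = b - b.mean()
    va = np.dot(a, a) / len(a)
    vb = np.dot(b, b) / len(b)
    if va < 1e-6 or vb < 1e-6:
        return None
    return float(np.dot(a, b) / (len(a) * np.sqrt(va * vb)))


def incircle_center(triangle: np.ndarray) -> np.ndarray:
    """Incenter (a A + b B + c C)/(a + b + c); side lengths oppose vertices."""
    tri = np.asarray(triangle, dtype=float)
    if abs(_signed_area(tri)) < 1e-9:
        raise DegenerateGeometryError("degenerate triangle has no incircle")
    A, B, C = tri
    a = np.linalg.norm(B - C)
    b = np.linalg.norm(C - A)
    c = np.linalg.norm(A - B)
    return (a * A + b * B + c * C) / (a + b + c)


def epipolar_segment(
    F: FundamentalMatrix | np.ndarray, p: np.ndarray, tgt_triangle: np.ndarray
) -> np.ndarray | None:
    """Intersection of p's epipolar line with the closed target triangle.

    Returns the segment as a (2, 2) array of endpoints, or ``None`` when
    the line misses the triangle.
    """
    line = epipolar_line(F, p)
    a, b, c = line
    tri = np.asarray(tgt_triangle, dtype=float)
    P0 = np.array([-a * c, -b * c])  # closest point of the line to the origin
    d = np.array([-b, a])
    tlo, thi = -np.inf, np.inf
    for i in range(3):
        v0, v1 = tri[i], tri[(i + 1) % 3]
        v2 = tri[(i + 2) % 3]
        n = np.array([v1[1] - v0[1], v0[0] - v1[0]])  # edge normal
        e = -np.dot(n, v0)
        if np.dot(n, v2) + e < 0:  # orient so the third vertex is inside
            n, e = -n, -e
        num = np.dot(n, P0) + e
        den = np.dot(n, d)
        if abs(den) < 1e-12:
            if num < 0:
                return None  # parallel and outside
            continue
        tc = -num / den
        if den > 0:
            tlo = max(tlo, tc)
        else:
            thi = min(thi, tc)
    if tlo > thi:
        return None
    return np.array([P0 + tlo * d, P0 + thi * d])


def match_point_on_segment(
    img_ref: np.ndarray | DescriptorExtractor,
    img_tgt: np.ndarray | DescriptorExtractor,
    p: np.ndarray,
    segment: np.ndarray,
    cfg: HpftConfig,
    source: str = "center-forward",
) -> MatchPair | None:
    """Match ``p`` against candidates sampled every 1 px along ``segment``.

    The candidate distances [V_1 ... V_i] are squared descriptor distances;
    the argmin is returned only when V_min/V_second-min <= ratio (with more
    than one candidate) and V_min < epsilon.  Ties on V_min break toward the
    segment midpoint, then lower x, then lower y.
    """
    ext_ref = img_ref if isinstance(img_ref, DescriptorExtractor) else DescriptorExtractor(img_ref)
    ext_tgt = img_tgt if isinstance(img_tgt, DescriptorExtractor) else DescriptorExtractor(img_tgt)
    segment = np.asarray(segment, dtype=float)
    a, b = segment
    length = np.linalg.norm(b - a)
    n = max(int(np.floor(length)) + 1, 1)
    ts = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    cand = a[None, :] + ts[:, None] * (b - a)[None, :]
    h, w = ext_tgt.shape
    inb = (cand[:, 0] >= 0) & (cand[:, 0] <= w - 1) & (cand[:, 1] >= 0) & (cand[:, 1] <= h - 1)
    cand = cand[inb]
    if len(cand) == 0:
        return None
    dref = ext_ref.describe(np.atleast_2d(p))[0]
    dcand = ext_tgt.describe(cand)
    diff = dcand - dref[None, :]
    V = np.einsum("ij,ij->i", diff, diff)  # squared descriptor distances
    best = select_segment_candidate(V, cand, (a + b) / 2.0, cfg.ratio, cfg.epsilon)
    if best is None:
        return None
    return MatchPair(ref=np.asarray(p, dtype=float), tgt=cand[best], distance=float(V[best]), source=source)


def select_segment_candidate(
    V: np.ndarray,
    cand: np.ndarray | None = None,
    midpoint: np.ndarray | None = None,
    ratio: float = 0.8,
    epsilon: float = 0.35,
) -> int | None:
    """Apply the two acceptance rules to a candidate distance vector.

    Returns the argmin index only when V_min/V_second-min <= ``ratio`` (with
    at least two candidates) and V_min < ``epsilon``; ties on V_min break
    toward the segment midpoint, then lower x, then lower y.
    """
    V = np.asarray(V, dtype=float)
    vmin = V.min()
    mins = np.flatnonzero(V == vmin)
    if len(mins) > 1 and cand is not None and midpoint is not None:
        best = min(
            mins, key=lambda i: (np.linalg.norm(cand[i] - midpoint), cand[i, 0], cand[i, 1])
        )
    else:
        best = int(mins[0])
    if len(V) >= 2:
        rest = np.delete(V, best)
        vsec = rest.min()
        r = 1.0 if vsec == 0 else vmin / vsec
        if r > ratio:
            return None
    if vmin >= epsilon:
        return None
    return int(best)


def _patch_key(tri: np.ndarray) -> bytes:
    q = np.round(np.asarray(tri, dtype=float) * 100.0).astype(np.int64)
    order = np.lexsort((q[:, 1], q[:, 0]))
    return q[order].tobytes()


def hpft_register(
    img_ref: np.ndarray,
    img_tgt: np.ndarray,
    cam: preprocess.CameraModel | None = None,
    cfg: HpftConfig | None = None,
) -> RegistrationResult:
    """Run the full iterative registration on one image pair."""
    cfg = cfg or HpftConfig()
    img_ref = np.asarray(img_ref)
    img_tgt = np.asarray(img_tgt)
    if img_ref.shape != img_tgt.shape:
        raise ValueError("images must share dimensions")
    if cam is not None:
        img_ref = preprocess.undistort_image(img_ref, cam)
        img_tgt = preprocess.undistort_image(img_tgt, cam)
    mask_ref = preprocess.detect_specular_mask(img_ref)
    mask_tgt = preprocess.detect_specular_mask(img_tgt)

    feats_ref = detect_features(img_ref, mask_ref, budget=cfg.budget, seed=cfg.seed)
    # the budget caps the *initial* feature set; the target keeps its full
    # keypoint pool so budgeted reference features can find counterparts
    feats_tgt = detect_features(img_tgt, mask_tgt, budget=None, seed=cfg.seed)
    matches = initial_match(feats_ref, feats_tgt, ratio=cfg.ratio)
    if not matches:
        raise DegenerateGeometryError("no initial matches")
    fm = estimate_fundamental(matches, seed=cfg.seed)
    matches = [matches[i] for i in fm.inlier_indices]
    n_initial = len(matches)

    ext_ref = DescriptorExtractor(img_ref)
    ext_tgt = DescriptorExtractor(img_tgt)
    Ft = FundamentalMatrix(F=fm.F.T, inlier_indices=fm.inlier_indices)

    accepted: dict[tuple, PatchMatch] = {}
    dead: set[tuple] = set()
    trace: list[dict] = []
    iterations = 0
    while iterations < cfg.max_iterations:
        iterations += 1
        patches = triangulate_matches(matches)
        new_points = 0
        new_patches = 0
        ref_pts = np.stack([m.ref for m in matches])
        tgt_pts = np.stack([m.tgt for m in matches])
        for patch in patches:
            key = _patch_key(patch.ref_triangle)
            if key in accepted or key in dead:
                continue
            if not patch.matchable:
                dead.add(key)
                continue
            H = estimate_affine_homography(patch)
            d = patch_ncc(img_ref, img_tgt, patch, H, mask_ref, mask_tgt)
            if d is None:
                dead.add(key)
                continue
            if d >= cfg.ncc_accept:
                accepted[key] = PatchMatch(patch=patch, H=H, dif_h=d)
                new_patches += 1
                continue
            if abs(_signed_area(patch.ref_triangle)) < cfg.min_patch_area:
                dead.add(key)
                continue
            added_here = 0
            # forward: reference incircle center along its epipolar segment
            c_ref = incircle_center(patch.ref_triangle)
            seg = epipolar_segment(fm, c_ref, patch.tgt_triangle)
            if seg is not None:
                m = match_point_on_segment(ext_ref, ext_tgt, c_ref, seg, cfg, source="center-forward")
                if m is not None and _is_new(m.ref, ref_pts) and _is_new(m.tgt, tgt_pts):
                    matches.append(m)
                    ref_pts = np.vstack([ref_pts, m.ref])
                    tgt_pts = np.vstack([tgt_pts, m.tgt])
                    new_points += 1
                    added_here += 1
            # backward: target incircle center matched reversely via F^T
            c_tgt = incircle_center(patch.tgt_triangle)
            seg_r = epipolar_segment(Ft, c_tgt, patch.ref_triangle)
            if seg_r is not None:
                m = match_point_on_segment(ext_tgt, ext_ref, c_tgt, seg_r, cfg, source="center-backward")
                if m is not None and _is_new(m.tgt, ref_pts) and _is_new(m.ref, tgt_pts):
                    flipped = MatchPair(ref=m.tgt, tgt=m.ref, distance=m.distance, source="center-backward")
                    matches.append(flipped)
                    ref_pts = np.vstack([ref_pts, flipped.ref])
                    tgt_pts = np.vstack([tgt_pts, flipped.tgt])
                    new_points += 1
                    added_here += 1
            if added_here == 0:
                dead.add(key)
        trace.append(
            {
                "iteration": iterations,
                "new_points": new_points,
                "new_patches": new_patches,
                "total_points": len(matches),
                "total_patches": len(accepted),
            }
        )
        if new_points == 0:
            break  # triangulation is a fixpoint: nothing new can appear

    return RegistrationResult(
        matches=matches,
        patches=list(accepted.values()),
        iterations=iterations,
        trace=trace,
        fundamental=fm,
        n_initial_inliers=n_initial,
    )


def _is_new(p: np.ndarray, existing: np.ndarray, tol: float = 0.5) -> bool:
    return bool(np.all(np.hypot(existing[:, 0] - p[0], existing[:, 1] - p[1]) > tol))


def propagate_points(
    result: RegistrationResult, points: np.ndarray, radius: float | None = 30.0
) -> np.ndarray:
    """Map reference-frame points into the target via the registration.

    A point inside an accepted patch moves under that patch's affine H;
    otherwise it moves by the translation of the nearest matched point
    within ``radius`` px; otherwise it is lost (NaN).  ``radius=None``
    disables the fallback so only the homographic patch map is used —
    a point outside every validated patch then has no registration site.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.full_like(pts, np.nan)
    tris = [pm.patch.ref_triangle for pm in result.patches]
    for i, p in enumerate(pts):
        placed = False
        for tri, pm in zip(tris, result.patches):
            a, b, c = tri
            d = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
            s = ((p[0] - a[0]) * (c[1] - a[1]) - (p[1] - a[1]) * (c[0] - a[0])) / d
            t = ((p[1] - a[1]) * (b[0] - a[0]) - (p[0] - a[0]) * (b[1] - a[1])) / d
            if s >= -1e-9 and t >= -1e-9 and s + t <= 1 + 1e-9:
                out[i] = pm.H.apply(p)[0]
                placed = True
                break
        if placed or radius is None:
            continue
        ref = np.stack([m.ref for m in result.matches])
        dist = np.hypot(ref[:, 0] - p[0], ref[:, 1] - p[1])
        j = int(np.argmin(dist))
        if dist[j] <= radius:
            out[i] = p + (result.matches[j].tgt - result.matches[j].ref)
    return out
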