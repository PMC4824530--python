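"""Interest points, 32-element descriptors, initial matching, epipolar geometry.

The detector is standard SIFT (difference-of-Gaussian extrema with
orientation assignment).  Descriptors are the usual 4x4x8 gradient
histograms *pooled spatially 2x2* down to a 2x2x8 = 32-element vector and
L2-normalized: the pooling keeps all 8 orientation bins, so rotation
behavior is preserved while matching cost drops 4x.  Descriptor similarity
is the sum of squared element differences (no square root), ranging over
[0, 4] for normalized vectors.

The iterative registration core also needs descriptors at points that are
not scale-space extrema (triangle incircle centers and candidates along an
epipolar segment); :class:`DescriptorExtractor` computes the same 32-element
descriptor at an arbitrary subpixel location, at a fixed scale with
orientation assigned from the local gradient field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.feature import SIFT
from skimage.measure import ransac
from skimage.transform import FundamentalMatrixTransform

from ._rng import substream

__all__ = [
    "Feature",
    "MatchPair",
    "FundamentalMatrix",
    "FeatureDetectionError",
    "DegenerateGeometryError",
    "detect_features",
    "simplify_descriptor",
    "descriptor_distance",
    "initial_match",
    "estimate_fundamental",
    "epipolar_line",
    "DescriptorExtractor",
    "matches_to_csv",
    "matches_from_csv",
]


class FeatureDetectionError(RuntimeError):
    """Raised when an image is too poorly textured to register."""


class DegenerateGeometryError(RuntimeError):
    """Raised when the match geometry cannot support an epipolar estimate."""


@dataclass
class Feature:
    x: float
    y: float
    scale: float
    orientation: float
    descriptor: np.ndarray  # 32 non-negative reals, ||.||_2 = 1

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class MatchPair:
    """A reference<->target correspondence with provenance.

    ``source`` records how the pair was found: ``initial`` (descriptor
    matching of detected keypoints), ``center-forward`` (reference-side
    incircle center matched along its epipolar segment) or
    ``center-backward`` (the symmetric target-side operation).
    """

    ref: np.ndarray
    tgt: np.ndarray
    distance: float
    source: str = "initial"

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=float)
        self.tgt = np.asarray(self.tgt, dtype=float)
        if self.distance < 0:
            raise ValueError("descriptor distance must be non-negative")


@dataclass
class FundamentalMatrix:
    F: np.ndarray
    inlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def detect_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    budget: int | None = 200,
    seed: int = 0,
) -> list[Feature]:
    """SIFT keypoints with 32-element descriptors, outside the mask.

    If more than ``budget`` keypoints survive the mask, a seeded uniform
    random subset of exactly ``budget`` is returned, emulating a fixed
    initial feature budget per frame.  ``budget=None`` keeps every
    keypoint (used for the target side, where the full candidate pool is
    needed to find counterparts of the budgeted reference set).
    """
    if budget is not None and budget < 4:
        raise ValueError("budget must be >= 4")
    image = np.asarray(image)
    sift = SIFT(upsampling=1, n_octaves=4)
    try:
        sift.detect_and_extract(image.astype(float))
    except RuntimeError as exc:  # skimage signals "no extrema" this way
        raise FeatureDetectionError("no scale-space extrema found (untextured input?)") from exc
    pos = sift.positions  # (n, 2) subpixel (row, col)
    desc128 = sift.descriptors.astype(float)
    scales = sift.sigmas
    orients = sift.orientations
    h, w = image.shape[:2]
    keep = (pos[:, 0] >= 0) & (pos[:, 0] <= h - 1) & (pos[:, 1] >= 0) & (pos[:, 1] <= w - 1)
    if mask is not None:
        mi = np.clip(np.round(pos[:, 0]).astype(int), 0, h - 1)
        mj = np.clip(np.round(pos[:, 1]).astype(int), 0, w - 1)
        keep &= ~np.asarray(mask, dtype=bool)[mi, mj]
    idx = np.flatnonzero(keep)
    if len(idx) < 4:
        raise FeatureDetectionError(f"only {len(idx)} features found; image too poorly textured")
    if budget is not None and len(idx) > budget:
        rng = np.random.default_rng(substream(seed, "feature-budget"))
        idx = np.sort(rng.choice(idx, size=budget, replace=False))
    feats = []
    for i in idx:
        feats.append(
            Feature(
                x=float(pos[i, 1]),
                y=float(pos[i, 0]),
                scale=float(scales[i]),
                orientation=float(orients[i]),
                descriptor=simplify_descriptor(desc128[i]),
            )
        )
    return feats


def simplify_descriptor(desc128: np.ndarray) -> np.ndarray:
    """Pool the 4x4x8 SIFT histogram 2x2 spatially -> 32 values, L2-normalize."""
    desc128 = np.asarray(desc128, dtype=float)
    if desc128.shape != (128,):
        raise ValueError(f"expected a 128-element SIFT descriptor, got shape {desc128.shape}")
    grid = desc128.reshape(4, 4, 8)
    pooled = grid.reshape(2, 2, 2, 2, 8).sum(axis=(1, 3))  # (2, 2, 8)
    v = pooled.reshape(32)
    n = np.linalg.norm(v)
    if n == 0:
        return v
    return v / n


def descriptor_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of squared element differences of two 32-element descriptors.

    No square root is taken; for unit vectors the value is
    ``2 - 2<a, b>`` and lies in [0, 4].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    return float(np.dot(d, d))


def initial_match(
    feats_ref: list[Feature], feats_tgt: list[Feature], ratio: float = 0.8
) -> list[MatchPair]:
    """Mutual-best nearest-neighbor matching with Lowe's ratio test.

    For each reference feature the nearest and second-nearest target
    descriptors are found under :func:`descriptor_distance`; the pair is kept
    only if nearest/second-nearest < ``ratio`` and the match is mutual-best,
    which makes the result injective on both sides.
    """
    if not feats_ref or not feats_tgt:
        raise ValueError("both feature lists must be non-empty")
    A = np.stack([f.descriptor for f in feats_ref])
    B = np.stack([f.descriptor for f in feats_tgt])
    # squared Euclidean distances — exactly the descriptor metric
    D = np.maximum(
        (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * (A @ B.T), 0.0
    )
    best_t = np.argmin(D, axis=1)
    best_r = np.argmin(D, axis=0)
    matches = []
    for i, j in enumerate(best_t):
        if best_r[j] != i:
            continue
        d1 = D[i, j]
        if D.shape[1] >= 2:
            row = D[i].copy()
            row[j] = np.inf
            d2 = row.min()
            r = 1.0 if d2 == 0 else d1 / d2
            if r >= ratio:
                continue
        matches.append(
            MatchPair(ref=feats_ref[i].xy, tgt=feats_tgt[j].xy, distance=float(d1), source="initial")
        )
    return matches


def estimate_fundamental(
    matches: list[MatchPair],
    seed: int = 0,
    residual_threshold: float = 1.5,
    max_trials: int = 2000,
) -> FundamentalMatrix:
    """Normalized 8-point algorithm inside RANSAC (Sampson distance).

    The model is refit on the consensus set, rank 2 is enforced and the
    matrix scaled to unit Frobenius norm with a deterministic sign.
    """
    if len(matches) < 8:
        raise DegenerateGeometryError(f"need >= 8 matches, got {len(matches)}")
    src = np.stack([m.ref for m in matches])
    dst = np.stack([m.tgt for m in matches])
    rng = np.random.default_rng(substream(seed, "ransac"))
    model, inliers = ransac(
        (src, dst),
        FundamentalMatrixTransform,
        min_samples=8,
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        rng=rng,
    )
    if model is None or inliers is None or inliers.sum() < 8:
        raise DegenerateGeometryError("fewer than 8 epipolar inliers")
    refit = FundamentalMatrixTransform.from_estimate(src[inliers], dst[inliers])
    if not refit:
        raise DegenerateGeometryError("refit on inliers failed")
    F = np.asarray(refit.params, dtype=float)
    U, s, Vt = np.linalg.svd(F)
    s[-1] = 0.0
    F = U @ np.diag(s) @ Vt
    F /= np.linalg.norm(F)
    flat = F.ravel()
    if flat[np.argmax(np.abs(flat))] < 0:
        F = -F
    return FundamentalMatrix(F=F, inlier_indices=np.flatnonzero(inliers))


def epipolar_line(F: FundamentalMatrix | np.ndarray, p: np.ndarray) -> np.ndarray:
    """Line ``l = F (x, y, 1)^T`` in the target, scaled so a^2 + b^2 = 1."""
    M = F.F if isinstance(F, FundamentalMatrix) else np.asarray(F, dtype=float)
    p = np.asarray(p, dtype=float)
    l = M @ np.array([p[0], p[1], 1.0])
    n = np.hypot(l[0], l[1])
    if n < 1e-12:
        raise DegenerateGeometryError("point maps to the epipole; epipolar line undefined")
    return l / n


# ---------------------------------------------------------------------------
# descriptors at arbitrary (non-keypoint) locations
# ---------------------------------------------------------------------------

_N_ORI = 8
_N_SPATIAL = 4
_WINDOW = 16  # sample window side in pixels at the fixed scale


class DescriptorExtractor:
    """32-element descriptors at arbitrary subpixel points of one image.

    The gradient field of the (lightly smoothed) image is precomputed once;
    each query point gets a dominant orientation from a 36-bin gradient
    histogram in its neighborhood, then a 4x4x8 gradient histogram over a
    rotated 16x16 window which is pooled to 32 elements exactly like the
    keypoint descriptors.  The scale is fixed (sigma = 1.6) because these
    points are not scale-space extrema.
    """

    def __init__(self, image: np.ndarray, sigma: float = 1.6):
        img = gaussian_filter(np.asarray(image, dtype=float), sigma=sigma)
        self.gx = np.gradient(img, axis=1)
        self.gy = np.gradient(img, axis=0)
        # complex packing lets one interpolation call fetch both components
        self._g = self.gx + 1j * self.gy
        self.shape = img.shape
        # fixed sample grid in the rotated frame: 16x16 offsets at 1 px pitch
        half = _WINDOW / 2.0
        ax = np.arange(_WINDOW) - half + 0.5
        ox, oy = np.meshgrid(ax, ax)
        self._offsets = np.stack([ox.ravel(), oy.ravel()], axis=1)  # (256, 2)
        self._spatial_cell = (
            np.floor((self._offsets[:, 1] + half) / (_WINDOW / _N_SPATIAL)).astype(int) * _N_SPATIAL
            + np.floor((self._offsets[:, 0] + half) / (_WINDOW / _N_SPATIAL)).astype(int)
        )
        self._weight = np.exp(-(self._offsets**2).sum(1) / (2 * (half) ** 2))
        # orientation-assignment window
        r = 8
        wy, wx = np.mgrid[-r : r + 1, -r : r + 1]
        sel = wx * wx + wy * wy <= r * r
        self._ori_off = np.stack([wx[sel], wy[sel]], axis=1).astype(float)
        self._ori_w = np.exp(-(self._ori_off**2).sum(1) / (2 * (0.75 * r) ** 2))

    def _sample_grad(self, coords: np.ndarray):
        g = map_coordinates(self._g, [coords[..., 1], coords[..., 0]], order=1, mode="nearest")
        return g.real, g.imag

    def orientations(self, points: np.ndarray) -> np.ndarray:
        """Dominant local gradient orientation (radians) at each point."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        coords = pts[:, None, :] + self._ori_off[None, :, :]
        gx, gy = self._sample_grad(coords)
        mag = np.hypot(gx, gy) * self._ori_w[None, :]
        ang = np.arctan2(gy, gx)
        bins = np.floor((ang + np.pi) / (2 * np.pi) * 36).astype(int) % 36
        hist = np.zeros((len(pts), 36))
        rows = np.repeat(np.arange(len(pts)), bins.shape[1])
        np.add.at(hist, (rows, bins.ravel()), mag.ravel())
        # circular smoothing stabilizes the argmax
        for _ in range(2):
            hist = (np.roll(hist, 1, axis=1) + hist + np.roll(hist, -1, axis=1)) / 3.0
        peak = np.argmax(hist, axis=1)
        return (peak + 0.5) / 36 * 2 * np.pi - np.pi

    def describe(self, points: np.ndarray) -> np.ndarray:
        """(n, 32) descriptors, rows L2-normalized."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        theta = self.orientations(pts)
        c, s = np.cos(theta), np.sin(theta)
        # rotate the fixed grid into image coordinates per point
        off = self._offsets  # (256, 2)
        rx = off[:, 0][None, :] * c[:, None] - off[:, 1][None, :] * s[:, None]
        ry = off[:, 0][None, :] * s[:, None] + off[:, 1][None, :] * c[:, None]
        coords = np.stack([pts[:, 0][:, None] + rx, pts[:, 1][:, None] + ry], axis=-1)
        gx, gy = self._sample_grad(coords)
        # rotate gradients into the local frame
        lgx = gx * c[:, None] + gy * s[:, None]
        lgy = -gx * s[:, None] + gy * c[:, None]
        mag = np.hypot(lgx, lgy) * self._weight[None, :]
        ang = np.arctan2(lgy, lgx)  # [-pi, pi)
        fbin = (ang + np.pi) / (2 * np.pi) * _N_ORI
        b0 = np.floor(fbin).astype(int) % _N_ORI
        b1 = (b0 + 1) % _N_ORI
        w1 = fbin - np.floor(fbin)
        w0 = 1.0 - w1
        cell = self._spatial_cell[None, :].repeat(n, axis=0)
        hist = np.zeros((n, 16, _N_ORI))
        rows = np.repeat(np.arange(n), off.shape[0])
        np.add.at(hist, (rows, cell.ravel(), b0.ravel()), (mag * w0).ravel())
        np.add.at(hist, (rows, cell.ravel(), b1.ravel()), (mag * w1).ravel())
        desc = hist.reshape(n, 128)
        # standard SIFT normalize -> clip 0.2 -> renormalize
        norms = np.linalg.norm(desc, axis=1, keepdims=True)
        desc = desc / np.maximum(norms, 1e-12)
        desc = np.minimum(desc, 0.2)
        pooled = desc.reshape(n, 2, 2, 2, 2, 8).sum(axis=(2, 4)).reshape(n, 32)
        pn = np.linalg.norm(pooled, axis=1, keepdims=True)
        return pooled / np.maximum(pn, 1e-12)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def matches_to_csv(matches: list[MatchPair], path) -> None:
    df = pd.DataFrame(
        {
            "x_ref": [m.ref[0] for m in matches],
            "y_ref": [m.ref[1] for m in matches],
            "x_tgt": [m.tgt[0] for m in matches],
            "y_tgt": [m.tgt[1] for m in matches],
            "distance": [m.distance for m in matches],
            "source": [m.source for m in matches],
        }
    )
    df.to_csv(path, index=False, float_format="%.3f")


def matches_from_csv(path) -> list[MatchPair]:
    df = pd.read_csv(path)
    return [
        MatchPair(
            ref=np.array([r.x_ref, r.y_ref]),
            tgt=np.array([r.x_tgt, r.y_tgt]),
            distance=float(r.distance),
            source=str(r.source),
        )
        for r in df.itertuples()
    ]
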