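"""Seeded synthetic-scene generation with exact ground-truth warps.

Real gastroscopic footage shows a smoothly curved, textured mucosal surface
imaged under free camera motion — locally well approximated by planar
(affine-homographic) patches, corrupted by sensor noise and saturated
specular highlights.  This module emulates exactly those properties with
known per-pixel ground truth, so every stage of the registration and
evaluation pipeline can be tested offline without patient data.

All generators are pure functions of their arguments (including ``seed``).
Coordinates are 0-based with ``x`` = column (rightward) and ``y`` = row
(downward); pixel centers sit on integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import Delaunay

from ._rng import substream

__all__ = [
    "SyntheticScene",
    "generate_textured_plane",
    "warp_scene",
    "generate_piecewise_planar_scene",
    "generate_sequence",
    "add_specular_blobs",
    "save_scene",
    "load_scene",
]

#: minimum frame side accepted by the texture generator
MIN_SIDE = 64


@dataclass
class SyntheticScene:
    """An image pair with dense ground truth.

    Attributes
    ----------
    reference_image, target_image : (h, w) uint8 arrays.
    truth_map : (h, w, 2) float array; ``truth_map[y, x]`` is the (x, y)
        position in the target of reference pixel (x, y).  NaN where the
        reference pixel is not visible in the target frame.
    patch_truth : list of ``(polygon, H)`` with ``polygon`` an (k, 2) float
        array of reference-frame vertices and ``H`` the 3x3 affine matrix
        (last row (0, 0, 1)) valid inside that polygon.
    noise_sigma : gray levels of additive Gaussian noise in the target.
    seed : the seed that produced the scene.
    """

    reference_image: np.ndarray
    target_image: np.ndarray
    truth_map: np.ndarray
    patch_truth: list[tuple[np.ndarray, np.ndarray]]
    noise_sigma: float
    seed: int
    specular_mask: np.ndarray | None = field(default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference_image.shape


def generate_textured_plane(width: int, height: int, seed: int) -> np.ndarray:
    """Band-limited random texture with dense feature response.

    Gaussian-smoothed white noise (sigma = 2 px) scaled to [20, 235] plus a
    mild linear shading gradient.  The intensity ceiling of 235 leaves
    headroom for saturated specular blobs; every 64x64 tile keeps an
    intensity standard deviation >= 10 gray levels so blob detectors find
    interest points everywhere in the frame.
    """
    if width < MIN_SIDE or height < MIN_SIDE:
        raise ValueError(f"frame must be at least {MIN_SIDE}x{MIN_SIDE}, got {width}x{height}")
    rng = np.random.default_rng(substream(seed, "texture"))
    noise = gaussian_filter(rng.standard_normal((height, width)), sigma=2.0)
    noise = (noise - noise.min()) / np.ptp(noise)  # -> [0, 1]
    yy, xx = np.mgrid[0:height, 0:width]
    angle = rng.uniform(0, 2 * np.pi)
    grad = (np.cos(angle) * xx / width + np.sin(angle) * yy / height)
    grad = (grad - grad.min()) / max(np.ptp(grad), 1e-12)
    img = 0.85 * noise + 0.15 * grad
    img = (img - img.min()) / np.ptp(img)
    return np.round(20.0 + 215.0 * img).astype(np.uint8)


def _as_affine(H: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    if H.shape != (3, 3):
        raise ValueError("H must be 3x3")
    if abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("H is singular")
    return H / H[2, 2]


def _resample_through(texture: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Render the target: sample texture at H^-1 of every target pixel."""
    h, w = texture.shape
    Hinv = np.linalg.inv(H)
    yy, xx = np.mgrid[0:h, 0:w]
    ones = np.ones_like(xx, dtype=float)
    pts = np.stack([xx, yy, ones])  # homogeneous target pixels, (3, h, w)
    src = np.einsum("ij,jhw->ihw", Hinv, pts.astype(float))
    sx = src[0] / src[2]
    sy = src[1] / src[2]
    out = map_coordinates(texture.astype(float), [sy, sx], order=1, mode="constant", cval=0.0)
    inside = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
    out[~inside] = 0.0
    return out


def _add_noise(img: np.ndarray, noise_sigma: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sigma <= 0:
        return np.round(img).astype(np.uint8)
    noisy = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(np.round(noisy), 0, 255).astype(np.uint8)


def warp_scene(
    texture: np.ndarray, H: np.ndarray, noise_sigma: float = 0.0, seed: int = 0
) -> SyntheticScene:
    """Single-plane scene: the whole frame moves under one homography ``H``.

    ``truth_map`` is exactly the ``H`` mapping (NaN where the reference
    pixel leaves the target frame) and ``patch_truth`` holds the full frame
    with ``H``.
    """
    texture = np.asarray(texture)
    H = _as_affine(H)
    h, w = texture.shape
    target = _resample_through(texture, H)
    rng = np.random.default_rng(substream(seed, "warp-noise"))
    target = _add_noise(target, noise_sigma, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([xx, yy, np.ones_like(xx)]).astype(float)
    dst = np.einsum("ij,jhw->ihw", H, pts)
    tx = dst[0] / dst[2]
    ty = dst[1] / dst[2]
    visible = (tx >= 0) & (tx <= w - 1) & (ty >= 0) & (ty <= h - 1)
    truth = np.stack([tx, ty], axis=-1)
    truth[~visible] = np.nan
    frame_poly = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    return SyntheticScene(
        reference_image=texture.astype(np.uint8),
        target_image=target,
        truth_map=truth,
        patch_truth=[(frame_poly, H)],
        noise_sigma=float(noise_sigma),
        seed=seed,
    )


def _boundary_triangulation(w: int, h: int, n_patches: int, rng: np.random.Generator):
    """Triangulate the frame rectangle into exactly ``n_patches`` triangles.

    The four corners plus ``n_patches - 2`` extra perimeter sites form a
    convex polygon with ``n_patches + 2`` vertices, whose Delaunay
    triangulation has exactly ``n_patches`` triangles covering the frame.
    """
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    perim = 2 * (w - 1) + 2 * (h - 1)
    # perimeter arc-length positions of the corners, walked clockwise from (0,0)
    corner_s = np.array([0, w - 1, w - 1 + h - 1, 2 * (w - 1) + h - 1], dtype=float)
    n_extra = n_patches - 2
    extra = []
    if n_extra > 0:
        s = (np.arange(n_extra) + 0.5) / n_extra * perim
        s = (s + rng.uniform(-0.25, 0.25) * perim / n_extra) % perim
        # keep extra sites away from corners so triangles stay non-degenerate
        for si in s:
            d = np.min(np.abs(((si - corner_s) + perim / 2) % perim - perim / 2))
            if d < 8:
                si = (si + 16) % perim
            extra.append(si)
        pts = []
        for si in extra:
            if si < w - 1:
                pts.append([si, 0])
            elif si < w - 1 + h - 1:
                pts.append([w - 1, si - (w - 1)])
            elif si < 2 * (w - 1) + h - 1:
                pts.append([2 * (w - 1) + h - 1 - si, h - 1])
            else:
                pts.append([0, perim - si])
        sites = np.vstack([corners, np.array(pts, dtype=float)])
    else:
        sites = corners
    tri = Delaunay(sites)
    return sites, tri.simplices


def _fold_maps(
    sites: np.ndarray,
    simplices: np.ndarray,
    base_H: np.ndarray,
    fold: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """One affine per triangle, exactly continuous across shared edges.

    Breadth-first over the dual adjacency: a child's map adds to its
    parent's a rank-1 term ``u (n, c)`` built on the shared edge's line
    equation ``n . p + c = 0``, so both maps agree on that edge while their
    derivatives differ by about ``fold``.

    All updates share one direction ``b`` (only their signed magnitude is
    per-edge): the homographies of a rigid piecewise-planar surface under a
    camera translating parallel to the image plane differ exactly by
    rank-1 terms through the common epipole direction, so this keeps the
    whole scene consistent with a single fundamental matrix — without it,
    no epipolar constraint covers more than one cell.
    """
    n_tri = len(simplices)
    edge_owner: dict[tuple, int] = {}
    adj: list[list[tuple[int, tuple]]] = [[] for _ in range(n_tri)]
    for i, simplex in enumerate(simplices):
        for k in range(3):
            e = tuple(sorted((simplex[k], simplex[(k + 1) % 3])))
            if e in edge_owner:
                j = edge_owner[e]
                adj[i].append((j, e))
                adj[j].append((i, e))
            else:
                edge_owner[e] = i
    maps: list[np.ndarray | None] = [None] * n_tri
    maps[0] = base_H.copy()
    beta = rng.uniform(0, 2 * np.pi)  # common epipole direction
    b = np.array([np.cos(beta), np.sin(beta)])
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for nxt, e in adj[cur]:
            if maps[nxt] is not None:
                continue
            p0, p1 = sites[e[0]], sites[e[1]]
            t = p1 - p0
            n = np.array([-t[1], t[0]]) / np.linalg.norm(t)
            line = np.array([n[0], n[1], -np.dot(n, p0)])
            mag = fold * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            H = maps[cur].copy()
            H[:2, :] += np.outer(mag * b, line)
            maps[nxt] = H
            queue.append(nxt)
    return [m for m in maps]


def _affine_from_triangles(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Affine matrix mapping the 3 ``src`` vertices exactly onto ``dst``."""
    A = np.hstack([src, np.ones((3, 1))])  # (3, 3)
    coef = np.linalg.solve(A, dst)  # (3, 2): columns are affine rows^T
    H = np.eye(3)
    H[0, :] = np.array([coef[0, 0], coef[1, 0], coef[2, 0]])
    H[1, :] = np.array([coef[0, 1], coef[1, 1], coef[2, 1]])
    return H


def generate_piecewise_planar_scene(
    n_patches: int,
    seed: int,
    noise_sigma: float = 0.0,
    width: int = 560,
    height: int = 480,
    base_H: np.ndarray | None = None,
    fold: float = 0.25,
) -> SyntheticScene:
    """Scene whose warp is affine per patch but continuous across patch edges.

    The frame is partitioned into ``n_patches`` triangles sharing a common
    base affine; crossing from one triangle to a neighbor, the map picks up
    a rank-1 update that vanishes exactly on the shared edge, so the warp
    stays continuous while its first derivative jumps by 0.5-1x ``fold``
    along every fold line — the way a smooth organ surface bends across a
    mucosal fold.  The default (0.25) corresponds to adjacent patches
    deviating by up to ~5 degrees of rotation plus ~5% of scale on either
    side of the base map, enough that triangles straddling a fold visibly
    violate the planar hypothesis.  Because the dual
    graph of a triangulated polygon is a tree, assigning the updates along
    a breadth-first traversal keeps every shared edge exactly continuous.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    texture = generate_textured_plane(width, height, seed)
    rng = np.random.default_rng(substream(seed, "piecewise"))
    if base_H is None:
        ang = rng.uniform(-0.05, 0.05)
        sc = rng.uniform(0.97, 1.03)
        t = rng.uniform(-8, 8, 2)
        base_H = np.array(
            [
                [sc * np.cos(ang), -sc * np.sin(ang), t[0]],
                [sc * np.sin(ang), sc * np.cos(ang), t[1]],
                [0, 0, 1],
            ]
        )
    base_H = _as_affine(base_H)
    if n_patches == 1:
        return warp_scene(texture, base_H, noise_sigma=noise_sigma, seed=seed)

    sites, simplices = _boundary_triangulation(width, height, n_patches, rng)
    maps = _fold_maps(sites, simplices, base_H, fold, rng)
    patch_truth: list[tuple[np.ndarray, np.ndarray]] = [
        (sites[simplex].copy(), H) for simplex, H in zip(simplices, maps)
    ]

    h, w = height, width
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    tri = Delaunay(sites)
    member = tri.find_simplex(pix)
    member[member < 0] = 0  # numerical boundary cases

    truth = np.empty((h, w, 2), dtype=float)
    target = np.zeros((h, w), dtype=float)
    filled = np.zeros((h, w), dtype=bool)
    texf = texture.astype(float)
    for i, (_, H) in enumerate(patch_truth):
        sel = member == i
        p = pix[sel]
        fwd = p @ H[:2, :2].T + H[:2, 2]
        truth.reshape(-1, 2)[sel] = fwd
        # inverse render: target pixels whose preimage under this patch lies in it
        Hinv = np.linalg.inv(H)
        back = pix @ Hinv[:2, :2].T + Hinv[:2, 2]
        bc = _barycentric(back, sites[simplices[i]])
        inside = np.all(bc >= -1e-9, axis=1)
        src = back[inside]
        vals = map_coordinates(texf, [src[:, 1], src[:, 0]], order=1, mode="constant", cval=0.0)
        ok = (
            (src[:, 0] >= 0)
            & (src[:, 0] <= w - 1)
            & (src[:, 1] >= 0)
            & (src[:, 1] <= h - 1)
        )
        idx = np.flatnonzero(inside)[ok]
        target.ravel()[idx] = vals[ok]
        filled.ravel()[idx] = True

    tx, ty = truth[..., 0], truth[..., 1]
    visible = (tx >= 0) & (tx <= w - 1) & (ty >= 0) & (ty <= h - 1)
    truth[~visible] = np.nan
    target = _add_noise(target, noise_sigma, np.random.default_rng(substream(seed, "pw-noise")))
    return SyntheticScene(
        reference_image=texture,
        target_image=target,
        truth_map=truth,
        patch_truth=patch_truth,
        noise_sigma=float(noise_sigma),
        seed=seed,
    )


def _barycentric(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``points`` w.r.t. triangle ``tri`` (3, 2)."""
    T = np.column_stack([tri[0] - tri[2], tri[1] - tri[2]])
    rhs = (points - tri[2]).T
    st = np.linalg.solve(T, rhs).T
    return np.column_stack([st, 1.0 - st.sum(axis=1)])


def generate_sequence(
    n_frames: int,
    seed: int,
    noise_sigma: float = 0.0,
    width: int = 560,
    height: int = 480,
    max_rotation: float = 0.02,
    max_scale: float = 0.02,
    max_translation: float = 4.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Ordered frames under a random smooth affine camera motion.

    Returns ``(frames, truth)`` where ``truth[t]`` maps frame-0 coordinates
    into frame ``t`` (``truth[0]`` is the identity).  Per-frame increments
    are small rotations/scalings/translations, emulating slow endoscope
    drift at video rate; each frame gets independent additive noise.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    texture = generate_textured_plane(width, height, seed)
    rng = np.random.default_rng(substream(seed, "sequence"))
    frames = [texture.copy()]
    truth = [np.eye(3)]
    H = np.eye(3)
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    recenter = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    center = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    for t in range(1, n_frames):
        ang = rng.uniform(-max_rotation, max_rotation)
        sc = 1.0 + rng.uniform(-max_scale, max_scale)
        dx, dy = rng.uniform(-max_translation, max_translation, 2)
        step = np.array(
            [
                [sc * np.cos(ang), -sc * np.sin(ang), dx],
                [sc * np.sin(ang), sc * np.cos(ang), dy],
                [0, 0, 1],
            ]
        )
        H = recenter @ step @ center @ H
        scene = warp_scene(texture, H, noise_sigma=noise_sigma, seed=substream(seed, f"frame{t}"))
        frames.append(scene.target_image)
        truth.append(H.copy())
    if noise_sigma > 0:
        frames[0] = _add_noise(
            texture.astype(float), noise_sigma, np.random.default_rng(substream(seed, "frame0"))
        )
    return frames, truth


def add_specular_blobs(
    image: np.ndarray, n_blobs: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Paste saturated elliptical highlights; return (image, truth mask).

    Specular reflections on wet mucosa saturate the sensor; they move with
    the light source rather than the tissue, so downstream code must mask
    them before feature detection.  Blobs have a fully saturated (255) core
    — which is the returned truth mask — and a soft ~2 px border blending
    back into the tissue.
    """
    if n_blobs < 0:
        raise ValueError("n_blobs must be >= 0")
    image = np.asarray(image)
    out = image.astype(float).copy()
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    if n_blobs == 0:
        return image.copy(), mask
    rng = np.random.default_rng(substream(seed, "specular"))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cx = rng.uniform(0.1 * w, 0.9 * w)
        cy = rng.uniform(0.1 * h, 0.9 * h)
        a = rng.uniform(4, 12)
        b = rng.uniform(3, 8)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        core = r <= 1.0
        # soft border: alpha ramps 1 -> 0 over ~2 px beyond the core
        ramp = np.clip(1.0 - (r - 1.0) * np.minimum(a, b) / 2.0, 0.0, 1.0)
        alpha = np.where(core, 1.0, ramp)
        out = alpha * 255.0 + (1.0 - alpha) * out
        mask |= core
    return np.clip(np.round(out), 0, 255).astype(np.uint8), mask


def save_scene(scene: SyntheticScene, out_dir: str | Path) -> None:
    """Write reference/target PNGs plus a JSON sidecar with the truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "reference.png", scene.reference_image)
    iio.imwrite(out / "target.png", scene.target_image)
    sidecar = {
        "noise_sigma": scene.noise_sigma,
        "seed": scene.seed,
        "patch_truth": [
            {"polygon": poly.tolist(), "H": H.ravel().tolist()} for poly, H in scene.patch_truth
        ],
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=2))


def load_scene(out_dir: str | Path) -> SyntheticScene:
    out = Path(out_dir)
    ref = iio.imread(out / "reference.png")
    tgt = iio.imread(out / "target.png")
    meta = json.loads((out / "scene.json").read_text())
    patch_truth = [
        (np.array(p["polygon"], dtype=float), np.array(p["H"], dtype=float).reshape(3, 3))
        for p in meta["patch_truth"]
    ]
    h, w = ref.shape
    truth = np.full((h, w, 2), np.nan)
    tri_polys = [p for p, _ in patch_truth]
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    claimed = np.zeros(pix.shape[0], dtype=bool)
    for poly, H in patch_truth:
        if len(poly) == 3:
            bc = _barycentric(pix, poly)
            inside = np.all(bc >= -1e-9, axis=1) & ~claimed
        else:
            inside = ~claimed
        fwd = pix[inside] @ H[:2, :2].T + H[:2, 2]
        truth.reshape(-1, 2)[inside] = fwd
        claimed |= inside
    tx, ty = truth[..., 0], truth[..., 1]
    visible = (tx >= 0) & (tx <= w - 1) & (ty >= 0) & (ty <= h - 1)
    truth[~visible] = np.nan
    return SyntheticScene(
        reference_image=ref,
        target_image=tgt,
        truth_map=truth,
        patch_truth=patch_truth,
        noise_sigma=float(meta["noise_sigma"]),
        seed=int(meta["seed"]),
    )
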