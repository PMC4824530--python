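"""Lens undistortion and specular-highlight masking.

Endoscopes carry wide-angle (fisheye) optics whose radial and tangential
distortion must be rectified before any geometry (epipolar constraints,
patch homographies) is meaningful.  Intrinsics and distortion coefficients
are inputs here — estimating them from calibration targets is a separate,
standard procedure and out of scope.

Wet mucosa produces saturated specular highlights that move with the light
source, not the tissue, so they are masked out before feature detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import binary_dilation, map_coordinates

__all__ = [
    "CameraModel",
    "undistort_image",
    "undistort_points",
    "distort_points",
    "detect_specular_mask",
    "save_mask",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics with radial(k1,k2) + tangential(p1,p2) distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "CameraModel":
        data = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {"fx", "fy", "cx", "cy", "k1", "k2", "p1", "p2"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown camera keys {sorted(unknown)}; valid keys: {sorted(allowed)}")
        missing = {"fx", "fy", "cx", "cy"} - set(data)
        if missing:
            raise ValueError(f"camera file must define {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})


def _distort_normalized(x: np.ndarray, y: np.ndarray, cam: CameraModel):
    """Forward distortion model on normalized image coordinates."""
    r2 = x * x + y * y
    radial = 1.0 + cam.k1 * r2 + cam.k2 * r2 * r2
    xd = x * radial + 2 * cam.p1 * x * y + cam.p2 * (r2 + 2 * x * x)
    yd = y * radial + cam.p1 * (r2 + 2 * y * y) + 2 * cam.p2 * x * y
    return xd, yd


def distort_points(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Map ideal (undistorted) pixel positions to observed (distorted) ones."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x = (pts[:, 0] - cam.cx) / cam.fx
    y = (pts[:, 1] - cam.cy) / cam.fy
    xd, yd = _distort_normalized(x, y, cam)
    return np.column_stack([xd * cam.fx + cam.cx, yd * cam.fy + cam.cy])


def undistort_points(
    points: np.ndarray, cam: CameraModel, tol: float = 1e-3, max_iter: int = 50
) -> np.ndarray:
    """Invert the distortion model by fixed-point iteration (< ``tol`` px).

    Pixels where the iteration fails to converge (possible far outside the
    calibrated field) are returned as NaN and counted in a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xd = (pts[:, 0] - cam.cx) / cam.fx
    yd = (pts[:, 1] - cam.cy) / cam.fy
    x, y = xd.copy(), yd.copy()
    f = min(cam.fx, cam.fy)
    for _ in range(max_iter):
        xf, yf = _distort_normalized(x, y, cam)
        err = np.hypot(xf - xd, yf - yd) * f
        if np.all(err < tol):
            break
        x = x + (xd - xf)
        y = y + (yd - yf)
    xf, yf = _distort_normalized(x, y, cam)
    bad = np.hypot(xf - xd, yf - yd) * f >= tol
    if bad.any():
        warnings.warn(f"undistort_points: {int(bad.sum())} point(s) did not converge", stacklevel=2)
        x[bad] = np.nan
        y[bad] = np.nan
    return np.column_stack([x * cam.fx + cam.cx, y * cam.fy + cam.cy])


def undistort_image(image: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Resample so straight world lines become straight image lines.

    Each output (undistorted) pixel is pushed through the closed-form
    forward distortion to find its source location in the observed image,
    then bilinearly sampled; locations outside the source are set to 0.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    src = distort_points(np.column_stack([xx.ravel(), yy.ravel()]).astype(float), cam)
    sx = src[:, 0].reshape(h, w)
    sy = src[:, 1].reshape(h, w)
    out = map_coordinates(image.astype(float), [sy, sx], order=1, mode="constant", cval=0.0)
    inside = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
    out[~inside] = 0.0
    return np.clip(np.round(out), 0, 255).astype(image.dtype)


def detect_specular_mask(
    image: np.ndarray,
    gray_threshold: int = 240,
    value_threshold: int = 230,
    saturation_threshold: float = 0.15,
    dilation_px: int = 2,
) -> np.ndarray:
    """Binary mask of saturated specular highlights, dilated by 2 px.

    Grayscale: pixels at or above ``gray_threshold``.  Color: bright
    (value >= ``value_threshold``) and desaturated
    (saturation <= ``saturation_threshold``) pixels — specular highlights
    saturate the sensor and wash out color.  The dilation grows the mask
    over the soft halo around each highlight so that no feature is seeded
    on its rim.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        raw = image >= gray_threshold
    else:
        rgb = image[..., :3].astype(float)
        v = rgb.max(axis=-1)
        s = np.where(v > 0, (v - rgb.min(axis=-1)) / np.maximum(v, 1e-12), 0.0)
        raw = (v >= value_threshold) & (s <= saturation_threshold)
    if not raw.any() or dilation_px <= 0:
        return raw
    r = dilation_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = xx * xx + yy * yy <= r * r
    return binary_dilation(raw, structure=disk)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))
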