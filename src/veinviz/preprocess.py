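"""Illumination preprocessing: adaptive gamma and shading removal.

Light correction finds the entropy-optimal gamma in closed form,
γ* = −1 / mean(ln u) over the skin region of the gray-scale image, and
raises all three channels to it. Shading removal assumes a Lambertian
multiplicative image model I = (shading) × (reflectance detail): in the
log domain an iterated bilateral filter isolates the smooth shading
layer, which is replaced by its spatial mean over the skin region.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import denoise_bilateral

__all__ = ["ImagePlane", "ShadingDecomposition", "estimate_gamma",
           "apply_gamma", "to_grayscale", "bilateral_sigmas",
           "remove_shading"]

#: ITU-R BT.601 luminance weights for the gray-scale conversion
_LUMA = np.array([0.299, 0.587, 0.114])
#: floor (on the 0-255 scale) applied before taking logs
_LOG_FLOOR = 1.0


class EmptyRegionError(ValueError):
    """Raised when an operation needs skin pixels but the mask is empty."""


@dataclass
class ImagePlane:
    """2-D scalar or 3-band raster with a skin-region mask.

    ``value_range`` declares the pixel domain, (0, 1) or (0, 255);
    operations that need a specific domain rescale explicitly.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be HxW or HxWx3")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("color images must have exactly 3 bands")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match image shape")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def normalized(self) -> "ImagePlane":
        """Copy rescaled to [0, 1]."""
        lo, hi = self.value_range
        return ImagePlane((self.pixels - lo) / (hi - lo), self.mask.copy(),
                          (0.0, 1.0))

    def require_mask(self) -> None:
        if not self.mask.any():
            raise EmptyRegionError("skin mask is empty")


@dataclass
class ShadingDecomposition:
    """Log-domain split ln I = base + detail, with the corrected image."""

    base_log: np.ndarray
    detail_log: np.ndarray
    corrected: ImagePlane


def to_grayscale(image: ImagePlane) -> np.ndarray:
    """Luminance-weighted gray-scale (pass-through for scalar images)."""
    if image.is_color:
        return image.pixels @ _LUMA
    return image.pixels.copy()


def estimate_gamma(image: ImagePlane, floor: float = 1.0 / 255.0) -> float:
    """Entropy-optimal restoration exponent γ*.

    γ* = −1 / mean(ln u) over the skin region, with u the gray-scale
    image normalized to (0, 1]; zeros are clamped to ``floor`` so the
    log exists. This closed form maximizes the differential entropy of
    u^γ (the histogram-entropy criterion in the large-sample limit).
    """
    image.require_mask()
    u = to_grayscale(image.normalized())
    u = np.clip(u[image.mask], floor, 1.0)
    mean_log = float(np.mean(np.log(u)))
    if mean_log >= 0.0 or not np.isfinite(mean_log):
        raise ValueError("degenerate image: all pixels at the upper bound, "
                         "gamma is unbounded")
    return -1.0 / mean_log


def apply_gamma(image: ImagePlane, gamma: float) -> ImagePlane:
    """Raise every channel to ``gamma`` (image normalized to [0, 1])."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    norm = image.normalized()
    return ImagePlane(np.clip(norm.pixels, 0.0, 1.0) ** gamma,
                      image.mask.copy(), (0.0, 1.0))


def bilateral_sigmas(image_or_pixels, filter_input: np.ndarray | None = None,
                     mask: np.ndarray | None = None) -> tuple[float, float]:
    """Spatial and intensity bandwidths for one bilateral pass.

    σ1 = 0.05·min(width, height) pixels; σ2 = 0.05·max of the current
    filter input over the skin region (the input changes per iteration,
    so σ2 is recomputed each pass).
    """
    if isinstance(image_or_pixels, ImagePlane):
        pixels = image_or_pixels.pixels
        if mask is None:
            mask = image_or_pixels.mask
    else:
        pixels = np.asarray(image_or_pixels)
    h, w = pixels.shape[:2]
    sigma1 = 0.05 * min(w, h)
    src = pixels if filter_input is None else filter_input
    region = src[mask] if mask is not None else src
    sigma2 = 0.05 * float(np.max(region))
    return sigma1, sigma2


def _bilateral_pass(plane: np.ndarray, sigma1: float, sigma2: float) -> np.ndarray:
    # denoise_bilateral wants modest value ranges; work on a scaled copy
    scale = max(1.0, float(np.max(np.abs(plane))))
    win = 2 * int(np.ceil(3.0 * sigma1)) + 1
    out = denoise_bilateral(plane / scale, win_size=win,
                            sigma_color=sigma2 / scale,
                            sigma_spatial=sigma1, mode="reflect")
    return out * scale


def remove_shading(image: ImagePlane, n_iter: int = 5) -> ShadingDecomposition:
    """Iterated bilateral decomposition in the log domain.

    The image is scaled to [0, 255] and floored at 1 before the log.
    Per channel, ``n_iter`` bilateral passes on ln I produce the smooth
    base (shading) layer; detail = ln I − base. The corrected image
    keeps the detail layer and re-adds the skin-region mean of the base
    layer as a flat base color.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    image.require_mask()
    norm = image.normalized()
    scaled = np.clip(norm.pixels * 255.0, _LOG_FLOOR, 255.0)
    if scaled.ndim == 2:
        scaled = scaled[..., None]
    log_img = np.log(scaled)
    base = np.empty_like(log_img)
    for c in range(log_img.shape[2]):
        remain = log_img[..., c]
        for _ in range(n_iter):
            _, sigma2 = bilateral_sigmas(remain, mask=image.mask)
            sigma1 = 0.05 * min(remain.shape[1], remain.shape[0])
            remain = _bilateral_pass(remain, sigma1, sigma2)
        base[..., c] = remain
    detail = log_img - base
    mean_base = base[image.mask].reshape(-1, base.shape[2]).mean(axis=0)
    corrected = np.exp(detail + mean_base[None, None, :])
    corrected = np.clip(corrected, 0.0, 255.0)
    # non-skin pixels pass through untouched
    passthrough = np.clip(norm.pixels * 255.0, 0.0, 255.0)
    if passthrough.ndim == 2:
        passthrough = passthrough[..., None]
    corrected[~image.mask] = passthrough[~image.mask]
    if not image.is_color:
        corrected = corrected[..., 0]
        base = base[..., 0]
        detail = detail[..., 0]
    out = ImagePlane(corrected / 255.0, image.mask.copy(), (0.0, 1.0))
    return ShadingDecomposition(base, detail, out)
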