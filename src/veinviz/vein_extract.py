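"""Vein-pattern extraction with a 16-filter Gabor bank, plus scoring.

Veins are elongated dark ridges in a blood-concentration map or an NIR
image. A bank of 16 real Gabor kernels (2 scales × 8 orientations)
responds maximally where an oriented line structure matches a filter;
the per-pixel maximum response is contrast-stretched, thresholded with
Otsu's method inside the skin region, and cleaned of small components.
Predictions are scored against ground-truth masks pixel-by-pixel with
accuracy, precision, recall and F1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel, threshold_otsu

from .preprocess import ImagePlane, EmptyRegionError

__all__ = ["GaborBank", "VeinMask", "ConfusionCounts", "Metrics",
           "extract_veins", "score", "dice"]


@dataclass
class GaborBank:
    """Real parts of Gabor kernels over scales × orientations."""

    kernels: list[np.ndarray]
    sigmas: tuple[float, ...]
    orientations: tuple[float, ...]

    @classmethod
    def default(cls, sigmas: tuple[float, ...] = (2.0, 4.0),
                n_orientations: int = 8,
                cycles_per_sigma: float = 0.28) -> "GaborBank":
        """16 filters: 2 scales × 8 orientations spanning [0, π).

        ``cycles_per_sigma`` sets the carrier frequency as
        f = cycles_per_sigma / σ, so the half-wavelength (the dark-bar
        width a filter prefers) scales with σ.
        """
        thetas = tuple(np.pi * k / n_orientations
                       for k in range(n_orientations))
        kernels = []
        for sigma in sigmas:
            freq = cycles_per_sigma / sigma
            for theta in thetas:
                k = np.real(gabor_kernel(freq, theta=theta,
                                         sigma_x=sigma, sigma_y=3.0 * sigma))
                k -= k.mean()          # zero DC: flat regions give no response
                kernels.append(k)
        return cls(kernels, tuple(sigmas), thetas)

    def __len__(self) -> int:
        return len(self.kernels)


@dataclass
class VeinMask:
    """Boolean vein map (True = vein), restricted to the skin region."""

    veins: np.ndarray
    skin: np.ndarray

    def __post_init__(self) -> None:
        self.veins = np.asarray(self.veins, dtype=bool)
        self.skin = np.asarray(self.skin, dtype=bool)
        if self.veins.shape != self.skin.shape:
            raise ValueError("vein and skin masks must share a shape")
        self.veins = self.veins & self.skin


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def extract_veins(image: ImagePlane, bank: GaborBank | None = None,
                  dark_veins: bool = True,
                  min_component_px: int = 50) -> VeinMask:
    """Gabor max-response → contrast stretch → Otsu → component cleanup.

    ``dark_veins`` says veins are darker than background (blood maps are
    displayed inverted, NIR veins are dark); set False for bright-vein
    inputs.
    """
    image.require_mask()
    if image.is_color:
        raise ValueError("vein extraction expects a scalar image")
    img = image.normalized().pixels
    signal = -img if dark_veins else img
    # zero-mean inside the skin region so mask borders don't dominate
    signal = signal - signal[image.mask].mean()
    signal[~image.mask] = 0.0
    response = np.full(img.shape, -np.inf)
    for k in bank.kernels if bank is not None else GaborBank.default().kernels:
        resp = ndimage.convolve(signal, k, mode="nearest")
        np.maximum(response, resp, out=response)
    region = response[image.mask]
    lo, hi = np.percentile(region, [1.0, 99.0])
    if hi <= lo:
        return VeinMask(np.zeros_like(image.mask), image.mask)
    enhanced = np.clip((response - lo) / (hi - lo), 0.0, 1.0)
    vals = enhanced[image.mask]
    if np.ptp(vals) < 1e-9:
        return VeinMask(np.zeros_like(image.mask), image.mask)
    thr = threshold_otsu(vals)
    binary = (enhanced > thr) & image.mask
    labels, n_comp = ndimage.label(binary)
    if n_comp:
        sizes = ndimage.sum_labels(binary, labels, np.arange(1, n_comp + 1))
        small = np.flatnonzero(sizes < min_component_px) + 1
        binary[np.isin(labels, small)] = False
    return VeinMask(binary, image.mask)


def score(pred: VeinMask, truth: VeinMask) -> tuple[ConfusionCounts, Metrics]:
    """Pixelwise confusion counts and the four headline metrics.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``Metrics.undefined``.
    """
    if pred.veins.shape != truth.veins.shape:
        raise ValueError("prediction and truth shapes differ")
    valid = pred.skin & truth.skin
    p = pred.veins[valid]
    t = truth.veins[valid]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    counts = ConfusionCounts(tp, fp, fn, tn)
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = ratio(tp + tn, counts.total, "accuracy")
    prec = ratio(tp, tp + fp, "precision")
    rec = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * prec * rec, prec + rec, "f1") if (prec + rec) > 0 else (
        undefined.append("f1") or 0.0)
    return counts, Metrics(acc, prec, rec, f1, tuple(undefined))


def dice(pred: VeinMask, truth: VeinMask) -> float:
    """Dice overlap of the two vein sets within the shared skin region."""
    valid = pred.skin & truth.skin
    p = pred.veins[valid]
    t = truth.veins[valid]
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & t)) / denom
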