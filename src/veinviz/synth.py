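"""Synthetic skin-image phantoms with known chromophore ground truth.

Stands in for a camera dataset: a phantom is a (Cm, Cb) concentration
field — smooth background variation plus tube-shaped veins of elevated
blood fraction — rendered to RGB through the same color-formation model
the pipeline inverts (per-band reflectance lookup from the Monte Carlo
training grid, RGB = F·r), then degraded with multiplicative shading, a
display gamma, sensor noise, and 8-bit quantization. The generating
vein mask and concentration maps are returned as ground truth, playing
the role of a co-registered NIR reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .optics_data import DEFAULT_GRID, REFLECTANCE_FLOOR, WavelengthGrid
from .mc_skin import CM_RANGE, CB_RANGE, TrainingPair
from .preprocess import ImagePlane
from .spectral_recon import SystemMatrix
from .inverse_model import ConcentrationMap
from .vein_extract import VeinMask

__all__ = ["PhantomSpec", "ReflectanceLookup", "render_phantom"]


@dataclass
class PhantomSpec:
    """Everything needed to draw one phantom, reproducibly."""

    height: int = 128
    width: int = 128
    background_cm: float = 0.08
    background_cb: float = 0.012
    field_noise: float = 0.15          # relative smooth spatial variation
    n_veins: int = 1
    vein_width_px: tuple[float, float] = (4.0, 10.0)
    vein_cb_elevation: float = 0.030   # added blood fraction inside veins
    shading: str = "spotlight"         # "ramp" | "spotlight" | "none"
    shading_min: float = 0.30          # darkest multiplier of the shading field
    gamma_true: float = 2.2            # sensor stores linear^(1/gamma_true)
    sensor_noise_dn: float = 1.5       # additive Gaussian sigma on 0-255
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vein_cb_elevation <= 0:
            raise ValueError("vein Cb elevation must be positive")
        if self.shading not in ("ramp", "spotlight", "none"):
            raise ValueError("shading must be ramp, spotlight or none")
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "vein_width_px" in raw:
            raw["vein_width_px"] = tuple(raw["vein_width_px"])
        return cls(**raw)


class ReflectanceLookup:
    """Bilinear (Cm, Cb) → r(λ) interpolation over the training lattice."""

    def __init__(self, pairs: Sequence[TrainingPair]):
        cms = np.array(sorted({round(p.Cm, 12) for p in pairs}))
        cbs = np.array(sorted({round(p.Cb, 12) for p in pairs}))
        grid = pairs[0].reflectance.grid
        if len(cms) * len(cbs) != len(pairs):
            raise ValueError("training pairs do not form a full lattice")
        values = np.empty((len(cms), len(cbs), grid.n_bands))
        index = {(round(p.Cm, 12), round(p.Cb, 12)): p for p in pairs}
        for i, cm in enumerate(cms):
            for j, cb in enumerate(cbs):
                values[i, j] = index[(cm, cb)].reflectance.values
        self.grid = grid
        self._interp = RegularGridInterpolator(
            (cms, cbs), values, method="linear", bounds_error=True)
        self.cm_bounds = (cms[0], cms[-1])
        self.cb_bounds = (cbs[0], cbs[-1])

    def __call__(self, cm: np.ndarray, cb: np.ndarray) -> np.ndarray:
        """(...,) concentration arrays → (..., B) reflectance."""
        pts = np.stack([np.asarray(cm, dtype=float),
                        np.asarray(cb, dtype=float)], axis=-1)
        try:
            out = self._interp(pts.reshape(-1, 2))
        except ValueError as exc:
            raise ValueError(
                "concentrations fall outside the training lattice hull"
            ) from exc
        out = out.reshape(pts.shape[:-1] + (self.grid.n_bands,))
        return np.clip(out, REFLECTANCE_FLOOR, 1.0)


def _smooth_noise(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    """Zero-mean unit-RMS smooth random field."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma_px)
    rms = np.sqrt(np.mean(sm ** 2))
    return sm / max(rms, 1e-12)


def _draw_vein(rng: np.random.Generator, shape,
               width_range: tuple[float, float]) -> np.ndarray:
    """A smooth random-walk tube crossing the frame, as a boolean mask."""
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    # start on one edge, head roughly across the image
    if rng.random() < 0.5:
        y, x = rng.uniform(0.2 * h, 0.8 * h), 0.0
        angle = rng.uniform(-0.35, 0.35)
    else:
        y, x = 0.0, rng.uniform(0.2 * w, 0.8 * w)
        angle = np.pi / 2 + rng.uniform(-0.35, 0.35)
    step = 1.0
    while 0 <= y < h and 0 <= x < w:
        canvas[int(y), int(x)] = True
        angle += rng.normal(0.0, 0.06)
        y += step * np.sin(angle)
        x += step * np.cos(angle)
    width = rng.uniform(*width_range)
    dist = ndimage.distance_transform_edt(~canvas)
    return dist <= width / 2.0


def render_phantom(spec: PhantomSpec, system: SystemMatrix,
                   lookup: ReflectanceLookup
                   ) -> tuple[ImagePlane, VeinMask, ConcentrationMap]:
    """Render one phantom.

    Returns the 8-bit RGB image (value range 0–255), the ground-truth
    vein mask, and the generating concentration maps. Identical specs
    give byte-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    shape = (h, w)

    # concentration fields: smooth relative variation around the background
    cm_map = spec.background_cm * (
        1.0 + spec.field_noise * _smooth_noise(rng, shape, 0.12 * min(h, w)))
    cb_map = spec.background_cb * (
        1.0 + spec.field_noise * _smooth_noise(rng, shape, 0.12 * min(h, w)))
    vein = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_veins):
        vein |= _draw_vein(rng, shape, spec.vein_width_px)
    cb_map = cb_map + spec.vein_cb_elevation * vein
    cm_map = np.clip(cm_map, *CM_RANGE)
    cb_map = np.clip(cb_map, *CB_RANGE)

    refl = lookup(cm_map, cb_map)                    # (h, w, B)
    rgb_linear = refl @ system.F.T                   # (h, w, 3)

    if spec.shading == "ramp":
        ramp = np.linspace(spec.shading_min, 1.0, w)[None, :]
        shade = np.broadcast_to(ramp, shape).copy()
        shade *= np.linspace(1.0, 0.85 + 0.15 * spec.shading_min, h)[:, None]
    elif spec.shading == "spotlight":
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = rng.uniform(0.3, 0.7) * h, rng.uniform(0.3, 0.7) * w
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (0.5 * min(h, w)) ** 2
        shade = spec.shading_min + (1.0 - spec.shading_min) * np.exp(-r2)
    else:
        shade = np.ones(shape)
    rgb_shaded = np.clip(rgb_linear * shade[..., None], 0.0, 1.0)

    displayed = rgb_shaded ** (1.0 / spec.gamma_true)
    dn = displayed * 255.0 + rng.normal(0.0, spec.sensor_noise_dn, (h, w, 3))
    dn = np.round(np.clip(dn, 0.0, 255.0)).astype(np.uint8)

    skin = np.ones(shape, dtype=bool)
    image = ImagePlane(dn.astype(float), skin, (0.0, 255.0))
    truth_mask = VeinMask(vein, skin)
    truth_maps = ConcentrationMap(cm_map, cb_map, skin,
                                  {"source": "synthetic phantom",
                                   "seed": spec.seed})
    return image, truth_mask, truth_maps
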