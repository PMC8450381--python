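"""Wiener estimation: RGB pixel → 31-band reflectance spectrum.

The color formation model is I = F r with F = S E, S the 3×B stacked
camera responses and E the B×B diagonal illuminant. Given the
second-moment prior ⟨r rᵀ⟩ of skin reflectance spectra, the linear
minimum-mean-squared-error estimator is

    W = ⟨r rᵀ⟩ Fᵀ (F ⟨r rᵀ⟩ Fᵀ)⁻¹,   r̃ = W I.

The prior is built by averaging r rᵀ over a spectra collection — by
default the Monte Carlo training spectra, standing in for a measured
skin reflectance database.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics_data import (DEFAULT_GRID, REFLECTANCE_FLOOR, Spectrum,
                          WavelengthGrid, default_camera_responses,
                          default_illuminant)
from .preprocess import ImagePlane

__all__ = ["SystemMatrix", "ReflectancePrior", "SpectralCube",
           "build_system_matrix", "build_prior", "build_wiener_matrix",
           "fit_exposure_gain", "reconstruct_cube", "save_cube", "load_cube"]


@dataclass
class SystemMatrix:
    """F = S·E (3×B), rows in R, G, B order, with its global gain applied."""

    F: np.ndarray
    grid: WavelengthGrid
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (3, self.grid.n_bands):
            raise ValueError("F must be 3 x n_bands")
        if np.linalg.matrix_rank(self.F) != 3:
            raise ValueError("F must have rank 3")

    def render(self, spectra: np.ndarray) -> np.ndarray:
        """RGB for reflectance row-vectors: (n, B) → (n, 3)."""
        return np.atleast_2d(spectra) @ self.F.T


@dataclass
class ReflectancePrior:
    """Second-moment matrix ⟨r rᵀ⟩ of a reflectance spectra family."""

    autocorr: np.ndarray
    grid: WavelengthGrid
    provenance: str = ""
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.autocorr = np.asarray(self.autocorr, dtype=float)
        b = self.grid.n_bands
        if self.autocorr.shape != (b, b):
            raise ValueError("autocorrelation must be B x B")
        if np.max(np.abs(self.autocorr - self.autocorr.T)) > 1e-10:
            raise ValueError("autocorrelation must be symmetric")
        w = np.linalg.eigvalsh(self.autocorr)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValueError("autocorrelation must be positive semidefinite")


@dataclass
class SpectralCube:
    """H×W×B reflectance values in (0, 1] with a skin mask."""

    values: np.ndarray
    grid: WavelengthGrid
    mask: np.ndarray
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != self.grid.n_bands:
            raise ValueError("cube must be H x W x n_bands")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must match cube")


def build_system_matrix(grid: WavelengthGrid = DEFAULT_GRID,
                        responses: Sequence[Spectrum] | None = None,
                        illuminant: Spectrum | None = None,
                        reference_spectra: np.ndarray | None = None) -> SystemMatrix:
    """Compose F = S·E and normalize its overall gain.

    If ``reference_spectra`` (n, B) are given, the gain is set so the
    brightest of them renders with a maximum channel value of 1 — pinning
    the arbitrary radiometric scale of the camera/illuminant product.
    """
    if responses is None:
        responses = default_camera_responses(grid)
    if illuminant is None:
        illuminant = default_illuminant(grid)
    S = np.stack([r.values for r in responses])
    F = S * illuminant.values[None, :]
    gain = 1.0
    if reference_spectra is not None:
        peak = float(np.max(np.atleast_2d(reference_spectra) @ F.T))
        if peak > 0:
            gain = 1.0 / peak
    return SystemMatrix(F * gain, grid, gain)


def build_prior(spectra: Sequence[Spectrum] | np.ndarray,
                grid: WavelengthGrid = DEFAULT_GRID,
                provenance: str = "") -> ReflectancePrior:
    """Average r·rᵀ over a spectra collection."""
    if isinstance(spectra, np.ndarray):
        mat = np.atleast_2d(spectra)
    else:
        spectra = list(spectra)
        if len(spectra) == 0:
            raise ValueError("cannot build a prior from an empty collection")
        grid = spectra[0].grid
        mat = np.stack([s.values for s in spectra])
    if mat.shape[0] == 0:
        raise ValueError("cannot build a prior from an empty collection")
    if mat.shape[1] != grid.n_bands:
        raise ValueError("spectra are not on the stated grid")
    autocorr = mat.T @ mat / mat.shape[0]
    autocorr = 0.5 * (autocorr + autocorr.T)
    return ReflectancePrior(autocorr, grid, provenance, samples=mat)


def build_wiener_matrix(prior: ReflectancePrior, system: SystemMatrix,
                        cond_limit: float = 1e12) -> np.ndarray:
    """W = ⟨r rᵀ⟩ Fᵀ (F ⟨r rᵀ⟩ Fᵀ)⁻¹, shape B×3.

    A ridge term is added to the 3×3 Gram matrix (with a warning) if it
    is numerically singular.
    """
    F = system.F
    R = prior.autocorr
    gram = F @ R @ F.T
    if np.linalg.cond(gram) > cond_limit:
        warnings.warn("singular camera Gram matrix; ridge-regularizing",
                      RuntimeWarning, stacklevel=2)
        gram = gram + 1e-9 * np.trace(gram) / 3.0 * np.eye(3)
    return R @ F.T @ np.linalg.inv(gram)


def fit_exposure_gain(rgb: ImagePlane, system: SystemMatrix,
                      prior: ReflectancePrior) -> float:
    """Scalar exposure gain absorbing the unknown shading constant.

    Ratio of the image's median masked intensity to the median rendered
    intensity of the prior's sample spectra. Dividing the image by this
    gain puts it on the radiometric scale W was built for.
    """
    if prior.samples is None:
        raise ValueError("prior carries no sample spectra to render")
    img = rgb.normalized()
    med_img = float(np.median(img.pixels[img.mask]))
    med_prior = float(np.median(system.render(prior.samples)))
    if med_prior <= 0 or med_img <= 0:
        return 1.0
    return med_img / med_prior


def reconstruct_cube(rgb: ImagePlane, W: np.ndarray,
                     grid: WavelengthGrid = DEFAULT_GRID,
                     gain: float = 1.0) -> SpectralCube:
    """Per-pixel r̃ = W·[R,G,B]ᵀ, clipped to (ε, 1].

    ``gain`` is the per-image exposure factor from
    :func:`fit_exposure_gain`; unmasked pixels are filled with 1.
    """
    if W.shape != (grid.n_bands, 3):
        raise ValueError(f"W must be {grid.n_bands} x 3, got {W.shape}")
    img = rgb.normalized()
    if not img.is_color:
        raise ValueError("reconstruction needs an RGB image")
    h, w, _ = img.pixels.shape
    flat = img.pixels.reshape(-1, 3) / gain
    cube = (flat @ W.T).reshape(h, w, grid.n_bands)
    out_of_range = ((cube[rgb.mask] <= REFLECTANCE_FLOOR) |
                    (cube[rgb.mask] > 1.0)).mean() if rgb.mask.any() else 0.0
    cube = np.clip(cube, REFLECTANCE_FLOOR, 1.0)
    cube[~rgb.mask] = 1.0
    return SpectralCube(cube, grid, rgb.mask.copy(),
                        clipped_fraction=float(out_of_range))


def save_cube(cube: SpectralCube, path) -> None:
    """Band-sequential float64 binary with a JSON sidecar.

    ``path`` gets the raw values (band-sequential, C order); ``path`` with
    a ``.json`` suffix records dims, grid, dtype and the mask (packed as
    0/1 bytes alongside)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0)).tofile(path)
    cube.mask.astype(np.uint8).tofile(path.with_suffix(".mask"))
    meta = {"height": cube.values.shape[0], "width": cube.values.shape[1],
            "bands": cube.values.shape[2], "dtype": "float64",
            "interleave": "bsq",
            "grid": {"start_nm": cube.grid.start_nm,
                     "stop_nm": cube.grid.stop_nm,
                     "step_nm": cube.grid.step_nm},
            "clipped_fraction": cube.clipped_fraction}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_cube(path) -> SpectralCube:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    g = meta["grid"]
    grid = WavelengthGrid(g["start_nm"], g["stop_nm"], g["step_nm"])
    h, w, b = meta["height"], meta["width"], meta["bands"]
    values = np.moveaxis(
        np.fromfile(path, dtype=np.float64).reshape(b, h, w), 0, 2)
    mask = np.fromfile(path.with_suffix(".mask"),
                       dtype=np.uint8).reshape(h, w).astype(bool)
    return SpectralCube(values.copy(), grid, mask,
                        meta.get("clipped_fraction", 0.0))
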