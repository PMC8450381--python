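"""Spectral constants and skin-layer optical properties.

Every physical curve the pipeline consumes — illuminant power, camera
channel sensitivities, chromophore molar extinction coefficients, and
per-layer absorption/scattering/anisotropy — enters through this module.
Curves live on a shared :class:`WavelengthGrid` (default 400–700 nm at
10 nm, 31 bands); loaders resample arbitrary tabulations onto it by
linear interpolation and apply role-specific validation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "ChromophoreSet",
    "LayerProperties",
    "SkinLayerStack",
    "load_spectral_table",
    "write_spectral_table",
    "load_fixture",
    "fixture_manifest",
    "default_illuminant",
    "default_camera_responses",
    "default_chromophores",
    "default_skin_stack",
]

#: floor applied to reflectance values so log-absorbance is always defined
REFLECTANCE_FLOOR = 1e-4

_ROLES = {"illuminant", "response", "reflectance", "extinction", "mu_a",
          "mu_s", "anisotropy", "generic"}


class SpectralCoverageError(ValueError):
    """Raised when a table does not cover the requested wavelength grid."""


class SpectralFormatError(ValueError):
    """Raised for malformed spectral tables."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling in nanometres."""

    start_nm: float = 400.0
    stop_nm: float = 700.0
    step_nm: float = 10.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise ValueError("start_nm must be below stop_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        span = self.stop_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid span must be divisible by step_nm")

    @property
    def n_bands(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    def subgrid(self, start_nm: float, stop_nm: float,
                step_nm: float | None = None) -> "WavelengthGrid":
        """Restrict to [start_nm, stop_nm]; optionally coarsen the step."""
        step = self.step_nm if step_nm is None else step_nm
        if step % self.step_nm:
            raise ValueError("sub-grid step must be a multiple of the parent step")
        return WavelengthGrid(start_nm, stop_nm, step)

    def indices_in(self, parent: "WavelengthGrid") -> np.ndarray:
        """Indices of this grid's bands inside a parent grid."""
        idx = (self.wavelengths - parent.start_nm) / parent.step_nm
        if np.any(np.abs(idx - np.round(idx)) > 1e-9):
            raise ValueError("grid is not aligned with the parent grid")
        idx = np.round(idx).astype(int)
        if idx.min() < 0 or idx.max() >= parent.n_bands:
            raise ValueError("grid extends beyond the parent grid")
        return idx


#: the working grid used throughout: 400–700 nm at 10 nm → 31 bands
DEFAULT_GRID = WavelengthGrid(400.0, 700.0, 10.0)
#: regression sub-grid where oxy/deoxy hemoglobin separate best
REGRESSION_GRID = WavelengthGrid(500.0, 600.0, 10.0)


@dataclass
class Spectrum:
    """Per-band values on a :class:`WavelengthGrid`.

    The physical meaning of ``values`` depends on the role: relative power
    (illuminant), relative sensitivity (camera), fraction (reflectance),
    cm^-1/(mol/L) (molar extinction) or cm^-1 (absorption/scattering).
    """

    grid: WavelengthGrid
    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError(
                f"expected {self.grid.n_bands} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")
        _validate_role(self.values, self.role)

    def resample(self, grid: WavelengthGrid) -> "Spectrum":
        """Linear interpolation onto another grid (must be covered)."""
        wl_src = self.grid.wavelengths
        wl_dst = grid.wavelengths
        if wl_dst[0] < wl_src[0] - 1e-9 or wl_dst[-1] > wl_src[-1] + 1e-9:
            raise SpectralCoverageError("target grid not covered by spectrum")
        return Spectrum(grid, np.interp(wl_dst, wl_src, self.values), self.role)

    def __len__(self) -> int:
        return self.grid.n_bands


def _validate_role(values: np.ndarray, role: str) -> None:
    if role not in _ROLES:
        raise ValueError(f"unknown spectrum role {role!r}")
    if role == "reflectance":
        if np.any(values <= 0) or np.any(values > 1 + 1e-12):
            raise ValueError("reflectance values must lie in (0, 1]")
    elif role == "extinction":
        if np.any(values <= 0):
            raise ValueError("extinction coefficients must be positive")
    elif role in ("illuminant", "response", "mu_a"):
        if np.any(values < 0):
            raise ValueError(f"{role} values must be nonnegative")
    elif role == "mu_s":
        if np.any(values <= 0):
            raise ValueError("scattering coefficients must be positive")
    elif role == "anisotropy":
        if np.any(np.abs(values) > 1):
            raise ValueError("anisotropy must lie in [-1, 1]")


def load_spectral_table(path: str | Path, role: str = "generic",
                        grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Read a ``wavelength_nm,value`` CSV and resample onto ``grid``.

    The table must cover the grid; wavelengths must be strictly increasing.
    """
    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"} <= set(df.columns):
        raise SpectralFormatError(
            f"{path}: expected columns wavelength_nm,value")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    vals = df["value"].to_numpy(dtype=float)
    if len(wl) < 2 or np.any(np.diff(wl) <= 0):
        raise SpectralFormatError(f"{path}: wavelengths must be strictly increasing")
    lo, hi = grid.wavelengths[0], grid.wavelengths[-1]
    if wl[0] > lo + 1e-9 or wl[-1] < hi - 1e-9:
        raise SpectralCoverageError(
            f"{path}: table covers {wl[0]}-{wl[-1]} nm, grid needs {lo}-{hi} nm")
    return Spectrum(grid, np.interp(grid.wavelengths, wl, vals), role)


def write_spectral_table(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum back out as a ``wavelength_nm,value`` CSV."""
    df = pd.DataFrame({"wavelength_nm": spectrum.grid.wavelengths,
                       "value": spectrum.values})
    df.to_csv(path, index=False, float_format="%.17g")


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("veinviz").joinpath("data", name)))


def load_fixture(name: str, role: str = "generic",
                 grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Load one of the bundled spectral-constant CSVs."""
    return load_spectral_table(_fixture_path(name), role, grid)


def fixture_manifest() -> dict:
    with open(_fixture_path("manifest.json")) as fh:
        return json.load(fh)


@dataclass
class ChromophoreSet:
    """Molar extinction curves of the three pigments used in unmixing."""

    eps_melanin: Spectrum
    eps_oxy: Spectrum
    eps_deoxy: Spectrum

    def __post_init__(self) -> None:
        g = self.eps_melanin.grid
        if self.eps_oxy.grid != g or self.eps_deoxy.grid != g:
            raise ValueError("chromophore spectra must share one grid")

    def resample(self, grid: WavelengthGrid) -> "ChromophoreSet":
        return ChromophoreSet(self.eps_melanin.resample(grid),
                              self.eps_oxy.resample(grid),
                              self.eps_deoxy.resample(grid))

    def design_matrix(self) -> np.ndarray:
        """Bands x 4 matrix [eps_m, eps_ob, eps_db, 1] for absorbance fits."""
        n = len(self.eps_melanin)
        return np.column_stack([self.eps_melanin.values, self.eps_oxy.values,
                                self.eps_deoxy.values, np.ones(n)])


def default_chromophores(grid: WavelengthGrid = DEFAULT_GRID) -> ChromophoreSet:
    return ChromophoreSet(
        load_fixture("eps_melanin.csv", "extinction", grid),
        load_fixture("eps_hbo2.csv", "extinction", grid),
        load_fixture("eps_hb.csv", "extinction", grid),
    )


def default_illuminant(grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """CIE D65, normalized to unit mean (only relative shape enters F = SE)."""
    s = load_fixture("illuminant_d65.csv", "illuminant", grid)
    return Spectrum(grid, s.values / s.values.mean(), "illuminant")


def default_camera_responses(grid: WavelengthGrid = DEFAULT_GRID) -> list[Spectrum]:
    """R, G, B channel sensitivities (bundled Gaussian model), in that order."""
    return [load_fixture(f"camera_response_{c}.csv", "response", grid)
            for c in ("r", "g", "b")]


@dataclass
class LayerProperties:
    """Optical properties of one homogeneous skin layer.

    mu_a and mu_s in cm^-1, anisotropy g dimensionless, refractive index n,
    thickness d in cm.
    """

    name: str
    mu_a: Spectrum
    mu_s: Spectrum
    g: Spectrum
    n: float
    d: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.d <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class SkinLayerStack:
    """Ordered top-down layers plus the absorption building blocks.

    ``mua_baseline`` is the pigment-free tissue absorption shared by the
    epidermis and dermis; melanin and hemoglobin absorption are mixed in
    per (Cm, Cb) by :func:`veinviz.mc_skin.compose_absorption`.
    """

    layers: list[LayerProperties]
    mua_baseline: Spectrum
    mua_melanin: Spectrum
    chromophores: ChromophoreSet
    grid: WavelengthGrid = DEFAULT_GRID

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)


def default_skin_stack(grid: WavelengthGrid = DEFAULT_GRID) -> SkinLayerStack:
    """Three-layer forearm skin model: epidermis, dermis, hypodermis.

    Thicknesses 0.006 / 0.09 / 0.03 cm and refractive indices
    1.37 / 1.37 / 1.44. The epidermis and dermis mu_a stored here are the
    pigment-free baseline; per-concentration absorption is composed at
    simulation time.
    """
    base = load_fixture("mua_baseline.csv", "mu_a", grid)
    mel = Spectrum(grid, 6.6e11 * grid.wavelengths ** -3.33, "mu_a")
    layers = [
        LayerProperties("epidermis", base,
                        load_fixture("mus_epidermis.csv", "mu_s", grid),
                        load_fixture("g_epidermis.csv", "anisotropy", grid),
                        n=1.37, d=0.006),
        LayerProperties("dermis", base,
                        load_fixture("mus_dermis.csv", "mu_s", grid),
                        load_fixture("g_dermis.csv", "anisotropy", grid),
                        n=1.37, d=0.09),
        LayerProperties("hypodermis",
                        load_fixture("mua_hypodermis.csv", "mu_a", grid),
                        load_fixture("mus_hypodermis.csv", "mu_s", grid),
                        load_fixture("g_hypodermis.csv", "anisotropy", grid),
                        n=1.44, d=0.03),
    ]
    return SkinLayerStack(layers, base, mel, default_chromophores(grid), grid)
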