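"""Two-stage regression inverse: spectra → chromophore concentrations.

Stage one fits each absorbance spectrum A(λ) = −log10 r(λ) with the
modified Beer–Lambert model

    A(λ) = am·εm(λ) + aob·εob(λ) + adb·εdb(λ) + a0,

where the coefficients fold concentration × mean-path-length products
and a0 absorbs scattering loss. Stage two maps (am, atb = aob + adb, a0)
through a fixed 14-term cubic feature vector to the melanin and blood
volume fractions, with the 14-vectors bm and btb fitted by least squares
on the Monte Carlo training pairs.

Fitting is restricted to the 500–600 nm sub-grid by default, where the
oxy/deoxy hemoglobin extinction shapes differ most; the full 400–700 nm
fit is noticeably worse (the Soret-band nonlinearity is not captured by
a wavelength-independent path length).
"""
from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .optics_data import (ChromophoreSet, REGRESSION_GRID, Spectrum,
                          WavelengthGrid, default_chromophores)
from .mc_skin import TrainingPair

__all__ = [
    "AbsorbanceSpectrum", "RegressionCoefficients", "ConcentrationMap",
    "InverseModel", "to_absorbance", "fit_absorbance_regression",
    "build_feature_vector", "train_concentration_map",
    "predict_concentrations",
]

#: condition-number guard before the ridge fallback kicks in
_COND_LIMIT = 1e12


@dataclass
class AbsorbanceSpectrum:
    """A(λ) = −log10 r(λ) on a regression sub-grid."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError("absorbance length does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("absorbance contains non-finite values")


@dataclass
class RegressionCoefficients:
    """Stage-one coefficients for one spectrum; atb is derived."""

    am: float
    aob: float
    adb: float
    a0: float
    r_squared: float

    @property
    def atb(self) -> float:
        return self.aob + self.adb


@dataclass
class ConcentrationMap:
    """Per-pixel melanin and blood volume-fraction maps."""

    Cm_map: np.ndarray
    Cb_map: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class InverseModel:
    """Trained stage-two map: feature vector → (Cm, Cb).

    ``a0_reference`` is the median stage-one intercept over the training
    spectra; exposure errors shift every pixel's a0 by the same constant,
    so aligning an image's median a0 to this reference fixes the unknown
    radiometric scale.
    """

    bm: np.ndarray
    btb: np.ndarray
    grid: WavelengthGrid
    training_rmse: tuple[float, float] = (float("nan"), float("nan"))
    a0_reference: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bm = np.asarray(self.bm, dtype=float)
        self.btb = np.asarray(self.btb, dtype=float)
        if self.bm.shape != (14,) or self.btb.shape != (14,):
            raise ValueError("bm and btb must be 14-vectors")

    def save(self, path: str | Path) -> None:
        payload = {
            "bm": self.bm.tolist(), "btb": self.btb.tolist(),
            "grid": {"start_nm": self.grid.start_nm,
                     "stop_nm": self.grid.stop_nm,
                     "step_nm": self.grid.step_nm},
            "training_rmse": list(self.training_rmse),
            "a0_reference": self.a0_reference,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "InverseModel":
        with open(path) as fh:
            payload = json.load(fh)
        g = payload["grid"]
        return cls(np.array(payload["bm"]), np.array(payload["btb"]),
                   WavelengthGrid(g["start_nm"], g["stop_nm"], g["step_nm"]),
                   tuple(payload.get("training_rmse", (np.nan, np.nan))),
                   payload.get("a0_reference", 0.0),
                   payload.get("provenance", {}))


def to_absorbance(r: Spectrum,
                  grid: WavelengthGrid = REGRESSION_GRID) -> AbsorbanceSpectrum:
    """Elementwise −log10 of reflectance, restricted to a sub-grid."""
    idx = grid.indices_in(r.grid)
    vals = r.values[idx]
    if np.any(vals <= 0):
        raise ValueError("reflectance must be positive (pre-clip it)")
    return AbsorbanceSpectrum(grid, -np.log10(vals))


def _design(chroms: ChromophoreSet, grid: WavelengthGrid) -> np.ndarray:
    return chroms.resample(grid).design_matrix()


def _solve_ls(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with a minimum-norm / ridge fallback on rank issues."""
    if np.linalg.cond(X) > _COND_LIMIT:
        import warnings
        warnings.warn("near-collinear design; using ridge-regularized solve",
                      RuntimeWarning, stacklevel=3)
        XtX = X.T @ X
        eps = 1e-10 * np.trace(XtX) / X.shape[1]
        return np.linalg.solve(XtX + eps * np.eye(X.shape[1]), X.T @ y)
    sol, *_ = np.linalg.lstsq(X, y, rcond=None)
    return sol


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30:
        return 1.0 if ss_res <= 1e-30 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def fit_absorbance_regression(A: AbsorbanceSpectrum,
                              chroms: ChromophoreSet) -> RegressionCoefficients:
    """OLS of absorbance on [εm, εob, εdb, 1] with an R² report."""
    if A.grid.n_bands < 4:
        raise ValueError("need at least 4 bands for the 4-parameter fit")
    X = _design(chroms, A.grid)
    coef = _solve_ls(X, A.values)
    resid = A.values - X @ coef
    return RegressionCoefficients(float(coef[0]), float(coef[1]),
                                  float(coef[2]), float(coef[3]),
                                  _r_squared(A.values, resid))


def build_feature_vector(coefs: RegressionCoefficients) -> np.ndarray:
    """The fixed 14-term cubic feature vector of (am, atb, a0)."""
    return _features(np.array([[coefs.am, coefs.atb, coefs.a0]]))[0]


def _features(ata: np.ndarray) -> np.ndarray:
    """(n, 3) array of [am, atb, a0] → (n, 14) cubic feature matrix."""
    am, atb, a0 = ata[:, 0], ata[:, 1], ata[:, 2]
    return np.column_stack([
        np.ones_like(am), am, atb, a0,
        am ** 3, atb ** 3, a0 ** 3,
        am * atb * a0,
        am ** 2 * atb, am ** 2 * a0,
        atb ** 2 * am, atb ** 2 * a0,
        a0 ** 2 * am, a0 ** 2 * atb,
    ])


def _monomial_weights(s: np.ndarray) -> np.ndarray:
    """Per-feature scale factors induced by scaling (am, atb, a0) by s."""
    sm, st, s0 = s
    return np.array([
        1.0, sm, st, s0,
        sm ** 3, st ** 3, s0 ** 3,
        sm * st * s0,
        sm ** 2 * st, sm ** 2 * s0,
        st ** 2 * sm, st ** 2 * s0,
        s0 ** 2 * sm, s0 ** 2 * st,
    ])


def _stage_one_batch(refl: np.ndarray, refl_grid: WavelengthGrid,
                     chroms: ChromophoreSet,
                     grid: WavelengthGrid) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized stage-one fit for many spectra.

    ``refl``: (n, B) reflectance on ``refl_grid``. Returns the (n, 3)
    [am, atb, a0] array and the per-spectrum R².
    """
    idx = grid.indices_in(refl_grid)
    A = -np.log10(refl[:, idx])
    X = _design(chroms, grid)
    pinv = np.linalg.pinv(X)
    coef = A @ pinv.T                       # (n, 4): am, aob, adb, a0
    resid = A - coef @ X.T
    ss_res = np.sum(resid ** 2, axis=1)
    ss_tot = np.sum((A - A.mean(axis=1, keepdims=True)) ** 2, axis=1)
    r2 = np.where(ss_tot > 1e-30, 1.0 - ss_res / np.maximum(ss_tot, 1e-30),
                  np.where(ss_res <= 1e-30, 1.0, 0.0))
    ata = np.column_stack([coef[:, 0], coef[:, 1] + coef[:, 2], coef[:, 3]])
    return ata, np.clip(r2, 0.0, 1.0)


def mean_r_squared(pairs: Sequence[TrainingPair], chroms: ChromophoreSet,
                   grid: WavelengthGrid) -> float:
    """Mean stage-one R² over a set of training spectra."""
    refl = np.stack([p.reflectance.values for p in pairs])
    _, r2 = _stage_one_batch(refl, pairs[0].reflectance.grid, chroms, grid)
    return float(r2.mean())


def train_concentration_map(pairs: Sequence[TrainingPair],
                            chroms: ChromophoreSet | None = None,
                            grid: WavelengthGrid = REGRESSION_GRID) -> InverseModel:
    """Fit bm and btb on MC training pairs.

    Stage one is fitted per pair on ``grid``; the cubic features are then
    regressed against the known Cm and Cb (volume fractions).
    """
    if len(pairs) < 14:
        raise ValueError("need at least 14 training pairs")
    if chroms is None:
        chroms = default_chromophores(pairs[0].reflectance.grid)
    refl = np.stack([p.reflectance.values for p in pairs])
    ata, r2 = _stage_one_batch(refl, pairs[0].reflectance.grid, chroms, grid)
    # the raw monomials span many orders of magnitude (the extinction
    # scale makes am, atb tiny); solve in a column-scaled basis and map
    # the coefficients back exactly
    scale = np.sqrt(np.mean(ata ** 2, axis=0))
    scale[scale <= 0] = 1.0
    weights = _monomial_weights(scale)
    feats = _features(ata / scale)
    cm = np.array([p.Cm for p in pairs])
    cb = np.array([p.Cb for p in pairs])
    bm = _solve_ls(feats, cm) / weights
    btb = _solve_ls(feats, cb) / weights
    feats = _features(ata)
    rmse_m = float(np.sqrt(np.mean((feats @ bm - cm) ** 2)))
    rmse_b = float(np.sqrt(np.mean((feats @ btb - cb) ** 2)))
    prov = {
        "n_pairs": len(pairs),
        "mean_stage1_r2": float(r2.mean()),
        "dataset_hash": hashlib.sha256(refl.tobytes()).hexdigest()[:16],
    }
    a0_ref = float(np.median(ata[:, 2]))
    return InverseModel(bm, btb, grid, (rmse_m, rmse_b), a0_ref, prov)


def predict_concentrations(cube, model: InverseModel,
                           chroms: ChromophoreSet | None = None,
                           grid: WavelengthGrid | None = None) -> ConcentrationMap:
    """Apply the trained two-stage inverse to a reflectance cube.

    ``cube`` is a :class:`veinviz.spectral_recon.SpectralCube`. ``grid``
    selects the stage-one fit bands at inference (defaults to the
    training sub-grid; a 20-nm step is the supported alternative).
    Predicted concentrations are volume fractions and are deliberately
    not clipped to the training range — out-of-range values carry vein
    contrast.
    """
    if chroms is None:
        chroms = default_chromophores(cube.grid)
    if grid is None:
        grid = model.grid
    h, w, _ = cube.values.shape
    flat = cube.values.reshape(h * w, -1)
    mask_flat = cube.mask.ravel()
    ata = np.zeros((h * w, 3))
    sub, r2 = _stage_one_batch(flat[mask_flat], cube.grid, chroms, grid)
    ata[mask_flat] = sub
    feats = _features(ata)
    cm = (feats @ model.bm).reshape(h, w)
    cb = (feats @ model.btb).reshape(h, w)
    cm[~cube.mask] = 0.0
    cb[~cube.mask] = 0.0
    prov = dict(model.provenance)
    prov["mean_pixel_stage1_r2"] = float(r2.mean()) if len(r2) else float("nan")
    return ConcentrationMap(cm, cb, cube.mask.copy(), prov)
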