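"""Monte Carlo photon transport in layered skin (MCML-style).

The forward model: for a concentration pair (Cm, Cb) — melanin volume
fraction in the epidermis, blood volume fraction in the dermis — compose
per-layer absorption coefficients and estimate the total diffuse
reflectance of the three-layer stack by a hop/drop/spin photon random
walk with Henyey–Greenstein scattering, Fresnel boundaries, and Russian
roulette. Sweeping a (Cm, Cb) lattice yields the training pairs that
drive both the reflectance prior for Wiener estimation and the
regression inverse model.

Two estimators are provided:

* :func:`simulate_reflectance` — the classic absorption-weighted walk
  (weight drop mu_a/mu_t each interaction, roulette termination).
* pathlength reweighting, used by :func:`build_training_grid` — paths are
  sampled once per wavelength band in the scattering-only medium and each
  escaped path is attenuated by exp(-sum_l mu_a,l * s_l) for every
  concentration pair. Both estimators are unbiased for the same radiative
  transfer problem; reweighting amortizes one path ensemble over the
  whole concentration sweep.

Only total diffuse reflectance is scored (pencil beam, laterally
infinite layers); there is no spatial or temporal binning.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from numba import uint64, float64

from .optics_data import (DEFAULT_GRID, Spectrum, SkinLayerStack,
                          WavelengthGrid, default_skin_stack,
                          REFLECTANCE_FLOOR)

__all__ = [
    "CM_RANGE", "CB_RANGE", "PhotonRunConfig", "SimResult", "TrainingPair",
    "compose_absorption", "blood_mua", "simulate_reflectance",
    "simulate_spectrum", "sample_paths", "reflectance_from_paths",
    "build_training_grid", "save_training_pairs", "load_training_pairs",
]

#: melanin volume-fraction range spanned by the training grid
CM_RANGE = (0.013, 0.43)
#: blood volume-fraction range spanned by the training grid
CB_RANGE = (0.001, 0.07)

#: hemoglobin molarity of whole blood: 150 g/L over 64500 g/mol
HB_MOLARITY = 150.0 / 64500.0
LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class PhotonRunConfig:
    """Termination and sampling controls for one MC run."""

    n_photons: int = 100_000
    seed: int = 0
    weight_threshold: float = 1e-4
    roulette_chance: float = 0.1
    max_steps: int = 1_000_000
    oxygen_saturation: float = 0.75

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0 < self.weight_threshold < 1:
            raise ValueError("weight_threshold must lie in (0, 1)")
        if not 0 < self.roulette_chance < 1:
            raise ValueError("roulette_chance must lie in (0, 1)")
        if not 0 <= self.oxygen_saturation <= 1:
            raise ValueError("oxygen_saturation must lie in [0, 1]")

    def with_seed(self, seed: int) -> "PhotonRunConfig":
        return PhotonRunConfig(self.n_photons, int(seed) % (2**31 - 1),
                               self.weight_threshold, self.roulette_chance,
                               self.max_steps, self.oxygen_saturation)


@dataclass
class SimResult:
    """Weight bookkeeping of one run; fractions of launched energy."""

    diffuse_reflectance: float
    specular_reflectance: float
    transmittance: float
    absorbed: float
    std_error: float

    @property
    def total(self) -> float:
        return (self.diffuse_reflectance + self.specular_reflectance +
                self.transmittance + self.absorbed)


@dataclass
class TrainingPair:
    """(Cm, Cb) concentrations with their simulated reflectance spectrum."""

    Cm: float
    Cb: float
    reflectance: Spectrum


def blood_mua(eps_oxy: np.ndarray, eps_deoxy: np.ndarray,
              oxygen_saturation: float = 0.75) -> np.ndarray:
    """Whole-blood absorption, cm^-1, at a given oxygen saturation."""
    eps = oxygen_saturation * eps_oxy + (1.0 - oxygen_saturation) * eps_deoxy
    return LN10 * eps * HB_MOLARITY


def compose_absorption(Cm: float, Cb: float, stack: SkinLayerStack,
                       oxygen_saturation: float = 0.75,
                       check_range: bool = True) -> np.ndarray:
    """Per-layer absorption spectra for a concentration pair.

    Epidermis: Cm * mua_melanin + (1-Cm) * baseline.
    Dermis:    Cb * mua_blood   + (1-Cb) * baseline, blood mixing oxy and
    deoxy hemoglobin at ``oxygen_saturation``.
    Hypodermis: fixed fixture curve, independent of (Cm, Cb).

    Returns an array of shape (3, n_bands), cm^-1.
    """
    if check_range and not (CM_RANGE[0] - 1e-12 <= Cm <= CM_RANGE[1] + 1e-12):
        raise ValueError(f"Cm={Cm} outside training range {CM_RANGE}")
    if check_range and not (CB_RANGE[0] - 1e-12 <= Cb <= CB_RANGE[1] + 1e-12):
        raise ValueError(f"Cb={Cb} outside training range {CB_RANGE}")
    base = stack.mua_baseline.values
    mel = stack.mua_melanin.values
    blood = blood_mua(stack.chromophores.eps_oxy.values,
                      stack.chromophores.eps_deoxy.values, oxygen_saturation)
    mua_epi = Cm * mel + (1.0 - Cm) * base
    mua_derm = Cb * blood + (1.0 - Cb) * base
    mua_hypo = stack.layers[2].mu_a.values
    return np.stack([mua_epi, mua_derm, mua_hypo])


# ---------------------------------------------------------------------------
# random number generation: xorshift64* stream, seeded through splitmix64
# ---------------------------------------------------------------------------

_U = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(uint64(uint64), cache=True, inline="always")
def _splitmix64(x):
    x = (x + _U(0x9E3779B97F4A7C15)) & _U(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)) & _U(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)) & _U(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> _U(31))


@njit(uint64(uint64), cache=True, inline="always")
def _xorshift(s):
    s ^= s >> _U(12)
    s ^= (s << _U(25)) & _U(0xFFFFFFFFFFFFFFFF)
    s ^= s >> _U(27)
    return s


@njit(float64(uint64), cache=True, inline="always")
def _to_u01(s):
    bits = ((s * _U(0x2545F4914F6CDD1D)) & _U(0xFFFFFFFFFFFFFFFF)) >> _U(11)
    return (np.float64(bits) + 0.5) * _INV_2_53


@njit(cache=True, fastmath=True, inline="always")
def _hg_cos(g, xi):
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


@njit(cache=True, fastmath=True, inline="always")
def _fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance and transmitted cosine."""
    if n1 == n2:
        return 0.0, cos_i
    if cos_i > 0.99999:
        r = (n2 - n1) / (n2 + n1)
        return r * r, 1.0
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, fastmath=True)
def _mc_kernel(mu_a, mu_s, g, n, z_top, z_bot, n_photons, seed,
               w_thresh, roulette_chance, max_steps):
    """Absorption-weighted multi-layer walk at a single wavelength.

    Returns (rd_sum, rd_sumsq, specular_total, tt_sum, a_sum) as summed
    photon weights; rd_sumsq accumulates per-photon escaped-top weight
    squared for the variance estimate.
    """
    rng = _splitmix64(_U(seed))
    n_layers = mu_a.shape[0]
    r0 = (1.0 - n[0]) / (1.0 + n[0])
    rsp = r0 * r0
    rd_sum = 0.0
    rd_sumsq = 0.0
    tt_sum = 0.0
    a_sum = 0.0
    for _ in range(n_photons):
        w = 1.0 - rsp
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        rd_photon = 0.0
        alive = True
        steps = 0
        rng = _xorshift(rng)
        s_left = -np.log(_to_u01(rng))
        while alive:
            steps += 1
            if steps > max_steps:
                a_sum += w
                break
            mt = mu_a[layer] + mu_s[layer]
            s = s_left / mt
            if uz > 0.0:
                db = (z_bot[layer] - z) / uz
            elif uz < 0.0:
                db = (z_top[layer] - z) / uz
            else:
                db = 1e30
            if db < s:
                # hit a boundary; bank the unused dimensionless step
                z = z_bot[layer] if uz > 0.0 else z_top[layer]
                s_left -= db * mt
                cos_i = abs(uz)
                if uz > 0.0:
                    n_next = n[layer + 1] if layer + 1 < n_layers else 1.0
                else:
                    n_next = n[layer - 1] if layer > 0 else 1.0
                refl, cos_t = _fresnel(n[layer], n_next, cos_i)
                rng = _xorshift(rng)
                if _to_u01(rng) < refl:
                    uz = -uz
                else:
                    scale = n[layer] / n_next
                    ux *= scale
                    uy *= scale
                    uz = cos_t if uz > 0.0 else -cos_t
                    if uz > 0.0:
                        if layer + 1 >= n_layers:
                            tt_sum += w
                            alive = False
                        else:
                            layer += 1
                    else:
                        if layer == 0:
                            rd_photon += w
                            alive = False
                        else:
                            layer -= 1
                continue
            # interior interaction: move, drop, spin
            z += s * uz
            rng = _xorshift(rng)
            s_left = -np.log(_to_u01(rng))
            dw = w * mu_a[layer] / mt
            a_sum += dw
            w -= dw
            rng = _xorshift(rng)
            cos_theta = _hg_cos(g[layer], _to_u01(rng))
            sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
            # azimuth by rejection sampling in the unit disc (no trig)
            while True:
                rng = _xorshift(rng)
                a = 2.0 * _to_u01(rng) - 1.0
                rng = _xorshift(rng)
                b = 2.0 * _to_u01(rng) - 1.0
                r2 = a * a + b * b
                if 1e-12 < r2 <= 1.0:
                    break
            inv_r = 1.0 / np.sqrt(r2)
            cos_phi = a * inv_r
            sin_phi = b * inv_r
            if abs(uz) > 0.99999:
                ux = sin_theta * cos_phi
                uy = sin_theta * sin_phi
                uz = cos_theta if uz > 0.0 else -cos_theta
            else:
                tmp = np.sqrt(1.0 - uz * uz)
                ux_new = sin_theta * (ux * uz * cos_phi - uy * sin_phi) / tmp \
                    + ux * cos_theta
                uy_new = sin_theta * (uy * uz * cos_phi + ux * sin_phi) / tmp \
                    + uy * cos_theta
                uz_new = -sin_theta * cos_phi * tmp + uz * cos_theta
                ux = ux_new
                uy = uy_new
                uz = uz_new
            if w < w_thresh:
                # roulette; survivors draw their boost from the absorbed
                # bucket so every run conserves weight exactly
                rng = _xorshift(rng)
                if _to_u01(rng) < roulette_chance:
                    a_sum -= w * (1.0 / roulette_chance - 1.0)
                    w /= roulette_chance
                else:
                    a_sum += w
                    alive = False
        rd_sum += rd_photon
        rd_sumsq += rd_photon * rd_photon
    return rd_sum, rd_sumsq, rsp * n_photons, tt_sum, a_sum


@njit(cache=True, fastmath=True)
def _path_kernel(mu_s, g, n, z_top, z_bot, n_paths, seed, max_steps):
    """Scattering-only walk recording per-layer path lengths.

    Returns (paths, fate): paths[i, l] is the geometric path length of
    photon i in layer l (cm); fate[i] is 1 if it escaped through the top,
    0 if it left through the bottom or hit the step cap.
    """
    rng = _splitmix64(_U(seed))
    n_layers = mu_s.shape[0]
    paths = np.zeros((n_paths, n_layers))
    fate = np.zeros(n_paths, dtype=np.int8)
    for i in range(n_paths):
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        alive = True
        steps = 0
        rng = _xorshift(rng)
        s_left = -np.log(_to_u01(rng))
        while alive:
            steps += 1
            if steps > max_steps:
                break
            mt = mu_s[layer]
            s = s_left / mt
            if uz > 0.0:
                db = (z_bot[layer] - z) / uz
            elif uz < 0.0:
                db = (z_top[layer] - z) / uz
            else:
                db = 1e30
            if db < s:
                paths[i, layer] += db
                z = z_bot[layer] if uz > 0.0 else z_top[layer]
                s_left -= db * mt
                cos_i = abs(uz)
                if uz > 0.0:
                    n_next = n[layer + 1] if layer + 1 < n_layers else 1.0
                else:
                    n_next = n[layer - 1] if layer > 0 else 1.0
                refl, cos_t = _fresnel(n[layer], n_next, cos_i)
                rng = _xorshift(rng)
                if _to_u01(rng) < refl:
                    uz = -uz
                else:
                    scale = n[layer] / n_next
                    ux *= scale
                    uy *= scale
                    uz = cos_t if uz > 0.0 else -cos_t
                    if uz > 0.0:
                        if layer + 1 >= n_layers:
                            alive = False
                        else:
                            layer += 1
                    else:
                        if layer == 0:
                            fate[i] = 1
                            alive = False
                        else:
                            layer -= 1
                continue
            paths[i, layer] += s
            z += s * uz
            rng = _xorshift(rng)
            s_left = -np.log(_to_u01(rng))
            rng = _xorshift(rng)
            cos_theta = _hg_cos(g[layer], _to_u01(rng))
            sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
            while True:
                rng = _xorshift(rng)
                a = 2.0 * _to_u01(rng) - 1.0
                rng = _xorshift(rng)
                b = 2.0 * _to_u01(rng) - 1.0
                r2 = a * a + b * b
                if 1e-12 < r2 <= 1.0:
                    break
            inv_r = 1.0 / np.sqrt(r2)
            cos_phi = a * inv_r
            sin_phi = b * inv_r
            if abs(uz) > 0.99999:
                ux = sin_theta * cos_phi
                uy = sin_theta * sin_phi
                uz = cos_theta if uz > 0.0 else -cos_theta
            else:
                tmp = np.sqrt(1.0 - uz * uz)
                ux_new = sin_theta * (ux * uz * cos_phi - uy * sin_phi) / tmp \
                    + ux * cos_theta
                uy_new = sin_theta * (uy * uz * cos_phi + ux * sin_phi) / tmp \
                    + uy * cos_theta
                uz_new = -sin_theta * cos_phi * tmp + uz * cos_theta
                ux = ux_new
                uy = uy_new
                uz = uz_new
    return paths, fate


def simulate_reflectance(mu_a: Sequence[float], mu_s: Sequence[float],
                         g: Sequence[float], n: Sequence[float],
                         d: Sequence[float],
                         cfg: PhotonRunConfig) -> SimResult:
    """Run one single-wavelength simulation over an arbitrary layer stack.

    Parameters are per-layer scalars (top to bottom); the ambient medium
    above and below has refractive index 1. Deterministic for a fixed
    config (single seeded stream).
    """
    mu_a = np.asarray(mu_a, dtype=np.float64)
    mu_s = np.asarray(mu_s, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if not (mu_a.shape == mu_s.shape == g.shape == n.shape == d.shape):
        raise ValueError("layer property arrays must have equal length")
    if np.any(mu_a < 0) or np.any(mu_s <= 0) or np.any(d <= 0) or np.any(n < 1):
        raise ValueError("nonphysical layer properties")
    if np.any(np.abs(g) > 1):
        raise ValueError("anisotropy must lie in [-1, 1]")
    z_bot = np.cumsum(d)
    z_top = z_bot - d
    rd_sum, rd_sumsq, sp_sum, tt_sum, a_sum = _mc_kernel(
        mu_a, mu_s, g, n, z_top, z_bot, cfg.n_photons, cfg.seed,
        cfg.weight_threshold, cfg.roulette_chance, cfg.max_steps)
    rd_mean = rd_sum / cfg.n_photons
    var = max(0.0, rd_sumsq / cfg.n_photons - rd_mean * rd_mean)
    se = float(np.sqrt(var / cfg.n_photons))
    return SimResult(rd_mean, sp_sum / cfg.n_photons, tt_sum / cfg.n_photons,
                     a_sum / cfg.n_photons, se)


def sample_paths(mu_s: Sequence[float], g: Sequence[float],
                 n: Sequence[float], d: Sequence[float],
                 n_paths: int, seed: int,
                 max_steps: int = 1_000_000):
    """Sample scattering-only photon paths through a layer stack.

    Returns (paths, escaped_top, specular): per-layer geometric path
    lengths (cm) per photon, a boolean escape flag, and the specular
    reflectance deducted at entry.
    """
    mu_s = np.asarray(mu_s, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    z_bot = np.cumsum(d)
    z_top = z_bot - d
    paths, fate = _path_kernel(mu_s, g, n, z_top, z_bot, int(n_paths),
                               int(seed) % (2**31 - 1), int(max_steps))
    r0 = (1.0 - n[0]) / (1.0 + n[0])
    return paths, fate.astype(bool), float(r0 * r0)


def reflectance_from_paths(paths: np.ndarray, escaped: np.ndarray,
                           specular: float, mu_a: np.ndarray) -> np.ndarray:
    """Diffuse reflectance for one or many absorption vectors.

    ``mu_a`` has shape (n_layers,) or (n_sets, n_layers); each escaped
    path contributes exp(-mu_a . path). Returns a scalar or a vector of
    length n_sets.
    """
    mu_a = np.atleast_2d(np.asarray(mu_a, dtype=np.float64))
    p = paths[escaped]
    n_paths = paths.shape[0]
    att = np.exp(-(p @ mu_a.T))
    rd = (1.0 - specular) * att.sum(axis=0) / n_paths
    return rd[0] if mu_a.shape[0] == 1 else rd


def simulate_spectrum(Cm: float, Cb: float, stack: SkinLayerStack,
                      cfg: PhotonRunConfig) -> Spectrum:
    """Diffuse reflectance spectrum for one (Cm, Cb) pair.

    One absorption-weighted MC run per wavelength band; band seeds are
    derived from ``cfg.seed`` so the whole spectrum is reproducible.
    """
    grid = stack.grid
    mua = compose_absorption(Cm, Cb, stack, cfg.oxygen_saturation)
    n = np.array([lay.n for lay in stack.layers])
    d = np.array([lay.d for lay in stack.layers])
    out = np.empty(grid.n_bands)
    for b in range(grid.n_bands):
        mu_s = np.array([lay.mu_s.values[b] for lay in stack.layers])
        g = np.array([lay.g.values[b] for lay in stack.layers])
        res = simulate_reflectance(mua[:, b], mu_s, g, n, d,
                                   cfg.with_seed(cfg.seed * 31 + b))
        out[b] = min(1.0, max(REFLECTANCE_FLOOR, res.diffuse_reflectance))
    return Spectrum(grid, out, "reflectance")


def build_training_grid(n_m: int, n_b: int, cfg: PhotonRunConfig,
                        stack: SkinLayerStack | None = None,
                        out_path: str | Path | None = None,
                        method: str = "replay",
                        progress: bool = False) -> list[TrainingPair]:
    """Simulate reflectance over a uniform (Cm, Cb) lattice.

    Cm spans 1.3%–43% and Cb 0.1%–7% (volume fractions), each uniformly
    divided into ``n_m`` and ``n_b`` points, giving ``n_m * n_b`` pairs.

    ``method="replay"`` (default) samples ``cfg.n_photons`` scattering-only
    paths per wavelength band and reweights them for every pair;
    ``method="direct"`` runs an independent absorption-weighted simulation
    per pair per band. When ``out_path`` is given the dataset CSV plus a
    JSON provenance sidecar are written there.
    """
    if n_m < 2 or n_b < 2:
        raise ValueError("need at least a 2x2 concentration grid")
    if method not in ("replay", "direct"):
        raise ValueError("method must be 'replay' or 'direct'")
    if stack is None:
        stack = default_skin_stack()
    grid = stack.grid
    cms = np.linspace(CM_RANGE[0], CM_RANGE[1], n_m)
    cbs = np.linspace(CB_RANGE[0], CB_RANGE[1], n_b)
    cm_mesh, cb_mesh = [a.ravel() for a in np.meshgrid(cms, cbs, indexing="ij")]
    n_pairs = n_m * n_b
    refl = np.empty((n_pairs, grid.n_bands))

    if method == "replay":
        # (n_pairs, 3, n_bands) absorption for every pair
        mua_all = np.stack([
            compose_absorption(cm, cb, stack, cfg.oxygen_saturation)
            for cm, cb in zip(cm_mesh, cb_mesh)])
        n_arr = np.array([lay.n for lay in stack.layers])
        d_arr = np.array([lay.d for lay in stack.layers])
        for b in range(grid.n_bands):
            mu_s = np.array([lay.mu_s.values[b] for lay in stack.layers])
            g = np.array([lay.g.values[b] for lay in stack.layers])
            paths, escaped, rsp = sample_paths(
                mu_s, g, n_arr, d_arr, cfg.n_photons,
                cfg.seed * 31 + b, cfg.max_steps)
            refl[:, b] = reflectance_from_paths(paths, escaped, rsp,
                                                mua_all[:, :, b])
            if progress:
                print(f"\r  MC training grid: band {b + 1}/{grid.n_bands}",
                      end="", flush=True)
    else:
        for k, (cm, cb) in enumerate(zip(cm_mesh, cb_mesh)):
            spec = simulate_spectrum(cm, cb, stack,
                                     cfg.with_seed(cfg.seed + 7919 * k))
            refl[k] = spec.values
            if progress:
                print(f"\r  MC training grid: {k + 1}/{n_pairs} pairs",
                      end="", flush=True)
    if progress:
        print()

    refl = np.clip(refl, REFLECTANCE_FLOOR, 1.0)
    pairs = [TrainingPair(float(cm), float(cb),
                          Spectrum(grid, refl[k], "reflectance"))
             for k, (cm, cb) in enumerate(zip(cm_mesh, cb_mesh))]
    if out_path is not None:
        save_training_pairs(pairs, out_path, cfg, grid)
    return pairs


def save_training_pairs(pairs: Sequence[TrainingPair], path: str | Path,
                        cfg: PhotonRunConfig | None = None,
                        grid: WavelengthGrid = DEFAULT_GRID) -> None:
    """CSV with columns Cm, Cb, r_<wavelength>..., plus a JSON sidecar."""
    cols = {"Cm": [p.Cm for p in pairs], "Cb": [p.Cb for p in pairs]}
    for b, wl in enumerate(grid.wavelengths):
        cols[f"r_{int(wl)}"] = [p.reflectance.values[b] for p in pairs]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    meta = {"grid": {"start_nm": grid.start_nm, "stop_nm": grid.stop_nm,
                     "step_nm": grid.step_nm},
            "n_pairs": len(pairs)}
    if cfg is not None:
        meta["config"] = asdict(cfg)
    with open(Path(path).with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_training_pairs(path: str | Path,
                        grid: WavelengthGrid = DEFAULT_GRID) -> list[TrainingPair]:
    df = pd.read_csv(path)
    rcols = [f"r_{int(wl)}" for wl in grid.wavelengths]
    missing = [c for c in ["Cm", "Cb"] + rcols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [TrainingPair(row.Cm, row.Cb,
                         Spectrum(grid, row[rcols].to_numpy(dtype=float),
                                  "reflectance"))
            for _, row in df.iterrows()]
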