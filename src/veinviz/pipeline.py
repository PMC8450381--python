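"""End-to-end orchestration: RGB image → vein mask, with provenance.

Stage order: light correction → shading removal → Wiener spectral
reconstruction → two-stage regression inverse → blood-map visualization
→ Gabor vein extraction. Each stage can be toggled or parameterized
through :class:`PipelineConfig`; a :class:`VeinVisualizer` bundles the
trained artifacts (system matrix, Wiener matrix, inverse model,
reflectance lookup) built from one Monte Carlo training dataset.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .optics_data import DEFAULT_GRID, REGRESSION_GRID, WavelengthGrid, \
    default_chromophores
from .mc_skin import TrainingPair, PhotonRunConfig, build_training_grid, \
    load_training_pairs
from .preprocess import ImagePlane, estimate_gamma, apply_gamma, remove_shading
from .spectral_recon import (build_prior, build_system_matrix,
                             build_wiener_matrix, reconstruct_cube,
                             SpectralCube)
from .inverse_model import (InverseModel, ConcentrationMap,
                            train_concentration_map, predict_concentrations)
from .vein_extract import GaborBank, VeinMask, Metrics, extract_veins, score
from .synth import ReflectanceLookup

__all__ = ["PipelineConfig", "PipelineResult", "VeinVisualizer",
           "run_pipeline", "evaluate_batch", "segment_skin",
           "visualize_blood_map"]


@dataclass
class PipelineConfig:
    """Toggles and parameters for one pipeline run."""

    light_correction: bool = True
    shading_removal: bool = True
    n_iter: int = 5
    application_step_nm: float = 10.0      # stage-one fit step at inference
    gabor_sigmas: tuple[float, float] = (2.0, 4.0)
    min_component_px: int = 50
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Artifacts of one run plus a provenance block."""

    gamma: float | None
    preprocessed: ImagePlane
    cube: SpectralCube
    maps: ConcentrationMap
    visualization: ImagePlane
    vein_mask: VeinMask
    provenance: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def segment_skin(image: ImagePlane) -> np.ndarray:
    """Crude color-threshold skin segmentation.

    Keeps pixels that are neither saturated nor near-black and whose red
    channel dominates blue (skin is warm-toned). Rough boundaries are
    harmless downstream; supply an explicit mask to override.
    """
    norm = image.normalized()
    if not norm.is_color:
        return (norm.pixels > 0.02) & (norm.pixels < 0.995)
    r, g, b = norm.pixels[..., 0], norm.pixels[..., 1], norm.pixels[..., 2]
    brightness = norm.pixels.mean(axis=2)
    return (brightness > 0.02) & (brightness < 0.995) & (r >= b)


def visualize_blood_map(maps: ConcentrationMap) -> ImagePlane:
    """Contrast-normalized, inverted blood map (high Cb renders dark).

    Min–max normalization is computed within the skin mask, mimicking
    the appearance of an NIR image where veins absorb and look dark.
    """
    cb = maps.Cb_map
    region = cb[maps.mask]
    lo, hi = float(region.min()), float(region.max())
    if hi <= lo:
        vis = np.zeros_like(cb)
    else:
        vis = np.clip((cb - lo) / (hi - lo), 0.0, 1.0)
    out = 1.0 - vis
    out[~maps.mask] = 1.0
    return ImagePlane(out, maps.mask.copy(), (0.0, 1.0))


def fit_exposure_gain_a0(image: ImagePlane, W: np.ndarray,
                         model: InverseModel, chroms,
                         cube_grid: WavelengthGrid = DEFAULT_GRID,
                         fit_grid: WavelengthGrid | None = None,
                         max_pixels: int = 20000) -> float:
    """Per-image exposure gain fitted in the absorbance-intercept domain.

    A scalar exposure error k scales every reconstructed spectrum by 1/k,
    which shifts each pixel's stage-one intercept a0 by exactly log10(k)
    and leaves am/atb untouched. The gain is therefore chosen so the
    image's median a0 matches the training population's median — placing
    the stage-two features inside the region the cubic map was fitted on.
    """
    from .inverse_model import _stage_one_batch

    if fit_grid is None:
        fit_grid = model.grid
    img = image.normalized()
    flat = img.pixels.reshape(-1, 3)[img.mask.ravel()]
    if flat.shape[0] > max_pixels:
        stride = flat.shape[0] // max_pixels + 1
        flat = flat[::stride]
    raw = flat @ W.T                                  # unclipped spectra
    idx = fit_grid.indices_in(cube_grid)
    valid = np.all(raw[:, idx] > 0, axis=1)
    if valid.sum() < 16:
        return 1.0
    ata, _ = _stage_one_batch(np.clip(raw[valid], 1e-6, None), cube_grid,
                              chroms, fit_grid)
    med_a0 = float(np.median(ata[:, 2]))
    return float(10.0 ** (med_a0 - model.a0_reference))


class VeinVisualizer:
    """Trained pipeline: holds every artifact derived from one dataset."""

    def __init__(self, pairs: Sequence[TrainingPair],
                 config: PipelineConfig | None = None,
                 grid: WavelengthGrid = DEFAULT_GRID):
        if config is None:
            config = PipelineConfig()
        self.config = config
        self.grid = grid
        self.pairs = list(pairs)
        self.chroms = default_chromophores(grid)
        self.prior = build_prior([p.reflectance for p in self.pairs], grid,
                                 provenance="MC training spectra")
        self.system = build_system_matrix(
            grid, reference_spectra=self.prior.samples)
        self.W = build_wiener_matrix(self.prior, self.system)
        # calibrate the stage-two map on the same signal path inference
        # sees: at run time every spectrum has passed through W·F, so the
        # regression is trained on the Wiener-projected training spectra
        from .optics_data import REFLECTANCE_FLOOR, Spectrum
        from .mc_skin import TrainingPair as _TP
        proj = np.clip(
            np.stack([p.reflectance.values for p in self.pairs])
            @ (self.system.F.T @ self.W.T), REFLECTANCE_FLOOR, 1.0)
        proj_pairs = [_TP(p.Cm, p.Cb, Spectrum(grid, proj[i], "reflectance"))
                      for i, p in enumerate(self.pairs)]
        self.model = train_concentration_map(proj_pairs, self.chroms,
                                             REGRESSION_GRID)
        self.lookup = ReflectanceLookup(self.pairs)
        self.bank = GaborBank.default(sigmas=tuple(config.gabor_sigmas))

    @property
    def application_grid(self) -> WavelengthGrid:
        return WavelengthGrid(500.0, 600.0, self.config.application_step_nm)

    def run(self, image: ImagePlane) -> PipelineResult:
        cfg = self.config
        log: list[str] = []
        gamma = None
        work = image
        if cfg.light_correction:
            gamma = estimate_gamma(work)
            work = apply_gamma(work, gamma)
            log.append(f"light correction: gamma* = {gamma:.4f}")
        else:
            work = work.normalized()
            log.append("light correction: skipped")
        if cfg.shading_removal:
            decomp = remove_shading(work, n_iter=cfg.n_iter)
            work = decomp.corrected
            log.append(f"shading removal: {cfg.n_iter} bilateral passes")
        else:
            log.append("shading removal: skipped")
        gain = fit_exposure_gain_a0(work, self.W, self.model, self.chroms,
                                    self.grid, self.application_grid)
        cube = reconstruct_cube(work, self.W, self.grid, gain=gain)
        log.append(f"wiener reconstruction: exposure gain {gain:.4f}, "
                   f"{cube.clipped_fraction:.2%} out-of-range values clipped")
        maps = predict_concentrations(cube, self.model, self.chroms,
                                      grid=self.application_grid)
        vis = visualize_blood_map(maps)
        mask = extract_veins(vis, self.bank, dark_veins=True,
                             min_component_px=cfg.min_component_px)
        log.append(f"vein extraction: {int(mask.veins.sum())} vein pixels")
        prov = {"config": cfg.as_dict(),
                "model": self.model.provenance,
                "exposure_gain": gain,
                "gamma": gamma}
        return PipelineResult(gamma, work, cube, maps, vis, mask, prov, log)


def _load_or_build_pairs(dataset: str | Path | None, seed: int,
                         n_photons: int = 100_000,
                         n_grid: int = 10) -> list[TrainingPair]:
    if dataset is not None:
        return load_training_pairs(dataset)
    cfg = PhotonRunConfig(n_photons=n_photons, seed=seed)
    return build_training_grid(n_grid, n_grid, cfg)


def run_pipeline(rgb_path: str | Path, config: PipelineConfig | None = None,
                 dataset: str | Path | None = None,
                 mask_path: str | Path | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """File-level entry point: read an image, run everything, persist.

    ``dataset`` is a training-pairs CSV (regenerated at default scale
    when absent). Outputs (Cm/Cb maps, visualization, vein mask, log)
    are written under ``out_dir`` when given.
    """
    import imageio.v3 as iio

    if config is None:
        config = PipelineConfig()
    raw = np.asarray(iio.imread(rgb_path), dtype=float)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[..., :3]
    image = ImagePlane(raw, None, (0.0, 255.0))
    if mask_path is not None:
        m = np.asarray(iio.imread(mask_path))
        if m.ndim == 3:
            m = m[..., 0]
        image.mask = m >= 128
    else:
        image.mask = segment_skin(image)
    viz = VeinVisualizer(_load_or_build_pairs(dataset, config.seed), config)
    result = viz.run(image)
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out_dir: Path) -> None:
    import imageio.v3 as iio
    import tifffile

    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "Cm_map.tiff",
                     result.maps.Cm_map.astype(np.float32))
    tifffile.imwrite(out_dir / "Cb_map.tiff",
                     result.maps.Cb_map.astype(np.float32))
    iio.imwrite(out_dir / "visualization.png",
                np.round(result.visualization.pixels * 255).astype(np.uint8))
    iio.imwrite(out_dir / "vein_mask.png",
                (result.vein_mask.veins * 255).astype(np.uint8))
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, default=str)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")


def evaluate_batch(image_dir: str | Path, truth_dir: str | Path,
                   config: PipelineConfig | None = None,
                   dataset: str | Path | None = None,
                   out_csv: str | Path | None = None) -> pd.DataFrame:
    """Score every image against its same-named ground-truth mask.

    Returns a per-image metrics table with a final ``mean`` row, in the
    accuracy/precision/recall/F1 layout.
    """
    import imageio.v3 as iio
    import warnings

    if config is None:
        config = PipelineConfig()
    image_dir, truth_dir = Path(image_dir), Path(truth_dir)
    images = sorted(p for p in image_dir.iterdir()
                    if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not images:
        warnings.warn(f"no images found in {image_dir}", stacklevel=2)
        return pd.DataFrame(columns=["image", "accuracy", "precision",
                                     "recall", "f1"])
    unpaired = [p.name for p in images if not (truth_dir / p.name).exists()]
    if unpaired:
        raise FileNotFoundError(f"missing ground truth for: {unpaired}")
    viz = VeinVisualizer(_load_or_build_pairs(dataset, config.seed), config)
    rows = []
    for path in images:
        raw = np.asarray(iio.imread(path), dtype=float)
        if raw.ndim == 3 and raw.shape[2] == 4:
            raw = raw[..., :3]
        image = ImagePlane(raw, None, (0.0, 255.0))
        result = viz.run(image)
        t = np.asarray(iio.imread(truth_dir / path.name))
        if t.ndim == 3:
            t = t[..., 0]
        truth = VeinMask(t >= 128, image.mask)
        _, metrics = score(result.vein_mask, truth)
        rows.append({"image": path.name, **metrics.as_dict()})
    df = pd.DataFrame(rows)
    mean_row = {"image": "mean",
                **df[["accuracy", "precision", "recall", "f1"]].mean().to_dict()}
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False, float_format="%.6f")
    return df
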