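# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `veinviz`, at the level of detail a user needs to
judge what results on synthetic data do and do not imply about real images.

## Forward model: photon transport in layered skin

Skin is modeled as three homogeneous, laterally infinite slabs:

| layer      | n    | d (cm) | μs(λ)                         | g(λ)             |
|------------|------|--------|-------------------------------|------------------|
| epidermis  | 1.37 | 0.006  | 68.7·(λ/500)^−1.161 / (1−g)  | 0.62 + 2.9e−4·λ  |
| dermis     | 1.37 | 0.09   | 45.3·(λ/500)^−1.292 / (1−g)  | 0.62 + 2.9e−4·λ  |
| hypodermis | 1.44 | 0.03   | 15·(λ/500)^−0.68 / (1−g)     | 0.8              |

Absorption mixes chromophores by volume fraction:

- epidermis: μa = Cm·μa,mel + (1−Cm)·μa,base with μa,mel = 6.6e11·λ^−3.33
  cm⁻¹ (interior-melanosome scale) and μa,base = 0.244 + 85.3·exp(−(λ−154)/66.2);
- dermis: μa = Cb·μa,blood + (1−Cb)·μa,base, where whole-blood absorption is
  ln10 · ε(λ) · 150/64500 mol/L and ε mixes oxy/deoxy hemoglobin at a
  configurable oxygen saturation (default 0.75, venous-dominant, since the
  target structures are veins);
- hypodermis: fixed 0.13 cm⁻¹.

The bundled spectral constants (`src/veinviz/data/`, see `manifest.json`)
are approximate digitizations of the standard literature compilations;
the pipeline depends on their relative spectral shapes (Soret band, Q
bands, melanin power law), not on absolute calibration.

Transport follows the standard multi-layer Monte Carlo scheme: specular
deduction at entry, exponential step sampling with μt = μa + μs,
Henyey–Greenstein polar scattering, azimuth sampled trig-free by disc
rejection, unpolarized Fresnel reflection/refraction at boundaries (the
unused dimensionless step is banked across a crossing), absorption by
weight drop μa/μt, and Russian roulette below weight 1e−4 with survival
chance 0.1. Roulette bookkeeping transfers weight to/from the absorbed
bucket so specular + diffuse + transmitted + absorbed ≡ 1 exactly in every
run, not just in expectation. The RNG is an inlined xorshift64* stream
seeded through splitmix64; runs are single-threaded and bit-reproducible
for a given config. Below the hypodermis the medium is ambient (n = 1), so
deep-penetrating red light can be lost through the bottom; absolute
reflectance levels are therefore somewhat lower than for skin backed by
muscle, which is immaterial here because the same forward model generates
the prior, the training pairs and the phantoms.

### Two estimators

`simulate_reflectance` is the classic absorption-weighted walk.
`build_training_grid` defaults to pathlength reweighting ("white" Monte
Carlo): per wavelength band one ensemble of scattering-only paths is
sampled, each path's per-layer geometric lengths are recorded, and the
diffuse reflectance for any (Cm, Cb) pair is the mean over escaped paths
of exp(−Σ_l μa,l·s_l). Both estimators are unbiased for the same radiative
transfer problem and agree within Monte Carlo error (tested); reweighting
amortizes one path ensemble over the whole concentration sweep, reducing a
~40-minute lattice sweep to seconds at equal per-band path counts. Its
estimates are correlated across pairs (shared paths), which is harmless
for regression training and actually helps monotonicity along grid lines.
Variance grows toward the dark high-melanin corner, where surviving-path
weights are small.

## Training grid

Cm spans 1.3–43 % and Cb 0.1–7 %, uniformly divided; the full study design
is 50×50 = 2500 pairs. Routine work and the shipped statistics use a
reduced 10×10 lattice at 1e5 paths per band — a problem size chosen so the
whole chain (simulation, training, phantom experiments) runs interactively
on one CPU. The regression statistics are insensitive to the lattice
density beyond ~10 points per axis because the spectra family is smooth in
(Cm, Cb).

## Two-stage inverse

Stage one fits A(λ) = −log₁₀ r(λ) by OLS on [εm, εob, εdb, 1] over
500–600 nm at 10-nm steps (11 bands). The coefficients absorb
concentration × path-length products; the intercept absorbs scattering
loss and any global radiometric scale (a scalar exposure error k shifts
every a₀ by exactly log₁₀ k and nothing else — this is used below). The
500–600 nm restriction exists because oxy/deoxy extinction shapes
separate best there; over 400–700 nm the Soret-band nonlinearity is not
representable with a wavelength-independent path length and the fit
degrades (mean R² ≈ 0.99 vs ≈ 0.89 on the reduced grid — computed by the
test suite and `scripts/acceptance.py`).

Stage two maps the 14-term cubic feature vector
[1, am, atb, a0, am³, atb³, a0³, am·atb·a0, am²atb, am²a0, atb²am,
atb²a0, a0²am, a0²atb] to Cm and Cb by least squares over the training
pairs. The raw monomials span ~14 orders of magnitude (extinction
coefficients are O(1e4–1e5), so am is O(1e−5)); the solve is performed in
a column-scaled basis and the coefficients mapped back exactly, keeping
the stored b-vectors in the raw basis. A ridge fallback exists for
genuinely degenerate feature spreads. Predicted concentrations are not
clipped to the training range: out-of-range excursions carry exactly the
vein contrast the method visualizes.

Concentrations are volume fractions throughout (0.013–0.43, 0.001–0.07).
Training and inference both default to the 10-nm sub-grid; a 20-nm
application step is supported via `PipelineConfig.application_step_nm`.

## Wiener reconstruction and radiometric conventions

The camera model is three Gaussian responses peaking at 610/540/460 nm
with 60-nm FWHM (a stand-in for an unpublished sensor datasheet; under the
narrow-band assumption only the peak positions matter strongly), times a
CIE D65 illuminant normalized to unit mean. The overall scale of F = S·E
is pinned by requiring the brightest prior spectrum to render with peak
channel value 1. The reflectance prior is the second moment of the MC
training spectra — the measured-database prior the method would normally
use is not redistributable, and the MC family is the same spectral family
the inverse is trained on. Reconstructed reflectance is clipped to
[1e−4, 1] (the floor keeps log-absorbance finite); the clipped fraction is
reported in the run log.

Two calibration choices matter and are deliberate:

- **Per-image exposure gain.** The unknown scalar folding exposure,
  shading mean and illuminant level is fitted per image in the
  coefficient domain: the gain is 10^(median a₀(image) − median
  a₀(training)), which places every pixel's stage-two features inside the
  region the cubic map was trained on. Fitting the gain as a ratio of
  raw intensity medians instead mis-scales any skin brighter or darker
  than the prior's median member and sends the cubic map into
  extrapolation (this failure mode is easy to reproduce: a ~3× gain error
  produces Cb estimates an order of magnitude out of range).
- **Signal-path calibration.** The pipeline's stage-two vectors are
  trained on Wiener-projected spectra clip(W·F·r) rather than raw MC
  spectra, because at inference every spectrum has passed through W·F.
  The projection shifts stage-one coefficients enough that a raw-trained
  cubic map extrapolates badly (Cb correlation 0.49 vs 0.997 when
  calibrated on the projection). `train_concentration_map` itself is
  path-agnostic; the projection happens in `VeinVisualizer`.

W·F is an oblique projector onto range(W): it is the identity on the
prior's top-3 eigenspace only when the prior is (numerically) rank 3, and
three camera channels cannot span the curvature of the whole 2-parameter
reflectance family (typical on-family reconstruction error ~4 % RMS,
growing toward dark high-melanin members). The inverse tolerates this
because it is calibrated on the projected family.

## Preprocessing

Gamma correction uses the closed-form entropy maximizer; the gray
conversion uses BT.601 luminance weights; pixels are floored at 1/255
before the log. Shading removal scales to [0, 255], floors at 1, and runs
5 bilateral passes (n_iter configurable) per channel on the log image with
σ₁ = 0.05·min(W,H) and σ₂ recomputed each pass from the current filter
input; window truncated at 3σ₁. Masked (non-skin) pixels are excluded
from all statistics and passed through untouched. The decomposition is
exactly multiplicative (base + detail = log input to machine precision)
and approximately idempotent (≤5 % RMS change on a second pass).

The bilateral filter separates by contrast, not strictly by frequency:
reflectance detail survives in the detail layer because pigment-driven
variation is low-contrast in the log domain, while shading spans a larger
log range. High-contrast *fine* texture (hair!) would be misassigned.

## Vein extraction

16 real Gabor kernels — scales σ ∈ {2, 4} px × 8 orientations in [0, π),
carrier frequency 0.28/σ, elongation σy = 3σx, mean-subtracted so flat
regions give zero response — are applied to the inverted blood map; the
per-pixel maximum response is stretched between its 1st and 99th
percentile, thresholded by Otsu within the skin region, and components
under 50 px are removed. The published extraction this follows is cited
without parameters; these values are this package's substitution and are
configurable.

## Phantom generator: what it emulates, what it does not

A phantom is a (Cm, Cb) field — smooth background variation (15 % RMS
around Cm = 0.08, Cb = 0.012) plus random-walk tubes 4–10 px wide with
ΔCb = +0.03 — rendered through the forward lookup and F, then degraded:

- **spotlight shading**, minimum multiplier 0.30: a directional light on
  a curved arm leaves deep smooth shadows;
- **sensor gamma encoding**, stored = linear^(1/2.2): the sRGB-like tone
  transfer of consumer cameras, which *compresses* log-domain vein
  contrast and is what light correction must undo (γ\* > 1 restores it);
- additive Gaussian sensor noise (1.5 DN) and 8-bit quantization.

Generation is seeded and byte-reproducible. These defaults are the study
conditions for all ablation experiments: under them the raw pipeline's
mean F1 on ten phantoms roughly halves relative to clean renders, light
correction recovers most of the gap, and shading removal adds a further
increment — the directions the preprocessing stages exist for.

What passing phantom tests does **not** show about real data: phantoms
contain no hair or skin texture, no specular highlights, no illuminant
color cast or chromatic shading, no camera spectral mismatch (the phantom
is rendered through the same F the pipeline assumes), no vessel depth
variation, and tube veins rather than real vascular geometry. Results on
real images will be limited by exactly these mismatches, the camera
response approximation, and the fidelity of the bundled optical constants.

## Numerical conventions and degenerate inputs

- Reflectance floor 1e−4; log floor 1 DN on the 0–255 scale.
- Empty skin masks raise; an all-white image makes γ\* unbounded and
  raises; constant images yield empty vein masks and constant maps.
- Metric ratios with zero denominators are returned as 0 and flagged.
- Least-squares solves fall back to ridge regularization (with a warning)
  only when the design is numerically singular (condition > 1e12).
- All Monte Carlo entry points take explicit seeds; derived band/pair
  seeds stay below 2³¹.

## Known limitations

- CPU-only Monte Carlo; the full 50×50 × 31-band sweep at 1e5 paths/band
  takes minutes (reweighting) — the direct per-pair estimator at the same
  nominal sampling takes ~40 minutes.
- The oxygen saturation of dermal blood is a single global constant; the
  method does not estimate oxygenation.
- Absolute concentration values inherit the exposure-gain convention
  (median-a₀ alignment): maps are accurate up to a small per-image offset,
  and vein *contrast*, not absolute Cb, is the reliable output.
- The skin segmenter is a crude color threshold with a mask override; it
  is not a contribution of this package.
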