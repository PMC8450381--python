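# veinviz

Subcutaneous veins are nearly invisible in an ordinary RGB photograph of an
arm: vein pixels differ from the surrounding skin by only a few digital
numbers. They differ strongly, however, in one biophysical parameter — the
dermal blood volume fraction Cb. `veinviz` inverts the color-formation
process of skin to recover per-pixel melanin (Cm) and blood (Cb)
concentration maps from a single RGB image, and extracts vein patterns from
the blood map. The intended users are researchers in tissue optics and
biomedical image analysis who want a contact-free, camera-only alternative
to near-infrared vein imaging (venipuncture guidance, spider-vein "feeder"
localization), or a reference implementation of the underlying estimation
chain.

## Method

The pipeline chains five stages:

1. **Light correction.** The entropy-optimal restoration exponent is found
   in closed form, γ\* = −1 / mean(ln u) over the skin region Ω of the
   gray-scale image u, and all three channels are raised to γ\*.
2. **Shading removal.** Under a Lambertian model the image factorizes as
   I(x,y) = S(λ)E(λ) r(x,y,λ) w(x,y), with w the smooth shading of the
   curved arm. In the log domain an iterated bilateral filter
   (σ₁ = 0.05·min(W,H) px, σ₂ = 0.05·max of the current input) splits
   ln I into a smooth base layer and a detail layer; the base is replaced
   by its Ω-mean, removing shading while keeping the pigment detail.
3. **Wiener spectral reconstruction.** With F = S·E (3×31, camera response
   times illuminant on a 400–700 nm / 10 nm grid) and a second-moment
   reflectance prior ⟨r rᵀ⟩, each pixel's 31-band reflectance is estimated
   as r̃ = W I with W = ⟨r rᵀ⟩ Fᵀ (F ⟨r rᵀ⟩ Fᵀ)⁻¹.
4. **Concentration inversion.** Absorbance A(λ) = −log₁₀ r̃(λ) on the
   500–600 nm band is fitted by the modified Beer–Lambert model
   A = a_m ε_m + a_ob ε_ob + a_db ε_db + a₀, and a fixed 14-term cubic
   feature vector of (a_m, a_tb = a_ob + a_db, a₀) is mapped to (Cm, Cb)
   through vectors b_m, b_tb fitted on a Monte Carlo training set.
5. **Vein extraction.** The Cb map (inverted, so veins are dark as in NIR)
   is filtered with the real parts of 16 Gabor kernels (2 scales × 8
   orientations), contrast-stretched, Otsu-thresholded, and cleaned of
   small components. Predictions are scored against ground truth with
   accuracy, precision, recall and F1.

The prior and the inverse are both trained on a forward model: an
MCML-style Monte Carlo simulation of photon transport in three skin layers
(epidermis / dermis / hypodermis; n = 1.37/1.37/1.44, d = 0.006/0.09/0.03
cm), with epidermal absorption mixing melanin at volume fraction Cm and
dermal absorption mixing blood at fraction Cb. A (Cm, Cb) lattice spanning
1.3–43 % × 0.1–7 % yields (concentration, reflectance-spectrum) training
pairs.

Because no camera dataset ships with the package, a synthetic phantom
generator renders RGB skin images with known concentration fields,
tube-shaped veins, multiplicative shading, sensor gamma encoding and noise
— through the same color-formation model — so the whole chain is testable
end to end.

## Worked example

```python
from veinviz.mc_skin import build_training_grid, PhotonRunConfig
from veinviz.pipeline import VeinVisualizer
from veinviz.synth import PhantomSpec, render_phantom
from veinviz.vein_extract import score

pairs = build_training_grid(10, 10, PhotonRunConfig(n_photons=100_000, seed=1))
viz = VeinVisualizer(pairs)                      # prior, W, inverse model
rgb, truth, _ = render_phantom(PhantomSpec(seed=5), viz.system, viz.lookup)
result = viz.run(rgb)
print("\n".join(result.log))
counts, m = score(result.vein_mask, truth)
print(f"F1 = {m.f1:.4f}")
```

prints

```
light correction: gamma* = 1.4172
shading removal: 5 bilateral passes
wiener reconstruction: exposure gain 0.7043, 0.00% out-of-range values clipped
vein extraction: 880 vein pixels
F1 = 0.9048
```

γ\* ≈ 1.42 undoes most of the phantom's gamma encoding; the exposure gain
puts the reconstructed spectra on the radiometric scale the inverse model
was trained on; and the extracted vein mask overlaps the generating tube
with F1 ≈ 0.90 (accuracy 0.989, precision 0.967, recall 0.850 on this
phantom). The recovered blood map shows ≈ 2.5× more blood inside the vein
than outside (0.016 vs 0.006 volume fraction here).

The same stages are scriptable from the shell:

```sh
veinviz simulate-grid --n-m 10 --n-b 10 --photons 100000 --seed 1 --out pairs.csv
veinviz synth --seed 5 --dataset pairs.csv --out-dir phantom/
veinviz run --image phantom/rgb.png --dataset pairs.csv --out-dir out/
veinviz score --pred out/vein_mask.png --truth phantom/truth_mask.png
```

## Layout

```
src/veinviz/
  optics_data.py    wavelength grids, spectra, bundled constants, skin stack
  mc_skin.py        Monte Carlo photon transport + training-grid sweep
  preprocess.py     adaptive gamma, bilateral shading removal
  spectral_recon.py Wiener estimation RGB -> 31-band reflectance
  inverse_model.py  two-stage Beer-Lambert / cubic-feature inversion
  vein_extract.py   Gabor bank extraction + confusion-matrix metrics
  synth.py          phantom generator with ground truth
  pipeline.py       orchestration, batch evaluation
  cli.py            the `veinviz` command
  data/             spectral-constant CSVs + provenance manifest
docs/methods.md     model assumptions, parameters, limitations
```
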