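{
  "grid": {
    "start_nm": 400,
    "stop_nm": 700,
    "step_nm": 10
  },
  "files": {
    "illuminant_d65.csv": "CIE D65 daylight illuminant, relative spectral power (unnormalized tabulation).",
    "eps_hbo2.csv": "Oxyhemoglobin molar extinction, cm^-1/(mol/L); approximate digitization of the standard compilation.",
    "eps_hb.csv": "Deoxyhemoglobin molar extinction, cm^-1/(mol/L); approximate digitization of the standard compilation.",
    "eps_melanin.csv": "Melanin extinction on a nominal molar scale: 6.6e11*lambda^-3.33 cm^-1 divided by ln(10)*2.326e-3 M.",
    "mua_baseline.csv": "Pigment-free tissue baseline absorption 0.244 + 85.3*exp(-(lambda-154)/66.2) cm^-1.",
    "mua_hypodermis.csv": "Subcutaneous fat absorption, constant 0.13 cm^-1 (literature-scale).",
    "mus_epidermis.csv": "Epidermis scattering mu_s = 68.7*(lambda/500)^-1.161 / (1-g) cm^-1.",
    "mus_dermis.csv": "Dermis scattering mu_s = 45.3*(lambda/500)^-1.292 / (1-g) cm^-1.",
    "mus_hypodermis.csv": "Hypodermis scattering mu_s = 15*(lambda/500)^-0.68 / (1-g) cm^-1.",
    "g_epidermis.csv": "Henyey-Greenstein anisotropy 0.62 + 2.9e-4*lambda (epidermis).",
    "g_dermis.csv": "Henyey-Greenstein anisotropy 0.62 + 2.9e-4*lambda (dermis).",
    "g_hypodermis.csv": "Henyey-Greenstein anisotropy, constant 0.8 (hypodermis).",
    "camera_response_r.csv": "Synthetic Gaussian red-channel response, peak 610 nm, FWHM 60 nm.",
    "camera_response_g.csv": "Synthetic Gaussian green-channel response, peak 540 nm, FWHM 60 nm.",
    "camera_response_b.csv": "Synthetic Gaussian blue-channel response, peak 460 nm, FWHM 60 nm."
  },
  "notes": "Camera curves are a synthetic stand-in for an unpublished sensor datasheet; under the narrow-band (Dirac) response assumption only the peak wavelengths matter strongly. Chromophore and layer curves are approximate digitizations of the standard literature compilations, adequate for the relative spectral shapes the pipeline depends on."
}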