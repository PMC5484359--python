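# SYNTHETIC stand-in peak library for spectrum synthesis.
#
# The classification window is 0.5-4.0 ppm.  Each variable contributes a
# single unit-area Lorentzian at a canonical chemical shift; real in-vivo
# metabolites have multiplet structure and these line-shape parameters are
# deliberately simple stand-ins (no fitted line-shape parameters exist for
# this pipeline), chosen so the synthesized spectra carry the same class
# information as the underlying concentration profiles.  Edit freely.
#
# fwhm: full width at half maximum, ppm.  amplitude: scale on the unit-area
# lineshape.  noise_sd: i.i.d. Gaussian noise per spectral point.
baseline_level: 0.0
noise_sd: 0.5
# Number of axis points over 0.5-4.0 ppm; ~457 emulates resampling to
# 0.49 Hz/point at a 1.5 T proton frequency (~63.87 MHz -> ~0.0077 ppm/pt).
axis_points: 457
peaks:
  - {metabolite: citrate,               ppm: 2.60, fwhm: 0.04, amplitude: 1.0}
  - {metabolite: glycerophosphocholine, ppm: 3.21, fwhm: 0.04, amplitude: 1.0}
  - {metabolite: glucose,               ppm: 3.43, fwhm: 0.05, amplitude: 1.0}
  - {metabolite: glutamine,             ppm: 2.45, fwhm: 0.05, amplitude: 1.0}
  - {metabolite: glutathione,           ppm: 2.95, fwhm: 0.05, amplitude: 1.0}
  - {metabolite: glutamate,             ppm: 2.35, fwhm: 0.05, amplitude: 1.0}
  - {metabolite: glycine,               ppm: 3.55, fwhm: 0.04, amplitude: 1.0}
  - {metabolite: myo_inositol,          ppm: 3.56, fwhm: 0.05, amplitude: 1.0}
  - {metabolite: lactate,               ppm: 1.31, fwhm: 0.04, amplitude: 1.0}
  - {metabolite: phosphocholine,        ppm: 3.22, fwhm: 0.04, amplitude: 1.0}
  - {metabolite: scyllo_inositol,       ppm: 3.34, fwhm: 0.03, amplitude: 1.0}
  - {metabolite: taurine,               ppm: 3.42, fwhm: 0.05, amplitude: 1.0}
  - {metabolite: total_creatine,        ppm: 3.03, fwhm: 0.04, amplitude: 1.0}
  - {metabolite: total_naa,             ppm: 2.01, fwhm: 0.04, amplitude: 1.0}
  - {metabolite: TLM09,                 ppm: 0.90, fwhm: 0.15, amplitude: 1.0}
  - {metabolite: TLM13,                 ppm: 1.30, fwhm: 0.15, amplitude: 1.0}
  - {metabolite: TLM20,                 ppm: 2.00, fwhm: 0.15, amplitude: 1.0}
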