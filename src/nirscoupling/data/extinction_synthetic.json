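{
  "units": {
    "wavelength": "nm",
    "extinction": "OD * uM^-1 * cm^-1",
    "dpf": "dimensionless"
  },
  "chromophores": [
    "hbo2",
    "hhb",
    "oxcco"
  ],
  "source": "SYNTHETIC stand-in spectra: smooth analytic curves qualitatively shaped like published NIR extinction spectra (HbO2 rising over 780-900 nm, HHb falling, oxidised-minus-reduced CCO broad band near 830 nm). Not measured data; suitable for forward/inverse round-trip testing and simulation only.",
  "grid": {
    "start_nm": 780,
    "stop_nm": 900,
    "step_nm": 2
  }
}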