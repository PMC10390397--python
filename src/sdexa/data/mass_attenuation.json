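{
  "description": "Photon mass attenuation coefficients (cm^2/g) without coherent scattering corrections, compiled from standard published photon cross-section tabulations for the diagnostic energy range. Hydroxyapatite Ca10(PO4)6(OH)2 is composed from the elemental entries via the mixture rule.",
  "version": "1.0",
  "energies_kev": [30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0],
  "materials": {
    "water": [0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505, 0.1370],
    "H":  [0.3570, 0.3458, 0.3355, 0.3260, 0.3091, 0.2944, 0.2651, 0.2429],
    "O":  [0.3779, 0.2585, 0.2132, 0.1907, 0.1678, 0.1551, 0.1361, 0.1237],
    "P":  [1.7000, 0.8096, 0.4916, 0.3494, 0.2324, 0.1865, 0.1432, 0.1250],
    "Ca": [3.6560, 1.8300, 1.0190, 0.6578, 0.3656, 0.2451, 0.1582, 0.1306]
  },
  "hydroxyapatite_mass_fractions": {
    "Ca": 0.39894,
    "P": 0.18499,
    "O": 0.41407,
    "H": 0.00200
  }
}
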