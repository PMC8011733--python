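{
  "schema_version": "1",
  "description": "Population-level constants and average-healthy reference rate constants for the two-compartment oral glucose challenge model. Basal Gb/Ib are population defaults; personalization overrides them with each individual's measured fasting values.",
  "changelog": [
    "v1: initial parameterization, tuned once to an average-healthy 75 g OGTT morphology (glucose peak ~8 mmol/L near 30-45 min, insulin peak ~45 mU/L, near-basal return by 120 min); sigma kept at a Weibull shape of 1.34 rather than the pure-exponential fallback sigma=1."
  ],
  "constants": {
    "Gb": 5.0,
    "Ib": 8.0,
    "BW": 70.0,
    "vG": 0.17,
    "vI": 0.13,
    "f": 0.9,
    "Gth": 11.0,
    "c1": 0.1,
    "tau_i": 100.0,
    "tau_d": 10.0,
    "beta": 1.0,
    "c_liv": 0.03,
    "uii_b_flux": 0.55
  },
  "reference_parameters": {
    "k1": 0.025,
    "k2": 0.45,
    "k3": 0.005,
    "k4": 0.006,
    "k5": 0.012,
    "k6": 1.0,
    "k7": 0.03,
    "k8": 4.0,
    "k9": 0.08,
    "sigma": 1.34,
    "km": 5.0
  }
}
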