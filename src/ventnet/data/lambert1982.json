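{
  "schema": "ventnet-tube-law-table/1",
  "description": "Per-generation elastic tube-law coefficients and geometry for the human bronchial tree, generations 0-16, after the Lambert et al. (1982) parametrisation of Weibel's symmetric model. 'area_total' is the summed maximal cross-sectional area of the whole generation (cm^2); the per-airway reference area is area_total / 2^generation. 'alpha0' is the normalised area at zero transmural pressure, 'alpha0_prime' its slope there (per cm H2O), 'n1'/'n2' the shape exponents of the collapsed/distended branches, 'length' the airway length (cm).",
  "generations": [
    {"generation": 0,  "alpha0": 0.882, "alpha0_prime": 0.011, "n1": 0.5, "n2": 10.0, "area_total": 2.37,   "length": 12.0},
    {"generation": 1,  "alpha0": 0.882, "alpha0_prime": 0.011, "n1": 0.5, "n2": 10.0, "area_total": 2.37,   "length": 4.76},
    {"generation": 2,  "alpha0": 0.686, "alpha0_prime": 0.051, "n1": 0.6, "n2": 10.0, "area_total": 2.80,   "length": 1.90},
    {"generation": 3,  "alpha0": 0.546, "alpha0_prime": 0.080, "n1": 0.6, "n2": 10.0, "area_total": 3.50,   "length": 0.76},
    {"generation": 4,  "alpha0": 0.450, "alpha0_prime": 0.100, "n1": 0.7, "n2": 10.0, "area_total": 4.50,   "length": 1.27},
    {"generation": 5,  "alpha0": 0.370, "alpha0_prime": 0.125, "n1": 0.8, "n2": 10.0, "area_total": 5.30,   "length": 1.07},
    {"generation": 6,  "alpha0": 0.310, "alpha0_prime": 0.142, "n1": 0.9, "n2": 10.0, "area_total": 6.50,   "length": 0.90},
    {"generation": 7,  "alpha0": 0.255, "alpha0_prime": 0.159, "n1": 1.0, "n2": 10.0, "area_total": 8.00,   "length": 0.76},
    {"generation": 8,  "alpha0": 0.213, "alpha0_prime": 0.174, "n1": 1.0, "n2": 10.0, "area_total": 10.20,  "length": 0.64},
    {"generation": 9,  "alpha0": 0.184, "alpha0_prime": 0.184, "n1": 1.0, "n2": 10.0, "area_total": 12.70,  "length": 0.54},
    {"generation": 10, "alpha0": 0.153, "alpha0_prime": 0.194, "n1": 1.0, "n2": 10.0, "area_total": 15.94,  "length": 0.47},
    {"generation": 11, "alpha0": 0.125, "alpha0_prime": 0.206, "n1": 1.0, "n2": 9.0,  "area_total": 25.23,  "length": 0.39},
    {"generation": 12, "alpha0": 0.100, "alpha0_prime": 0.218, "n1": 1.0, "n2": 8.0,  "area_total": 31.00,  "length": 0.33},
    {"generation": 13, "alpha0": 0.075, "alpha0_prime": 0.226, "n1": 1.0, "n2": 8.0,  "area_total": 39.14,  "length": 0.27},
    {"generation": 14, "alpha0": 0.057, "alpha0_prime": 0.233, "n1": 1.0, "n2": 8.0,  "area_total": 51.13,  "length": 0.23},
    {"generation": 15, "alpha0": 0.045, "alpha0_prime": 0.239, "n1": 1.0, "n2": 7.0,  "area_total": 71.51,  "length": 0.20},
    {"generation": 16, "alpha0": 0.039, "alpha0_prime": 0.243, "n1": 1.0, "n2": 7.0,  "area_total": 105.00, "length": 0.165}
  ]
}
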