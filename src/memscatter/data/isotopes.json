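{
  "_schema": "label -> {b_coh_fm: coherent neutron scattering length (fm), Z: atomic number, mass_u: atomic/standard mass (u), b_inc_fm: incoherent scattering length (fm, optional)}",
  "_reference": "Sears, Neutron News 3 (1992) 26; standard atomic weights (CIAAW)",
  "H":   {"b_coh_fm": -3.7390, "Z": 1,  "mass_u": 1.008,    "b_inc_fm": 25.274},
  "2H":  {"b_coh_fm": 6.671,   "Z": 1,  "mass_u": 2.01410,  "b_inc_fm": 4.04},
  "3H":  {"b_coh_fm": 4.792,   "Z": 1,  "mass_u": 3.01605,  "b_inc_fm": -1.04},
  "Li":  {"b_coh_fm": -1.90,   "Z": 3,  "mass_u": 6.94},
  "B":   {"b_coh_fm": 5.30,    "Z": 5,  "mass_u": 10.81},
  "C":   {"b_coh_fm": 6.6460,  "Z": 6,  "mass_u": 12.011,   "b_inc_fm": 0.0},
  "13C": {"b_coh_fm": 6.19,    "Z": 6,  "mass_u": 13.00335},
  "N":   {"b_coh_fm": 9.36,    "Z": 7,  "mass_u": 14.007,   "b_inc_fm": 2.0},
  "15N": {"b_coh_fm": 6.44,    "Z": 7,  "mass_u": 15.00011},
  "O":   {"b_coh_fm": 5.803,   "Z": 8,  "mass_u": 15.999,   "b_inc_fm": 0.0},
  "F":   {"b_coh_fm": 5.654,   "Z": 9,  "mass_u": 18.998},
  "Na":  {"b_coh_fm": 3.63,    "Z": 11, "mass_u": 22.990},
  "Mg":  {"b_coh_fm": 5.375,   "Z": 12, "mass_u": 24.305},
  "Al":  {"b_coh_fm": 3.449,   "Z": 13, "mass_u": 26.982},
  "Si":  {"b_coh_fm": 4.1491,  "Z": 14, "mass_u": 28.085},
  "P":   {"b_coh_fm": 5.13,    "Z": 15, "mass_u": 30.974,   "b_inc_fm": 0.2},
  "S":   {"b_coh_fm": 2.847,   "Z": 16, "mass_u": 32.06},
  "Cl":  {"b_coh_fm": 9.5770,  "Z": 17, "mass_u": 35.45},
  "K":   {"b_coh_fm": 3.67,    "Z": 19, "mass_u": 39.098},
  "Ca":  {"b_coh_fm": 4.70,    "Z": 20, "mass_u": 40.078},
  "Ti":  {"b_coh_fm": -3.438,  "Z": 22, "mass_u": 47.867},
  "Cr":  {"b_coh_fm": 3.635,   "Z": 24, "mass_u": 51.996},
  "Mn":  {"b_coh_fm": -3.73,   "Z": 25, "mass_u": 54.938},
  "Fe":  {"b_coh_fm": 9.45,    "Z": 26, "mass_u": 55.845},
  "Ni":  {"b_coh_fm": 10.3,    "Z": 28, "mass_u": 58.693},
  "Cu":  {"b_coh_fm": 7.718,   "Z": 29, "mass_u": 63.546},
  "Zn":  {"b_coh_fm": 5.680,   "Z": 30, "mass_u": 65.38},
  "Br":  {"b_coh_fm": 6.795,   "Z": 35, "mass_u": 79.904},
  "I":   {"b_coh_fm": 5.28,    "Z": 53, "mass_u": 126.904},
  "Au":  {"b_coh_fm": 7.63,    "Z": 79, "mass_u": 196.967}
}
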