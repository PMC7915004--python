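[
 {"name": "BE-H-10", "density_g_cm3": 1.500,
  "mass_fractions": {"H": 5.11, "C": 42.45, "N": 1.73, "O": 28.13, "P": 7.00, "Cl": 0.09, "Ca": 15.49}},
 {"name": "BE-N-10", "density_g_cm3": 1.240,
  "mass_fractions": {"H": 6.97, "C": 60.03, "N": 2.45, "O": 21.79, "P": 2.30, "Cl": 0.13, "Ca": 6.33}},
 {"name": "BE-T-10", "density_g_cm3": 1.730,
  "mass_fractions": {"H": 3.69, "C": 29.22, "N": 1.19, "O": 32.66, "P": 10.24, "Cl": 0.06, "Ca": 22.92}},
 {"name": "WD-3010", "density_g_cm3": 1.018,
  "mass_fractions": {"H": 8.63, "C": 68.89, "N": 2.18, "O": 17.88, "Cl": 0.15, "Ca": 2.27}},
 {"name": "Aluminium", "density_g_cm3": 2.699,
  "mass_fractions": {"Al": 100.0}},
 {"name": "Graphite", "density_g_cm3": 2.210,
  "mass_fractions": {"C": 100.0}},
 {"name": "PMMA", "density_g_cm3": 1.170,
  "mass_fractions": {"H": 8.05, "C": 59.98, "O": 31.96}},
 {"name": "Water", "density_g_cm3": 1.000,
  "mass_fractions": {"H": 11.19, "O": 88.81}}
]
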