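{
  "name": "xylose_bdo",
  "description": "Xylose-to-2,3-BDO route: isomerase/xylulokinase feed the pentose phosphate rearrangement (rpe written in the net carbon-flow direction X5P->Ru5P), which returns carbon to the ED pathway and lower glycolysis. Relative fluxes are per mol 2,3-BDO and satisfy carbon balance (1.2 C5 = C4 + 2 CO2). dg0_prime/kinetics null where a user parameter table is required.",
  "temperature_K": 298.15,
  "conc_lb_mM": 0.001,
  "conc_ub_mM": 10.0,
  "fixed_conc_mM": {"xyl_e": 245.0},
  "boundary": ["xyl_e", "bdo", "co2", "atp", "adp", "pi", "nad", "nadh", "nadp", "nadph"],
  "product": "bdo",
  "carbon": {"xyl_e": 5, "xyl": 5, "xlu": 5, "x5p": 5, "ru5p": 5, "r5p": 5,
             "s7p": 7, "e4p": 4, "f6p": 6, "g6p": 6, "6pgl": 6, "6pg": 6,
             "kdpg": 6, "gap": 3, "bpg": 3, "3pg": 3, "2pg": 3, "pep": 3,
             "pyr": 3, "alac": 5, "actn": 4, "bdo": 4, "co2": 1,
             "atp": 0, "adp": 0, "pi": 0, "nad": 0, "nadh": 0, "nadp": 0, "nadph": 0},
  "reactions": [
    {"id": "glf",   "equation": "xyl_e -> xyl",               "dg0_prime_kj_mol": 0.0,  "rel_flux": 1.2, "irreversible": true},
    {"id": "xyl",   "equation": "xyl -> xlu",                 "dg0_prime_kj_mol": null, "rel_flux": 1.2, "irreversible": false},
    {"id": "xk",    "equation": "xlu + atp -> x5p + adp",     "dg0_prime_kj_mol": null, "rel_flux": 1.2, "irreversible": false},
    {"id": "rpe",   "equation": "x5p -> ru5p",                "dg0_prime_kj_mol": null, "rel_flux": 0.4, "irreversible": false},
    {"id": "rpi",   "equation": "ru5p -> r5p",                "dg0_prime_kj_mol": null, "rel_flux": 0.4, "irreversible": false},
    {"id": "tkt1",  "equation": "x5p + r5p -> s7p + gap",     "dg0_prime_kj_mol": null, "rel_flux": 0.4, "irreversible": false},
    {"id": "tal",   "equation": "s7p + gap -> e4p + f6p",     "dg0_prime_kj_mol": null, "rel_flux": 0.4, "irreversible": false},
    {"id": "tkt2",  "equation": "x5p + e4p -> f6p + gap",     "dg0_prime_kj_mol": null, "rel_flux": 0.4, "irreversible": false},
    {"id": "pgi",   "equation": "f6p -> g6p",                 "dg0_prime_kj_mol": null, "rel_flux": 0.8, "irreversible": false},
    {"id": "g6pdh", "equation": "g6p + nadp -> 6pgl + nadph", "dg0_prime_kj_mol": null, "rel_flux": 0.8, "irreversible": false},
    {"id": "pgl",   "equation": "6pgl -> 6pg",                "dg0_prime_kj_mol": null, "rel_flux": 0.8, "irreversible": false},
    {"id": "edd",   "equation": "6pg -> kdpg",                "dg0_prime_kj_mol": null, "rel_flux": 0.8, "irreversible": false},
    {"id": "eda",   "equation": "kdpg -> pyr + gap",          "dg0_prime_kj_mol": null, "rel_flux": 0.8, "irreversible": false},
    {"id": "gapdh", "equation": "gap + nad + pi -> bpg + nadh", "dg0_prime_kj_mol": null, "rel_flux": 1.2, "irreversible": false},
    {"id": "pgk",   "equation": "bpg + adp -> 3pg + atp",     "dg0_prime_kj_mol": null, "rel_flux": 1.2, "irreversible": false},
    {"id": "pgm",   "equation": "3pg -> 2pg",                 "dg0_prime_kj_mol": null, "rel_flux": 1.2, "irreversible": false},
    {"id": "eno",   "equation": "2pg -> pep",                 "dg0_prime_kj_mol": null, "rel_flux": 1.2, "irreversible": false},
    {"id": "pyk",   "equation": "pep + adp -> pyr + atp",     "dg0_prime_kj_mol": null, "rel_flux": 1.2, "irreversible": false},
    {"id": "als",   "equation": "2 pyr -> alac + co2",        "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": true},
    {"id": "aldc",  "equation": "alac -> actn + co2",         "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": true},
    {"id": "bdh",   "equation": "actn + nadh -> bdo + nad",   "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false}
  ]
}
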