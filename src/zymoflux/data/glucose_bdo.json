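{
  "name": "glucose_bdo",
  "description": "Glucose-to-2,3-BDO route via the Entner-Doudoroff pathway. dg0_prime_kj_mol and kinetics are null where a user-supplied parameter table (eQuilibrator / BRENDA sourced) is required; glf transport carries zero standard Gibbs energy by construction. Water and protons are absorbed into dg0_prime.",
  "temperature_K": 298.15,
  "conc_lb_mM": 0.001,
  "conc_ub_mM": 10.0,
  "fixed_conc_mM": {"glc_e": 443.0},
  "boundary": ["glc_e", "bdo", "co2", "atp", "adp", "pi", "nad", "nadh", "nadp", "nadph"],
  "product": "bdo",
  "carbon": {"glc_e": 6, "glc": 6, "g6p": 6, "6pgl": 6, "6pg": 6, "kdpg": 6,
             "gap": 3, "bpg": 3, "3pg": 3, "2pg": 3, "pep": 3, "pyr": 3,
             "alac": 5, "actn": 4, "bdo": 4, "co2": 1,
             "atp": 0, "adp": 0, "pi": 0, "nad": 0, "nadh": 0, "nadp": 0, "nadph": 0},
  "reactions": [
    {"id": "glf",   "equation": "glc_e -> glc",               "dg0_prime_kj_mol": 0.0,  "rel_flux": 1.0, "irreversible": true},
    {"id": "glk",   "equation": "glc + atp -> g6p + adp",     "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "g6pdh", "equation": "g6p + nadp -> 6pgl + nadph", "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "pgl",   "equation": "6pgl -> 6pg",                "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "edd",   "equation": "6pg -> kdpg",                "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "eda",   "equation": "kdpg -> pyr + gap",          "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "gapdh", "equation": "gap + nad + pi -> bpg + nadh", "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "pgk",   "equation": "bpg + adp -> 3pg + atp",     "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "pgm",   "equation": "3pg -> 2pg",                 "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "eno",   "equation": "2pg -> pep",                 "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "pyk",   "equation": "pep + adp -> pyr + atp",     "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false},
    {"id": "als",   "equation": "2 pyr -> alac + co2",        "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": true},
    {"id": "aldc",  "equation": "alac -> actn + co2",         "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": true},
    {"id": "bdh",   "equation": "actn + nadh -> bdo + nad",   "dg0_prime_kj_mol": null, "rel_flux": 1.0, "irreversible": false}
  ]
}
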