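{
 "name": "fig5_hybrid",
 "description": "Hybrid model: bistable GTPase toggle with conserved pools plus slow ECM feedback. Defaults sit at the antiphase-oscillatory point (gamma_R, gamma_rho) = (0.3, 0.4); (0.2, 0.2) is bistable-polarized.",
 "variant": {
  "tag": "M3",
  "ecm_to_rac": false
 },
 "parameters": {
  "n": 3,
  "delta": 1.0,
  "b_R": 6.0,
  "k_E": 2.6,
  "gamma_E": 0.4,
  "E0": 0.15,
  "k_R": 0.05,
  "gamma_R": 0.3,
  "R0": 1.0,
  "k_rho": 0.05,
  "gamma_rho": 0.4,
  "rho0": 1.0,
  "eps": 0.02,
  "l_c": 0.0,
  "R_T": 2.0,
  "rho_T": 2.0
 },
 "documented_points": {
  "polarized": {
   "gamma_R": 0.2,
   "gamma_rho": 0.2,
   "l_c": 0.0
  },
  "oscillatory": {
   "gamma_R": 0.3,
   "gamma_rho": 0.4,
   "l_c": 0.0
  }
 },
 "provenance": "n = 3, delta = 1, R_T = rho_T = 2 fixed; kinetic defaults calibrated so b_rho(E) spans the conserved toggle's polarity-unstable range (lower border ~2.12 at b_R = 6)."
}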