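{
 "name": "model2",
 "description": "Bistable-GTPase (toggle) model with abundant pools and slow ECM negative feedback; oscillates at the base point, but ROCK inhibition (gamma_rho reduction) leads to a non-polar stationary state.",
 "variant": {
  "tag": "M2",
  "ecm_to_rac": false
 },
 "parameters": {
  "n": 3,
  "delta": 1.0,
  "b_R": 2.0,
  "k_E": 1.2,
  "gamma_E": 3.0,
  "E0": 0.25,
  "k_R": 0.05,
  "gamma_R": 0.5,
  "R0": 1.0,
  "k_rho": 0.05,
  "gamma_rho": 0.5,
  "rho0": 1.0,
  "eps": 0.05,
  "l_c": 0.05
 },
 "documented_points": {
  "oscillatory": {
   "gamma_rho": 0.5
  },
  "rock_inhibited_nonpolar": {
   "gamma_rho": 0.125
  }
 },
 "provenance": "b_R chosen inside the toggle's bistable wedge; b_rho(E) spans beyond the bistable b_rho range [~1.65, ~3.3] at b_R = 2."
}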