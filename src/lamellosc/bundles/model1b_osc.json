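{
 "name": "model1b_osc",
 "description": "Lamellipod-competition model with conserved GTPase pools and linear feedbacks, calibrated to oscillate (antiphase) at gamma_rho = 1.5 with fast ECM dynamics (eps > 1); oscillations vanish for eps < 1.",
 "variant": {
  "tag": "M1B",
  "ecm_to_rac": false
 },
 "parameters": {
  "n": 1,
  "delta": 1.0,
  "b_R": 1.0,
  "k_E": 0.1,
  "gamma_E": 1.0,
  "k_R": 0.3,
  "gamma_R": 0.0,
  "k_rho": 0.05,
  "gamma_rho": 1.5,
  "eps": 12.0,
  "l_c": 1.7,
  "R_T": 2.0,
  "rho_T": 2.0
 },
 "documented_points": {
  "oscillatory": {
   "gamma_rho": 1.5
  },
  "polarized": {
   "gamma_rho": 0.5
  }
 },
 "provenance": "Monostable GTPase kinetics (n = 1); calibrated so the conservation bound 2*k_rho + gamma_rho*rho_T stays below 2*l_c at the oscillatory point, keeping the coexistence regime inaccessible."
}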