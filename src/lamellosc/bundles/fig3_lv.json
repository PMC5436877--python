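{
 "name": "fig3_lv",
 "description": "Isolated lamellipod-competition (Lotka-Volterra) submodel with frozen protrusion/contraction coefficients; three constrained sweep paths L_E1 + L_E2 = K.",
 "submodel": "ecm_competition",
 "coefficients": {
  "A_E1": 1.0,
  "A_E2": 1.0,
  "l_c": 1.0,
  "eps": 1.0
 },
 "K_paths": [
  0.9,
  1.5,
  3.5
 ],
 "provenance": "Frozen-coefficient competition analysis; A_E1 = A_E2 = l_c = 1."
}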