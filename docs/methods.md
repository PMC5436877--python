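# Methods

## Model family

All variants share the two-lamellipod skeleton described in the README:
per lamellipod, an activation–inactivation equation for Rac and for Rho
with mutual inhibition through decreasing Hill functions of cooperativity
*n*, and a competition equation for the cell–ECM contact level *E_k* with
logistic-type self-limitation and a bilinear inter-lamellipod competition
term `l_c·E_k·E_j`. Two structural axes distinguish the variants:

* **Kinetics.** The M1 family uses linear feedback terms
  (`A_E = k_R + γ̄_R·R`, `L_E = k_ρ + γ̄_ρ·ρ`, `b_ρ(E) = k_E + γ̄_E·E`,
  `B_E = 0`) and non-cooperative crosstalk (*n* = 1), so its ECM equation in
  isolation is a Lotka–Volterra competition model and all bistability lives
  in the competition layer. M2 and M3 use cooperative crosstalk (*n* = 3)
  and saturating Hill feedbacks of exponent 3
  (`B_E = k_R + γ_R·R³/(R₀³+R³)` etc., `A_E = 0`), placing the bistability
  in the GTPase toggle.
* **GTPase availability.** M1A and M2 treat the inactive pools as abundant
  (R_I = ρ_I = 1; the constant is absorbed into b_R, b_ρ by the
  nondimensionalization). M1B, M1C and M3 conserve totals
  `R₁+R₂+R_I = R_T`, `ρ₁+ρ₂+ρ_I = ρ_T`, coupling the lamellipods through a
  shared finite pool.

M1C inserts first-order effector trackers `dw_k/dt = ε₂(R_k − w_k)`,
`dc_k/dt = ε₂(ρ_k − c_k)` between the GTPases and the competition
coefficients (only `A_E`, `L_E` read *w*, *c*). In the ε₂ → ∞ limit the
trackers collapse onto (R, ρ) and the model reduces to M1B exactly; this
quasi-steady-state limit is verified numerically in the test suite (the
sup-norm distance between M1C and M1B trajectories falls monotonically as
ε₂ grows tenfold stepwise).

The optional ECM → Rac feedback of the hybrid model multiplies the Rac
activation rate by a saturating enhancement,
`b_R · (1 + γ_ER·E³/(E₀³+E³))`, mirroring the ECM → Rho Hill form. This is
one of several reasonable forms; only its saturating, magnitude-limited
character matters for the qualitative statements made here.

### ε placement

The dimensionless master form multiplies only the protrusion terms
`(B_E + A_E·E_k)` by ε; the contraction and competition terms are not
ε-scaled. An alternative convention scales the whole right-hand side of
the ECM equation. We implement the first (the linearization rate of the
ECM level then scales as √ε, which is what the slow-feedback arguments
below rely on); rescaling time and the contraction coefficients maps one
convention onto the other.

### State layout and conservation

Conserved variants integrate the inactive pools R_I, ρ_I as explicit state
variables (8 ODEs for M1B/M3, 12 for M1C) rather than substituting the
conservation law algebraically. The totals are then genuine first
integrals of the implemented vector field — a testable property rather
than an identity — and the acceptance machinery checks them to 1e-6 over
t = 10³. Equilibrium and stability analysis, by contrast, always works in
reduced coordinates (pools eliminated), because the explicit-pool form has
structurally zero eigenvalues along the conservation laws that would make
every equilibrium non-hyperbolic.

## Numerics

* **Integration.** LSODA (stiff-capable, automatic switching) with
  rel/abs tolerances 1e-8/1e-10 by default; output on a uniform grid
  decoupled from internal steps. The positive orthant is analytically
  invariant; an undershoot below −abs_tol triggers one retry at 100×
  tighter tolerance before an error is raised, and sub-tolerance negative
  excursions are clipped to zero on output.
* **Equilibria.** Batched damped Newton iteration from a seeded
  Latin-hypercube multistart over the positive orthant plus boundary-face
  seeds (the competition submodels keep exclusion equilibria on the faces
  E_k = 0) and a near-origin point. Roots are kept when the residual
  infinity-norm is below 1e-9, deduplicated at 1e-5, and classified by the
  eigenvalues of a central finite-difference Jacobian (relative step 1e-6,
  absolute floor 1e-8; verified against a symbolic-differentiation oracle
  in the tests). Stability labels treat |Re λ| ≤ 1e-8 as zero
  (non-hyperbolic).
* **Continuation.** One-parameter sweeps are naive natural-parameter
  continuation with reseeding: previous roots seed the next step's search,
  branches are matched by nearest neighbor with a penalty for roots whose
  zero-component pattern differs (so a boundary branch does not capture a
  colliding interior root near a transcritical crossing). Sign changes of
  the leading eigenvalue real part along a persisting branch are bisected
  to 1e-6 in the parameter and labeled Hopf (complex pair) or
  transcritical (real); branch terminations are bisected on root existence
  and labeled folds, unless the root persists beyond the point (a
  transcritical seen from the annihilated interior branch), in which case
  the surviving branch's eigenvalue crossing reports the point instead.
  Pseudo-arclength continuation was not needed: the systems are
  low-dimensional and the diagrams of interest are reproducible this way.
* **Phenotype classification.** The first half of a trajectory is
  discarded as transient. If the terminal |rhs|∞ is below 1e-6 the state
  is stationary: polarized when the polarity index |E₁−E₂|/(E₁+E₂)
  exceeds 0.2, apolar otherwise. Otherwise peaks of E₁ and E₂ (prominence
  ≥ 1% of the signal mean) define the period; a sustained oscillation
  needs ≥ 5 periods, period CV < 0.05, and a last-to-first cycle amplitude
  ratio > 0.9. Period statistics are computed from whichever channel shows
  more peaks, so relabeling the lamellipods cannot change the verdict.
  Antiphase means the E₂ peaks sit 0.35–0.65 periods after the E₁ peaks.
  All thresholds are configurable (`Thresholds`); the defaults are package
  choices — the experiments give no quantitative phenotype criteria.
  A parameter point is classified from a +1% E₁-biased near-symmetric
  initial condition and its mirror image; opposite winners ⇒ bistable
  polarity.

## Calibration of the shipped bundles

Rate parameters of this kind are not directly measurable, so the bundles
are calibrated by the models' own logic: choose
b_R so the GTPase layer has a bistable/polarity-competent range of b_ρ,
then place the range of b_ρ(E) relative to that window.

* **`fig5_hybrid`** (M3): n = 3, δ = 1, R_T = ρ_T = 2 are the bundle's
  fixed reference conditions. The two-lamellipod conserved toggle at
  b_R = 6 loses symmetric stability for common b_ρ ≳ 2.12 (computed by the
  package's own equilibrium analysis), with a polarization growth rate of
  order 0.1. The calibrated kinetics (k_E = 2.6, γ_E = 0.4, E₀ = 0.15,
  k_R = k_ρ = 0.05, R₀ = ρ₀ = 1, ε = 0.02) keep both lamellipods' b_ρ(E_k)
  inside the polarity-competent band at weak feedback — a stable polarized
  cell — while stronger feedback (larger γ_R, γ_ρ or γ_E) widens the gap
  between the winner's and the loser's b_ρ until the polarized state loses
  stability through a Hopf bifurcation (at γ_ρ ≈ 0.38 for γ_R = 0.3) and
  the antiphase relaxation cycle takes over. ε = 0.02 makes the ECM
  response (rate ~2√(ε·B·L) ≈ 0.04) slower than the polarization
  instability, which is what allows polarization at all: a faster ECM
  response feeds b_ρ back strongly enough to re-stabilize the symmetric
  state (the apolar outcomes seen near the boundary). At the documented
  points, (γ_R, γ_ρ) = (0.2, 0.2) is bistable-polar and (0.3, 0.4)
  antiphase-oscillatory with phase offset 0.50 and period ≈ 294. The
  polarized state's E-contrast at (0.2, 0.2) gives a polarity index of
  0.203, just above the 0.2 threshold — weak feedback polarizes weakly.
  Setting l_c = 0.1 instead of 0 enlarges the oscillatory region (points
  just inside the polar side flip to oscillation), consistent with direct
  competition promoting alternation.
* **`model2`** (M2): b_R = 2 puts the single-compartment toggle's bistable
  b_ρ window at ≈ (1.65, 3.33) (the package's fold sweep). k_E = 1.2,
  γ_E = 3, E₀ = 0.25 make b_ρ(E) traverse beyond both folds over the
  realized E range, producing a per-lamellipod relaxation oscillation
  (period ≈ 48); weak direct coupling l_c = 0.05 phase-locks the two
  lamellipods in antiphase (stronger coupling ≥ 0.1 stabilizes a symmetric
  stationary state instead). Reducing γ_ρ (the ROCK-inhibition analogue)
  raises the contracted state's E and hence its b_ρ above the lower fold:
  the relaxation loop parks, and because both identical lamellipods park
  the same way the outcome is a non-polar stationary state at every fold
  ≤ 0.75 — the documented direction-of-effect failure of this variant.
* **`model1b_osc`** (M1B): linear kinetics with n = 1, b_R = 1, k_E = 0.1,
  γ̄_E = 1, k_R = 0.3, γ̄_R = 0, k_ρ = 0.05, γ̄_ρ = 1.5, l_c = 1.7,
  R_T = ρ_T = 2, ε = 12. Fast ECM (ε > 1) with slow GTPase feedback drives
  the competition layer around its bistable regime: antiphase oscillation
  at γ̄_ρ = 1.5 (the documented oscillatory point). The conservation bound
  `L_E(ρ₁) + L_E(ρ₂) ≤ 2k_ρ + γ̄_ρ·ρ_T = 3.1 < 2 l_c` keeps the coexistence
  regime inaccessible. With ε < 1 (GTPase feedback faster than the ECM) no
  oscillation occurs — the timescale objection that disqualifies this
  variant. γ̄_R = 0 in this bundle: with a nonzero Rac → protrusion slope
  the abundant-pool counterpart acquires a two-delay feedback loop that
  oscillates on its own, which contradicts the intended M1A behavior
  (below); the M1B oscillation does not need it.
* **M1A** is the same bundle without the conserved totals. Across the
  calibrated γ̄_ρ sweep (0.3–2.0) it never antiphase-oscillates: at weak
  contraction (max L_E < l_c) it stays polarized (the competition layer
  cannot leave its bistable regime), and at strong contraction it crosses
  into coexistence and stabilizes there. Both failure modes appear on the
  sweep.
* **`fig3_lv`**: the frozen-coefficient competition submodel,
  A_E1 = A_E2 = l_c = 1 and the constrained paths L_E1 + L_E2 = K for
  K = 0.9, 1.5, 3.5.

The scenario checks (ROCK inhibition, PI3K up, fibronectin up, Rac
inhibition, microtubule ablation) sweep the mapped parameter over bounded
fold ranges around the hybrid bundle's base point and require a single
correctly-oriented polarized/oscillatory boundary. The fold ranges are
part of the calibration: far outside them the hybrid model re-enters
polarized or apolar regimes (e.g. γ_ρ ≥ 0.7 at γ_R = 0.3), a reminder that
the direction statements are local boundary shifts, not global
monotonicity.

## Population heterogeneity

Cell-to-cell variability is modeled as independent multiplicative
lognormal noise, median 1, with default σ = 0.3 on the three feedback
strengths {γ_R, γ_ρ, γ_E}; each synthetic cell is classified
independently with a shared seed. This is a deliberately simple stand-in:
it reproduces the qualitative statements (a population near the Hopf
boundary contains both phenotypes; ROCK inhibition moves mass from
oscillatory to polarized) and is labeled as qualitative in its reports.
The distribution choice and the choice of which parameters vary are
package decisions, not measured quantities.

## What the synthetic conditions do and do not show

The models are deterministic, two-compartment, and dimensionless. They do
not represent spatial signaling gradients within a lamellipod, stochastic
fluctuations (the wandering of the "random" phenotype is identified with
deterministic apolar coexistence, not simulated), mechanics beyond the
single competition coefficient, or absolute timescales/concentrations.
Passing tests therefore demonstrate internal consistency of the regime
structure and the direction of boundary shifts under parameter
perturbations — not quantitative agreement with any measured cell-fraction
data.

## Problem sizes

Defaults used by the tests and the acceptance script: simulations of
3 × 10³–10⁴ dimensionless time units at 2–6 × 10³ output points;
equilibrium searches with 12–64 multistarts; 41×41 (analytic vs numeric
competition regimes) and 50×50 (monostability) parameter grids; 7-point
scenario sweeps with paired simulations per point; populations of 5–16
synthetic cells in the unit tests. These sizes resolve every qualitative
feature the package asserts; all are arguments and can be raised.
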