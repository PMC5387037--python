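# Methods

## Model

The leaf is treated as a chain of diffusion resistances between the
intercellular air spaces (CO2 partial pressure C_i, μbar) and the Rubisco
carboxylation sites in the chloroplast stroma (C_c), coupled to FvCB
biochemistry. Net assimilation at a given C_c is the minimum of two
rectangular hyperbolae,

    A = (C_c − Γ*) · x1 / (C_c + x2) − R_d,

with (x1, x2) = (V_cmax, K_mC·(1 + O/K_mO)) when Rubisco limits and
(J/4, 2Γ*) when NADPH-limited electron transport does; Γ* = 0.5·O/S_c/o.
Gross carboxylation is V_c = x1·C_c/(C_c + x2) and photorespiratory release
F = V_c·Γ*/C_c, so A + F + R_d = V_c holds identically — this conservation
is enforced as a property test. An ATP-limited electron-transport variant
(x1 = J/4.5, x2 = 10.5Γ*/4.5) is selectable via
`PhotoParams(et_form="atp")`; the NADPH form is the default because it is
the form the variable-J estimation convention assumes.

The mesophyll resistance r_m,dif = 1/g_m,dif is split into
r_wp = (1−ω)·r_m,dif (cell wall + plasmalemma + most cytosol) and
r_ch = ω·r_m,dif (chloroplast envelope + stroma + residual cytosol). CO2
released in mitochondria re-enters the network at a position set by the
organelle arrangement: a fraction σ of it must cross r_ch (in addition to
r_wp and the stomatal resistance r_sc) to escape. σ decomposes as k·λ with
λ the inner-cytosol mitochondria fraction and k a chloroplast-gap factor
(0 ≤ k ≤ 1/λ); `ResistanceParams` accepts either σ directly or (λ, k) and
reduces immediately — k is not modelled mechanistically, which would need a
reaction–diffusion treatment outside this package's scope. The drawdown is

    C_c = C_i − A·r_m,dif − ω(1−σ)(F + R_d)·r_m,dif,

and the whole arrangement dependence enters through the single composite
ω_eff = ω(1−σ). Substituting the FvCB hyperbola gives a quadratic
C_c² + b·C_c + c = 0 with β = 1 − ω_eff,

    b = x2 − C_i + r·x1 − r·β·R_d,    c = −C_i·x2 − r·β·(x1·Γ* + R_d·x2).

c < 0 for all valid inputs, so the roots straddle zero and the positive
root is the unique physical solution — no iteration, no convergence
question. `operating_point` solves both limitation states this way and
keeps the smaller A (ties labelled Rubisco for deterministic reporting).
Below the compensation point the solver still returns the positive root
(C_c > C_i is physical there); g_m,app = A/(C_i − C_c) is reported as NaN
for A ≤ 0 where the ratio loses meaning.

The CO2 compensation point has the closed form
C_c,Γ = (Γ*·x1 + R_d·x2)/(x1 − R_d), shifted to
C_i,Γ = C_c,Γ + ω_eff·V_c(C_c,Γ)·r_m,dif since F + R_d = V_c at A = 0.

## Refixation

The refixed fraction of mitochondrial CO2 is a two-branch resistor ratio
(see README for the formula). The flux-to-pressure conversion factor
cancels in the ratio and never appears in code. Worked tables evaluate the
carboxylation resistance r_cx = (C_c + x2)/x1 at the reference point
C_c = Γ* with the Rubisco-limited (x1, x2) — this convention reproduces the
canonical values 0.385 (σ = 1) and 0.333 (σ = 0.5) for the reference chain
r_wp = r_ch = 1.25, r_sc = 2.5, r_cx ≈ 8.0 bar m² s mol⁻¹; an explicit C_c
can be supplied instead. The Case-III assumption that the released-CO2
partial-pressure factor is the same for inner and outer mitochondria pools
is hard-coded. r_sc defaults to r_m,dif when unspecified.

## Estimation and fitting

The variable-J method inverts the NADPH-limited equation,
C_c = Γ*(J + 8(A + R_d))/(J − 4(A + R_d)), feasible only for
J > 4(A + R_d). Back-calculation of g_m,dif from a candidate C_c infers
F̂ = (A + R_d)·Γ*/(C_c − Γ*) from that same C_c (the estimation pathway has
no access to the true F) and inverts the drawdown equation. In the bias
experiment J is held constant across C_i; any J(C_i) profile can be passed
per record.

`fit_multi_o2` minimises Σ(A_obs − A_model)² over g_m,dif ∈ (0, 10] and
ω_eff ∈ [0, 1] with scipy's bounded trust-region least squares, restarted
from a fixed 5×5 grid (g_m,dif ∈ {0.05, 0.2, 0.5, 1.5, 5},
ω_eff ∈ {0.05, 0.275, 0.5, 0.725, 0.95}) to avoid the shallow local minima
of the two-parameter surface; the fixed grid keeps results deterministic.
ω and σ are not separately identifiable from gas exchange (only ω(1−σ)
enters the model), so the fitter estimates the composite and
`sigma_from_omega` separates σ given an anatomically measured ω. At least
two distinct O2 levels are required: O2 contrast moves photorespiration and
hence the (F + R_d)/A leverage that separates ω_eff from g_m,dif.
Non-convergence is flagged on the result, not raised.

## Synthetic data

`generate_synthetic` emulates a gas-exchange campaign: for each (C_i, O2)
pair of a scenario it solves the forward model and adds independent
Gaussian noise (mean 0, default sd 0.2 μmol m⁻² s⁻¹) to A only — C_i and J
are treated as exactly controlled/known, and R_d and the biochemistry as
known. Real measurements violate all of these to some degree (instrument
noise on C_i, fluorescence calibration error in J, uncertain R_d and
S_c/o), so passing recovery tests here demonstrates correctness of the
estimation machinery under the stated noise model, not field-robustness of
the multi-O2 approach. Default study conditions: C_i grid 50–400 μbar
(14 points at step 27 for fitting scenarios, i.e. 42 records across the
three O2 levels 20/210/400 mbar), ambient O = 210 mbar elsewhere. The
default noiseless C_c is attached to every record so estimation paths can
be validated against ground truth.

## Numerical choices

- Unit convention: C_c/C_i/Γ*/K_mC/x2 in μbar; O and K_mO in mbar; fluxes
  in μmol m⁻² s⁻¹; resistances in bar m² s mol⁻¹, so resistance × flux is
  directly μbar. Conversions happen only at I/O boundaries (CSV headers
  carry units).
- Solver agreement tolerance 1e-6 μbar against the bisection oracle;
  algebraic identities tested at relative 1e-9 or 1e-12.
- Ambient O2 (210 mbar) is the default when a config omits O; r_sc
  defaults to r_m,dif. Both defaults are logged when applied.
- The tie at A_c = A_j is labelled Rubisco-limited.

## Limitations

- No TPU/triose-phosphate limitation, temperature or irradiance response
  of the parameters, C4/CAM biochemistry, or fluorescence physics for
  estimating J.
- The intercellular-air-space and cytosol resistances are folded into
  r_wp/r_ch rather than carried separately; spatial CO2 gradients are out
  of scope (they require reaction–diffusion models).
- The Monte-Carlo recovery evidence for multi-O2 fitting is conditional on
  the generator's noise model (noise on A only); identifiability under
  correlated or input-side errors is untested.
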