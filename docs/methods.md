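# Methods

## Model structure

The model is a whole-body PBPK system for a 70-kg adult with 22 amount
compartments and 6 cumulative elimination sinks per drug. Blood flows,
tissue volumes, gastrointestinal transit constants, intestinal radii
(2.0/1.63/1.45 cm for duodenum/jejunum/ileum) and GFR (120 mL/min) are
fixed physiological constants shipped as `data/physiology.yaml`. All
equations are written on blood concentrations; tissue:plasma partition
coefficients `Kp` are converted with the blood/plasma ratio,
`K_tissue:b = Kp / R_b`, which keeps every organ balance dimensionally
consistent.

**Gut.** An oral dose enters the stomach instantaneously and moves down a
transit chain (stomach → duodenum → jejunum → ileum → cecum → colon → fecal
sink) with first-order constants `K_t,i`. Only duodenum, jejunum and ileum
absorb, with `k_a,i = 2·P_eff,A-B/r_i` (or a directly supplied `k_a` applied
to all three segments). Enterocyte compartments exchange with the lumen:
apical efflux uses `k_b,i = 2·P_eff,B-A/r_i` per transporter, scaled by
regional expression factors `T_sf` (P-gp 0.16:1.2:1.0, BCRP 0.68:1.45:1.0,
MRP2 1.27:1.77:1.0 for duodenum:jejunum:ileum). Two drugs (pravastatin,
bosentan) carry a lumen-facing MRP2 efflux *clearance* instead of a
permeability; it is distributed over the three absorptive segments in
proportion to the MRP2 `T_sf` weights and acts on the enterocyte
concentration. Gut-wall CYP3A metabolism uses per-segment intrinsic
clearances derived from microsomal activity by a jejunum-anchored rule
(jejunal wet-weight fraction 0.51 x 3155.2 mg total intestinal microsomal
protein), regionalised by CYP3A4 abundance (9.7/38.4/22.4 nmol). Enterocyte
outflow to the portal stream and the metabolic loss both act on
`C_gw/(K_gut:b)`.

**Liver.** The 1690-mL liver splits into hepatic blood and hepatocytes;
the split (25% blood) is a structural constant exposed in the physiology
fixture, since only the total volume is a measured input. Hepatic blood
receives the portal outflows, the spleen outflow and a hepatic-artery flow
(total liver flow minus portal contributions, 663 mL/min), and exchanges
with hepatocytes via active OATP uptake `SF_act·CL_int,up,OATP` plus
passive diffusion `CL_int,pd`, both on the unbound blood concentration;
passive back-diffusion acts on the unbound intracellular concentration
referenced through `K_liver:b`. Hepatocytes lose drug irreversibly to
biliary efflux (per-transporter), CYP3A metabolism and non-CYP3A
metabolism. `SF_act` is the single empirical constant of the model: a
scaling factor bridging in-vitro uptake clearance to the in-vivo value,
drug-specific (0.1 for CsA up to 32.6 for atorvastatin).

**Kidney.** The kidney eliminates on its unbound tissue concentration
through an intrinsic filtration constant and an optional secretion constant
assigned to a named transporter. The intrinsic constants map to observable
clearances through the well-stirred form
`CL = f_ub·CL_int·Q_k/(f_ub·CL_int + Q_k)`. Where a drug supplies only an
observed renal clearance, the secretory component is `CL_ren − f_ub·GFR`
(clamped at zero — negative secretion would be reabsorption, outside the
model's scope) and inverted through the well-stirred form. The default
intrinsic filtration constant is `GFR·Q_k/(Q_k − GFR)` = 132.86 mL/min, the
value whose flow-limited clearance for a fully unbound tracer equals GFR;
this reproduces the printed pravastatin/rosuvastatin constant (132.9) and
makes filtration consistent across all drugs. A venous return term
`Q_k·C_k/K_kidney:b` is included so the kidney, which the venous pool
collects from, conserves mass.

**Inhibition.** A co-simulated perpetrator (CsA) divides each inhibitable
clearance by a competitive factor `1 + C_I/K_i`. The comparison
concentration is the total enterocyte concentration in the gut and the
unbound concentration (`f_ub^I·A^I/V`) in hepatic blood, hepatocytes and
kidney, matching the structure of the site-specific rate equations. `K_i`
values in µM are converted to ng/mL with the CsA molar mass (1202.61
g/mol); a molar conversion is the only dimensionally consistent reading.
The perpetrator itself runs uninhibited (no self-inhibition), which makes
its kinetics exactly dose-proportional — consistent with the linearity of
the reference CsA exposures (200 → 500 mg scales Cmax by exactly 2.5).

## Numerical choices

* Units: ng, mL, min throughout; doses converted at entry (1 mg = 1e6 ng);
  `mg/kg` clinical doses interpreted at 70 kg.
* Integration: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol
  1e-6 ng, restarted at each dose event; output on a regular grid of at
  most 2-min spacing plus all event times (post-dose state reported at
  event times). Halving the tolerances moves Cmax/AUC by far less than
  0.1%.
* The single-drug system is linear and time-invariant between doses; the
  test-suite uses a matrix-exponential propagator as an independent
  integration oracle and checks exact mass balance (compartments + sinks =
  dose) to 1e-6 relative along trajectories.
* AUC by trapezoid on the dense grid; windows are always explicit.
  Single-dose summaries and the contribution analysis use 0-24 h post
  dose; multi-dose scenarios use the window of their clinical design
  (e.g. day-28 AUC(0-24), day-8 morning-dose AUC(0-12) for the
  twice-daily bosentan design).
* Plasma concentration = venous blood concentration / `R_b`; comparisons
  use plasma.
* Degenerate inputs: nonpositive doses, unordered events, negative
  clearances, `f_ub` outside (0, 1] and unknown knockout targets are
  rejected with named-field errors; trajectories are clipped at a −1e-9
  ng/mL tolerance and larger negativity raises a solver error.

## Scenarios, knockouts, sensitivity

Fifteen clinical co-administration designs ship as YAML fixtures (doses,
schedules, evaluation windows); where a report stated a total daily CsA
dose given twice daily it is split evenly, and where it stated a
per-administration dose that is used directly. Victim and perpetrator doses
default to simultaneous morning administration unless the design specifies
offsets (repaglinide: 1 h after the morning CsA dose; bosentan: CsA starts
the day-1 evening).

Knockouts come in two modes. *Pathway removal* zeroes a term of the victim
model itself (removing hepatic OATP means only the active
`SF·CL_int,up,OATP` term — passive diffusion persists, so hepatocyte access
and metabolism continue). *Inhibition scope* forces the perpetrator's
inhibition factor to 1 at named sites during a DDI run; the "liver" scope
covers hepatic uptake, hepatic CYP3A and biliary efflux. Sensitivity scans
rerun the full paired simulation per level; `SF` and `CL_int,up` scans are
bit-identical because the two parameters enter only as a product, and the
transit-rate scan scales all six segmental constants jointly (the
alternative — scaling only small-intestinal transit — changes little and
was not adopted).

## Synthetic data and SF estimation

The synthetic generator emulates the statistical structure of sparse
clinical PK data: per-subject log-normal inter-individual variability on
`SF_act`, uptake or metabolic clearance, and multiplicative log-normal
residual noise on the sampled concentrations, all seeded. It reproduces
the model's own kinetics by construction, so passing recovery tests
demonstrates identifiability and estimator correctness under the assumed
error model — not structural adequacy for real patients (no covariates,
genotypes, disease effects, or model misspecification).

`SF_act` is estimated by least squares on log concentrations (profiles span
orders of magnitude, making log residuals the natural weighting; the
original estimation software's objective is not documented) with a bounded
multi-start search in log-SF. The bundled recovery experiment — 50
replicate 12-point atorvastatin profiles at 20% residual CV — recovers the
generating value (32.6) with median error 0.1% and single-profile spread of
roughly ±15%.

## Problem sizes

Default analyses use single-dose 24-h simulations (dense 2-min grid, ~720
points), multi-dose designs up to 28 days (the steady-state transplant
regimens), and 50-replicate recovery experiments; these sizes make every
driver and the full test suite run in minutes on one core while leaving
all reported quantities converged (grid-halving and tolerance-halving
checks are part of the suite).

## Known limitations

* Bile is a terminal sink: no enterohepatic recirculation, which will
  underpredict secondary peaks for biliary-excreted drugs.
* No metabolite kinetics; simvastatin acid is approximated by the parent
  model with an optional absorption lag (default 0).
* The printed lovastatin intestinal parameter row is internally
  inconsistent (its jejunal gut CLint disagrees with the regionalization
  rule that generated the duodenal and ileal values; a validation warning
  flags this) and lovastatin exposures are substantially overpredicted
  against reported means — its predictions should be treated as
  qualitative.
* Transplant patients are modelled with healthy physiology; disease
  effects on renal function (relevant for rosuvastatin) and OATP1B1
  polymorphisms are out of scope.
* CsA inhibition is purely competitive and instantaneous;
  pre-incubation/time-dependent potentiation of OATP inhibition is not
  modelled.
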