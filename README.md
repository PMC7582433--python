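# pbpkddi

Whole-body physiologically based pharmacokinetic (PBPK) modelling of the
**interplay between drug transporters and metabolic enzymes**, applied to
cyclosporin A (CsA) and nine OATP-substrate victim drugs (atorvastatin,
cerivastatin, pravastatin, rosuvastatin, fluvastatin, simvastatin,
lovastatin, repaglinide, bosentan).

The package is for pharmacokineticists and DDI modellers who want a fully
transparent, scriptable implementation of a transporter-enzyme PBPK model:
every parameter is a plain-text fixture, every rate equation is a pure
function, and every published-style analysis (single-drug PK, CsA
drug-drug interactions, pathway knockouts, sensitivity scans) is a short
driver over the library.

## The model

A 22-compartment whole-body ODE system (amounts in ng, time in min):

* **Gut**: stomach and five lumen segments chained by transit constants
  `K_t,i`; absorption in duodenum/jejunum/ileum with
  `k_a,i = 2·P_eff,A-B / r_i`; enterocyte compartments with apical efflux by
  P-gp/BCRP/MRP2 (`k_b,i·T_sf,i`, regionally scaled), CYP3A gut-wall
  metabolism (regional `CL_int,gut` anchored at the jejunum:
  `CL_int,jejunum = 0.51 × 3155.2 × CL_int,microsomal`, scaled to the other
  segments by CYP3A4 abundance 9.7 : 38.4 : 22.4 nmol), and portal outflow.
* **Liver**: hepatic blood and hepatocytes coupled by
  `SF_act·CL_int,up,OATP + CL_int,pd` on the unbound blood concentration,
  with biliary efflux (P-gp/BCRP/MRP2), CYP3A and non-CYP3A metabolism from
  the intracellular space.
* **Kidney**: elimination on the unbound tissue concentration through
  intrinsic filtration and transporter-mediated secretion constants, related
  to observable clearances by the well-stirred form
  `CL = f_ub·CL_int·Q_k / (f_ub·CL_int + Q_k)`.
* **Systemic**: flow-limited tissues (`dA/dt = Q·(C_art − C/K_tissue:b)`)
  with lung between venous and arterial pools at cardiac output.

A co-simulated perpetrator (CsA) inhibits each target competitively: every
inhibited clearance is divided by `1 + C_I/K_i`, with `K_i` = 0.014 µM
(OATP), 2 µM (CYP3A), 0.895 µM (P-gp), 0.28 µM (BCRP), 4.1 µM (MRP2),
converted to ng/mL by the CsA molar mass (1202.61 g/mol). The DDI magnitude
is reported as `AUCR = AUC_with / AUC_without` (likewise `CmaxR`), and model
performance as the absolute average fold error
`AAFE = 10^(mean |log10(pred/obs)|)` with the 0.5-2.0-fold criterion.

## Worked example

```python
import pbpkddi as pk

# single 40 mg oral atorvastatin dose
prof = pk.run(pk.load_drug("atorvastatin"), pk.DoseRegimen.single(40),
              duration_min=24 * 60).victim
s = pk.summarize(prof, (0, 24))
print(s.cmax, s.tmax_h, s.auc)
# 15.63 ng/mL   1.50 h   72.99 ng·h/mL

# same dose with a simultaneous 200 mg CsA dose
r = pk.run_scenario("atorvastatin_csa_200_sens")
print(r.with_inhibitor.cmax, r.aucr)
# 83.77 ng/mL   4.01
```

The first block predicts atorvastatin alone: peak plasma concentration
15.6 ng/mL at 1.5 h and a 0-24 h exposure of 73 ng·h/mL. Co-dosing 200 mg
CsA raises the peak to 84 ng/mL — a four-fold exposure increase produced
almost entirely by inhibition of hepatic OATP uptake, as the knockout
analysis (`analysis/03_contributions.py`) shows: removing active hepatic
uptake from the victim model raises AUC 17-fold, removing hepatic CYP3A
2.6-fold, and any single intestinal pathway less than 1.2-fold.

The same functionality is available from the shell:

```bash
pbpkddi simulate --drug cyclosporine --dose-mg 200 --out csa.csv
pbpkddi ddi --scenario repaglinide_csa_100
pbpkddi sensitivity --parameter SF --levels 0.5,1,2
```

## Analyses

Numbered drivers under `analysis/` rerun the package's main results and
write tables under `results/`:

1. `01_single_drug_pk.py` — Cmax/Tmax/AUC for one representative dose of
   each of the ten drugs, flagged against reported clinical means
   (18/20 exposure parameters within 2-fold).
2. `02_ddi_predictions.py` — AUCR/CmaxR for the bundled co-administration
   designs (repaglinide, bosentan, atorvastatin, pravastatin).
3. `03_contributions.py` — pathway knockouts (victim alone) and
   inhibition-scope runs (DDI) for atorvastatin.
4. `04_sensitivity_scan.py` — 0.5x/1x/2x factor scans of K_i,OATP,
   CL_int,up, SF, CsA dose and gut transit; ranking
   CL_int,up = SF > CsA dose > K_i,OATP > K_t.
5. `05_sf_recovery.py` — recovery of SF_act from 50 synthetic noisy
   datasets (median 32.55 vs truth 32.6).

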