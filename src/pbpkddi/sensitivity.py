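"""Local factor scans over model parameters for a DDI scenario.

Each scan level reruns the full paired simulation with one parameter scaled
and everything else fixed.  Because active hepatic uptake enters the rate
equations only as the product SF_act x CLint,up,OATP, scaling either factor
produces bit-identical trajectories; the scan keeps both rows for the
record.  The transit-rate scan scales all six segmental transit constants
jointly.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .ddi import Scenario, load_scenario
from .metrics import summarize
from .params import (DrugParams, InhibitionParams, PhysioParams, load_drug,
                     load_inhibition, load_physiology)
from .simulate import DoseRegimen, run

SCAN_PARAMETERS = ("Ki_OATP", "CLint_up", "SF", "CsA_dose", "Kt")


def _scaled_regimen(regimen: DoseRegimen, total_mg: float) -> DoseRegimen:
    base = sum(d for _, d in regimen.events)
    f = total_mg / base
    return DoseRegimen(events=[(t, d * f) for t, d in regimen.events],
                       lag_min=regimen.lag_min)


def scan(scenario: Scenario | str, parameter: str, levels,
         physio: Optional[PhysioParams] = None,
         inhibition: Optional[InhibitionParams] = None,
         **sim_opts) -> pd.DataFrame:
    """One paired simulation per level; rows of (parameter, level, Tmax_h,
    Cmax, AUC) for the victim over the scenario window."""
    if parameter not in SCAN_PARAMETERS:
        raise ValueError(f"unknown scan parameter {parameter!r}; "
                         f"valid: {SCAN_PARAMETERS}")
    if isinstance(scenario, str):
        scenario = load_scenario(scenario)
    physio = physio or load_physiology()
    inhibition = inhibition or load_inhibition()
    victim0 = load_drug(scenario.victim)
    inhibitor = load_drug(scenario.inhibitor)
    dur = max(scenario.window_h[1] * 60.0, scenario.victim_regimen.last_time,
              scenario.inhibitor_regimen.last_time) + 1.0

    rows = []
    for level in levels:
        if level <= 0:
            raise ValueError("scan levels must be positive")
        victim, inh, phys = victim0, inhibition, physio
        inh_regimen = scenario.inhibitor_regimen
        if parameter == "Ki_OATP":
            ki = dict(inh.ki_um)
            ki["oatp"] = ki["oatp"] * level
            inh = inh.copy(ki_um=ki)
        elif parameter == "CLint_up":
            victim = victim0.copy(clint_uptake_oatp=victim0.clint_uptake_oatp * level)
        elif parameter == "SF":
            victim = victim0.copy(sf_act=victim0.sf_act * level)
        elif parameter == "CsA_dose":
            inh_regimen = _scaled_regimen(scenario.inhibitor_regimen, level)
        elif parameter == "Kt":
            phys = replace(physio, gi_transit={s: k * level
                                               for s, k in physio.gi_transit.items()})
        res = run(victim, scenario.victim_regimen, phys, inhibitor, inh_regimen,
                  inhibition=inh, duration_min=dur, **sim_opts)
        s = summarize(res.victim, scenario.window_h, scenario.matrix)
        rows.append({"parameter": parameter, "level": level,
                     "tmax_h": s.tmax_h, "cmax_ngml": s.cmax, "auc_ngh_ml": s.auc})
    return pd.DataFrame(rows)


def rank_parameters(tables: dict) -> pd.Series:
    """Sensitivity index per parameter: max |log2(AUC at 2x / AUC at 0.5x)|.

    ``tables`` maps parameter name to its scan DataFrame; for the dose scan
    the outermost levels are used.
    """
    out = {}
    for param, df in tables.items():
        df = df.sort_values("level")
        lo, hi = df.iloc[0]["auc_ngh_ml"], df.iloc[-1]["auc_ngh_ml"]
        out[param] = abs(np.log2(hi / lo))
    return pd.Series(out).sort_values(ascending=False)
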