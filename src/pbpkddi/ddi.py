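"""Co-administration scenarios, AUC/Cmax ratios, and pathway analyses.

Two kinds of perturbation are distinguished:

* **pathway removal** (victim alone): a clearance or efflux term of the
  victim itself is zeroed, quantifying that pathway's contribution to
  disposition;
* **inhibition scope** (DDI): the perpetrator is co-simulated but its
  inhibition is switched off at named sites, quantifying where the
  interaction acts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Tuple

import yaml

from .core import PathwayMask
from .metrics import PKSummary, summarize
from .params import (DrugParams, InhibitionParams, PhysioParams, load_drug,
                     load_inhibition, load_physiology)
from .simulate import DoseRegimen, run

KNOCKOUT_TARGETS = (
    "liver_OATP", "liver_CYP3A", "liver_P-gp", "liver_BCRP", "liver_MRP2",
    "gut_CYP3A", "gut_P-gp", "gut_BCRP", "gut_MRP2",
    "liver_all", "gut_all", "CYP3A_all",
)
_CANON = {t.lower().replace("-", ""): t for t in KNOCKOUT_TARGETS}


@dataclass(frozen=True)
class DDIResult:
    scenario: str
    with_inhibitor: PKSummary
    without_inhibitor: PKSummary
    aucr: float
    cmaxr: float


@dataclass
class KnockoutSpec:
    """mode='pathway': remove victim pathways; mode='scope': disable the
    perpetrator's inhibition at the named sites during a DDI run."""

    mode: str
    targets: tuple = ()

    def __post_init__(self):
        if self.mode not in ("pathway", "scope"):
            raise ValueError("mode must be 'pathway' or 'scope'")
        canon = []
        for t in self.targets:
            key = t.lower().replace("-", "")
            if key not in _CANON:
                raise ValueError(f"unknown knockout target {t!r}; "
                                 f"valid: {KNOCKOUT_TARGETS}")
            canon.append(_CANON[key])
        self.targets = tuple(canon)

    # -- translation into model switches ------------------------------------
    def pathway_mask(self) -> PathwayMask:
        mask = PathwayMask()
        for t in self.targets:
            if t == "liver_OATP":
                mask.active_uptake = 0.0
            elif t == "liver_CYP3A":
                mask.liver_cyp3a = 0.0
            elif t.startswith("liver_") and t != "liver_all":
                mask.bile[t.split("_", 1)[1].lower().replace("-", "")] = 0.0
            elif t == "gut_CYP3A":
                mask.gut_met = 0.0
            elif t.startswith("gut_") and t != "gut_all":
                mask.gut_efflux[t.split("_", 1)[1].lower().replace("-", "")] = 0.0
            elif t == "gut_all":
                mask.gut_met = 0.0
                mask.gut_efflux = {k: 0.0 for k in mask.gut_efflux}
            elif t == "liver_all":
                mask.active_uptake = 0.0
                mask.liver_cyp3a = 0.0
                mask.bile = {k: 0.0 for k in mask.bile}
            elif t == "CYP3A_all":
                mask.liver_cyp3a = 0.0
                mask.gut_met = 0.0
        return mask

    def disabled_sites(self) -> frozenset:
        sites = set()
        trans = {"liver_P-gp": "bile_pgp", "liver_BCRP": "bile_bcrp",
                 "liver_MRP2": "bile_mrp2", "gut_P-gp": "gut_pgp",
                 "gut_BCRP": "gut_bcrp", "gut_MRP2": "gut_mrp2",
                 "liver_OATP": "liver_oatp", "liver_CYP3A": "liver_cyp3a",
                 "gut_CYP3A": "gut_cyp3a"}
        for t in self.targets:
            if t in trans:
                sites.add(trans[t])
            elif t == "gut_all":
                sites |= {"gut_pgp", "gut_bcrp", "gut_mrp2", "gut_cyp3a"}
            elif t == "liver_all":
                sites |= {"liver_oatp", "liver_cyp3a",
                          "bile_pgp", "bile_bcrp", "bile_mrp2"}
            elif t == "CYP3A_all":
                sites |= {"liver_cyp3a", "gut_cyp3a"}
        return frozenset(sites)


# ---------------------------------------------------------------------------
# Scenario fixtures

@dataclass
class Scenario:
    """A clinical co-administration design: regimens, AUC window, matrix."""

    id: str
    victim: str
    victim_regimen: DoseRegimen
    inhibitor: str
    inhibitor_regimen: DoseRegimen
    window_h: Tuple[float, float]
    matrix: str = "plasma"
    note: str = ""


def _parse_regimen(cfg: dict) -> DoseRegimen:
    if "events" in cfg:
        return DoseRegimen(events=[(e["time_h"] * 60.0, e["dose_mg"])
                                   for e in cfg["events"]])
    if "pattern" in cfg:
        p = cfg["pattern"]
        return DoseRegimen.repeated(p["dose_mg"], p["interval_h"], p["n"],
                                    start_min=p.get("start_h", 0.0) * 60.0)
    raise ValueError("regimen config needs 'events' or 'pattern'")


def available_scenarios() -> list:
    root = resources.files("pbpkddi.data").joinpath("scenarios")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(scenario_id: str) -> Scenario:
    path = resources.files("pbpkddi.data").joinpath(f"scenarios/{scenario_id}.yaml")
    try:
        cfg = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown scenario {scenario_id!r}; "
                         f"available: {', '.join(available_scenarios())}") from None
    return Scenario(
        id=cfg["id"], victim=cfg["victim"],
        victim_regimen=_parse_regimen(cfg["victim_regimen"]),
        inhibitor=cfg.get("inhibitor", "cyclosporine"),
        inhibitor_regimen=_parse_regimen(cfg["inhibitor_regimen"]),
        window_h=tuple(cfg["window_h"]), matrix=cfg.get("matrix", "plasma"),
        note=cfg.get("note", ""),
    )


# ---------------------------------------------------------------------------
# Operations

def _duration(window_h, *regimens) -> float:
    return max(window_h[1] * 60.0, *[r.last_time for r in regimens]) + 1.0


def ddi_ratios(victim: DrugParams, victim_regimen: DoseRegimen,
               inhibitor: DrugParams, inhibitor_regimen: DoseRegimen,
               window_h: Tuple[float, float],
               physio: Optional[PhysioParams] = None,
               inhibition: Optional[InhibitionParams] = None,
               matrix: str = "plasma",
               scenario_id: str = "",
               disabled_inhibition: frozenset = frozenset(),
               **sim_opts) -> DDIResult:
    """Paired victim simulations with and without the perpetrator on an
    identical window; returns AUC and Cmax ratios."""
    physio = physio or load_physiology()
    dur = _duration(window_h, victim_regimen, inhibitor_regimen)
    with_res = run(victim, victim_regimen, physio, inhibitor, inhibitor_regimen,
                   inhibition=inhibition, disabled_inhibition=disabled_inhibition,
                   duration_min=dur, **sim_opts)
    solo_res = run(victim, victim_regimen, physio, duration_min=dur, **sim_opts)
    s_with = summarize(with_res.victim, window_h, matrix)
    s_solo = summarize(solo_res.victim, window_h, matrix)
    return DDIResult(scenario=scenario_id, with_inhibitor=s_with,
                     without_inhibitor=s_solo,
                     aucr=s_with.auc / s_solo.auc,
                     cmaxr=s_with.cmax / s_solo.cmax)


def run_scenario(scenario_id: str, **kwargs) -> DDIResult:
    sc = load_scenario(scenario_id)
    return ddi_ratios(load_drug(sc.victim), sc.victim_regimen,
                      load_drug(sc.inhibitor), sc.inhibitor_regimen,
                      sc.window_h, matrix=sc.matrix, scenario_id=sc.id, **kwargs)


def knockout_run(drug: DrugParams, regimen: DoseRegimen,
                 spec: KnockoutSpec,
                 window_h: Tuple[float, float],
                 inhibitor: Optional[DrugParams] = None,
                 inhibitor_regimen: Optional[DoseRegimen] = None,
                 physio: Optional[PhysioParams] = None,
                 inhibition: Optional[InhibitionParams] = None,
                 matrix: str = "plasma", **sim_opts) -> PKSummary:
    """Victim summary under a pathway removal (alone) or a scoped DDI."""
    physio = physio or load_physiology()
    if spec.mode == "pathway":
        regs = [regimen] + ([inhibitor_regimen] if inhibitor_regimen else [])
        res = run(drug, regimen, physio, inhibitor, inhibitor_regimen,
                  inhibition=inhibition, pathway_mask=spec.pathway_mask(),
                  duration_min=_duration(window_h, *regs), **sim_opts)
    else:
        if inhibitor is None or inhibitor_regimen is None:
            raise ValueError("inhibition-scope mode requires a co-simulated inhibitor")
        res = run(drug, regimen, physio, inhibitor, inhibitor_regimen,
                  inhibition=inhibition,
                  disabled_inhibition=spec.disabled_sites(),
                  duration_min=_duration(window_h, regimen, inhibitor_regimen),
                  **sim_opts)
    return summarize(res.victim, window_h, matrix)
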