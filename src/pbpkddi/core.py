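"""Right-hand side of the whole-body PBPK system.

The state vector for one drug holds 22 amount compartments followed by 6
cumulative sinks (all ng):

* GI lumen: stomach and five lumen segments chained by transit constants,
  the colon emptying into a fecal sink;
* enterocytes (gut wall) for the three absorptive segments, with apical
  efflux (P-gp/BCRP/MRP2, regionally scaled), CYP3A gut-wall metabolism and
  portal outflow to the liver;
* systemic flow-limited tissues, arterial/venous pools and the lung in
  series at cardiac output;
* a liver split into hepatic blood and hepatocytes coupled by OATP-mediated
  active uptake (scaled by the empirical factor SF_act) plus passive
  diffusion, with biliary efflux and CYP3A / non-CYP3A metabolism from the
  intracellular space;
* a kidney eliminating by intrinsic filtration and transporter-mediated
  secretion on the unbound tissue concentration.

Every saturable interaction with the perpetrator enters through a
competitive factor 1 + C_I/Ki applied in the denominator of the inhibited
clearance.  With no inhibitor the system is linear and time-invariant, which
the test-suite exploits via a matrix-exponential oracle.

Mass balance is structural: every flux leaving a compartment enters another
compartment or a sink, so the state-vector total is conserved exactly
between dose events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import (ABSORPTIVE_SEGMENTS, DrugParams, InhibitionParams,
                     PhysioParams, derive_absorption_rates,
                     derive_renal_clearances)

# State layout -------------------------------------------------------------
COMPARTMENTS = (
    "stomach", "lumen_duodenum", "lumen_jejunum", "lumen_ileum",
    "lumen_cecum", "lumen_colon",
    "gw_duodenum", "gw_jejunum", "gw_ileum",
    "artery", "venous", "lung", "heart", "brain", "muscle", "skin",
    "adipose", "spleen", "kidney", "rob", "liver_blood", "hepatocytes",
)
SINKS = ("metabolized_gut", "metabolized_liver_cyp3a",
         "metabolized_liver_other", "bile", "urine", "fecal")
STATE_NAMES = COMPARTMENTS + SINKS
N_STATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

_FLOW_TISSUES = ("heart", "brain", "muscle", "skin", "adipose", "rob")

#: Inhibition sites that a scoped DDI run may disable individually.
INHIBITION_SITES = frozenset({
    "gut_pgp", "gut_bcrp", "gut_mrp2", "gut_cyp3a",
    "liver_oatp", "liver_cyp3a", "bile_pgp", "bile_bcrp", "bile_mrp2",
    "renal_sec",
})


class StateError(ValueError):
    """Contract violation on a model state."""


@dataclass
class PathwayMask:
    """Multiplicative knockout switches on the victim's own pathways (1 = intact)."""

    active_uptake: float = 1.0
    liver_cyp3a: float = 1.0
    liver_other: float = 1.0
    bile: dict = field(default_factory=lambda: {"pgp": 1.0, "bcrp": 1.0, "mrp2": 1.0})
    gut_met: float = 1.0
    gut_efflux: dict = field(default_factory=lambda: {"pgp": 1.0, "bcrp": 1.0, "mrp2": 1.0})
    renal_sec: float = 1.0


@dataclass
class InhibitorExposure:
    """Inhibitor concentrations at each interaction site, on the scale each
    rate equation compares against Ki: total concentration in enterocytes,
    unbound in hepatic blood, hepatocytes and kidney (ng/mL)."""

    gut_wall: np.ndarray = field(default_factory=lambda: np.zeros(3))
    liver_blood_u: float = 0.0
    hepatocyte_u: float = 0.0
    kidney_u: float = 0.0

    def __post_init__(self):
        self.gut_wall = np.asarray(self.gut_wall, dtype=float)
        if self.gut_wall.shape != (3,):
            raise StateError("gut_wall exposure must have one entry per absorptive segment")
        if (self.gut_wall < 0).any() or min(self.liver_blood_u, self.hepatocyte_u,
                                            self.kidney_u) < 0:
            raise StateError("inhibitor exposures must be nonnegative")


ZERO_EXPOSURE = InhibitorExposure()


def inhibition_factor(unbound_conc: float, ki_ngml: float) -> float:
    """Competitive inhibition multiplier 1 + C/Ki (>= 1)."""
    if ki_ngml <= 0:
        raise ValueError(f"Ki must be positive, got {ki_ngml}")
    if unbound_conc < 0:
        raise ValueError("inhibitor concentration must be nonnegative")
    return 1.0 + unbound_conc / ki_ngml


class DrugModel:
    """One drug's rate parameters bound to a physiology, ready to evaluate
    the time-derivative of its 28-element amount vector."""

    def __init__(self, drug: DrugParams, physio: PhysioParams,
                 inhibition: Optional[InhibitionParams] = None,
                 pathway_mask: Optional[PathwayMask] = None,
                 disabled_inhibition: frozenset = frozenset()):
        unknown = set(disabled_inhibition) - INHIBITION_SITES
        if unknown:
            raise ValueError(f"unknown inhibition sites: {sorted(unknown)}")
        self.drug = drug
        self.physio = physio
        self.inhibition = inhibition
        self.mask = pathway_mask or PathwayMask()
        self.disabled = frozenset(disabled_inhibition)

        m = self.mask
        self.fub = drug.fub
        self.kt = {s: physio.gi_transit[s] for s in physio.gi_transit}
        rates = derive_absorption_rates(drug, physio)
        self.ka = np.array([rates[s]["ka"] for s in ABSORPTIVE_SEGMENTS])
        # kb * Tsf per transporter per segment, knockout-masked
        self.kb_tsf = {
            t: np.array([rates[s]["kb"].get(t, 0.0) * drug.tsf[t][s]
                         * m.gut_efflux.get(t, 1.0)
                         for s in ABSORPTIVE_SEGMENTS])
            for t in drug.peff_ba
        }
        # lumen-facing efflux clearances (mL/min), Tsf-weighted over segments
        self.cl_lumen = {}
        for t, cl in drug.clint_efflux_lumen.items():
            w = np.array([drug.tsf[t][s] for s in ABSORPTIVE_SEGMENTS])
            self.cl_lumen[t] = cl * (w / w.sum()) * m.gut_efflux.get(t, 1.0)
        self.v_gw = np.array([physio.tissue_volumes[s] for s in ABSORPTIVE_SEGMENTS])
        self.q_gw = np.array([physio.tissue_flows[s] for s in ABSORPTIVE_SEGMENTS])
        self.clint_gut = np.array([drug.clint_gut.get(s, 0.0)
                                   for s in ABSORPTIVE_SEGMENTS]) * m.gut_met
        self.kg_b = drug.k_tissue_blood("intestine")

        self.v = physio.tissue_volumes
        self.q = physio.tissue_flows
        self.ktb = {tis: drug.k_tissue_blood(tis) for tis in
                    ("lung", "heart", "brain", "muscle", "skin", "adipose",
                     "spleen", "kidney")}
        self.ktb["rob"] = drug.k_tissue_blood("rest")

        self.v_hb = physio.v_liver_blood
        self.v_hc = physio.v_hepatocytes
        self.q_ha = physio.q_hepatic_artery
        self.q_h = physio.q_liver
        self.kh_b = drug.k_tissue_blood("liver")
        self.sf_clup = drug.sf_act * drug.clint_uptake_oatp * m.active_uptake
        self.clpd = drug.clint_pd
        self.cl_bile = {t: cl * m.bile.get(t, 1.0) for t, cl in drug.clint_bile.items()}
        self.cl_met_3a = drug.clint_met_cyp3a * m.liver_cyp3a
        self.cl_met_other = drug.clint_met_other * m.liver_other

        renal = derive_renal_clearances(drug, physio)
        self.clint_gfr = renal.clint_gfr
        self.clint_sec = renal.clint_sec * m.renal_sec
        self.sec_transporter = drug.sec_transporter
        self.q_k = physio.tissue_flows["kidney"]
        self.q_total = physio.cardiac_output

    # -- inhibition ---------------------------------------------------------
    def _factor(self, site: str, conc: float, target: str) -> float:
        if self.inhibition is None or site in self.disabled or conc == 0.0:
            return 1.0
        if not self.inhibition.enabled.get(target, True):
            return 1.0
        return inhibition_factor(conc, self.inhibition.ki_ngml(target))

    def exposure_from_state(self, y: np.ndarray) -> InhibitorExposure:
        """Inhibitor-site concentrations when *this* drug is the perpetrator."""
        gw = np.array([y[IDX[f"gw_{s}"]] for s in ABSORPTIVE_SEGMENTS]) / self.v_gw
        return InhibitorExposure(
            gut_wall=np.maximum(gw, 0.0),
            liver_blood_u=max(self.fub * y[IDX["liver_blood"]] / self.v_hb, 0.0),
            hepatocyte_u=max(self.fub * y[IDX["hepatocytes"]] / self.v_hc, 0.0),
            kidney_u=max(self.fub * y[IDX["kidney"]] / self.v["kidney"], 0.0),
        )

    # -- derivative ---------------------------------------------------------
    def rhs(self, y: np.ndarray, exposure: InhibitorExposure = ZERO_EXPOSURE) -> np.ndarray:
        dy = np.zeros(N_STATE)
        c_art = y[IDX["artery"]] / self.v["artery"]

        # GI transit chain: stomach -> duodenum -> ... -> colon -> feces
        dy[IDX["stomach"]] -= self.kt["stomach"] * y[IDX["stomach"]]
        chain = ("stomach", "lumen_duodenum", "lumen_jejunum", "lumen_ileum",
                 "lumen_cecum", "lumen_colon")
        seg_of = {"stomach": "stomach", "lumen_duodenum": "duodenum",
                  "lumen_jejunum": "jejunum", "lumen_ileum": "ileum",
                  "lumen_cecum": "cecum", "lumen_colon": "colon"}
        for prev, cur in zip(chain[:-1], chain[1:]):
            flux = self.kt[seg_of[prev]] * y[IDX[prev]]
            dy[IDX[cur]] += flux
            dy[IDX[cur]] -= self.kt[seg_of[cur]] * y[IDX[cur]]
        dy[IDX["fecal"]] += self.kt["colon"] * y[IDX["lumen_colon"]]

        # absorptive segments: lumen <-> enterocytes, portal outflow, gut metabolism
        portal = 0.0
        for i, seg in enumerate(ABSORPTIVE_SEGMENTS):
            lum, gw = IDX[f"lumen_{seg}"], IDX[f"gw_{seg}"]
            a_gw = y[gw]
            c_gw_i = exposure.gut_wall[i]

            efflux = 0.0
            for t, kbts in self.kb_tsf.items():
                efflux += kbts[i] / self._factor(f"gut_{t}", c_gw_i, t) * a_gw
            for t, cls in self.cl_lumen.items():
                efflux += cls[i] / self._factor(f"gut_{t}", c_gw_i, t) * a_gw / self.v_gw[i]

            absorbed = self.ka[i] * y[lum]
            dy[lum] += efflux - absorbed
            met = (self.fub * self.clint_gut[i]
                   / self._factor("gut_cyp3a", c_gw_i, "cyp3a"))
            c_gw_out = a_gw / (self.v_gw[i] * self.kg_b)
            dy[gw] += (self.q_gw[i] * c_art + absorbed - efflux
                       - (self.q_gw[i] + met) * c_gw_out)
            portal += self.q_gw[i] * c_gw_out
            dy[IDX["metabolized_gut"]] += met * c_gw_out

        # systemic flow-limited tissues -> venous pool
        ven_in = 0.0
        for tis in _FLOW_TISSUES:
            k = IDX[tis]
            ret = self.q[tis] * y[k] / (self.v[tis] * self.ktb[tis])
            dy[k] += self.q[tis] * c_art - ret
            ven_in += ret

        # spleen drains into the liver, not the venous pool
        sp = IDX["spleen"]
        spleen_out = self.q["spleen"] * y[sp] / (self.v["spleen"] * self.ktb["spleen"])
        dy[sp] += self.q["spleen"] * c_art - spleen_out

        # kidney: venous return plus elimination on the unbound concentration
        kid = IDX["kidney"]
        c_kid_out = y[kid] / (self.v["kidney"] * self.ktb["kidney"])
        ret = self.q_k * c_kid_out
        sec = self.clint_sec
        if sec and self.sec_transporter:
            sec = sec / self._factor("renal_sec", exposure.kidney_u, self.sec_transporter)
        elim = self.fub * c_kid_out * (self.clint_gfr + sec)
        dy[kid] += self.q_k * c_art - ret - elim
        dy[IDX["urine"]] += elim
        ven_in += ret

        # liver: hepatic blood <-> hepatocytes
        hb, hc = IDX["liver_blood"], IDX["hepatocytes"]
        c_hb = y[hb] / self.v_hb
        uptake = (self.sf_clup / self._factor("liver_oatp", exposure.liver_blood_u, "oatp")
                  + self.clpd) * self.fub * c_hb
        c_hc_u = self.fub * y[hc] / (self.v_hc * self.kh_b)
        backflux = self.clpd * c_hc_u
        dy[hb] += (portal + spleen_out + self.q_ha * c_art
                   - self.q_h * c_hb - uptake + backflux)
        bile = sum(cl / self._factor(f"bile_{t}", exposure.hepatocyte_u, t)
                   for t, cl in self.cl_bile.items())
        met3a = self.cl_met_3a / self._factor("liver_cyp3a", exposure.hepatocyte_u, "cyp3a")
        dy[hc] += uptake - backflux - (bile + met3a + self.cl_met_other) * c_hc_u
        dy[IDX["bile"]] += bile * c_hc_u
        dy[IDX["metabolized_liver_cyp3a"]] += met3a * c_hc_u
        dy[IDX["metabolized_liver_other"]] += self.cl_met_other * c_hc_u

        # central circulation: venous -> lung -> artery at cardiac output
        ven, lu, art = IDX["venous"], IDX["lung"], IDX["artery"]
        ven_in += self.q_h * c_hb
        dy[ven] += ven_in - self.q_total * y[ven] / self.v["venous"]
        c_lu_out = y[lu] / (self.v["lung"] * self.ktb["lung"])
        dy[lu] += self.q_total * (y[ven] / self.v["venous"] - c_lu_out)
        dy[art] += self.q_total * (c_lu_out - c_art)
        return dy

    def system_matrix(self) -> np.ndarray:
        """Jacobian of the uninhibited (linear) system, assembled column-wise
        from the right-hand side; used by matrix-exponential propagation."""
        m = np.empty((N_STATE, N_STATE))
        for j in range(N_STATE):
            e = np.zeros(N_STATE)
            e[j] = 1.0
            m[:, j] = self.rhs(e)
        return m


class JointModel:
    """Victim and perpetrator integrated side by side; the perpetrator runs
    uninhibited (linear) and its state drives the victim's inhibition factors."""

    def __init__(self, victim: DrugModel, inhibitor: DrugModel):
        self.victim = victim
        self.inhibitor = inhibitor
        self.n = 2 * N_STATE

    def rhs(self, y: np.ndarray) -> np.ndarray:
        if y.shape != (self.n,):
            raise StateError(f"joint state must have length {self.n}")
        y_v, y_i = y[:N_STATE], y[N_STATE:]
        exposure = self.inhibitor.exposure_from_state(y_i)
        return np.concatenate([self.victim.rhs(y_v, exposure),
                               self.inhibitor.rhs(y_i)])
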