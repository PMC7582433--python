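"""Physiological and drug parameters: loading, validation and derived rates.

All quantities use a single unit system: amounts in ng, volumes in mL, time
in min, clearances and flows in mL/min, concentrations in ng/mL.  Oral doses
given in mg are converted at entry (1 mg = 1e6 ng).  Partition coefficients
are stored as tissue:plasma (``kp``) and converted to tissue:blood with the
blood/plasma ratio, K_tissue:b = Kp / Rb, wherever the mass-balance equations
need blood-referenced concentrations.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Optional

import yaml

log = logging.getLogger("pbpkddi")

MG_TO_NG = 1.0e6

ABSORPTIVE_SEGMENTS = ("duodenum", "jejunum", "ileum")
GI_SEGMENTS = ("stomach", "duodenum", "jejunum", "ileum", "cecum", "colon")
TRANSPORTERS = ("pgp", "bcrp", "mrp2")

#: Regional scaling factors for apical efflux transporters, duodenum:jejunum:ileum
#: (ileum normalised to 1).
TSF_DEFAULTS = {
    "pgp": {"duodenum": 0.16, "jejunum": 1.2, "ileum": 1.0},
    "bcrp": {"duodenum": 0.68, "jejunum": 1.45, "ileum": 1.0},
    "mrp2": {"duodenum": 1.27, "jejunum": 1.77, "ileum": 1.0},
}

#: Regional intestinal CYP3A4 abundance (nmol per segment).
CYP3A_ABUNDANCE_NMOL = {"duodenum": 9.7, "jejunum": 38.4, "ileum": 22.4}

#: Total intestinal microsomal protein (mg) and jejunal wet-weight fraction
#: used to scale microsomal gut CLint to whole-segment clearances.
INTESTINAL_MICROSOMAL_PROTEIN_MG = 3155.2
JEJUNAL_WEIGHT_FRACTION = 0.51

_ALIASES = {
    "csa": "cyclosporine", "cya": "cyclosporine", "cyclosporin": "cyclosporine",
    "cyclosporin a": "cyclosporine",
    "ato": "atorvastatin", "cer": "cerivastatin", "pra": "pravastatin",
    "ros": "rosuvastatin", "flu": "fluvastatin", "sim": "simvastatin",
    "lov": "lovastatin", "rep": "repaglinide", "bos": "bosentan",
}

BUNDLED_DRUGS = (
    "cyclosporine", "atorvastatin", "cerivastatin", "pravastatin",
    "rosuvastatin", "fluvastatin", "simvastatin", "lovastatin",
    "repaglinide", "bosentan",
)


class ParameterError(ValueError):
    """A physiological or drug parameter violates its contract."""


# ---------------------------------------------------------------------------
# Physiology

@dataclass(frozen=True)
class PhysioParams:
    """Tissue volumes/flows, GI transit, radii and renal filtration for 70 kg."""

    tissue_volumes: dict
    tissue_flows: dict
    gi_transit: dict
    intestinal_radii: dict
    gfr: float
    cardiac_output: float
    liver_blood_fraction: float = 0.25

    def __post_init__(self):
        for name, v in {**self.tissue_volumes, **self.tissue_flows}.items():
            if v <= 0:
                raise ParameterError(f"volume/flow for {name!r} must be positive, got {v}")
        if self.gfr <= 0:
            raise ParameterError(f"gfr must be positive, got {self.gfr}")
        if tuple(sorted(self.gi_transit)) != tuple(sorted(GI_SEGMENTS)):
            raise ParameterError(
                f"gi_transit must cover exactly {GI_SEGMENTS}, got {sorted(self.gi_transit)}")
        if abs(self.cardiac_output - self.tissue_flows["lung"]) > 1e-9:
            raise ParameterError("cardiac output must equal the lung blood flow")
        if not 0 < self.liver_blood_fraction < 1:
            raise ParameterError("liver_blood_fraction must lie in (0, 1)")

    # Derived structural quantities -----------------------------------------
    @property
    def v_liver_blood(self) -> float:
        return self.liver_blood_fraction * self.tissue_volumes["liver"]

    @property
    def v_hepatocytes(self) -> float:
        return (1.0 - self.liver_blood_fraction) * self.tissue_volumes["liver"]

    @property
    def q_gut_wall(self) -> dict:
        return {s: self.tissue_flows[s] for s in ABSORPTIVE_SEGMENTS}

    @property
    def q_liver(self) -> float:
        return self.tissue_flows["liver"]

    @property
    def q_hepatic_artery(self) -> float:
        """Hepatic arterial flow: total liver flow minus portal contributions."""
        return self.q_liver - self.tissue_flows["spleen"] - sum(self.q_gut_wall.values())


# ---------------------------------------------------------------------------
# Drug

@dataclass
class DrugParams:
    """Per-drug partitioning, binding, clearance, transport and absorption.

    Pathways a drug lacks carry clearance 0, keeping the rate equations
    pathway-complete and purely data-driven.
    """

    name: str
    fub: float
    rb: float
    kp: dict
    clint_met_cyp3a: float = 0.0
    clint_met_other: float = 0.0
    clint_uptake_oatp: float = 0.0
    sf_act: float = 1.0
    clint_pd: float = 0.0
    clint_bile: dict = field(default_factory=dict)
    ka_direct: Optional[float] = None
    peff_ab: Optional[float] = None
    peff_ba: dict = field(default_factory=dict)
    clint_efflux_lumen: dict = field(default_factory=dict)
    clint_gut: dict = field(default_factory=dict)
    clint_gut_microsomal: Optional[float] = None
    tsf: dict = field(default_factory=lambda: copy.deepcopy(TSF_DEFAULTS))
    clren: Optional[float] = None
    clint_gfr: Optional[float] = None
    clint_sec: Optional[float] = None
    sec_transporter: Optional[str] = None
    lag_time: float = 0.0
    molar_mass: Optional[float] = None

    def __post_init__(self):
        if not 0 < self.fub <= 1:
            raise ParameterError(f"{self.name}: fub must lie in (0, 1], got {self.fub}")
        if self.rb <= 0:
            raise ParameterError(f"{self.name}: rb must be positive, got {self.rb}")
        if (self.ka_direct is None) == (self.peff_ab is None):
            raise ParameterError(
                f"{self.name}: exactly one of ka_direct / peff_ab must be provided")
        for fname in ("clint_met_cyp3a", "clint_met_other", "clint_uptake_oatp",
                      "sf_act", "clint_pd", "lag_time"):
            if getattr(self, fname) < 0:
                raise ParameterError(f"{self.name}: {fname} must be >= 0")
        for fname in ("clint_bile", "peff_ba", "clint_efflux_lumen", "clint_gut"):
            for k, v in getattr(self, fname).items():
                if v < 0:
                    raise ParameterError(f"{self.name}: {fname}[{k}] must be >= 0")
        for fname in ("clren", "clint_gfr", "clint_sec", "ka_direct", "peff_ab"):
            v = getattr(self, fname)
            if v is not None and v < 0:
                raise ParameterError(f"{self.name}: {fname} must be >= 0")
        for k, v in self.kp.items():
            if v <= 0:
                raise ParameterError(f"{self.name}: kp[{k}] must be positive")
        self._warn_gut_clint_pattern()

    def _warn_gut_clint_pattern(self):
        """Flag per-segment gut CLint inconsistent with the jejunum-anchored
        CYP3A-abundance regionalization (duodenum < jejunum > ileum)."""
        g = self.clint_gut
        if all(s in g for s in ABSORPTIVE_SEGMENTS) and g["jejunum"] > 0:
            if not (g["duodenum"] <= g["jejunum"] and g["ileum"] <= g["jejunum"]):
                warnings.warn(
                    f"{self.name}: per-segment gut CLint {g} does not follow the "
                    "regional CYP3A abundance pattern (duodenum < jejunum > ileum); "
                    "values kept as supplied", stacklevel=3)

    def k_tissue_blood(self, tissue: str) -> float:
        """Tissue:blood partition coefficient, Kp(tissue:plasma) / Rb."""
        return self.kp[tissue] / self.rb

    def to_config(self) -> dict:
        """Serialisable mapping; ``from_config`` restores every field."""
        d = asdict(self)
        return {k: v for k, v in d.items() if v not in (None,)}

    @classmethod
    def from_config(cls, cfg: dict) -> "DrugParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(cfg) - known
        if unknown:
            raise ParameterError(f"unknown drug parameter fields: {sorted(unknown)}")
        return cls(**cfg)

    def copy(self, **changes) -> "DrugParams":
        new = replace(copy.deepcopy(self))
        for k, v in changes.items():
            setattr(new, k, v)
        return new


@dataclass
class InhibitionParams:
    """Inhibitor (CsA) Ki values per target and the uM -> ng/mL conversion."""

    ki_um: dict
    molar_mass: float = 1202.61
    enabled: dict = field(default_factory=dict)

    def __post_init__(self):
        for target, ki in self.ki_um.items():
            if ki <= 0:
                raise ParameterError(f"Ki for {target!r} must be positive")
        if self.molar_mass <= 0:
            raise ParameterError("inhibitor molar mass must be positive")
        for t in self.ki_um:
            self.enabled.setdefault(t, True)

    def ki_ngml(self, target: str) -> float:
        return self.ki_um[target] * self.molar_mass

    def copy(self, **changes) -> "InhibitionParams":
        new = copy.deepcopy(self)
        for k, v in changes.items():
            setattr(new, k, v)
        return new


# ---------------------------------------------------------------------------
# Loading

def _data_text(relpath: str) -> str:
    return resources.files("pbpkddi.data").joinpath(relpath).read_text()


def load_physiology() -> PhysioParams:
    cfg = yaml.safe_load(_data_text("physiology.yaml"))
    return PhysioParams(**cfg)


def canonical_drug_name(name: str) -> str:
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in BUNDLED_DRUGS:
        raise ParameterError(
            f"unknown drug {name!r}; bundled drugs: {', '.join(BUNDLED_DRUGS)}")
    return key


def load_drug(name_or_config) -> DrugParams:
    """Return validated :class:`DrugParams` for a bundled drug name or a config dict."""
    if isinstance(name_or_config, dict):
        return DrugParams.from_config(name_or_config)
    name = canonical_drug_name(name_or_config)
    cfg = yaml.safe_load(_data_text(f"drugs/{name}.yaml"))
    drug = DrugParams.from_config(cfg)
    missing = [p for p, v in (("CYP3A metabolism", drug.clint_met_cyp3a),
                              ("non-CYP3A metabolism", drug.clint_met_other),
                              ("biliary efflux", sum(drug.clint_bile.values()) if drug.clint_bile else 0.0))
               if v == 0.0]
    if missing:
        log.debug("%s: pathways absent and zeroed: %s", name, ", ".join(missing))
    return drug


def load_inhibition() -> InhibitionParams:
    cfg = yaml.safe_load(_data_text("inhibition.yaml"))
    return InhibitionParams(ki_um=cfg["ki_um"], molar_mass=cfg["molar_mass"])


# ---------------------------------------------------------------------------
# Derivations

def derive_absorption_rates(drug: DrugParams, physio: PhysioParams) -> dict:
    """Per-segment absorption (ka) and per-transporter basolateral-to-apical
    efflux (kb) rate constants, ka_i = 2 Peff_AB / r_i and kb_i = 2 Peff_BA / r_i.

    A drug parameterised with a direct ka uses that value in all three
    absorptive segments.
    """
    out = {}
    for seg in ABSORPTIVE_SEGMENTS:
        r = physio.intestinal_radii[seg]
        ka = drug.ka_direct if drug.ka_direct is not None else 2.0 * drug.peff_ab / r
        kb = {t: 2.0 * p / r for t, p in drug.peff_ba.items()}
        out[seg] = {"ka": ka, "kb": kb}
    return out


def derive_gut_clint(clint_gut_microsomal: float,
                     protein_total: float = INTESTINAL_MICROSOMAL_PROTEIN_MG,
                     jejunal_weight_fraction: float = JEJUNAL_WEIGHT_FRACTION,
                     cyp3a_abundance: dict = None) -> dict:
    """Regionalise a microsomal gut CLint (mL/min/mg) into whole-segment
    clearances (mL/min).

    The jejunum anchors the conversion (fraction x total microsomal protein x
    microsomal CLint); duodenum and ileum scale by their CYP3A4 abundance
    relative to the jejunum.
    """
    if clint_gut_microsomal < 0:
        raise ParameterError("microsomal gut CLint must be >= 0")
    if protein_total <= 0 or not 0 < jejunal_weight_fraction <= 1:
        raise ParameterError("protein mass and jejunal weight fraction must be positive")
    ab = dict(CYP3A_ABUNDANCE_NMOL if cyp3a_abundance is None else cyp3a_abundance)
    if set(ab) != set(ABSORPTIVE_SEGMENTS):
        raise ParameterError(f"CYP3A abundance must cover {ABSORPTIVE_SEGMENTS}")
    if ab["jejunum"] <= 0:
        raise ParameterError("jejunal CYP3A abundance must be positive")
    cl_jej = jejunal_weight_fraction * protein_total * clint_gut_microsomal
    return {seg: cl_jej * ab[seg] / ab["jejunum"] for seg in ABSORPTIVE_SEGMENTS}


def well_stirred(fub: float, clint: float, q: float) -> float:
    """Flow-limited observable clearance, fub*CLint*Q / (fub*CLint + Q)."""
    if clint == 0:
        return 0.0
    return fub * clint * q / (fub * clint + q)


@dataclass(frozen=True)
class RenalClearances:
    clint_gfr: float
    clint_sec: float
    cl_gfr: float
    cl_sec: float


def derive_renal_clearances(drug: DrugParams, physio: PhysioParams) -> RenalClearances:
    """Intrinsic and observable renal clearances.

    Three parameterisations are accepted, in order of precedence:

    1. intrinsic constants supplied directly (``clint_gfr``/``clint_sec``);
    2. an observed renal clearance ``clren``: secretion is CLren - fub*GFR
       (clamped at 0 when filtration already exceeds CLren) and inverted
       through the well-stirred relation to an intrinsic constant;
    3. nothing: glomerular filtration only.

    The default intrinsic filtration constant GFR*Qk/(Qk - GFR) is the value
    whose flow-limited clearance at fub = 1 equals GFR, so the kidney equation
    reproduces CL_GFR = fub*GFR for every drug.
    """
    qk = physio.tissue_flows["kidney"]
    gfr = physio.gfr
    clint_gfr_default = gfr * qk / (qk - gfr)

    clint_gfr = drug.clint_gfr if drug.clint_gfr is not None else clint_gfr_default
    if drug.clint_sec is not None:
        clint_sec = drug.clint_sec
    elif drug.clren is not None:
        cl_sec_obs = max(drug.clren - drug.fub * gfr, 0.0)
        if cl_sec_obs >= qk:
            raise ParameterError(f"{drug.name}: secretory clearance exceeds renal blood flow")
        clint_sec = (cl_sec_obs * qk / (drug.fub * (qk - cl_sec_obs))
                     if cl_sec_obs > 0 else 0.0)
    else:
        clint_sec = 0.0
    return RenalClearances(
        clint_gfr=clint_gfr,
        clint_sec=clint_sec,
        cl_gfr=well_stirred(drug.fub, clint_gfr, qk),
        cl_sec=well_stirred(drug.fub, clint_sec, qk),
    )
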