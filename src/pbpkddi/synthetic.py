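"""Pseudo-observed concentration data with the error structure the analysis
assumes: log-normal inter-individual variability on disposition parameters
and multiplicative log-normal residual noise around the model prediction.

This stands in for clinical profiles when exercising the AAFE machinery and
the SF-recovery workflow; it reproduces the model's own kinetics by
construction and therefore says nothing about structural model error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import DrugParams, PhysioParams, load_physiology
from .simulate import DoseRegimen, run

#: drug fields that inter-individual variability may act on
IIV_PARAMETERS = {"SF": "sf_act", "CLint_uptake": "clint_uptake_oatp",
                  "CLint_met": "clint_met_cyp3a"}


@dataclass
class SyntheticDataset:
    observations: pd.DataFrame   # subject, time_h, conc_ngml
    true_parameters: pd.DataFrame  # subject plus the perturbed parameter values
    seed: int

    def subject(self, i: int) -> np.ndarray:
        df = self.observations
        sub = df[df["subject"] == i]
        return sub[["time_h", "conc_ngml"]].to_numpy()


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-median multiplicative deviate with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_observed(drug: DrugParams, regimen: DoseRegimen,
                      sample_times_h, noise_cv: float = 0.2,
                      n_subjects: int = 1, iiv: Optional[dict] = None,
                      seed: int = 0,
                      physio: Optional[PhysioParams] = None,
                      **sim_opts) -> SyntheticDataset:
    """Per-subject noisy plasma samples plus the true parameters used.

    Each subject's SF/uptake/metabolic clearance is multiplied by a
    log-normal deviate at the stated CV, the model is simulated, and
    residual log-normal noise at ``noise_cv`` is applied to the sampled
    concentrations.  Reproducible by ``seed``.
    """
    times = np.asarray(sample_times_h, dtype=float)
    if times.size == 0:
        raise ValueError("sample_times_h must be nonempty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    iiv = iiv or {}
    unknown = set(iiv) - set(IIV_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown IIV parameters: {sorted(unknown)}; "
                         f"valid: {sorted(IIV_PARAMETERS)}")
    physio = physio or load_physiology()
    rng = np.random.default_rng(seed)
    dur = float(times.max() * 60.0) + 1.0

    obs_rows, par_rows = [], []
    base_clean = None  # shared across subjects when no IIV perturbs the model
    for subject in range(n_subjects):
        factors = {p: float(_lognormal_factor(rng, cv)) for p, cv in iiv.items()}
        changes = {IIV_PARAMETERS[p]: getattr(drug, IIV_PARAMETERS[p]) * f
                   for p, f in factors.items()}
        if changes:
            prof = run(drug.copy(**changes), regimen, physio,
                       duration_min=dur, **sim_opts).victim
            clean = np.interp(times, prof.time_h, prof.plasma_ngml)
        else:
            if base_clean is None:
                prof = run(drug, regimen, physio, duration_min=dur, **sim_opts).victim
                base_clean = np.interp(times, prof.time_h, prof.plasma_ngml)
            clean = base_clean
        noisy = clean * _lognormal_factor(rng, noise_cv, size=times.size)
        for t, c in zip(times, noisy):
            obs_rows.append({"subject": subject, "time_h": t, "conc_ngml": c})
        par_rows.append({"subject": subject,
                         **{IIV_PARAMETERS[p]: changes.get(IIV_PARAMETERS[p],
                                                           getattr(drug, IIV_PARAMETERS[p]))
                            for p in IIV_PARAMETERS}})
    return SyntheticDataset(observations=pd.DataFrame(obs_rows),
                            true_parameters=pd.DataFrame(par_rows), seed=seed)
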