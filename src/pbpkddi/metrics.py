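"""Noncompartmental summaries (Cmax/Tmax/AUC) and model-performance metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .simulate import ConcentrationProfile


@dataclass(frozen=True)
class PKSummary:
    cmax: float          # ng/mL
    tmax_h: float        # h since window start
    auc: float           # ng*h/mL over the window
    window_h: Tuple[float, float]
    dose_mg: float

    def dose_normalized(self, ref_dose_mg: float) -> "PKSummary":
        """Linear rescale to a reference dose (e.g. '10 mg-normalised')."""
        f = ref_dose_mg / self.dose_mg
        return PKSummary(self.cmax * f, self.tmax_h, self.auc * f,
                         self.window_h, ref_dose_mg)


def summarize(profile: ConcentrationProfile,
              window_h: Tuple[float, float],
              matrix: str = "plasma",
              dose_mg: Optional[float] = None) -> PKSummary:
    """Cmax, Tmax and trapezoidal AUC over a stated window of the dense grid."""
    start, end = window_h
    if not start < end:
        raise ValueError(f"window must satisfy start < end, got {window_h}")
    t = profile.time_h
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ValueError(f"window {window_h} h outside simulated span "
                         f"[{t[0]:.2f}, {t[-1]:.2f}] h")
    sel = (t >= start - 1e-9) & (t <= end + 1e-9)
    if sel.sum() < 2:
        raise ValueError("window too narrow for the output grid")
    tt = t[sel]
    cc = profile.concentration(matrix)[sel]
    imax = int(np.argmax(cc))
    return PKSummary(
        cmax=float(cc[imax]),
        tmax_h=float(tt[imax] - start),
        auc=float(np.trapezoid(cc, tt)),
        window_h=(float(start), float(end)),
        dose_mg=float(dose_mg if dose_mg is not None else profile.dose_mg_total),
    )


def aafe(pred, obs) -> float:
    """Absolute average fold error, 10^(mean |log10(pred/obs)|); 1 is perfect."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equally sized, nonempty")
    if (pred <= 0).any() or (obs <= 0).any():
        raise ValueError("AAFE requires strictly positive concentrations")
    return float(10.0 ** np.mean(np.abs(np.log10(pred / obs))))


def fold_check(pred: float, obs: float) -> Tuple[float, bool]:
    """Prediction/observation ratio and whether it falls in [0.5, 2.0]."""
    if obs <= 0:
        raise ValueError("observation must be positive")
    ratio = pred / obs
    return ratio, bool(0.5 <= ratio <= 2.0)
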